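"""CSV/JSON serialization of simulation states, links and run manifests.

Snapshots are one row per cell (tick, cell id, coordinates, phenotype); a
JSON sidecar carries the resolved parameters, seeds and software version so
every output is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .dynamics import ModelParams, SimulationState
from .lattice import Lattice, Phenotype

__all__ = [
    "state_to_frame",
    "links_to_frame",
    "write_snapshot",
    "read_snapshot",
    "write_manifest",
    "read_manifest",
]


def state_to_frame(state: SimulationState) -> pd.DataFrame:
    lat = state.lattice
    coords = lat.coords_array()
    data = {
        "tick": state.tick,
        "cell_id": range(lat.n_cells),
        "x": coords[:, 0],
        "y": coords[:, 1],
    }
    if lat.dim == 3:
        data["z"] = coords[:, 2]
    data["phenotype"] = [Phenotype(c).name for c in lat.phenotypes]
    return pd.DataFrame(data)


def links_to_frame(state: SimulationState) -> pd.DataFrame:
    rows = [
        {"tick": state.tick, "id1": i, "id2": j, "kind": state.link_kind((i, j))}
        for (i, j) in sorted(state.links)
    ]
    return pd.DataFrame(rows, columns=["tick", "id1", "id2", "kind"])


def write_snapshot(state: SimulationState, path) -> None:
    path = Path(path)
    state_to_frame(state).to_csv(path, index=False)
    meta = {
        "dim": state.lattice.dim,
        "side": state.lattice.side,
        "seeding_radius": state.lattice.seeding_radius,
        "tick": state.tick,
        "params": state.params.as_dict(),
        "version": __version__,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_snapshot(path) -> SimulationState:
    """Inverse of :func:`write_snapshot`; exact round trip of the lattice."""
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    dim, side = meta["dim"], meta["side"]
    occupancy = [-1] * side**dim
    positions = [0] * len(frame)
    phenotypes = [0] * len(frame)
    for row in frame.itertuples():
        flat = row.x * side + row.y if dim == 2 else (row.x * side + row.y) * side + row.z
        i = int(row.cell_id)
        occupancy[int(flat)] = i
        positions[i] = int(flat)
        phenotypes[i] = int(Phenotype[row.phenotype])
    lattice = Lattice(
        dim=dim,
        side=side,
        seeding_radius=meta["seeding_radius"],
        occupancy=occupancy,
        positions=positions,
        phenotypes=phenotypes,
    )
    params = ModelParams(**meta["params"])
    return SimulationState(lattice, params, tick=meta["tick"])


def write_manifest(path, **entries) -> None:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Phenotype):
            return o.name
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    payload = {"version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=default))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
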