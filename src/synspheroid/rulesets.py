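"""Named presets: the calibrated baseline, the nine circuit x profile
rulesets, and experiment expansion for replicate sweeps.

A ruleset combines a signaling circuit (1 constitutive, 2 unidirectional,
3 bidirectional) with a homotypic-adhesion profile:

* profile A: (p_a, p_b, p_ab) = (1.0, 1.0, 0.0) — core/pole patterns;
* profile B: (1.0, 0.0, 1.0) — core/shell with a green core;
* profile C: (0.0, 1.0, 1.0) — core/shell with a red core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .dynamics import ModelParams, SeedingSpec

__all__ = [
    "RulesetId",
    "ExperimentSpec",
    "RunConfig",
    "PROFILES",
    "baseline_params",
    "make_ruleset",
    "expand_experiment",
]

PROFILES = {
    "A": (1.0, 1.0, 0.0),
    "B": (1.0, 0.0, 1.0),
    "C": (0.0, 1.0, 1.0),
}

_SEED_MODULUS = 2**31


@dataclass(frozen=True)
class RulesetId:
    circuit: int
    profile: str

    def __post_init__(self):
        if self.circuit not in (1, 2, 3) or self.profile not in PROFILES:
            raise ValueError(f"unknown ruleset {self.circuit}{self.profile}")

    @classmethod
    def parse(cls, text) -> "RulesetId":
        if isinstance(text, RulesetId):
            return text
        m = re.fullmatch(r"([123])([ABC])", str(text).strip().upper())
        if not m:
            raise ValueError(f"cannot parse ruleset id {text!r}")
        return cls(int(m.group(1)), m.group(2))

    def __str__(self):
        return f"{self.circuit}{self.profile}"


def baseline_params() -> ModelParams:
    """The calibrated baseline parameter set (bidirectional circuit)."""
    return ModelParams()


def make_ruleset(ruleset_id, base: ModelParams | None = None) -> ModelParams:
    """Parameters for one of the nine named rulesets (pure function).

    The profile overrides the three adhesion probabilities; the circuit field
    selects which induction arms run and which phenotypes are seeded (the
    seeding itself happens in :func:`synspheroid.dynamics.initial_state`).
    """
    rid = RulesetId.parse(ruleset_id)
    base = baseline_params() if base is None else base
    p_a, p_b, p_ab = PROFILES[rid.profile]
    return base.replace(circuit=rid.circuit, p_a=p_a, p_b=p_b, p_ab=p_ab)


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    seeding: SeedingSpec
    n_ticks: int
    seed: int
    grid_point: tuple = ()
    replicate: int = 0

    def grid_dict(self) -> dict:
        return dict(self.grid_point)


@dataclass(frozen=True)
class ExperimentSpec:
    """A sweep: one ruleset/seeding, an optional parameter grid, replicates.

    ``grid`` maps ModelParams field names (plus the shorthands ``c_i`` and
    ``p_i``, which set both phenotypes' values) to lists of values.  Replicate
    seeds are ``master_seed + running index`` (mod 2^31), so every run in the
    Cartesian product grid x replicates has a distinct, deterministic seed.
    """

    ruleset: str = "3C"
    seeding: SeedingSpec = field(default_factory=SeedingSpec)
    n_ticks: int = 100
    n_replicates: int = 1
    grid: dict = field(default_factory=dict)
    master_seed: int = 0
    base_params: ModelParams | None = None


def _apply_override(params: ModelParams, name: str, value) -> ModelParams:
    if name == "c_i":
        return params.with_c_i(value)
    if name == "p_i":
        return params.with_p_i(value)
    return params.replace(**{name: value})


def expand_experiment(spec: ExperimentSpec) -> list[RunConfig]:
    """Cartesian product of grid values x replicates, each with a unique seed."""
    if spec.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = make_ruleset(spec.ruleset, spec.base_params)
    names = list(spec.grid)
    value_lists = [list(spec.grid[n]) for n in names]
    if any(len(v) == 0 for v in value_lists):
        raise ValueError("empty parameter grid")

    points: list[tuple] = [()]
    for name, values in zip(names, value_lists):
        points = [pt + ((name, v),) for pt in points for v in values]

    configs = []
    idx = 0
    for pt in points:
        params = base
        for name, v in pt:
            params = _apply_override(params, name, v)
        for rep in range(spec.n_replicates):
            configs.append(
                RunConfig(
                    params=params,
                    seeding=spec.seeding,
                    n_ticks=spec.n_ticks,
                    seed=(spec.master_seed + idx) % _SEED_MODULUS,
                    grid_point=pt,
                    replicate=rep,
                )
            )
            idx += 1
    return configs
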