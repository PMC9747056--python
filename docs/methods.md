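# Model and methods

## The system

Spheroids of engineered L929-like cells carry a synthetic bidirectional
juxtacrine circuit built on the synNotch receptor system: seeded **BFP+
sender** cells induce **GFP/N-cadherin** expression in seeded **-/-
receiver** cells on contact, and newly green cells reciprocally induce
**mCherry/P-cadherin** in the remaining BFP+ cells. Because like cadherins
bind strongly and unlike cadherins weakly, the induced adhesion differences
drive cell sorting (the differential adhesion hypothesis), and the interplay
of signaling delays and adhesion strengths selects a multicellular pattern:
core/pole, core/shell, soccer ball, stripes, or bull's eye.

`synspheroid` models this as an on-lattice agent-based model. One square
(2D) or cubic (3D) site is 10 μm — one cell diameter — and holds at most one
cell. One tick is 30 min, so a 50-hour culture is 100 ticks. There is no
proliferation or death: the cell count is constant over a run.

## The per-tick rules

1. **Centripetal movement.** Each cell (fresh random order per tick) moves
   to the unoccupied Moore neighbor closest to the world center, standing in
   for gravity and bulk adhesion collecting cells at the bottom of a
   low-attachment well. Cells with no open neighbor stay. Cells holding
   adhesion junctions are anchored and skip this rule; they move with their
   cluster (rule 2). Compaction completes well before the first cadherin is
   expressed (tick a+Δa = 20), so this anchoring choice only affects the
   sorted phase.
2. **Small-cluster movement.** Each link-connected component with fewer than
   μ cells picks its member nearest the center as leader; the leader steps
   to a uniformly random open Moore neighbor and the component translates
   rigidly with it (which provably preserves connectivity). Bystanders on
   target sites relocate uniformly at random into the vacated sites.
   Junctions stretched beyond Moore adjacency by any move detach.
3. **Induction.** From tick *a* on, each -/- receiver with n ≥ 1 BFP+ Moore
   neighbors commits to GFP/Ncad with per-tick probability
   P = 1 − exp(−c_a·n/n_max), n_max = 8 (2D) or 26 (3D); from tick *b* on,
   each BFP+ cell next to an expressed GFP/Ncad cell commits to mCherry/Pcad
   with the analogous c_b probability. A committed cell changes color and
   becomes adhesive Δa (resp. Δb) ticks later. Circuit 2 runs only the first
   arm with seeded mCherry/Pcad senders; circuit 1 seeds both cadherin
   phenotypes directly and performs no induction.
4. **Adhesion and switching.** Every unlinked, non-cooldown pair of adjacent
   cadherin-expressing cells links with probability P_a (green–green), P_b
   (red–red) or P_ab (green–red). Then position switching: a cadherin cell
   wedged between two cells of the other cadherin type on a collinear
   cardinal triple swaps with one flank with that type's homotypic
   probability (making the two like cells adjacent); a non-cadherin cell
   separating unlike cadherin cells swaps with probability P_ab. **The
   switching cell swaps with the flank farther from the spheroid center**,
   so displaced material drifts outward — see "Design choices" below.
5. **Link breaking.** Within each link-connected component, ⌈L/2⌉ of its L
   junctions break, chosen uniformly; a broken pair cannot re-link for
   t_reform ticks. A per-link Bernoulli(0.5) variant is available
   (`break_per_link=True`).

### Parameters (baseline values)

| name | value | meaning |
|---|---|---|
| a, Δa | 10, 10 ticks | green induction delay / expression lag |
| b, Δb | 25, 10 ticks | red induction delay / expression lag |
| μ | 5 cells | largest movable linked cluster |
| t | 3 ticks | junction re-form cooldown |
| c_i (= c_a = c_b) | 0.20 | induction constant |
| P_i (= P_a = P_b) | 0.95 | homotypic adhesion probability per tick |
| P_ab | 0.05 | heterotypic adhesion probability per tick |

The delays place first green expression no earlier than tick 20 and first
red no earlier than tick 35, anchoring the experimental appearance times
(13 h → tick 26, 21 h → tick 42 at 30 min/tick). `tick_minutes` is metadata:
changing it rescales reported hours only; a caller who wants a finer grid
must rescale a, b, Δa, Δb and t accordingly.

Profiles override the adhesion triple: A = (1, 1, 0) → core/pole,
B = (1, 0, 1) → core/shell with green core, C = (0, 1, 1) → core/shell with
red core. Circuits 1–3 times the signaling as above; circuit × profile gives
the nine named rulesets 1A…3C.

## Seeding

Cells are placed uniformly at random on distinct sites of a disk/ball of the
given radius. With a radius given, the disk fills to `saturation` (default
1.0). With a cell count given, the radius defaults to the smallest one whose
disk holds the cells at ~90% saturation, so the centripetal rule has room to
compact the aggregate. The sender:receiver split is `round(n·r/(s+r))`
receivers (ties up), reproducing the exact splits for the published ratios
at 60 and 200 cells.

One experiment family states "~350 cells" at "radius 6.4 px", which is
geometrically impossible (a radius-6.4 disk holds 129 sites). Both seedings
are supported; the soccer-ball experiment preset and the acceptance script
use the stated cell count (350, auto radius 11.2 px). This matters: in
129-cell spheroids the largest same-color cluster of the final random mosaic
frequently exceeds 40% of its color (a percolation finite-size effect) and
the multicluster pattern test then fails, which at 350 cells it almost never
does.

## Pattern quantification

A *cluster* is a cardinal-connected group of ≥ 3 same-color cells (scipy
`ndimage.label` with the cardinal structuring element); smaller groups count
as individual cells. Per color we report the cell fraction, mean cluster
size over total cells, mean cluster-centroid distance to the spheroid center
over the spheroid radius, cluster/individual counts, and bounding-box
width/height circularities. The spheroid center is the centroid of all cells
at the measured tick (spheroids drift off the seeding center; the world
center is available via `center_mode="world"`), and the radius is the
maximum cell distance from it.

The *core* is the cluster minimizing the mean distance to all other
clusters, where cluster-to-cluster distance is the minimum member-to-member
separation (single linkage): the enclosed central cluster touches every
cluster around it and wins. (A centroid-based distance was tried first and
can misidentify the core in core/shell states — a shell arc, or a small
non-adhesive cluster near the middle, can beat the true core on mean
centroid distance.) In two-cluster states the criterion ties structurally;
ties break toward the inner cluster (smallest maximum member distance from
the joint centroid of clustered cells), then the larger one, then the
phenotype name. The inner-first rule is what makes an enclosed core beat
its larger enclosing shell. The *contiguous area fraction* is the
share of the core cluster's perimeter cells (those with a cardinal neighbor
outside the cluster) touching the other adhesive color. *Enclosure* of a
non-adhesive group means > 75% of its perimeter cells touch the enclosing
color; the same ≥ 3 size floor as for clusters is applied (a documented
divergence risk — the source material says "groups" without a floor).

## Pattern labeler

`label_pattern` is a deterministic cascade with explicit thresholds
(`AtlasThresholds`): first dominant-central-core tests — a color whose
largest cluster holds > 50% of its cells, sits within half the spheroid
radius of the center, and occupies the center (a member within 2 sites;
this excludes hollow rings) is a core; perimeter coverage by the other
adhesive color > 0.8 makes it core/shell, otherwise core/pole. Then the
multicluster tests — ≥ 4 clusters of each adhesive color, none holding
> 40% of its color: mean circularity in [0.5, 2] → soccer ball, outside →
striped. Then bull's eye: ≥ 2 alternations of the ≥ 70%-majority color
across 6 equal annuli. Else "other". The 0.8 shell-coverage value separates the coverage distributions of
profile-B core/shell states (a few unconverted cells always interrupt the
shell, keeping coverage below 1) from profile-A core/pole states; a 0.9
cut misclassifies most genuine shells as poles.

k-means (z-scored features, elbow rule on the within-cluster deviation
curve, largest second difference) and tSNE are provided for the unsupervised
atlas view; quantitative claims always use the heuristic labeler, because
mapping k-means groups to pattern names requires visual inspection of
representatives.

## Calibration

The univariate sensitivity of output y to parameter x is
S = (y_b − y_p)/|x_b − x_p| · x_p/y_p, computed on 100-replicate means with
common random numbers at base and perturbed values. Probability parameters
clip at 1 (so P_i·1.1 → 1.0, recorded as such). For the integer parameters
μ and t a ±10% perturbation rounds back onto the base value; the
implementation then steps ±1 instead and records the value actually used.
Note that for the three small-magnitude parameters the 10% perturbation is
tiny in absolute terms, so the coefficient amplifies replicate noise
considerably; rankings between parameters of similar true sensitivity are
not stable at 100 replicates.

The evolutionary algorithm minimizes E = (exp(Σ_j |y_j − Y_j|) − 1)² over
(c_i, P_i), where the seven outputs are the green/red/blue cell fractions,
green/red mean fractional cluster areas, and green/red cluster counts.
Defaults follow the published protocol: population 20, 100 generations,
10-replicate error averaging, crossover 0.5, mutation 0.8, 30 restarts.
The selection operator, mutation kernel and bounds are not published;
we use binary tournament with elitism 1 (the elite's stored error is
never re-evaluated, making the best-so-far trace nonincreasing), uniform
gene-swap crossover, Gaussian mutation with σ = 10% of the range reflected
at the bounds [0, 5] for c_i and [0, 1] for P_i. Recovery is validated on
synthetic targets generated at known parameters; the original in vitro
image targets are out of scope.

## Design choices where the rules were open

* **Switch direction (the load-bearing one).** The source description says
  only that wedged/separating cells "switch places". With an unbiased flank
  choice, a fully compacted aggregate cannot sort: the movement rules need
  vacancies, switching is then the only transport, and unbiased switching
  only coarsens locally — core identification stays at chance in every
  core/shell ruleset. Directing each switch so the switching cell takes the
  farther-from-center flank position gives displaced cells a net outward
  drift, the same asymmetry the centripetal movement rule encodes, and
  reproduces the published phenomenology: the strongly homotypic
  phenotype cores ≈ 98% of profile-B/C runs (recomputed by
  `scripts/acceptance.py`) with clear green/red radial segregation. The
  unbiased variant remains available (`switch_outward=False`).
* Linked cells are anchored against individual centripetal movement, since
  junctions must stay Moore-adjacent; clusters move via rule 2.
* Cluster movement translates components rigidly; "clusters" for movement
  are link-connected components, while "clusters" for metrics are cardinal
  color components — deliberately distinct definitions.
* Induction delays a and b count from tick 0, not from first contact.
* Switching runs after link formation within a tick
  (`switch_before_link=False` to flip); displaced bystanders relocate only
  into vacated sites (no cascading displacement).
* Link breaking removes a fixed ⌈L/2⌉ per component rather than per-link
  coin flips (variant available); cooldowns are per cell pair.
* Circuit 1 seeds a 1:1 green:red split (constitutive expression with both
  adhesive types present from tick 0); a variant retaining a non-adhesive
  population is selectable through the seeding phenotypes.

## What the simulations do and do not show

All quantitative checks run on simulated lattices and hand-specified label
grids. The synthetic-data fixtures emulate idealized geometries (disks,
annuli, blocks) with exactly known metrics; they contain no microscope
noise, thresholding artifacts, uneven illumination, or cell-size
variability, so passing metric tests says nothing about robustness to real
image segmentation. Model-level claims (core fractions, pattern
frequencies) are statements about this reconstruction of the rules, whose
underdetermined details (switch direction, movement anchoring) were fixed
as described above; the in vitro comparisons of the source study are not
reproduced here.

Problem sizes used by the test suite and the acceptance script: 100
replicates per condition; 200-cell spheroids for ruleset comparisons
(400 agents for the in-vitro-scale seeding-ratio checks, matching the
doubled-seeding convention); 350 cells for the zero-adhesion pattern
experiment; radius 6.4 px (129 cells) for enclosure counting; 300 ticks for
radius sweeps and zero-adhesion runs, otherwise 100–200 ticks. The EA
recovery test uses 60-cell spheroids, 50 ticks, and a reduced protocol
(population 10, 20 generations, 3 replicates, 5 restarts).

## Known limitations

* No proliferation, apoptosis, cadherin downregulation, expression
  heterogeneity, or diffusible morphogens; no off-lattice or Potts-style
  energy minimization.
* The enclosure statistic sits at the hot edge of the published ~12–20%
  band (22–30% at radius 6.4, depending on seeds): straight one-cell-wide
  red streaks inside the green core are stable under cardinal wedge
  switching and count as fully enclosed groups. A diagonal-line wedge
  variant removes such streaks (and nearly all enclosures with them); the
  cardinal rule is the one the model definition names, and it is what
  ships.
* Sensitivity rankings among weakly sensitive parameters are noise-limited
  at the published replicate count (see Calibration).
* 3D support is implemented throughout the lattice, dynamics and
  composition metrics, but the cluster-shape metrics (circularity) keep
  their 2D width/height definition.
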