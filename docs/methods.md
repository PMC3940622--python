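# Methods

`hedgewalk` simulates the movement of central-place-foraging pollinators
(solitary bees, bumblebees) through agricultural landscapes, and measures
how two common stewardship interventions — converting whole fields to wild
set-aside, and removing hedgerows — change that movement. This note
documents the model, its parameters, the numerical and design choices made
where the design was open, and what the test suite does and does not
establish.

## Landscape model

A landscape is a rectangular grid of unit cells (default 1000 × 1000). A
number of *field seeds* (default drawn uniformly from [101, 200]) is placed
on distinct uniformly random cells, and every cell joins the field of its
nearest seed — a grid-based Voronoi tessellation. Distance is Euclidean
between cell centres, computed in exact integer arithmetic so that ties are
well-defined; ties go to the lowest field id, which makes the assignment
independent of the order seeds are listed in.

Cells on the boundary between two fields are classified as wild habitat
("hedgerows"); everything else is cultivated crop. The classification is a
*one-sided* scan: a cell is wild iff its right or lower neighbour belongs
to a different field. Marking one side only keeps every field–field
interface exactly one cell wide (the naive "any differing neighbour" rule
marks both sides and doubles the thickness). Grid-border cells are compared
only against in-grid neighbours; the border itself is not automatically
wild.

### Corridor-network connectivity: a deliberate and consequential property

The one-sided single-thickness rule has a subtle consequence that turns out
to drive one of the package's headline results. Along axis-aligned
boundaries the wild strip is orthogonally connected, but along staircase
(oblique) boundaries consecutive strip cells meet only at corners. The
corridor network is therefore:

* **connected as a geometric object** — under 8-adjacency (corner contacts
  count) a generated landscape's wild cells almost always form a single
  component (occasionally a corner-clipped hedge whose both ends terminate
  on the grid border forms a second one);
* **heavily fragmented under orthogonal adjacency** — the adjacency the
  walker actually uses. A 250 × 250 landscape with 101–200 fields typically
  splits into several hundred orthogonal fragments.

Because walkers move orthogonally, a habitat specialist (switching
reduction r = 0, below) is confined to the fragment its nest sits on, which
is often small. Converting fields to wild set-aside merges fragments into
large contiguous wild areas, which is why set-asides markedly extend
specialist foraging distance in the set-aside protocol. We verified that an
alternative edge rule restoring orthogonal connectivity (adding a diagonal
comparison to the scan) eliminates that distance response almost entirely;
the fragmenting one-sided rule is the one consistent with the behaviour
this model family reports, and is retained as the package's definition of
single thickness. `wild_components(grid, diagonal=...)` exposes both views
so users can audit the distinction.

Nests are placed on a uniformly random wild cell (a landscape with a single
field has no wild cells and raises an error).

## Movement model

A walker occupies one cell and carries a heading — the absolute direction
(N/E/S/W) of its previous move. Relative to the heading it can step
forward, backward, left or right with base probabilities `p_F`, `p_B` and
`p_S` (each side), `p_F + p_B + 2 p_S = 1`. The protocols construct the
kernel from a forward bias `p_F` and a constant `v ∈ [0, 1]`:

    p_S = (1 − p_F)/3 + v (1 − p_F)/6,     p_B = 1 − p_F − 2 p_S.

`v` tilts the non-forward mass from "all three residual directions equal"
(v = 0) to "no backward steps" (v = 1).

Habitat preference enters as a multiplicative switching reduction
`r ∈ [0, 1]` on the preference for entering a cell whose habitat differs
from the current cell:

    m_i = p_i        if c_i = c_current
    m_i = r · p_i    otherwise,

and the realised move probabilities are `a_i = m_i / Σ m`. `r = 1` is
habitat-neutral; `r = 0` forbids switching entirely (specialists).

Decisions the source model family leaves open, resolved as follows:

* **Initial heading** — drawn uniformly from the four directions at t = 0.
* **Grid border** — off-grid neighbours get `m_i = 0` and the remaining
  directions renormalise; walkers cannot leave the grid. Border contact is
  counted per walk and reported (`border_contacts`) so its influence can be
  audited; with interior nests at full scale it is rare.
* **Σm = 0** — the walker stays in place for that timestep with heading
  unchanged; the timestep still counts toward `prop_wild`. Reachable only
  for r = 0 on an isolated wild cell, or in a grid corner.
* **Summary-statistic denominators** — the three per-walk statistics are
  computed over the T post-move positions (the nest cell at t = 0 is
  excluded): `max_distance` is the maximum Euclidean distance from the
  nest in grid units; `n_switches` counts habitat changes between
  consecutively occupied cells (a stay can never switch); `prop_wild` is
  the fraction of post-move positions on wild cells.

The per-walk loop inlines the step logic for speed; the step-level
functions (`adjusted_preferences`, `step_probabilities`, `step`) define the
contract and the tests check the loop against them distributionally, plus
against the closed-form mean squared displacement E[d²] = T of the
symmetric lattice walk (p_F = p_B = p_S = 1/4, r = 1).

## Interventions

* **Set-aside conversion** — k further fields chosen uniformly among the
  not-yet-converted are filled entirely with wild habitat. Field
  membership never changes, so conversion is cumulative bookkeeping over
  the habitat raster. All fields are eligible regardless of size.
* **Hedge removal** — an individual hedge is the strip of wild cells
  between one specific pair of adjacent fields: a wild cell belongs to the
  hedge (A, B) iff its own field is A or B and the set of field ids among
  itself and its orthogonal neighbours is exactly {A, B}. Junction cells
  touching ≥ 3 fields belong to no hedge and are never removed — they are
  the vertices of the corridor network, hedges are its edges. Removal sets
  the member cells back to crop, cumulatively; enumeration is defined on
  the basal landscape and removal state is tracked separately. If the nest
  cell itself is removed, a new nest is drawn from the remaining wild
  cells and the redraw is logged.

## Experiment protocols

All protocols share the repeated-measures design: per environment, a
landscape, a nest and the nuisance movement parameters are drawn once, and
one independent walk is run at every level of the systematic variable.
Randomness is a `SeedSequence` spawn tree (environment → named substreams
for landscape / nest / parameters / manipulation / per-level walks), so
results are byte-reproducible and adding levels or environments never
perturbs existing ones. Environments violating a protocol's preconditions
(no wild cell, fewer hedges than the removal schedule needs) are redrawn
and counted.

| protocol | systematic variable | nuisance draws per environment |
|---|---|---|
| M1 | p_F ∈ {0.25, 0.375, …, 0.875} | r ~ U(0,1), v ~ U(0,1) |
| M2 | r ∈ {(2/3)⁰, …, (2/3)¹³} | p_F ~ U(0.25,1), v ~ U(0,1) |
| M3 | set-asides 0, 5, …, 50 | p_F ~ U(0.25,1), v, r ~ U(0,1) |
| M3a | set-asides 0, 5, …, 50 | as M3 with r = 0; distance only |
| M4 | hedges removed 0, 4, …, 40 | as M3 |
| M4a | hedges removed 0, 4, …, 40 | as M3 with r = 0; distance only |

Defaults are the full study conditions (1000 environments, 1000 × 1000
cells, T = 1000 timesteps); desk runs pass a smaller `ExperimentConfig`.
The factorial sensitivity sweep crosses one axis — p_F (0.1…0.9), p_S
(0…0.45, with p_F = (1 − 2 p_S)·U[0,1] so p_B ≥ 0 by construction), r
(0…0.9), or the seeded field count (101…200 in six steps; the levels are a
package choice, the source protocol names the axis but not its grid) —
against a manipulation schedule, with 1000 randomised nuisance sets by
default and one walker per grid point; it reports per-point means and
standard deviations.

## Statistical analysis

Each movement statistic is modelled as a linear mixed model against the
systematic variable coded categorical, with the environment as a random
intercept, fitted by maximum likelihood (ML rather than REML because the
likelihood-ratio test compares models differing in fixed effects). The LRT
statistic is 2·(logLik_full − logLik_null) on (levels − 1) degrees of
freedom. Significant LRTs are followed by all-pairs Wald contrasts of level
means with Holm familywise adjustment (recorded in the result metadata; a
single-step multivariate-t adjustment would be marginally less
conservative but is not available in the fitting library). Fitting is
delegated to statsmodels `MixedLM` with two robustness guards: a fallback
chain of optimizers (the default can fail with a singular Hessian when the
random-intercept variance collapses to the boundary) and rejection of
fits reporting non-finite log-likelihoods. Tables with zero response
variance short-circuit to χ² = 0, p = 1, flagged `degenerate`.

The type-I error of this harness, measured on 1000 null tables
(run effect + noise, no level effect; 30 runs × 6 levels), sits near 6% at
α = 0.05 — the mild liberality expected of an asymptotic χ² reference at
this group count.

## Test scales and what passing shows

The full study conditions are too heavy for routine testing, so the
acceptance suite runs scaled replications: 250 × 250 landscapes with the
full field-count range [101, 200] and full-length walks (T = 1000), with
100 environments for the trend replications (800 for the forward-bias
protocol, where resolving adjacent level medians needs median standard
errors below the ~5-grid-unit gap between the closest levels). These sizes
are the package's choice of desk scale; absolute χ² magnitudes and median
values are not comparable across scales. One direction-of-effect is not
scale-robust: the wild-time response to the switching reduction r depends
on corridor fragment length, which shrinks with the grid (reluctant
switchers leak out of short fragments, flattening the trend), so the
switching-reduction protocol is replicated at the full 1000 × 1000
landscape geometry with 100 environments.

The synthetic data here *is* the study system — the generator implements
the study conditions rather than emulating an external dataset. What
passing tests do not show: anything about real agricultural rasters
(field-shape distributions, non-uniform hedgerow widths, >2 habitat
classes), about movement rules richer than a first-order correlated walk
(memory, traplining, state dependence, resource depletion), or about
multi-forager systems. Those are explicit non-goals.

## Known limitations

* The one-sided edge rule makes orthogonal corridor fragmentation a
  structural feature (see above); users wanting orthogonally connected
  corridors must supply their own habitat raster.
* Walkers cannot leave the grid; at small grid sizes with long walks the
  forbidden border measurably compresses `max_distance` (audit via
  `border_contacts`).
* The LRT harness is mildly liberal at small group counts (see
  calibration above).
* `enumerate_hedges` assigns junction cells to no hedge; a removal
  schedule can therefore never disconnect the network at its vertices,
  only along its edges.
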