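# Methods

## The model

`combmorph` simulates the rotation of the male *Drosophila melanogaster*
sex comb (SC) — a row of modified bristles on the first tarsal segment of
the foreleg that turns from a near-horizontal to a near-vertical
orientation during pupal development — with a two-dimensional cellular
Potts model (CPM) of the surrounding epithelium. The driving hypothesis is
the *push* model: epithelial cells distal to (below) the comb expand their
apical areas, and the spatial and temporal pattern of that expansion
supplies the torque that rotates the comb about its base. Proximal cells
(above the comb) respond passively, shrinking and sometimes extruding from
the epithelium.

The tissue is a lattice of `n_x x n_y = 114 x 84` unit pixels, periodic in
x (the leg is a cylinder) and open in y, with a frozen two-row "barrier"
(BA) at the bottom. Each pixel carries a cell index; a cell is the set of
pixels with that index and belongs to one of five types: EP1 and EP2
(distal epithelium, base-adjacent and tip-adjacent respectively), EP3
(proximal epithelium), SCT (comb teeth, 6 x 6-pixel cells), and BA. The
effective energy is

    H = H_boundary + H_length + H_area
    H_boundary = sum over heterocellular contact pairs of J(c_i, c_j)
    H_length   = sum over cells of lambda_l (l - l_target)^2
    H_area     = sum over cells of lambda_a (a - a_target)^2

with contacts taken over the von Neumann (4-pixel) neighbourhood. Dynamics
are Metropolis pixel-copy attempts: per Monte Carlo step (mcs) the engine
draws 9576 target pixels uniformly, each with a uniform Moore (8-pixel)
flip neighbour, and accepts each proposed re-labelling with probability
min(1, exp(-dH/T)) at T = 100. Attempts whose neighbour falls outside the
open y-boundaries, same-cell pairs, and any attempt touching a BA cell are
rejected no-ops. Runs last 2000 mcs.

### Contact-energy counting

Every heterocellular contact contributes its adhesion coefficient J
**once** — the convention of the standard CPM contact-energy
implementations — so published J tables (epithelial pairs 1000,
epithelium–tooth 10000, tooth–tooth the experimental variable) keep their
meaning relative to the area and length stiffnesses. Writing the boundary
sum over ordered pixel pairs would double every interface tension relative
to those stiffnesses; in calibration runs that variant visibly degraded
rotation (final angles ~33 degrees instead of ~46, inter-tooth angle SD
~34 instead of ~26 degrees, and far more mid-adhesion breaking), so the
single-count convention is used throughout. J rows involving the frozen BA
type are set to 0; they can never drive dynamics and this keeps flips next
to the barrier free of spurious terms.

### Cell length

`l(sigma)` is the principal-axis length: `sqrt(12 * lambda_max)` of the
covariance matrix of the cell's pixel centres plus the unit-square smear
`I/12` (each pixel treated as a 1 x 1 square). Under this convention a
filled `s x s` square has length exactly `s`, a single pixel has length 1
with no special case, and a square cell at rest satisfies its target
`l_target = ceil(sqrt(a_target))` exactly. Coordinates are unwrapped by
minimal image in x; cells are required to stay narrower than half the
lattice (checked at construction for generated configurations), which all
simulated cells satisfy by an order of magnitude.

### Bookkeeping and retired cells

Per-cell area, coordinate sums and covariance sums are maintained
incrementally per accepted flip; `LatticeState.check_consistency()`
recomputes them from the grid and is exercised by the test suite. A cell
whose area reaches 0 is retired and never reappears; it keeps contributing
the constant `lambda_a a_target^2 + lambda_l l_target^2` (its length is
defined as 0), so H remains an exact state function across cell death and
the incremental dH equals the global recomputation everywhere. For
extruded cells both targets are 0, so the residual constant vanishes.

### Axial expansion preference

Distal cells expand preferentially along y. During a flip attempt, the
area term of the target and invading cells whose type has an axial
parameter epsilon > 0 is weighted by

    1 - epsilon * (1 - sin^2(theta) / R)

where theta and R are the direction and length of the vector from that
cell's **pre-flip** centre of mass to the target pixel; the same pre-flip
geometry is used in both the before and after energies of the attempt, so
the weighted term is a state function per attempt (not globally — exact
reversibility holds for epsilon = 0). R is clamped below at 0.5 pixel
because the weight diverges as R -> 0; such proposals are geometrically
rare and the clamp bounds the factor. epsilon = 0.03 for EP1/EP2, 0 for
all other types. In double-resolution mode (228 x 168 lattice, 38304
attempts/mcs, all areas x4 and lengths x2) R is replaced by R^2 to
preserve the relative scale.

## Time-dependent rules

Every `dt = 10` mcs the target area of each live, non-extruded epithelial
cell relaxes toward its type's terminal value:

    a_target(t + dt) = a_target(t) * (1 + (a_term / a_target(t) - 1) * dt / tau)

the Euler form of `da/dt = (a_term - a)/tau`, whose iterate has the exact
closed form `a_term + (a0 - a_term)(1 - dt/tau)^(t/dt)` used as the test
oracle. Each update also resets `l_target = ceil(sqrt(a_target))`. SCT and
BA targets never change. The terminal targets and time constant depend on
comb length (the experimental rotation time grows with comb length):

| teeth | a_term(EP1) | a_term(EP2) | tau (mcs) |
|------:|------------:|------------:|----------:|
| 5     | 9           | 13          | 100       |
| 7     | 9           | 13.2        | 160       |
| 9     | 9.8         | 12.8        | 220       |
| 11    | 9.8         | 12.6        | 280       |

EP3 contracts from a starting target of 9 toward 5 px with the same tau
(lambda_a = 500, i.e. much softer than the distal cells' 1e4). An EP3 cell
squeezed below 3 pixels is extruded: its a_target and l_target collapse to
0 under a stiffness of 1e6 (large against every other energy scale while
keeping energies finite), the marking is irreversible, and the cell is
promptly consumed by its neighbours. A type may start expanding late
(`expansion_delay`, applied per type at the update cadence); delaying EP1
by ~120 mcs is the temporal-sequence intervention studied for long combs.

## Initial configurations

The generator is deterministic (no RNG). It lays two BA rows at the
bottom; places `n_teeth` 6 x 6 SCT cells in a contiguous chain with the
base (pivot) tooth at `base_anchor` and each following tooth 6 px toward
-x and raised to follow `initial_angle`; tiles the distal band between
barrier and comb with rectangular EP cells; and tiles everything above
with 9-px EP3 cells. Ragged pixels at region boundaries are absorbed by
the adjacent cell so every pixel is assigned exactly once. Persistent
tooth ids are recorded base-to-tip for the morphometrics.

Distal seed areas decay from `area_near_base` (9.8 px) at the base to
`area_near_tip` (3.3 px) at the tip; cells in the base half are EP1,
tip half EP2 (demarcation at the comb's half-length, mirroring the
experimental convention). Two shape choices matter and were calibrated
once against the acceptance suite, then frozen:

* **Factor interpolation.** The linear expansion ratio
  `sqrt(a_term / seed)` — not the seed area itself — interpolates along
  the comb. This keeps the realized push profile continuous across the
  EP1/EP2 boundary despite their different terminal targets; with
  seed-linear interpolation the profile kinks at mid-comb and the comb
  bends there.
* **Tip-weighted decay** (`gradient_power = 0.6`): the seed-area drop is
  concentrated toward the tip, which concentrates differential push where
  the tip must travel farthest while keeping short combs robust.

Beyond the tip the distal band keeps its tip-level depth (`beyond_tip =
"deep"`); the expanding cells there carry the tip region upward. The
calibrated geometry is `base_anchor = (88, 12)`, `initial_angle = 18`
degrees. In homogeneous mode (the control configuration) every distal
cell is seeded at the tip area — uniformly small cells whose expansion is
strong but carries no base-to-tip differential.

Under the calibrated defaults, 9-tooth combs at J(SCT,SCT) = 4000 rotate
to alpha ~45 degrees with median inter-tooth angle SD ~27 degrees and stay
intact in ~8/8 replicates; the homogeneous controls (terminal target 13 or
20 px) barely rotate or buckle, with median SD 36/60 degrees — the
bent-or-broken control phenotype. Final angles are lower than a fully
vertical comb (see Limitations).

## Morphometrics

* **alpha** — angle in [0, 180) between the line joining the centres of
  mass of the two extreme teeth (base -> tip, accumulated through
  consecutive minimal-image steps so combs longer than half the lattice
  unwrap correctly) and the -x axis. 0 = horizontal, 90 = vertical.
* **beta_1..beta_{n-1}** — orientations (vs +x) of consecutive inter-tooth
  CoM vectors, unwrapped to one branch around their circular mean; their
  sample SD (n-1 denominator) is 0 for
  a straight comb and invariant under rigid rotation.
* **intact** — all SCT pixels form a single connected component under
  8-connectivity (diagonal contact counts), periodic in x; 4-connectivity
  is available behind a flag. Extreme teeth are identified by persistent
  id, not by coordinates, so bent combs are handled robustly.

Replicate sets aggregate the intact ratio over all runs and the
inter-tooth SD distribution over intact runs only.

## Experiments

A set is `replicates` runs sharing parameters but differing in seed; the
full-scale protocol uses 48 replicates and 9 adhesion values per comb
length (36 sets; 108 more with the three EP1 delays). The shipped
acceptance protocol scales this to 12 replicates on 3-value adhesion
grids, and 8 replicates for the configuration contrasts — sizes chosen so
the whole suite runs on a desk machine in minutes while keeping binomial
resolution of ~0.1 on intact ratios. Per-condition seeds are derived from
a CRC of the condition (comb length and adhesion, excluding the delay) so
delayed and non-delayed sets run with matched seeds and compare pair by
pair. Snapshots are written as legacy-VTK STRUCTURED_POINTS ASCII files
with the cell index and type code as two scalar point fields.

Reproducibility: every simulation seeds the engine RNG once at start and
runs single-threaded to completion, so (configuration, seed) determines
every byte of output. The engine RNG is numba's thread-local Mersenne
Twister; statistics are generator-independent.

## Growth-curve statistics

The synthetic apical-area generator emulates the confocal measurements:
per-cell percentage area change on a half-hourly grid over 22–41.5 h after
pupariation, following a per-group three-parameter logistic with
multiplicative Gaussian measurement noise (5% default), mild per-cell
heterogeneity in asymptote (10%) and onset (0.25 h), and an optional slow
sinusoid mirroring the area oscillations seen in some cells. Default group
onsets are 23.3 h (EP2, tip-adjacent) and 27.4 h (EP1, base-adjacent) —
the delayed-base pattern measured in long combs.

Fitting uses the lag parameterization

    y(t) = A / (1 + exp((4 mu / A)(lag - t) + 2))

in which `lag` is exactly the time-axis intercept of the tangent at the
inflexion point — the standard growth-curve construction of the expansion
onset — so the quantity of interest is a direct parameter rather than a
post-hoc tangent computation. 95% CIs come from a nonparametric bootstrap
over cells (default 1000 resamples; the tests use 200, which changes CI
endpoints by far less than their width), studentized as point estimate
+/- t(n_cells - 1) times the bootstrap SE; with the ~10 cells of one
confocal field the raw percentile interval runs measurably narrow. The
fitted model carries a free intercept because a series referenced to its
first measurement is a vertically shifted logistic whenever growth has
already begun at the first time point; without the intercept the onset of
the early-starting group is biased late. The expansion rate of a cell is
`(final area / initial area) / duration`; the inhomogeneity coefficient is
the ratio of mean EP2 to mean EP1 rate, > 1 meaning the tip-adjacent cells
expand faster. Bootstrap probability statements use within-group
resampling with an outer repetition loop, reporting the median Pr and the
fraction of repetitions with Pr > 0.5 — the "median Pr(...)" reporting
style of the experimental comparisons. The exact published definitions of
the inhomogeneity statistic and resampling unit are in supplementary
material not available here; the implemented mean-rate ratio preserves the
"> 1 iff tip cells faster" semantics all in-text claims use.

## What the synthetic data do and do not show

The generator produces logistic growth with known onsets and noise, so
passing the recovery tests shows the fitting machinery is calibrated
(CI coverage, translation equivariance, gap detection) — it does not
validate the logistic form against real confocal measurements, nor the
biological onset values. Likewise the lattice simulations test the model's
internal phenomenology (gradient-driven straight rotation, length- and
adhesion-dependent breaking, delay rescue), not quantitative agreement
with measured cell areas.

## Numerical choices

* dH = 0 is accepted with certainty (exp(0) = 1).
* Target updates run at t = dt, 2dt, ... before the mcs of that tick;
  extrusion is checked immediately after each update.
* Flip-neighbour draws at the open y-boundaries sample the full Moore
  offset set and treat out-of-lattice picks as rejected attempts.
* The covariance eigenvalue uses the closed 2x2 form; negative rounding
  residuals are clamped at 0.
* Seeds are masked to 31 bits everywhere.

## Limitations

* Final rotation angles plateau around 45–55 degrees rather than the
  nearly vertical orientation of the real comb: once the distal targets
  saturate, pixel exchanges between equally satisfied cells cost ~2
  lambda_a and the tissue arrests, freezing the comb on the
  distal/proximal interface profile reached during the growth window. The
  original study likewise reported simulated angles below the expected
  values.
* 11-tooth combs at strong tooth-tooth adhesion (J = 0) essentially never
  break at this scale (they do at J = -4000, the cluster-driven regime,
  and at weak adhesion J >= 8000 via epithelial intrusion); the observed
  occasional strong-adhesion breaking of long combs is not reproduced at
  desk scale. Relatedly, 11-tooth combs at mid-range adhesion are near
  their intact ceiling here, so the delayed-EP1 rescue mostly manifests as
  "no worse, occasionally better" rather than a large intact-ratio gain.
* With per-cell onset heterogeneity enabled in the time-course generator
  (off by default), the pooled logistic lag acquires a small early bias
  that the cell bootstrap does not cover; CI calibration statements apply
  to the shared-onset defaults.
* The pull and push-and-pull hypotheses, joint formation, and the
  mechanism of the slow area oscillations are out of scope; the
  oscillation appears only as a generator nuisance term.
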