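# Methods

## Model

Hansen theory places every compound at (δD, δP, δH) in MPa^0.5 — the
dispersion, polar and hydrogen-bonding components of its cohesive energy
density — and models solute–solvent affinity with the scaled Euclidean
distance

    Ra^2 = 4 (δD_a − δD_b)^2 + (δP_a − δP_b)^2 + (δH_a − δH_b)^2,

the conventional factor 4 doubling the weight of the dispersion axis. A
solute additionally carries an interaction radius R0; the relative energy
difference RED = Ra / R0 is below 1 for solvents predicted to dissolve it
well. The package treats solvent HSPs as frozen 25 °C handbook constants
(bundled in `hspfit/data/solvents.csv` with a source tag per row, no
temperature correction) and estimates solute spheres from binary good/bad
solvent labels.

A separate "visual" distance without the factor 4 exists only behind an
explicit flag (`hansen_distance(..., visual=True)`) because 3-D sphere
renderings are usually drawn in unscaled coordinates; all classification
and screening uses the factor-4 metric.

## Solvent classification

A solvent is good when the solute's equilibrium solubility reaches a
threshold, default 20 g·L⁻¹, inclusive; solvents too insoluble to quantify
are bad by construction. The threshold is a judgment about "appreciable"
solubility, so `threshold_sweep` re-labels and refits at several limits
(default 15/20/30 g·L⁻¹) to check that the sphere is not a threshold
artifact, and explicit per-solvent overrides are supported (and recorded as
`manual_override`) for borderline cases. Classification works in g·L⁻¹;
mole-fraction conversions need densities and molar masses and are out of
scope.

## Sphere fitting

Parameters: center (δD, δP, δH) within the box δD ∈ [10, 25], δP, δH ∈
[5, 25] (physically motivated for hydroxyl-rich solutes: dispersion below
alkane-like values, substantial polarity and hydrogen bonding), and radius
R0 ≥ 1. Rather than penalizing violations, R0 is parameterized by
substitution as

    R0 = max(1, max_i Ra_i over good solvents) + s,   s ∈ [0, 2],

so every candidate automatically contains all good solvents. When a distant
good solvent pushes R0 past the nominal guideline of 10, containment wins
and a `ConstraintConflictWarning` names the binding solvent — fitted radii
slightly above 10 are a real feature of screens whose good set is spread
out.

The maximized objective is a penalized data-fit desirability, the geometric
mean of per-solvent terms d_i with d_i = 1 for a correctly classified
solvent and d_i = exp(−|Ra_i − R0|) otherwise. It equals 1 exactly at
perfect separation and decays with how deep each misclassified solvent sits
on the wrong side of the boundary. Because any perfectly separating sphere
scores 1, ties are resolved hierarchically by two weak additive terms:

1. a separation-margin bonus, 1e−3 × (min bad Ra − max good Ra), which
   centers the boundary in the empty gap between the classes — without it
   the optimum collapses to the minimal enclosing sphere of the good
   solvents, whose center is a visibly biased location estimate;
2. a radius penalty, 1e−7 × R0, which drives the slack s to 0 so the
   smallest feasible radius is reported.

Both weights are far below the objective change caused by misclassifying
any solvent by a non-trivial distance, so they only act on (near-)ties.

The search is `scipy.optimize.differential_evolution` (vectorized fitness,
population 20, up to 300 generations, best of 10 independent restarts with
per-restart generators derived from one seed; defaults reducible for small
problems). The initial center is the component-wise mean of the good
solvents' HSPs. Results are deterministic given the seed. `evaluate_sphere`
applies the same diagnostics to any fixed sphere (e.g. a literature one)
without optimizing. `data_fit_percent` is the plain fraction correctly
classified; `objective_value` is the desirability, reported separately
because the two readings of "data fit" differ once separation is imperfect.

Degenerate inputs: fewer than 4 labeled solvents or none good is an error;
all-good warns and returns the minimal feasible enclosing sphere.

## Binary mixtures

Blend HSPs mix linearly in mole fraction component-wise (a volume-fraction
variant exists but requires molar volumes and is never the default).
Profiles are indexed by the mole fraction x of solvent 2. Since the blend
point moves along a straight segment, Ra²(x) = a x² + b x + c with a ≥ 0,
so a RED profile has at most one interior minimum; `min_red_closed_form`
returns the clamped vertex x* = −b/2a analytically, and the grid scan
(default 0, 0.1, …, 1) reports the grid argmin, which is what printed
compositions are compared to. Ties — including exactly flat profiles when
the two solvents coincide — resolve to the smaller x (tolerance 1e−12 on
RED). Synergy is declared when the grid minimum is strictly below both
pure-solvent REDs; the quadratic coefficient a is reported as a flatness
diagnostic but has no classification threshold.

## Synthetic screens

`generate_dataset` emulates a monosolvent screen with known truth: solvents
uniform in a box of Hansen space (rejection-sampled so no true RED falls
within a margin, default 0.15, of the boundary), labels by RED ≤ 1 against
a truth sphere (default center (12, 10, 12), R0 8), and solubilities from a
declared generative map s = s_max · exp(−k·RED²) · exp(ε), ε ~ N(0, σ²).
Defaults: s_max = 100 g·L⁻¹ and k = ln 5, so that thresholding at
s_max·e^(−k) = 20 g·L⁻¹ recovers the labels exactly when σ = 0; σ = 0.25
as a moderate assay-noise level. Optional label noise flips each observed
label independently. One seed drives three deterministic substreams
(positions, solubility noise, flips).

The default sampling box is δD ∈ [13, 16], δP ∈ [3, 17], δH ∈ [3, 21],
chosen so that roughly 40% of sampled solvents are good against the default
truth sphere — the good-solvent fraction seen in real screens of this kind
(8/17, 6/20). A box stretching to δD = 20 looks more like a full solvent
catalogue but, under the factor-4 metric, leaves ~94% of samples outside
the sphere, and screens of 20 then routinely contain no good solvents at
all and cannot anchor a fit.

What the generator does **not** emulate: real solvents cluster by chemical
family rather than filling a box uniformly; solubility does not follow a
clean Gaussian-in-RED decay; and measurement error is not lognormal with
known σ. Passing recovery tests therefore demonstrates the estimator's
correctness under the stated model, not its accuracy on any particular real
screen.

## Problem sizes and verification

The test suite validates geometry against hand-evaluated distances and the
bundled study values, checks metric axioms and mixing-path convexity with
property-based tests (1,000 random systems against a 10⁴-point brute-force
grid for the closed-form minimum), and exercises fitting end to end:
single-screen recovery of the truth center within 1 MPa^0.5 per axis, and
20-replicate medians (per-axis center error < 0.5 MPa^0.5 noiseless,
degrading monotonically at label-flip rates 0.05 and 0.1). Fits in the
suite use a reduced optimizer budget (2–3 restarts, 150 generations,
population 15), ample for 20-solvent problems; the library defaults are
larger. A coarse exhaustive grid over the constraint box doubles as an
optimizer oracle on a 4-solvent lattice problem.

## Known limitations

* The fitted objective is one defensible choice among several used in the
  field; fitted spheres (and the 80%-vs-82% style data-fit numbers) are
  comparable to published ones qualitatively, not digit for digit, and the
  published spheres themselves are bundled for exact-diagnostic work.
* Solvent constants are single-source handbook values; a different
  compilation shifts REDs near the boundary by a few hundredths, which is
  exactly where sphere anomalies live.
* Mole-fraction linear mixing is an approximation that ignores excess
  volume and specific cross-association; it predicts the composition of a
  solubility maximum, not its magnitude.
* Ternary and higher blends are out of scope.
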