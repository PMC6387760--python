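# Methods

## Geometry: superelliptical frustum slicing

A body is represented by its digitized outline extrema — dorsal and ventral
y and half-width z at strictly increasing anteroposterior stations x, in
metres from the rostrum tip — with one region label (head, neck, trunk,
tail) per station and bilateral symmetry assumed. Each inter-station
interval becomes a frustum whose faces are superellipses `|y/a|^k + |z/b|^k
≤ 1`. The area constant `C(k)` (area ÷ bounding-box area) is evaluated in
closed form as `Γ(1+1/k)²/Γ(1+2/k)`; a second source interpolating the four
published constants (0.7854, 0.8227, 0.8324, 0.8408 at k = 2, 2.3, 2.4,
2.5) is selectable because those printed values derive from polynomial
regressions and sit up to ~0.5% below the exact values for k > 2. Only
k = 2 is treated as an exact reference value.

Volume uses the prismatoid formula, exact for any linearly tapering
cross-section, which is why refining the slicing of a cone leaves its volume
bit-identical. Regional densities default to head 990, neck 930, trunk 740,
tail and legs 1060 kg m⁻³ (air spaces lower the front of the body; the
post-thoracic regions take muscle density). The head takes a single averaged
density.

Per-frustum anteroposterior COM uses the circular-frustum centroid formula
with a single effective radius per face, taken as the geometric mean
`√(r_DV·r_LM)` — exact for circular faces, area-preserving for elliptical
ones. The vertical COM uses the four-point average of the dorsal and ventral
face coordinates. A taper-weighted vertical variant is retained behind a
flag only: its literal form assumes all frusta share a common base plane and
its printed parenthesization is dimensionally suspect, so it is excluded
from defaults and from body-frame outputs. A second validation-mode shortcut
(frustum COM at its larger face) exists for cross-checks; the difference on
a long smooth body is sub-millimetre.

Yaw inertia about a vertical axis sums per frustum the slab term
`C(k)·ρ·l·r̄_DV·r̄³_LM` (equal to `m r²_LM/4` at k = 2) plus the
parallel-axis term `m (x_COM − pivot)²`. The per-slice length term
`m l²/12` is omitted by default — with 60+ slices the parallel-axis sum
recovers it to well under 0.1%, as the convergence tests quantify — and can
be switched on, in which case a uniformly sliced cylinder matches the closed
form exactly at any slice count. Leg inertia about the leg's own long axis
uses the polar slab term `C(k)·ρ·l·(r̄_AP r̄³_LM + r̄_LM r̄³_AP)`. The
en pointe composition is `I_body + I_leg + m_body r² + m_leg r²` with
horizontal-plane distances to the collective COM; it can never fall below
the body-only inertia, which is what the table validator checks.

The graphical-double-integration (GDI) cross-check treats each segment as an
extruded anterior-face cylinder. It agrees with the frustum sum within 0.5%
on smooth, finely sliced bodies and over-estimates strongly tapered limbs at
coarse slicing (anterior-face bias); both behaviours are asserted in tests.

Tail modifiers: half-widths ×1.4 (the adult-crocodylian upper bound on tail
thickness) and depths ±10% about each station's own midline (articulation
uncertainty of haemal arches). Width and depth act on independent axes and
commute. The station shared by trunk and tail also bounds the last trunk
frustum, so that single transition interval shifts with the tail; this is a
property of any shared-boundary digitization, not of the modifier.

## Muscle-force proxies

Ilium lateral area is the shoelace area of a traced simple polygon (cm²),
validated and computed through shapely; it is invariant to rigid motion and
vertex-order reversal. The CFL cross-section is one semicircle of radius
half the hypaxial depth (caudal-rib tip to chevron tip), minus the centrum
cross-section, per side:

    area = width_factor · (π/2)(depth/2)² − centrum_area

with width_factor defaulting to 1 and 1.4 as the crocodylian-informed upper
bound. The width factor multiplies the semicircle term; with no centrum
subtraction (the only configuration for which an exact published statement
exists) total area scales by exactly 1.4. Depth sensitivity scales the
centrum with the square of the same linear factor, so ±10% depth changes
area by exactly +21%/−19%. Whether the centrum should be subtracted per side
or in total is not established; the per-side convention is the default and
configurable. CFL areas are reported but excluded from the regression
response (too few taxa preserve complete tails).

## Agility indices

`Agility_force = A_ilium / I_y` and `Agility_moment = τ_rel / I_y` with
`τ_rel = (m^{1/3}/100)·A_ilium·20 N/cm²`. The 20 N/cm² specific tension and
the /100 divisor are configuration constants; the divisor is an arbitrary
linear adjustment and a test asserts it never affects between-taxon ratios.
For geometrically scaled copies of one body plan (A ∝ s², m ∝ s³, I ∝ s⁵)
the log-log slopes against mass are exactly −1 (force) and −2/3 (moment);
the synthetic scaling series makes these identities hold to 1e-6, which
brackets slopes fitted to real data.

The specimen-table validator recomputes all four agility columns from each
row's own mass, ilium area and inertias and flags: (i) printed cells that
disagree beyond one unit in their last printed decimal (one unit, not half,
because the source tables round intermediate quantities — e.g. a printed
1.75 against a recomputed 1.744); (ii) rows with composed inertia below
body-only inertia, which the parallel-axis theorem forbids; (iii)
non-positive quantities. On the packaged 20-row reference table it flags,
among others, one juvenile tyrannosaur force cell, one juvenile moment cell,
and two physically impossible composed-inertia cells; nothing is silently
corrected.

## Phylogenetic statistics

Tip covariance under Brownian motion is the shared root-to-MRCA path length;
Pagel's λ multiplies off-diagonals only. λ is estimated by bounded ML
(tolerance 1e-8) with the mean and rate profiled out analytically; the
boundary values λ = 0, 1 are always evaluated explicitly so the optimizer
can never miss a boundary optimum. A constant trait raises an error rather
than returning a meaningless λ.

PGLS is GLS by Cholesky whitening. Results carry coefficient standard
errors, t-tests, the log-likelihood, and two R² flavours that can diverge
substantially and are therefore both reported and labelled: `r2_gls`
(whitened space, against the whitened intercept model) and `r2_raw`
(original scale). Confidence intervals come from the t distribution on
n − p df; prediction intervals add the tip's own phylogenetic variance
`σ²V_ii`, so per-tip "at or above the 95% PI" flags can be emitted.

The grade ANCOVA compares nested PGLS designs over the *whole* sample:
each comparison is a pair of grade assignments (full vs reduced), e.g.
{adult, juvenile, other} vs a single grade for the among-groups test,
{adult, juvenile, other} vs {tyrannosaur, other} for the juvenile-vs-adult
test, and {tyrannosaur, other} vs a single grade for the
tyrannosaurs-vs-others test. Grades free intercepts by default and slopes
optionally. One common λ — estimated on the pooled single-grade model — is
shared by both designs so nested models compare like with like. The F
statistic is the usual nested-model ratio on whitened residual sums of
squares, with numerator df from design-rank differences (a collinear "full"
design degrades to F = 0, p = 1 rather than an error). F values from the
originally published grade formulation are not expected to be reproduced
exactly — that formulation lives in an external package and its inputs are
not desk-reproducible — but the α(p) mapping of every published p-value is.

`α(p) = (1 + [−e p ln p]⁻¹)⁻¹` is defined on 0 < p < 1, increases
monotonically up to p = 1/e (where it is exactly 0.5) and decreases beyond.

Time calibration is deliberately simplified: tips sit at their first
appearance date, each internal node at its oldest descendant first
appearance plus a padding (default 1 Myr) that is *not* compounded across
nested nodes, and a final pass opens any non-positive branch by ε (default
0.001 × tree depth). Nested nodes sharing an oldest descendant therefore
collapse to ε-length internal branches — exactly the near-zero-branch
treatment hard polytomies need, keeping same-species tips exchangeable while
the covariance matrix stays invertible (a guarded Cholesky adds a 1e-10
relative ridge in the semidefinite limit). Pre-calibrated Newick input
bypasses the calibrator entirely. The two-pass equal-rate-sharing algorithm
used in the original analyses is not reimplemented.

## Synthetic data: what it emulates and what it does not

Analytic solids (elliptical cylinder, circular cone, spheroid) pair a sliced
station series with closed-form mass, COM and yaw inertia; integration
errors shrink monotonically with slice count and sit below 0.5% at 200+
slices. The parametric bipedal body draws smooth monotone (PCHIP) depth and
width profiles through region-anchored control points: default proportions
describe a ~2.6 t, 9 m biped (head 1.0 m, neck 1.2 m, trunk 3.0 m, tail
3.8 m; trunk depth 1.3 m). Tail proportions (proximal depth 0.60 × trunk
depth, mid-tail 0.32 × proximal) were fixed so the default body sits inside
the published tail-sensitivity envelope that defines a representative body —
±10% tail depth moves total mass <3% and I_y <4%, and the ×1.4 tail width
adds ~5% mass — and were not adjusted afterwards. Seeded jitter (±4% on
control points) varies bodies without breaking invariants. The synthetic
ilium area is a fixed fraction (default 0.12) of the trunk's lateral profile
area so geometric scaling laws hold exactly.

Random trees are pure-birth with unit rate, rescaled to a configurable depth
(default 100 Myr). Because the simulator stops exactly at the n-th
speciation — leaving the youngest cherry with zero-length terminal branches
and a singular covariance — pendant edges are extended by the exponential
waiting time to the next (uncounted) birth event. Traits follow
`y = intercept + slope·x + ε` with x itself a Brownian draw (so covariates
are phylogenetically structured, as in real data) and ε multivariate normal
under the λ-transformed covariance, plus optional per-group grade offsets.

What passing tests therefore show: the integrators, indices and statistics
are correct on bodies and trees whose ground truth is known. What they do
not show: fidelity of any particular skeletal reconstruction, digitization
error, non-superelliptical cross-sections, forelimbs (excluded), pitch/roll
inertia (out of scope), or the behaviour of the statistics under
non-Brownian evolution.

## Numerical choices and problem sizes

- λ optimization: bounded Brent, xatol 1e-8, boundaries checked explicitly.
- Whitened least squares via `lstsq`; design rank by `matrix_rank` so
  collinear grade designs are handled, not crashed.
- Guarded Cholesky ridge: 1e-10 × mean diagonal, only on factorization
  failure.
- Default test/acceptance problem sizes, chosen to keep every check
  statistically meaningful at interactive run times: 200–500 slices for
  closed-form convergence; 50-tip trees × 200 replicates for λ recovery;
  a 20-tip tree × 1,000 replicates for type-I calibration of the grade
  F-test (the common λ fixed at its generating value of 1 so the check
  isolates the F-test from plug-in estimation noise — the ML plug-in makes
  the test mildly conservative, ~0.03 at 20 tips); 500 replicates for PGLS
  CI coverage.
- Rounding for reproducing printed table cells: Python's round (half-even)
  to the printed number of decimals.

## Known limitations

- The calibrator is a documented simplification; branch lengths (and hence
  λ and p-values) from it will differ from the original two-pass method.
- The en pointe leg COM uses the hip's anteroposterior position and a
  lateral offset; fore-aft excursion of a protracting leg is not modelled.
- Lungs and air sacs enter only through regional densities.
- CFL reconstruction ignores the intermuscular septum and fascicle
  architecture; it is a cross-section proxy, not a force model.
- The λ-transform is the only evolutionary model offered (no OU or rate
  shifts), matching the scope of the analyses it supports.
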