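# Methods

## Model overview

`osteofuzz` models the osteogenic differentiation of mesenchymal stem
cells (MSCs) as a single-cell decision process driven by five extracellular
signals: Mg²⁺ ions (mM) and the inflammatory cytokines TNF-α, IL-10, IL-8
and IL-1β (ng/ml). A Mamdani fuzzy controller maps the signal state to two
crisp rates in [0, 1] — the fuzzy early-differentiation rate `f_e` and the
fuzzy late-differentiation rate `f_l` — with 0.5 denoting the physiological
rate. These are scaled into physical rates, integrated into a *maturity*
state in [0, 1], and mapped to the measurable markers ALP (early),
osteocalcin (OC) and alizarin red staining (ARS) (late).

## Fuzzy controller

**Semantics.** Standard Mamdani min/max semantics: AND = min, NOT = 1 − μ,
implication = min-clipping, aggregation = max, defuzzification = centroid of
the max-union of the clipped output memberships. The centroid is evaluated
on a uniform 1001-point grid over the unit output interval; with output
Gaussians of σ = 0.05 this resolves a standard deviation with ~50 points,
and the analytic-grid centroid agrees with a 10⁵-point trapezoid
integration oracle to better than 10⁻³ (tested over random activation
patterns). Zero total activation raises a defined error; a sweep test over
a broad input grid verifies the rule base covers all physiologically
reachable states.

**Input fuzzification.** Triangular/trapezoidal memberships; an inclusive
vertical-edge convention (`a == b` or `c == d`) keeps shoulder levels at
degree 1 on the domain boundary. Cytokine axes are fuzzified on a log₁₀
scale over 10⁻⁴–10³ ng/ml (anchors span four decades; zero concentration
maps to the lower edge, i.e. fully Negligible); the Mg²⁺ axis is linear
over 0–30 mM. Out-of-domain values are clamped to the boundary by default,
so extreme concentrations behave as the extreme level. Textual anchors
honored by the default breakpoints, with roughly 50 % overlap between
adjacent levels:

- **Mg²⁺** (six levels): Inhibitory-ED dominant below 0.8 mM;
  Physiological peaking at 0.8 mM (standard MEM); Stimulatory rising from
  0.8 mM to its peak `p_ms` (free, prior 2–10 mM); Ineffective as the
  transition peaking at `p_md`; Inhibitory-LD rising above 1.8 mM;
  Destructive dominant above 20 mM (viability limit).
- **TNF-α**: Negligible near zero, Stimulatory peaking at 1 ng/ml,
  Ineffective (neutral) at 10 ng/ml, Inhibitory dominant at 100 ng/ml.
- **IL-10**, exposure-switched at 48 h of cumulative application:
  short-term membership set with Stimulatory increasing monotonically from
  0 to 10 ng/ml; long-term set with Stimulatory peaking at 0.1 ng/ml and
  Inhibitory dominating at ≥ 10 ng/ml.
- **IL-8**: Negligible / Favorable (peak `p_8f`) / Stimulatory rising to
  100 ng/ml.
- **IL-1β**: Negligible / Stimulatory (peak `p_1bs`, support ending at
  `p_1bie`) / Ineffective above the window.

**Outputs.** Gaussian levels (activation 1, σ = 0.05) on [0, 1]. ED has
six levels — Arrested (0.05, never referenced by a rule; it completes the
stated six-level inventory), Slow (`p_es`), Physiological (0.5, fixed),
Fast (`p_ef`), Very fast (`p_evf`), Extremely fast (0.95, fixed). LD has
five — Arrested, Slow (`p_ls`), Physiological (0.5), Fast (`p_lf`), Very
fast (0.9, fixed).

**Rule base.** "Any-of" rows are expanded into one rule per listed input
(OR realized by max aggregation); simultaneous rows are AND conjunctions
with internal or-groups expanded combinatorially (e.g. the ED
Physiological row becomes 8 rules). The IL-8/IL-1β antagonism is encoded
by three conjunction rules: either cytokine alone can drive Very fast (and
IL-8 Stimulatory alone Extremely fast), but both present together fire the
`IL8 not-Negligible AND IL1β not-Negligible → Very fast` rule while
blocking Extremely fast, capping the combined response below the
IL-8-alone maximum. The rule base serializes to and from a plain IF/THEN
text format.

## Dynamics

The scaling function is `S(x) = 2·α·(x − 0.5) + 1` with the stimulatory
coefficient on the branch x > 0.5 and the inhibitory coefficient on
x ≤ 0.5, clamped at 0 from below. (The branch assignment is switchable via
`stimulatory_branch_high`; the default follows the narrative in which a
larger α_es accelerates maturation.) Physical rates are `r = S(f)/T_d`
per day, so the physiological state yields `r_0 = 1/T_d` exactly.

Maturity accumulates `r_e` until the early phase ends and `r_l`
afterwards. Phase switching is **time-based** at `T_e = M_t·T_d` (the
printed piecewise form) rather than maturity-based; the two coincide only
at physiological rates, and the time-based reading is taken as primary.
Integration is forward Euler with dt = 1 h over piecewise-constant
schedules; because the rates are state-independent the trajectory is exact
whenever segment edges and `T_e` align with the step grid, and first-order
accurate (error ≤ dt·max r) otherwise. The controller is re-evaluated once
per schedule segment, and (parameters, inputs) pairs are memoized — during
calibration with fixed membership parameters every objective evaluation
after the first reuses the cached crisp rates. After a cytokine's
application window a schedule reverts to the physiological medium (Mg
0.8 mM, cytokines 0).

Markers: `y_i = (x + β_i)^{n_i} · k_{i,j}` with x = min(maturity, M_t)
for ALP (early marker, constant once the early phase completes) and
x = maturity for OC/ARS. β_i is the baseline detectable at maturity zero,
n_i the nonlinearity degree, and k_{i,j} a per-study correction factor
absorbing unit differences between experiments.

## Study designs and synthetic data

Five built-in designs mirror the calibration experiments: (1) Mg 0.08 /
0.8 / 8 mM, ALP at days 3 and 7; (2) Mg 0.8 / 5 mM, ALP day 7, OC day 21;
(3) IL-10 {0, 0.1, 1, 10} and TNF-α {0, 1, 10, 100} ng/ml applied for
48 h, ALP day 14, ARS day 21; (4) IL-10 {0, 0.1, 1, 10, 100} ng/ml applied
continuously, ALP day 3 and ARS day 9, reported as fold over an
undifferentiated control simulated as the all-physiological schedule;
(5) IL-8 {0, 10, 100}, IL-1β {0, 10} and the combined IL-8 100 + IL-1β 10
condition applied continuously, ALP day 9. Study 4 uses the long-exposure
IL-10 membership set (its dose–response — maximum at 0.1 ng/ml, inhibition
at ≥ 10 ng/ml — is the defining signature of sustained exposure); study 3's
48-h pulses use the short-exposure set. Study 5's cytokines are applied
continuously until measurement, the natural reading where no application
window is specified.

The source experiments publish their measurements only as figure bars, so
no digitized empirical values ship with the package; users who digitize
figures can supply their own CSV in the documented schema. The synthetic
generator instead simulates all designs at a ground-truth parameter set and
applies multiplicative lognormal noise with unit mean and a chosen
coefficient of variation (default CV 0.1, a typical bar-plot spread for
these assays; the reported sd is CV·value). A multiplicative model was
chosen because marker readouts are positive and their errors roughly scale
with the signal; an additive truncated-Gaussian alternative would change
small-signal behavior but none of the recovery logic. Synthetic data are a
clean-room substrate: passing recovery tests demonstrates the estimator's
self-consistency, not agreement with any laboratory measurement —
donor-to-donor heterogeneity, plate effects and inter-study unit drift are
deliberately absent.

## Calibration

Per-item fitness is `clamp(1 − |E − S|/E, 0, 1)` (1 = perfect fit; the raw
normalized discrepancy is available behind a flag) and the objective is the
mean over items. The 30-parameter registry comprises 5 membership anchors,
5 output-level centers, M_t, T_d, 4 α's, 3 β's, 3 n's and 8 correction
factors; per-study calibration exposes only the relevant subset (a study's
own anchors, reachable output centers, phase dynamics and marker
parameters — never another study's k factors). Default priors: p_ms ∈
[2,10] mM, p_md ∈ [10,20] mM, p_8f ∈ [1,100] ng/ml (log), p_1bs ∈ [1,10],
p_1bie ∈ [10,100] ng/ml, Slow centers ∈ [0.05,0.45], Fast ∈ [0.55,0.95],
p_evf ∈ [0.6,0.99], M_t ∈ [0.1,0.9], T_d ∈ [7,30] d, α ∈ [0,1],
β ∈ [0,2], n ∈ [0.5,3], k ∈ [0.1,10] (log). Log-scaled parameters are
searched in log₁₀ units.

Optimization uses differential evolution (rand/1/bin, F = 0.8, CR = 0.9,
population 15 by default, no polishing step, fixed generation count) under
a fixed seed per run; search points violating an ordering constraint score
zero. Because single runs can settle in different optima, calibration is
repeated (run *i* seeded `base_seed + i`); the inferred value is the mean
of per-run bests and convergence requires the first- and second-half run
means of every parameter to agree within a tolerance (default 0.05) of the
prior length, measured on the search axis. Odd run counts split
floor/ceil. The bundled recovery experiment calibrates {M_t, T_d, α_es}
from noise-free synthetic data over 20 runs of 200 generations with
population 15 — sized so the whole protocol completes in minutes on one
core while still exercising the repeated-run machinery end to end.

## Sensitivity analysis

**LSSP** perturbs a study's relevant parameters simultaneously by ±50 %
of their current values, sampling combinations with an orthogonal
two-level fractional factorial design: resolution III designs take the
non-constant columns of the smallest Sylvester–Hadamard matrix, and the
default resolution IV is its fold-over (main effects unconfounded with
two-factor interactions). On an orthogonal design the ANOVA main-effect
sum of squares reduces exactly to the contrast `N·(effect/2)²`; per-item
sums of squares are normalized by their total so the ranking is invariant
to rescaling any output by a positive constant, and parameters are ranked
by the mean normalized share across the study's measurement items (top
five highlighted). When a measurement table is supplied, the mean fitness
is analyzed as an auxiliary response. Perturbed candidates are clipped to
the prior box and then minimally repaired to respect ordering constraints
(±50 % can, e.g., push `p_ef` above `p_evf`); every adjusted parameter is
flagged in the report.

**SSIP** perturbs one parameter at a time by ±15 % and reports, per
measurement item, the standard deviation across the pair of perturbed
outputs (the error bar) and the mean absolute percentage change. For a
purely multiplicative parameter (a correction factor under absolute
normalization) the percentage equals the magnitude exactly; parameters not
entering a study's computation give exactly 0 % there — both serve as
analytic self-checks.

## Numerical and design notes

- Centroid grid: 1001 points; single-level symmetric activations return
  the level center to ~10⁻⁹, which is why the physiological fixed point
  (f_e = f_l = 0.5) holds essentially exactly.
- The fold-over-control normalization of study 4 cancels its correction
  factors k_ALP,4 and k_ARS,4; they remain in the registry (preserving the
  30-entry inventory) but are structurally unidentifiable from study-4
  data and show zero sensitivity — expected, not a bug.
- Noise-free synthetic data evaluated at the generating parameters score a
  mean fitness of exactly 1.0; this whole-pipeline identity is asserted in
  the tests.
- Degenerate membership shapes (equal abscissae) are legal and produce
  inclusive vertical edges; Gaussian σ must be positive.
- CSV round-trips are bit-exact (`%.17g` on write, round-trip float
  parsing on read).

## Known limitations

- Membership breakpoints not named in the source text are qualitative
  choices (50 % overlap heuristic) collected in one place
  (`controller.py`) for refitting; the supplementary rule listing and
  prior table of the original study were not available, so the rule base
  and priors derive from the main-text table and prose.
- No cell-population or spatial dynamics, no macrophage feedback, no
  substrate stiffness, no TGF-β/BMP signals — the model describes the
  average single-cell response.
- The maturity-based phase-switch variant is exploratory
  (`phase switching` is time-based by default); negative-rate clamping in
  S(x) is this package's choice.
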