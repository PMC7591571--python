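# Methods

## Assay model and normalization

Each well of a dual-reporter plate carries two luminescence readings: Fluc
(JH-response-element reporter; rises with JH signaling) and Rluc
(constitutive promoter; tracks viable cell mass). Every plate carries its own
control populations — positive controls are DMSO-only (no JH, baseline
signal) and negative controls are 1 nM JH I (full signal). The inhibition
rate of a sample reading S,

    InH (%) = 100 · (1 − (S − mean_p)/(mean_n − mean_p)),

is computed strictly per plate and per channel; replicate wells are
normalized against their own plate's controls first and averaged afterwards.
InH is intentionally unbounded: values above 100% mean super-maximal signal
loss, negative values mean activation (agonist-like compounds). Control SDs
use the sample convention (n − 1) because only 8–16 control wells per role
are available. Plate quality is Z′ = 1 − 3(SD_p + SD_n)/|mean_n − mean_p|;
the separation is taken as an absolute value with a warning when the controls
are inverted (a degenerate simulation or swapped annotation), and plates
below a configurable Z′ floor (default 0.5, standard HTS practice) are
excluded from scoring.

### The Rluc counterscreen

On the Rluc channel both control populations are compound-free, so their
means coincide in expectation and the control-separation normalization above
is undefined there (the denominator would be pure noise). The counterscreen
quantity is therefore the viability reading's percent loss against the pooled
mean of all control wells: InH_rluc = 100 · (1 − rluc/mean(control rluc)).
This is the quantity for which "Rluc InH = 50%" means half the viability
signal is gone; compounds with InH_rluc strictly above 50% at the highest
tested dose are excluded as cytotoxic false positives. `inhibition_rate`
itself always implements the control-separation formula and raises on
degenerate separation.

## The triage cascade

Stage thresholds (all configurable via `CascadeConfig` / YAML):

| stage | condition | boundary reading |
|---|---|---|
| 1 (primary, 5 µM, n = 1) | InH ≥ 26% | inclusive |
| 2 (confirmation, n = 4) | mean InH ≥ 20% and no adherence flag | "less than 20%" excludes, so 20.0 passes |
| 3 (dose–response) | InH > 10% at the lowest tested dose | strict |
| 4 (analog/dose test) | InH > 15% at 0.5 µM and > −10% at 0.05 µM | strict |
| counterscreen | Rluc InH ≤ 50% at the top dose | strictly greater excludes |

The stage-3 selection concentration is the lowest tested compound dose
(default 0.05 µM of the 0.05/0.5/5 µM series): the criterion's intent is
"activity retained at low dose", and the same three-point series is used for
stages 3 and 4. Stage 3 additionally applies a monotonicity sanity check —
dose-mean InH may not drop by more than a tolerance (default 10 percentage
points) between successive doses — standing in for the by-eye inspection of
dose–response plots; it can be disabled. The "weakened cell adherence"
exclusion is not computable from luminescence and is carried as a manual
boolean flag on wells; any flagged well excludes its compound at stage 2.
Compounds are traced across stages by compound_id; a compound appearing in a
later stage without earlier-stage data triggers a lineage warning, and final
actives always carry results for all four stages plus the counterscreen.

## Dose–response fitting

The 4PL model R(c) = bottom + (top − bottom)/(1 + (EC50/c)^h) is fitted by
`scipy.optimize.least_squares` (trf) over (bottom, top, log10 EC50,
log10 h). Optimizing potency and slope on the log scale removes positivity
constraints and conditions the problem across concentration decades. Bounds:
EC50 within the tested range ±2 decades, h ∈ [0.2, 5]; initialization takes
the asymptotes from the lowest/highest dose means (a zero-dose mean, if
present, anchors the baseline), EC50 from the dose nearest mid-range
response, h = 1. Zero-dose points are excluded from the log-concentration
fit. Descending curves (e.g. relative expression vs inhibitor dose) are the
same family with the asymptotes swapped; fits are canonicalized to
bottom ≤ top with a `direction` label, and the response at the fitted EC50 is
exactly (bottom + top)/2 either way.

Because luminescence noise is multiplicative (approximately constant CV), the
default loss divides residuals by |model| + 0.05·mean|y| — a
variance-stabilizing weight with a floor so near-zero asymptotes cannot
dominate. `weighting="absolute"` selects the unweighted fit, which is the
right choice when the response is already a normalized quantity whose noise
is not proportional to its value (InH curves, where noise scales with the
underlying luminescence, not with InH itself). Degenerate inputs are
rejected: fewer than 4 distinct positive doses, exactly constant responses,
or a dose-mean span smaller than 3× the pooled replicate SD (a flat curve has
no identifiable EC50). Non-convergence raises an error carrying the best
point found.

## Antagonist-mode classification

The assay grid is the JH I series 0, 10⁻¹⁰ … 10⁻⁶ M crossed with inhibitor at
0, 0.5, 5 µM (n = 3 per cell by default). The maximal-effect test compares
replicate responses at 10⁻⁶ M JH alone versus with 0.5 µM inhibitor using an
equal-variance two-sided Student's t-test; the noncompetitive call requires
p < 0.001 **and** a reduced treated mean (a significant increase is not a
reduction). With zero pooled variance the test returns p = 1 for equal means.
The competitive-like rule — non-significant maximal-effect test plus a fitted
EC50 dose ratio ≥ 2 at the highest inhibitor concentration — operationalizes
the "parallel rightward shift" pattern that is otherwise judged visually; the
threshold 2 corresponds to [I] ≥ K_i under the Gaddum relation
DR = 1 + [I]/K_i. Compounds with neither signature are indeterminate.

A caveat the test suite works around deliberately: with the 6-point assay
grid only one dose sits below the JH EC50 and the zero-dose anchor is outside
the log-fit, so individual EC50 fits on this grid are noisy (dose *ratios*
remain reliably large for genuine shifts, which is all the classifier needs).
Quantitative dose-ratio recovery checks use an agonist series that spans the
EC50 symmetrically.

## qPCR relative expression

2^−ΔΔCt with PCR efficiency fixed at 2 per cycle and a single constitutive
reference gene. Replicates are averaged on the Ct scale before the ΔΔCt
(default), giving one relative-expression value per dose; a per-replicate
mode computes individual ΔΔCt values (their arithmetic summary on the
2^−ΔΔCt scale corresponds to a geometric mean on the expression scale). The
calibrator is the agonist-alone condition. Shifting both reference Cts by a
constant leaves results unchanged — only ΔCt differences matter.

## Synthetic data generator

The simulator is phenomenological at the reporter level; it does not model
transcriptionally explicit Met/SRC/Kr-h1 dynamics. Deterministic expected
signals per well:

* agonist occupancy A = c^h/(c^h + EC50_JH^h), defaults EC50_JH = 3.7·10⁻¹⁰ M,
  h = 1 (the cell line's measured JH I potency regime);
* competitive inhibitors: EC50_JH → EC50_JH·(1 + [I]/K_i) (Gaddum);
* noncompetitive inhibitors: span f_max → f_max/(1 + [I]/K_i);
* cytotoxics: both channels × v = 1/(1 + ([I]/TC50)^h_tox);
* agonist compounds add efficacy-scaled occupancy of their own EC50;
* Fluc = (f₀ + f_max_eff·A)·v, Rluc = r₀·v, with f₀ = 50, f_max = 2000,
  r₀ = 1000 RLU (arbitrary; InH is affine-invariant).

Measurement noise is independent multiplicative lognormal with unit mean —
control wells at 5% CV, compound wells at 10% CV by default, which puts
simulated plates in the Z′ ≈ 0.8–0.9 regime a well-behaved dual-reporter
screen occupies. All randomness flows through one seeded numpy Generator;
identical (config, seed) reproduces plates bit-identically.

Potency defaults (log-uniform): competitive K_i ∈ [10⁻⁸, 10⁻⁷] M — anchored
on the observation that a cellular inhibition EC50 of ~3·10⁻⁷ M at 1 nM JH
implies K_i = EC50/(1 + [JH]/EC50_JH) ≈ 9·10⁻⁸ M, so planted hits resemble a
real screen's best compounds; noncompetitive K_i ∈ [5·10⁻⁸, 7.5·10⁻⁷] M
(maximal-effect reduction between 40% and ~91% at the 0.5 µM test dose);
cytotoxic TC50 ∈ [2·10⁻⁸, 10⁻⁷] M with h_tox = 1 — potent enough that the
viability loss masquerades as Fluc inhibition through all four stages, which
is precisely the false-positive mode the Rluc counterscreen exists to catch
(milder toxins simply fail the stage-3 low-dose criterion and never reach
it). Default class mix: 97% inactive, 1% competitive, 0.5% each
noncompetitive / cytotoxic / agonist / inhibitor-and-cytotoxic (~3% planted
actives).

What the generator does **not** emulate: plate spatial gradients and edge
effects (no positional artifacts by default), inter-plate drift, compound
carry-over, pipetting failures, adherence loss (only a manual flag),
heteroscedastic detector saturation, and correlated noise between the two
channels. Passing tests therefore demonstrate the statistical machinery is
correct under the assay's idealized noise model, not that real plates need no
spatial correction.

## Problem sizes and numerical choices

Simulated campaigns in the tests use 960-compound libraries (one-tenth the
scale of a 9600-compound core-library screen, with the same 384-well
320 + 16 + 16 plate economy and the 96-well confirmation format), 20-seed
repetition for survival-rate properties, and 100-seed repetition for fit
recovery and classifier error rates; these sizes make every distributional
claim a direct computation while keeping the default suite fast. Optimizer
tolerances are set to 10⁻¹⁵ (xtol/ftol/gtol) so noiseless fits recover
parameters to ~10⁻⁶ relative error or better; equality-sensitive quantities
(InH endpoints, ΔΔCt hand values, Z′ at zero variance) are exact in floating
point by construction of the formulas. Concentration matching inside the
cascade uses a 10⁻⁶ relative tolerance; boundary comparisons at thresholds
follow the inclusivity conventions in the table above.

## Known limitations

* EC50s from the 6-point antagonist grid are individually noisy (see above);
  the classifier uses them only through dose ratios.
* The stage-3 monotonicity check can reject genuinely bell-shaped responses
  (e.g. compounds that are inhibitory then cytotoxic); disable it when that
  pattern is of interest.
* The 96-well second-screen geometry is a proportional scaling of the
  384-well layout; control placement is configurable but defaults to edge
  columns, and no statistic depends on geometry because no spatial
  correction is applied.
* `z_prime` follows the classic formula and is reported for the Rluc channel
  only on explicit request; it is not meaningful there (no control
  separation by design).
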