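# Methods

`asymlung` implements the quantitative analysis pipeline of a porcine study of
asymmetric (unilateral, left-sided) acute lung injury comparing two PEEP
strategies over six hours of volume-controlled ventilation: a fixed PEEP of
5 cmH₂O versus hourly PEEP titration targeting a slightly positive
end-expiratory transpulmonary pressure (TPP_exp between 0 and 3 cmH₂O,
estimated by esophageal manometry). This note documents the models, the
defaults that matter, and the design choices made where the source protocol
left the procedure open.

## Derived respiratory mechanics

From one static hold-maneuver reading (P_peak, P_plat, PEEP, P_ES,insp,
P_ES,exp, V_T, RR) the package computes

- ΔP = P_plat − PEEP
- TPP_exp = PEEP − P_ES,exp,  TPP_insp = P_plat − P_ES,insp,
  ΔP_L = TPP_insp − TPP_exp
- MP = 0.098 · RR · V_T · (P_peak − ½(P_plat − PEEP))  [J/min]
- C_RS ≈ V_T / ΔP (quasi-static estimate)

Units: all pressures in cmH₂O; V_T is supplied in mL and converted to litres
only inside the power formula (0.098 J per L·cmH₂O). Ventilator-reported
compliance and resistance are pass-through inputs: the device compliance is
not the quasi-static V_T/ΔP estimate (group means computed from one are not
reproduced by the other) and the two are kept strictly separate. No flow
signal is modelled, so resistance is never computed. When ΔP = 0 the
quasi-static compliance is reported as undefined while the remaining
quantities are still returned.

## Titration rule

The protocol specifies only the target band (TPP_exp ∈ [0, 3] cmH₂O, hourly
adjustment). The rule implemented is a one-shot set: if the observed TPP_exp
is out of band, PEEP is set to P_ES,exp + band midpoint, rounded to the
ventilator step (default 1 cmH₂O, ties away from zero) and clamped to
configurable bounds (default 4–24 cmH₂O); in-band readings leave PEEP
unchanged. This is the simplest policy consistent with the observed endpoint
(PEEP ≈ 10.8 at P_ES,exp ≈ 9.6); whether the original study stepped PEEP
incrementally is unknown, and the policy object makes the band, step and
bounds configurable.

Against a linear chest-wall response P_ES,exp = a + b·PEEP the closed-loop
error contracts by the factor b per step, so a uniform ≤10-step convergence
bound cannot hold for slopes arbitrarily close to 1 from distant starting
points. The convergence property is therefore verified on a 10×10 grid of
slopes 0–0.75 and intercepts 0–8 cmH₂O — generous relative to physiological
chest-wall elastance fractions of roughly 0.3–0.5 — with bounds wide enough
that the clamp is not binding, using brute-force iteration.

## Histological lung injury score

Per high-power field (20 per sample by convention; three samples per lung
side), neutrophil counts are binned none→0, 1–5→1, >5→2 and septal thickening
<2×→0, 2–4×→1 (both endpoints inclusive), >4×→2. The modified
(early-exudative) score weights the three components 20/14/2. The printed
formula divides by n_fields × 72 while the documented range is 0–0.72; these
are mutually inconsistent, and the default `per_field_100` denominator keeps
the original five-component score's 100-point per-field normalization (after
dropping the two 7-weighted components), which reproduces the stated 0.72
maximum. The literal ÷72 reading remains selectable. The original
five-component score (weights 20/14/7/7/2, range 0–1) is implemented
independently. Side values are the mean over a side's samples before pairing
— the combination rule for the three samples per side is not stated in the
protocol and the mean is the declared choice, matching the averaging used for
CT regions.

## HRCT score

Readers grade each lung region by the percent extent of four patterns:
normal, ground-glass, consolidation, and "bronchodilatation" (the merged
traction-bronchiectasis grades; honeycombing excluded as a late-fibrotic
pattern). Numeric weights are not published; the package retains the ordinal
grades 1–3 and assigns the merged grade weight 4, with the whole table
configurable. A region scores Σ weight × extent%, i.e. 100 for fully normal
to 400 for fully bronchodilatated, which is the reconstruction that makes the
reported side scores (≈116–270) arithmetically possible; a side scores the
mean of its regions (default 3 per side in synthetic data — the reader
partition is unpublished). Extents must sum to 100 ± 0.5%. Recruitability of
a side is the expiratory-hold minus inspiratory-hold score.

## Antibody-array statistics

The assay is a reference-design dual-colour antibody microarray
(~120–260 targets, quadruplicate spots). Processing:

1. **Aggregation** — median over replicate spots after local-background
   subtraction, floored at ε = 1 intensity unit before log₂; replicate CV is
   reported. M = log₂(sample/reference), A = ½·log₂(sample·reference).
2. **Rank-invariant lowess normalization** — the vendor's "invariant lowess"
   is proprietary; the reconstruction selects per array the antibodies whose
   within-array channel ranks differ by ≤ 5% of n, fits a lowess of M on A
   over that set (span 0.4), and subtracts the interpolated trend from all M.
   Fewer than 10 invariant antibodies triggers a median-centering fallback
   with a warning. Span and rank tolerance are configurable.
3. **Moderated contrasts** — per-antibody least-squares condition means;
   residual variance s² on d df is shrunk toward an empirical-Bayes prior,
   s²_post = (d₀s₀² + d s²)/(d₀ + d), with (d₀, s₀²) estimated by method of
   moments on log s² across antibodies (trigamma inversion by Newton
   iteration; a non-positive excess log-variance yields d₀ = ∞, i.e. a fully
   pooled prior; zero-variance antibodies are excluded from the fit). The
   moderated t = logFC / (s_post·√(Σc²_g/n_g)) is referred to t with d₀ + d
   df. Setting d₀ = 0 recovers the ordinary per-antibody t exactly.
4. **Multiplicity and calls** — Benjamini–Hochberg step-up adjustment
   (canonical definition; note that re-applying the adjustment to adjusted
   values is not an identity — the meaningful invariant, tested here, is that
   thresholding adjusted values at any level reproduces the step-up rejection
   set). Default classification follows the reported-results convention:
   differential if |logFC| > 0.5 and adjusted p < 0.05; noteworthy if
   |logFC| > 0.5 and adjusted p ∈ [0.05, 0.9). A stricter preset
   (adjusted p < 0.005, noteworthy as 0.25 < |logFC| ≤ 0.5) is available, and
   all four numbers are configurable.
5. **Clustering** — per-antibody z-scoring then average-linkage hierarchical
   clustering (Euclidean) for heatmap row/column orders; zero-variance rows
   are scaled to zero with a warning.

Contrasts shipped by the pipeline: each group's t6 versus pooled baseline,
and fixed-PEEP versus titrated arm at t6.

## Comparison battery

Matching the study's mapping: one-way ANOVA with Bonferroni-corrected
pairwise t tests for group effects (mechanics, LIS); exact Wilcoxon
signed-rank for within-animal side pairs; exact Mann–Whitney U for HRCT group
contrasts. Conventions (not stated in the source and declared here): zeros in
signed-rank differences are dropped and noted; |differences| are mid-ranked;
two-sided p is the doubled one-sided exact tail capped at 1; Bonferroni
multiplies by the number of pairs actually compared. Exact null distributions
are computed by counting dynamic programming — Gaussian-binomial recursion
for U, sign-pattern convolution over doubled (hence integer) mid-ranks for W
— which is exactly equivalent to full enumeration and is cross-checked
against brute-force `itertools` enumeration in the tests. Limits: exact U for
combined n ≤ 25 (seeded mid-rank permutation with ≥10⁴ resamples when ties
are present), exact W for m ≤ 20; beyond these, normal approximations with
tie corrections.

## Synthetic cohorts

The generator emulates the data structures behind the study's tables with
known ground truth; the shipped preset (6 + 6 + 2 animals) is calibrated to
the published t6 group means.

- **Mechanics**: single-compartment statics with a linear per-group
  compliance trajectory (fixed arm 30 → 25.2 mL/cmH₂O over t0–t6, titrated
  arm 30 → 33.3, sham flat 37), linear chest-wall response (slope 0.6;
  intercepts 4.6 / 3.1 / 0.8 cmH₂O chosen so the observed esophageal
  pressures are reproduced at the observed PEEPs), constant resistive
  pressure, and Gaussian noise of 1.2 cmH₂O — consistent with the published
  SEMs at n = 6. The titrated arm runs the actual titration rule hourly.
- **Histology**: Poisson counts (injured side λ_alv ≈ 8.5–9, λ_int ≈ 3.3–3.5;
  non-injured ≈ 1.3–1.5; sham ≈ 2–2.2) and log-normal thickening folds,
  giving closed-form expected scores ≈ 0.54–0.55 (injured), 0.25–0.27
  (non-injured), 0.31 (sham) against published means of 0.54–0.56, 0.27–0.30
  and 0.32–0.33.
- **HRCT**: Dirichlet extents with concentration total 100 (inter-region
  variability comparable to the published SEMs); expected side scores 264/268
  (injured, exp/insp), 142/125 (fixed-arm right), 121/116 (titrated right).
- **Array**: log-normal reference abundances (log₂ mean 10, sd 1.5); planted
  +1.0 log₂ effects on 5% of antibodies in the titrated arm at t6 (emulating
  the reported time-dependent response seen only in that arm); biological
  noise sd 0.4, spot noise sd 0.05, dye bias M ← M + 0.3 + 0.1·A, additive
  background 20 ± 3.

What the generator does **not** model: gas exchange, hemodynamics,
waveform-level dynamics, reader variability in scores, spatial correlation of
histology fields or CT regions, antibody cross-reactivity, or array batch
effects. Passing tests therefore demonstrate correctness of the computations
and calibration of the statistical procedures under these idealized
generative models, not fidelity to any individual animal: the published
per-animal raw data are unavailable (means ± SEM only), so calibration
matches moments, not individuals, and published real-data outcomes such as
the count of differential proteins are not reproduction targets.

## Numerical choices and degenerate inputs

- Rounding in titration: nearest step, ties away from zero.
- Intensity floor ε = 1 before log₂; negative net intensities floor to ε.
- Extent-sum tolerance ±0.5%; violations raise rather than renormalize.
- Identical ANOVA groups (zero within- and between-variance) report F = 0,
  p = 1 rather than NaN.
- All-zero paired differences raise ("no nonzero pairs").
- Moderated contrasts with zero residual df raise with advice to pool.
- Every stochastic routine takes an explicit seed; cohort generation spawns
  per-stage child seeds from one master seed, so identical config + seed
  yields byte-identical tables.

## Problem sizes used in validation

Simulation-based checks use 1000-antibody null arrays and 400-antibody
planted-effect arrays at n = 5 per group over 20 seeds; rank-test calibration
uses 2000 null replicates at the study's group sizes (n = 5, 6); the
end-to-end regression uses the shipped preset cohort (14 animals) at seed 42.

## Known limitations

- The HRCT extent-weighting formula and the grade-4 weight are
  reconstructions; only the reader-produced side scores were published.
- The invariant-lowess reconstruction approximates a proprietary vendor
  method; absolute log-ratios after normalization are comparable within, not
  across, normalization schemes.
- The one-shot titration policy is a declared choice, not the documented
  bedside procedure.
- Exact tests beyond their size limits fall back to asymptotics; at the
  study's n this never happens.
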