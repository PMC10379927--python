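# Methods

`anacquant` implements the data-analysis half of an external-standard
HPLC–DAD assay for the three anacardic acids (AnAc 15:3, 15:2, 15:1) of
cashew peduncle: signal → peak table → calibration → validation verdicts →
sequential-extraction quantification. This note records the models, the
defaults and why, the numerical choices, and what the synthetic data can
and cannot demonstrate.

## Signal model and simulator

A diode-array chromatogram is a time × wavelength absorbance matrix
(minutes × nm, mAU). The simulator renders each analyte as an
exponentially modified Gaussian in time (pure Gaussian at tailing constant
τ = 0, the default, since no asymmetry information is available for this
separation), scaled across wavelength by the analyte's reference UV
spectrum normalised to its 280 nm value — so the 280 nm monitor trace
carries exactly the nominal peak area. Peak area follows the linear
response `area = a·c + b` of the external-standard calibration
(defaults a = 2333.5 area units per µg·mL⁻¹, b = 2956.2, the published
line for the triene standard). The baseline is linear (offset + drift),
detector noise is additive i.i.d. Gaussian on the matrix, and retention
times jitter between injections with a configurable normal SD. Default
acquisition grid: 30 min at 100 points·min⁻¹, wavelengths 200–400 nm at
1 nm — the documented instrument settings for this assay (isocratic C18,
1.5 mL·min⁻¹, 20 µL injections, monitored at 280 nm).

Reference UV spectra are sums of Gaussian bands with unit maximum. The
catalog spectra use a salicylate-like pair of bands (~245 nm strong,
~308 nm weak) with small per-analyte red shifts, so the three homologues
are mutually similar (as in reality) yet distinguishable. Retention times
are not printed numerically in the study this package re-analyses, so the
catalog defaults (11.0 / 13.5 / 17.0 min, triene first — elution order by
decreasing polarity on C18) were fixed once as realistic values inside the
30 min run; nothing downstream depends on their exact positions.

What the simulator deliberately omits: column chemistry, gradient effects,
detector saturation, correlated (1/f) detector noise, and wavelength-
dependent noise. Passing tests on synthetic data therefore demonstrate the
correctness of the *arithmetic pipeline* under the stated statistical
model, not robustness to every instrument artefact.

Injection noise for series simulation defaults to a relative SD
(`cv_target`) of 0.002. No noise figure is published for this assay;
0.2% reproduces the order of magnitude of the reported sub-1% injection
CVs and is treated as a fixed study condition, not a tuning knob.

## Baseline estimation

The baseline estimator is an asymmetric-least-squares (Whittaker)
smoother: minimise `Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with weights p = 0.001 for
points above the current baseline and 1−p below, solved as a pentadiagonal
banded system (10 iterations or until the weight sets stabilise). The
`window` parameter (minutes, default 2) sets the stiffness via
λ = (window·sampling rate)⁴. A rolling-minimum baseline was considered and
rejected: on a drifting baseline it is biased low by slope·window/2, which
breaks the requirement that a peak-free drifting trace be recovered to
within 1% of its range. The AsLS fit recovers any linear trend exactly
(the second-difference penalty vanishes on lines) while narrow peaks
barely pull it up. Because asymmetric weighting settles on the lower noise
envelope, the fitted baseline is re-centred by the median of the small
residuals afterwards, so peak-free regions leave zero-median residuals.

## Peak detection, integration, matching

Detection runs on the baseline-corrected monitor trace with
`scipy.signal.find_peaks`: height and prominence at least `min_snr` ×
noise SD (noise estimated robustly from the median absolute first
difference, or supplied explicitly), width at least `min_width` minutes
(default 0.02). Boundaries go to the nearer of the baseline re-crossing
(trace falling to the noise level) or the local minimum towards the
neighbouring peak. Integration is the trapezoid rule on the sampled grid
over `[start, end]`, with negative baseline-corrected values clipped to
zero; a zero-width interval integrates to zero.

Retention-time matching requires catalog analytes separated by more than
twice the matching tolerance (default 0.5 min). Each analyte claims the
nearest peak within tolerance; ties break toward the larger area; the
losing peak is flagged ambiguous rather than reassigned.

## Peak purity (selectivity)

Purity is the minimum cosine similarity, over three points across the peak
(apex and the two half-height flanks), between the background-corrected
spectrum at that point and the analyte's reference spectrum, restricted to
220–400 nm (below 220 nm the mobile phase absorbs). Background per
wavelength is the linear interpolation between the matrix rows at the peak
bounds — the standard DAD correction. If a half-height crossing is not
found inside the bounds the bound itself is used and the result flagged.
The single-compound verdict uses an inclusive 0.95 threshold. Cosine
similarity was chosen because "spectral similarity" is reported without a
formula by vendor software; consequently the assay's printed purities
(99.17/98.19/99.40%) are carried as reference metadata, not as numbers
this package can recompute.

## Calibration statistics

Replicates enter the OLS fit as individual points, so n counts injections
(8 levels × 3 replicates = 24 by default). Dispersions use the
determinant form: `s_y² = Σdᵢ²/(n−2)`, `D = nΣxᵢ² − (Σxᵢ)²`,
`s_a² = s_y²·n/D`, `s_b² = s_y²·Σxᵢ²/D` — identical to the textbook
(XᵀX)⁻¹ standard errors, which the tests verify against a brute-force
matrix oracle. Coefficient significance is `t = |coef|/s` against the
two-sided Student quantile at n−2 degrees of freedom; the regression F
test is MS_reg/MS_res with (1, n−2) df, equal to t_slope² identically for
a straight line. Zero-dispersion exact fits report an infinite sentinel
and a significant verdict. A two-point fit is flagged degenerate and all
dispersion statistics are refused (zero residual df). Weighted fits are
not implemented; the assay uses unweighted calibration.

The published summary carries t_tab = 2.009 and F_tab = 1.576. Neither
matches the quantiles at 22 df (2.074 and 4.30); they are stored verbatim
as reference metadata while computed verdicts use the scipy quantiles at
n−2 df.

## Validation metrics

Precision uses the sample SD (n−1) and CV = 100·S/x̄. Intraday precision
is per-level over same-day replicates; interday reduces each level to day
means and takes the CV across those (the pooling scheme is not specified
in the source study; day-means is the conventional reading). The summary
CV is the mean of per-level CVs. System suitability is the RSD of
retention time and area over ≥ 6 consecutive injections of one level
(10 used in the assay), pass threshold 2.0% by default with a strict 1.0%
guideline profile. Detection limits implement the two conventional numeric
routes — signal-to-noise (LOD = 3σ/slope, LOQ = 10σ/slope) and residual-SD
(3.3·s_y/slope, 10·s_y/slope) — because the assay's own "visual
evaluation" is not computable; its printed 0.18/0.85 µg·mL⁻¹ are reference
metadata (the ratio 4.7 matches neither numeric method's fixed 10/3 or
10/3.3 ratio, confirming they came from visual assessment). Where the
source material prints both 0.85 and 0.83 for the LOQ, 0.85 (the summary
table) is stored.

## Sequential-extraction quantification

Unit chain: `concentration = (area − b)/a` µg·mL⁻¹, then
`amount = concentration × V/m × 0.1` mg per 100 g dry weight
(V = 3 mL reconstitution, m = 0.5 g powder by default). Negative
back-calculated concentrations quantify as 0 and are flagged;
concentrations above the top calibration level are flagged
`above_calibration_range` rather than silently extrapolated (several
published monoene first extracts imply ~180 µg·mL⁻¹ against a 100 µg·mL⁻¹
top level, with no dilution documented).

Censoring: records with concentration strictly below the LOQ are marked
censored (the LOQ itself is quantifiable); censored amounts are excluded
from totals but their raw areas remain in the recovery denominator. This
is the only reading that reconciles recovery tables with five nonzero
entries per row against amount tables printing `<LOQ` in the same cells.

Recovery per step is the raw-area share `R% = A_x/ΣA_n × 100`; cumulative
recovery is the prefix sum, and `extractions_needed` is the smallest k
whose cumulative reaches the threshold (default 90%). Matrices built from
raw areas sum to exactly 100; matrices built from published
presentation-rounded percentages are accepted if they sum to 100 ± 1.5
(published rows stray up to ~1% from 100 after rounding).

A caveat that matters for simulation: because the generator back-computes
areas through the full calibration line, a nonzero intercept adds a
constant to every step's area, so area shares are biased towards the small
late steps relative to amount fractions. Depletion round-trip tests
therefore use a proportional (zero-intercept) response — physically, a
blank injection has zero peak area and the fitted intercept is a
regression artefact. Published recovery rows are consistent with raw areas
carrying such an offset, which is why recovery shares and amount fractions
differ in the published tables as well.

The depletion model itself is per-step efficiency applied to the analyte
*remaining* before that step (not a geometric ratio, which the observed
profiles do not follow); efficiencies are free parameters and
`DepletionProfile.from_step_fractions` inverts observed per-step shares
exactly.

Internal arithmetic is never rounded; presentation rounds to 2 decimals,
and comparisons against published tables use a 0.02 absolute tolerance for
re-added rounded components.

## Problem sizes in tests

Monte-Carlo checks use sizes chosen to make the statistics decisive while
keeping the suite quick: 1000 null regressions for the type-I error rate,
500 seeds for calibration parameter recovery, 400 pure-noise traces for
the false-positive rate, 25 full-pipeline chromatograms for the area-error
distribution, 20–200 seeds elsewhere.

## Known limitations

- No deconvolution of fused peaks; heavily overlapped peaks integrate as
  their merged envelope and fail purity instead.
- The purity score is not the vendor's (undocumented) purity index.
- Interday pooling and the LOD/LOQ method are package decisions where the
  source assay is silent or non-computable.
- Uncertainty propagation across extraction replicates reports plain SDs;
  no calibration-uncertainty propagation into amounts.
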