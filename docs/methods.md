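# Methods

This note documents the models, conventions and numerical choices behind
`cardioresp`, and what the synthetic cohorts do and do not establish about
real recordings.

## Analysis pipeline

**Segmentation.** The maneuver protocol (default SR/CR6/CR15, 120 s each) is
laid end to end from the recording origin with half-open windows
[start, end), so every beat inside the protocol span belongs to exactly one
phase and boundary beats are never double-counted. A phase with fewer than
30 beats is rejected as unanalyzable.

**Rhythm screening.** A recording is excluded whole if any beat looks
ectopic. Beat *k* is flagged when its RR deviates from the 11-beat local
median by more than 20 % of that median *and* shows the ectopic jump-pair
signature: sign-reversing successive differences on both sides, each larger
than 1.25 × 20 % of the local median. The second condition is what makes the
filter specific: vagotonic subjects at slow heart rates sample their
respiratory sinus arrhythmia at only ~4 beats per breath, so individual
beats legitimately sit 20–30 % away from the local median, but a smooth
oscillation never produces an abrupt down–up pair of that size, whereas a
premature beat plus compensatory pause does. On simulated cohorts the two
populations separate by more than a factor of two in this metric. The
verdict semantics (exclude on any flag) mirror the practice of dropping
whole recordings with extrasystoles or non-sinus rhythm; the operator is a
stand-in for what is usually a manual decision.

**Time domain and geometric indices.** RMSSD is the root mean squared
successive difference; pNN50 the percentage of successive differences above
50 ms. The Baevsky stress index SI = AMo/(2·Mo·MxDMn) uses a histogram with
fixed 50 ms bins anchored at zero; Mo is the modal-bin midpoint in seconds
(ties broken toward the slower bin), AMo the modal-bin percentage, MxDMn the
RR range in seconds. This is the only convention under which the 30/100 c.u.
classification thresholds are dimensionally sensible. All-identical input
makes SI undefined and raises.

**Spectra.** The beat-value series (RR ms, SBP/DBP mmHg) is cubic-spline
resampled at 4 Hz, linearly detrended, and analyzed with Welch's method
(Hann window of min(100 s, record length), 50 % overlap). Band powers are
trapezoid integrals over VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz; TP
integrates 0.0033–0.40 Hz; LFn/HFn normalize LF and HF to their sum. On
2-minute phases the VLF estimate is intrinsically low-resolution (≤ 4 cycles
of the slowest in-band component per window); treat absolute VLF and TP from
such short records as estimator-dependent.

**Coupling indices.** Baroreflex sensitivity is the spectral α-coefficient
α = √(P_RR/P_SBP) per band. The un-rooted power ratio is available as an
explicit option but warns: it is a squared gain (ms²·mmHg⁻²), an order of
magnitude above physiological α values — applying both to the published
per-type median band powers reproduces the published BRS medians only under
the square root. HI = HR/RR_resp and VSI = CO/V_E are exact quotients;
respiratory rate is the count-based per-minute rate over the phase (not the
reciprocal mean cycle), CO = SV·HR/1000 from the per-beat stroke-volume
channel.

**Classification.** Shlyk rules on resting (SI, VLF, TP): I = SI > 100 &
VLF > 240; II = SI > 100 & VLF ≤ 240; III = 30 ≤ SI ≤ 100 & VLF > 240;
IV = SI < 30 & VLF > 500 & TP > 8000. Published boundary membership is
ambiguous; the conventions here (inclusive 30–100, ≤ 240 as the complement
of > 240, the lower bound of the printed "8000–10000" TP range) are explicit
package choices, overridable via `ClassifierThresholds`. Triples matching no
rule return UNCLASSIFIED with a rationale rather than being forced to a
nearest type.

**Increments and cohort statistics.** δX = X(CR) − X(SR) per subject
(positive δHI at CR6 means HI rose under slow paced breathing — the sign
convention that matches the direction of reported changes). Subjects with
any failed phase are dropped from delta analysis entirely (complete case).
Cohort tables report median (Q1; Q3) with linear-interpolation (type 7)
quantiles. Wilcoxon matched-pairs uses exact enumeration for ≤ 20 tie-free
non-zero pairs and the continuity-corrected normal approximation otherwise;
|z| is always reported from the normal standardization. Between-group
comparisons use Mann–Whitney (exact for small tie-free samples, else
tie-corrected asymptotic). The two-way ANOVA uses sequential (Type I) sums
of squares — A (paced condition, 2 levels), then B (HRR type, 4 levels),
then A×B — the only decomposition whose components sum exactly to the total
under heavily unbalanced groups; with 183 subjects × 2 conditions this gives
the (1, 3, 3, 358) df pattern. Grouping uses the cohort's design labels
(generating type), with each subject's pipeline classification reported
alongside.

## Synthetic-data generator

**Model.** Beat times follow an integrate-to-next-beat rule
t_{k+1} = t_k + RR(t_k)/1000 with

RR(t) = mean_rr + sat(x(t)) + ε,  x(t) = Σ components,  sat(x) = S·tanh(x/S)

The components are a narrowband VLF carrier at 0.025 Hz, a 0.1 Hz Mayer-wave
(LF) sinusoid, and a respiratory-sinus-arrhythmia term whose phase
integrates the breath-by-breath instantaneous respiratory frequency
(phase-continuous across breaths), each with amplitude √(2·band target) so
nominal sinusoid power equals the requested band power. Systolic pressure
carries the same LF and respiratory oscillations divided by the preset
baroreflex gains α_LF, α_HF, plus noise; it is kept linear (no clamp), so
the measured spectral ratio √(LF_RR/LF_SBP) of a spontaneous phase recovers
α_LF by construction. DBP = SBP − 40 mmHg + noise; stroke volume is
constant. Default measurement noise: 3 ms (RR), 1.5 mmHg (SBP).

**Phase gains.** Slow paced breathing multiplies the RR-side RSA amplitude
by `rsa_gain_cr6` (default 2.0; vagal enhancement of deep slow breathing);
hyperventilation multiplies both the LF and RSA RR amplitudes by
`rsa_gain_cr15` (default 0.6; global vagal withdrawal). Pressure-side
amplitudes never change, so measured BRS rises at CR6 and falls at CR15.
These two defaults are calibration knobs chosen to reproduce the observed
sign structure of the maneuver response, not measured quantities.

**Why a rhythm clamp.** A pure sinusoid sum has a platykurtic marginal: its
histogram is wide and flat, and the emergent stress index of a
sympathicotonic profile comes out near 90 where real records show ~170.
The tanh clamp bounds RR excursions (tight S for central-regulation types,
loose for autonomous ones), concentrating the histogram the way stabilized
sympathicotonic rhythms are in practice. S is solved per type so the
emergent SI matches the type's median profile.

**Why a single VLF component.** On 2-minute records, any VLF realization
with several components ~0.01 Hz apart beats with periods comparable to the
window, and the realized in-band power scatters severalfold between seeds.
A single 0.025 Hz carrier estimates almost deterministically (0.96–1.00 of
nominal) and makes band-power calibration meaningful. The cost is that
simulated VLF is narrowband, unlike real 1/f-like VLF.

**Calibration.** Per type, fixed multipliers (c_vlf, c_lf, c_hf) and the
clamp scale S are solved once by a damped fixed-point iteration on fixed
internal seeds (15 recordings per iteration, 8 joint + 2 gain-only rounds),
so that the band powers *measured by the package's own spectral pipeline*
and the emergent SI match the type's targets; results are cached, making
`make_preset` deterministic and cheap. Residual bias is a few per cent,
except the most tightly clamped type where deep saturation leaves measured
LF ~8 % under target — an inherent trade-off between the SI and band-power
targets under this model, inside the generator's 15 % calibration contract.

**Cohorts and seeds.** Default sizes 53/29/85/16 (n = 183). One master seed
spawns per-subject `numpy.random.SeedSequence` children, so any subject can
be regenerated independently. Subject-level dispersion is invented (the
published tables give only medians and quartiles): median-preserving
lognormal scatter on powers (shared factor σ = 0.30 plus per-band σ = 0.15)
and baroreflex gains (σ = 0.15), mild coefficients of variation on rates and
volumes, all draws truncated at ±1.8 σ to keep subjects physiological.
Paced-phase tidal volumes are derived from the published median VSI
increments at the median cardiac output, which is why simulated δVSI medians
land near the published ones by design.

**What the simulator does not emulate.** Continuous waveforms (no PQRST
morphology, no pulse contour); broadband/fractal VLF; nonlinear closed-loop
baroreflex dynamics (no DeBoer-style feedback — gains are prescribed, not
emergent); ectopy beyond the uniform RR-spike injector used for QC tests;
hemodynamic stroke-volume responses to the maneuver (SV constant). Passing
tests therefore show that the *analysis* pipeline is correct and internally
consistent and that the generator meets its calibration contract — they do
not validate physiological claims about real athletes.

## Numerical details and degenerate inputs

- Resampling requires ≥ 30 beats spanning ≥ 60 s; spectra require ≥ 60 s of
  uniform samples. Shorter inputs raise with a named reason.
- Band integration uses trapezoids on the Welch grid; a band covered by
  fewer than two frequency bins contributes zero.
- SI modal-bin ties break toward the slower (longer-RR) bin via argmax on
  the anchored histogram.
- brs_alpha raises on zero pressure power ("BRS undefined") rather than
  returning infinity.
- The generator floors RR at 0.3 × mean_rr (an IPFM guard against
  non-physical negative intervals; never active at default parameters).
- Wilcoxon drops zero differences and requires ≥ 5 informative pairs; ties
  in |d| force the normal-approximation branch at any n.
- ANOVA validates every design cell non-empty and ≥ 1 residual df; the
  implementation is OLS + sequential anova_lm, cross-checked in the tests
  against explicit nested least-squares projections.
- Problem sizes in tests and the acceptance script (20–50 seeds per
  recovery estimate, one 183-subject cohort) were chosen as the smallest
  that make the medians stable; all are package defaults, reproducible from
  the stated seeds.

## Known limitations

- Absolute VLF and TP from 2-minute phases are estimator-dependent;
  comparisons with values from other devices/estimators should be treated
  as order-of-magnitude only.
- The classifier reproduces published *rules*; published cohort proportions
  cannot be validated without the raw data.
- BR_HF during CR6 is ill-defined in principle (the HF band is empty of
  respiratory drive when breathing at 0.1 Hz); the pipeline still reports
  it, and on synthetic data it reflects the noise floors of both channels.
- The Mann–Whitney choice for between-group p-values is an assumption; the
  source tables do not name their between-group test.
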