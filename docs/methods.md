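# Methods

`spinefate` implements the analysis chain of a single-synapse optogenetic
plasticity experiment: presynaptic axons expressing a channelrhodopsin are
driven with light pulses while a postsynaptic pyramidal neuron expressing a
calcium indicator (GCaMP6s-like kinetics) and a volume marker is imaged with
two-photon microscopy. The pipeline quantifies evoked spine calcium
transients (EPSCaTs), classifies LTP/LTD induction outcomes, converts spine
fluorescence to absolute volume via a PSF calibration, and follows spine
survival across imaging days (d0, d1, d7). A seeded synthetic-data generator
emulates each recording modality so that every stage can be validated by
parameter recovery against recorded ground truth.

## EPSCaT model and quantification

**Transient shape.** A single evoked transient is modeled as a unit-peak
double exponential

    f(t) = [exp(−(t−t0)/τ_decay) − exp(−(t−t0)/τ_rise)] / peak,   t ≥ t0,

with τ_rise < τ_decay. Paired test stimuli (two 2-ms pulses, 40 ms apart)
produce a two-onset shape; the summed shape is renormalized to unit peak so
that fitted amplitudes remain in ΔF/F₀ units regardless of pulse overlap.

**Template extraction.** τ_rise, τ_decay and a shared onset offset are fit
to the trial-average trace by bounded nonlinear least squares
(`scipy.optimize.least_squares`, tolerances 1e-10), initialized from
curvature heuristics: τ_rise = time-to-peak / 3, τ_decay = 2 × post-peak
half-life / ln 2. Bounds: τ_rise ∈ [1 ms, 1 s], τ_decay ∈ [10 ms, 10 s],
onset offset ∈ [−20, +50] ms. The fit is deterministic (no random
restarts). A mean trace whose peak is below 2·σ/√n_trials is reported as
"no template" (returns `None`) rather than fitted. An optimum with
τ_rise ≥ τ_decay raises a diagnostic error.

**Per-trial amplitude.** With the template fixed, the only free parameter
per trial is the amplitude; the least-squares optimum is the closed-form
projection a = ⟨y, s⟩ / ⟨s, s⟩. Because s is unit-peak, a is directly the
value of the fitted curve at its maximum. Negative optima are retained (and
classified as failures) so that the mean amplitude is unbiased under the
null.

**Success rule and baseline σ.** A trial is a success iff its amplitude
strictly exceeds 2σ of baseline noise. σ is estimated in *amplitude units*:
each trial's pre-stimulus segment (everything before the first stimulus
minus a 10-ms guard) is projected onto the template transient placed at the
segment start, and σ is the SD of these pseudo-amplitudes across trials.
This makes the 2σ threshold commensurate with fitted amplitudes; since the
baseline window is shorter than the analysis window, σ slightly
overestimates the amplitude noise and the rule is conservative (measured
false-positive rate ≈ 0.2 % per trial rather than the 2.3 % a raw 2-SD
Gaussian tail would give). A `raw` mode (pooled SD of baseline samples) is
available behind a config switch. Early mean-subtraction of the baseline
segments was deliberately avoided: removing each segment's mean also removes
most of the slowly varying template component and collapses σ several-fold.

**Summaries.** Per spine: mean amplitude (all trials, failures included —
a `zeroed_failures` mode zeroes them instead), potency (mean over successes
only; undefined and flagged when there are none), and P_Ca = success
fraction, the proxy for presynaptic release probability.

**Responder detection (frame scans).** Per ROI, ΔF/F₀ is computed against
the mean of the pre-stimulus frames; the resting SD is pooled over the
pre-stimulus frames of all trials; an ROI is "potentially responding" when
any post-stimulus frame of any single trial exceeds 2 × that SD. This is a
screening criterion: its per-ROI false-flag probability under pure noise is
the tail of the max of all post-stimulus samples and is therefore high by
design (candidates are confirmed by line scans). Tests validate it by hit
rate on true responders and by agreement of the null flag rate with a
Monte-Carlo simulation of the same decision arithmetic.

## Induction classification

The response measure is the mean EPSCaT amplitude over 10–20 trials
(failures included; a potency-based mode exists for sensitivity analysis).
With ratio = post / same-day pre:

* LTD after low-frequency stimulation (oLFS, 900 pulses at 1 Hz) is
  successful iff ratio < 0.90 (strict);
* LTP after theta-frequency stimulation (oTFS, 150 pulses at 5 Hz) is
  successful iff ratio > 1.10 (strict).

Day-1 ratios always use a freshly measured day-1 baseline. Experiments
failing the day-0 criterion are labeled `excluded` and take no further part
in survival analysis. Outcome pairs map onto the condition taxonomy
(`LTD_then_LTP`, `LTD_then_oTFS_fail`, `LTP_then_LTD`,
`LTP_then_oLFS_fail`, single-day `LTD`, `LTP_with_CSB`, `oTFS_no_CSB`).

**CSB proxy.** Complex spike bursts are gated electrophysiologically in the
lab; here they are detected from the dendritic calcium trace recorded
during induction: any sample exceeding 5 × the pre-induction baseline SD
(configurable) marks a CSB-like event; contiguous supra-threshold runs
count once. The 5×SD default separates the large dendritic transients that
accompany bursts from single-synapse signals; it is a heuristic proxy and
is not validated against electrophysiology. A missing dendrite trace yields
"not applicable", never a silent `False`.

**Postsynaptic spike probability** during an induction train is the median
total action-potential count across experiments divided by the number of
pulses (e.g. 1.5 APs / 900 pulses ≈ 0.17 %).

## Volumetry

**PSF calibration.** Sub-resolution beads (0.17 µm, smaller than the
lateral FWHM) are segmented as isolated blobs and each is fit with a 3-D
Gaussian; per-axis FWHMs are averaged. From the Gaussian closed forms:
V_PSF = (2π)^{3/2}σxσyσz, A_xy = 2πσxσy, and the effective axial extent
z_eff = V_PSF / A_xy = √(2π)·σz.

**f_max.** The brightness of the cytoplasm with the PSF fully immersed is
the 99th-percentile value of a locally box-averaged (5³ voxels) stack
inside a trunk ROI. The local averaging keeps the "robust maximum"
semantics while suppressing the upward bias a raw-voxel percentile takes
from shot noise (+2.33 SD). Trunks thinner than 2 × the lateral FWHM are
flagged: f_max then underestimates true brightness.

**Volume conversion.** From a single optical section through the head
center:

    V = Σ_ROI (F − background) · a_pixel / f_max_corrected · z_eff,
    f_max_corrected = f_max · exp(−Δdepth / λ),

with background the median of an annulus around the ROI and λ the
exponential attenuation length accounting for laser power loss with depth
(default 50 µm; the exponential form and its constant are modeling
assumptions surfaced in config, not measured quantities). The formula's
defining property — an ROI in a uniform cytoplasm slab returns exactly
ROI area × z_eff — is asserted in tests. On synthetic spheres of
0.05–0.5 µm³ rendered through the default PSF the estimator is accurate to
better than 10 % (bias grows toward −7 % at 0.5 µm³ because the axial
Gaussian weighting under-samples the sphere's poles).

**Registration and tracking.** Sessions are aligned by the integer-voxel
shift maximizing the FFT cross-correlation (no rotation; a rigid-body hook
is left in the interface; the synthetic data contains no rotation). Spines
are tracked by greedy nearest-position matching along the dendrite.
A matched spine displaced by more than 1 µm between consecutive sessions is
*excluded* from analysis (identity ambiguous), not counted as eliminated;
an unmatched prior spine is eliminated, terminally (re-appearing detections
are reported as gained but not used in survival). Detections closer than
0.2 µm raise an ambiguity error.

**Roles.** Relative to the stimulated spine: ≤ 5 µm → nearest neighbor,
(5, 10] µm → distant, > 10 µm ignored. The boundary closures are a
documented convention (the source thresholds are quoted as ">5 µm" and
"within 10 µm" without closures) and are configurable, as is a
`single_closest` mode restricting "nearest neighbor" to the one closest
spine.

**Survival.** Per condition × role, the surviving fraction between two
sessions among non-excluded spines present at the start session, with a
seeded percentile bootstrap over experiments (cluster bootstrap). Zero
denominators give NaN (undefined), never 0.

## Synthetic-data generator

The generator's defaults are the study conditions; they live in one
declarative calibration table (`spinefate.config.DEFAULT_CALIBRATION`,
editable via YAML) and are read by the generators at run time — changing
the table changes behavior with no code change.

* **Trial sets** (line scans, 500 Hz, 20 trials, 3 s): Gaussian baseline
  noise (SD 0.1 ΔF/F) plus, per pulse, an independent Bernoulli release
  (default p = 0.5) scaled by a log-normal amplitude (mean 1.0 ΔF/F,
  CV 0.3; log-normal because quantal responses are strictly positive and
  right-skewed). The second pulse of a pair is scaled by a paired-pulse
  ratio (default 1.0). Trial-to-trial amplitude distributions and
  paired-pulse dynamics are not reported for this preparation; these
  defaults are flagged as placeholders in the config.
* **Frame scans** (14 frames, 64×64 px, 7.8 Hz, 10×10 µm): 2-D Gaussian
  spine blobs on a static dendrite band; the responding spine follows the
  transient resampled at the frame rate; noise is Gaussian with variance
  proportional to intensity. No motion artifacts.
* **Structural stacks:** spherical heads on a cylindrical dendrite
  (radius 0.4 µm, neck 1.0 µm — long enough at the default PSF that head
  and dendrite light are separable in the measurement ROI), scaled by
  exp(−depth/λ), convolved with the Gaussian PSF, optional Gaussian noise.
  Spheres give analytic ground-truth volumes.
* **Bead stacks:** solid 0.17-µm spheres rasterized with sub-voxel
  supersampling and convolved with the stated PSF; bead size inflates the
  recovered lateral FWHM by ~2.5 %, which the 5 % calibration tolerance
  absorbs.
* **Cohorts:** per experiment, one stimulated spine mid-dendrite plus
  neighbors placed uniformly within the 10-µm horizon (6 spines/dendrite,
  20-µm segment, baseline volumes log-normal: mean 0.15 µm³, CV 0.5).
  Induction success is Bernoulli with the condition's configured
  probability (LTD day 0: 0.70; LTP after LTD: 0.64; LTP day 0: 0.72;
  LTD after LTP: 0.33). Successful LTP scales d0-post volumes by role
  (+21 % stimulated, +15 % nearest, +2 % distant) and relaxes to baseline
  by day 1. Elimination between d1 and d7 is a single Bernoulli event per
  spine with role- and outcome-specific probability (control 27 %,
  LTD 45 %, LTD►LTP 12 %, LTD + failed oTFS 43 %, LTP►LTD 50 %,
  LTP + failed oLFS 8 %; successful first-day LTP 9 % ≙ 1/11 spines).
  When induction fails, elimination falls back to the matching
  failed-protocol condition. Measured post/pre response ratios carry
  log-normal measurement error with CV 0.03, representing the standard
  error of a 10–20-trial averaged amplitude ratio under good SNR; the
  value keeps threshold classification errors small relative to binomial
  sampling, so recovery tests probe the survival bookkeeping rather than
  classifier noise. Per-session volume measurements carry 5 % log-normal
  noise; 2 % of spines are displaced > 1 µm to exercise the exclusion
  rule.

Ground truth (every Bernoulli and log-normal draw) is emitted alongside
each dataset and never consumed by analysis stages.

What the generator does **not** emulate: motion and rotation between
sessions, bleaching, neuropil contamination, non-Gaussian PSF aberrations,
spine-neck fluorescence, dendritic spikes in the spine trace, correlated
release across pulses, and intermediate imaging sessions between d1 and d7.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated generative model, not robustness to artifacts absent from
it.

## Numerical and design choices

* Strict inequalities at every threshold (2σ success, 0.90/1.10 induction)
  follow the "exceeded / dropped below" wording of the criteria.
* The recovered-vs-configured table is computed within each generated
  cohort (experiments whose measured label equals the generating
  condition), because pooling across cohorts lets misclassified
  experiments from neighboring conditions leak low- or high-elimination
  spines into a cell and bias it.
* One global seed expands into per-stage substreams via
  `SeedSequence([seed, crc32(stage)])`, so stages are individually
  reproducible; all generators are byte-deterministic given a seed.
* Problem sizes in the validation suite (e.g. ~1000 spines/condition over
  10 seed replicates for survival recovery, 10⁵ Monte-Carlo trials for the
  null calibration) were chosen so that 3-SE recovery bands are a few
  percentage points wide while the whole suite runs in well under a minute.
* Neuron-health exclusion is a pass-through boolean on user data; it is
  not computed from images.

## Known limitations

* The volume estimator's accuracy degrades for heads approaching the axial
  PSF extent (−7 % at 0.5 µm³) and for sub-PSF heads the linearity test is
  the only guard; deconvolution is out of scope.
* The CSB proxy threshold (5×SD) is not validated against
  electrophysiology.
* Registration handles translations only.
* The hypothesis-test battery of the original workflow is deliberately
  replaced by descriptive statistics and bootstrap intervals.
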