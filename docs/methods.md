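# Methods

## The design being modeled

A session consists of eight ~3-minute blocks crossing visual load (low,
high) with the tone stream (oddball, equiprobable control), each
combination appearing once per half-session in random order. Every
500-ms trial presents a 100-ms cross at fixation simultaneously with a
100-ms tone. The visual stimuli are identical under both loads — only
the target rule changes (low: any red cross; high: upright-yellow or
inverted-green) — so load effects cannot be confounded by physical
stimulus differences. The oddball stream is 550-Hz standards with 12.5%
500-Hz deviants; the control stream presents eight frequencies
(500–974 Hz) at 12.5% each, which makes the 500-Hz *critical* tone
physically identical to and exactly as frequent as the deviant. The
oddball MMN (deviant − standard) is therefore confounded by frequency
and probability differences; the corrected MMN (deviant − critical)
isolates the pattern-violation response.

## Sequence generation

The published constraints say *what* held, not *how* randomization was
done, so the generators commit to exactly-uniform sampling over the
admissible set:

- **Deviant placement.** The ≥3-standards-between-deviants rule is a
  gap composition: subtracting the minimum gaps leaves a weak
  composition of the slack, sampled exactly by stars and bars. Every
  admissible placement has equal probability (verified against brute
  force enumeration on 16-trial blocks).
- **Target placement.** The 72 pre-target runs (each 2–6 non-targets,
  summing to 288; the block ends on a target) are drawn uniformly over
  valid compositions by sequential sampling from a dynamic-programming
  count table (verified against exhaustive enumeration on a toy
  design). Independent per-gap draws would bias the gap distribution.
- **Control sets.** Each set of 8 is a uniform permutation, re-drawn
  whole when its first tone repeats the previous set's last; this
  makes each set uniform over admissible permutations given its
  predecessor. (The alternative — local swaps — would bias later
  positions.)
- **Tone–target independence.** The published property that targets sat
  on exactly 20% of 500-Hz trials and 20% of the rest is enforced at
  session composition by re-drawing the visual block until the
  coincidence counts are exact (9/45 and 63/315), i.e. sampling
  conditional on the constraint. Warm-up trials (7 tone + 7 aligned
  visual non-targets) precede each block and are flagged out of every
  analysis.

## Synthetic EEG

Each epoch spans −100…+500 ms around onset at a default 256 Hz (the
original recording was 1024 Hz; 256 Hz keeps every window well sampled
at desk-scale cost; tests mostly run at 128 Hz, the enforced minimum).
An epoch is the sum of:

- **Components.** Half-cosine bumps over the component's own
  measurement window, weighted across channels (N1/MMN frontocentral:
  Fz = Cz = 1, Pz = 0.4; P3a/visual-P3 centroparietal: Cz = Pz = 1,
  Fz = 0.4; P9/P10 carry 0.3 of either so the nose-vs-mastoid
  rereferencing contrast is non-degenerate). Amplitudes are specified
  as the *mean over the window* and the discrete envelope is
  normalized to unit window mean, so a noise-free simulation
  reproduces injected truths exactly at any sampling rate. Deviants
  carry standard response + oddball-MMN (+ P3a); the critical tone
  carries standard response + (oddball-MMN − corrected-MMN), making
  deviant − critical equal the injected corrected MMN. Visual targets
  add the visual P3 in all tone conditions equally; because targets
  are exactly equally frequent on every tone class, the visual P3
  cancels identically in every tone difference wave, and tone
  components cancel in the target − non-target contrast.
- **Noise.** AR(1) with coefficient 0.95 scaled to a stationary SD of
  3 μV by default (a low-frequency-dominated spectrum resembling EEG
  at trivial cost); white and 1/f options are available. Per-epoch
  offset and linear drift (SD 0.5 μV) stand in for slow potentials.
  None of these values is a claim about the original recordings —
  the noise model there is unknowable from the publication.
- **Artifacts.** With probability 0.02 per epoch, a ±300 μV
  (×U(0.7, 1.3)) half-cosine excursion on all channels. 2% is
  realistic for cooperative adults and sits below the default
  rejection cutoff's 2.5% breakdown point (see below).

Cohorts draw each subject's low-load amplitude and high-minus-low
effect from independent normals per component (defaults: the published
cell means, with SDs back-computed from the published CIs). Working
memory capacity shares a latent standard normal with the N1 load
effect at a configurable correlation (default 0.35, the published
value) and maps to a PCU score as 0.7 + 0.12·z clipped to [0, 1]; the
clipping slightly attenuates extreme correlations but is immaterial at
|ρ| ≤ 0.5. All randomness flows from one seed through separated
per-subject session/noise streams, so cohorts are bit-reproducible.

What the generator does **not** emulate: ocular and muscle artifact
morphology, volume conduction/montage structure beyond fixed channel
weights, latency jitter, overlapping responses from adjacent 500-ms
trials, and component shapes other than the half-cosine. Passing tests
therefore certify the *pipeline and inference machinery*, not claims
about real-EEG robustness to those phenomena.

## Measurement pipeline

Baseline = mean over samples in [−100, 0) ms, subtracted per
epoch/channel. Rereferencing: `nose` (identity on simulated data) or
`mastoid_mean` (subtract the P9/P10 average per sample). Artifact
rejection is condition-blind and uses the within-epoch amplitude range
(max − min per channel, maximized over the analysis channels Fz, Cz,
Pz): an epoch is rejected when the range exceeds the cutoff. The
original study set cutoffs by per-subject visual inspection, which is
irreproducible; the default here is a deterministic stand-in — 1.5 ×
the subject's own 97.5th range percentile — with an absolute-μV
override. Subjects are excluded when any primary cell (deviants,
standards, control tones, per load) retains < 70% of epochs. Mean
amplitudes average samples with start ≤ t ≤ end (inclusive endpoints,
matching common ERP-toolbox behavior; discretization error is bounded
by one sample) and then average the listed electrodes. The N1 is
measured on all control-condition tones per load; P3a uses the
deviant − standard difference (the published deviation from the
preregistered deviant-only variant, which remains available behind a
flag). The published 30-Hz low-pass is presentation-only and exists
solely as a plotting helper, never before measurement.

## Inference

The Dienes-style Bayes factor treats the group mean difference m (SE
`se`, df = n − 1) as scaled-t likelihood f_t((m−δ)/se)/se and puts a
uniform prior on δ: [−1.5, +1.5] μV two-tailed, or the hypothesized
half ([0, +1.5] for the N1/MMN load effects, [−1.5, 0] for P3a and the
visual P3 — orientation chosen per effect's predicted sign). The
marginal likelihood is evaluated by adaptive quadrature on the t scale
with the integrand rescaled by its in-range peak, keeping far-tail
cases (|t| > 8, e.g. the visual P3 at t ≈ −10.5, where both marginals
are ~1e−13) finite; results carry log BF₁₀ alongside BF₁₀ and BF₀₁
(reciprocals by construction). Quadrature tolerance is 1e−10 relative
with a 1e−6 convergence guard; an exact t-CDF closed form and dense
Riemann sums serve as independent oracles in the tests, agreeing to
1e−6–1e−8 relative. When per-subject spread is numerically zero
(noise-free simulations) the likelihood has no scale and the results
table flags the row degenerate instead of fabricating a BF.

Printed-summary reproduction inverts each published 95% CI to an SE
via se = width / (2 t(0.975, 48)). Recomputed BFs then match the
published ones within ~1% (two-tailed) to ~4% (one-tailed and
correlations); the residual is consistent with the 2-decimal rounding
of the printed inputs and possibly integrator details of the original
custom scripts, and is documented rather than tuned away.

Correlation BFs use the exact sampling density of Pearson's r under
bivariate normality, p(r|ρ,n) ∝ (1−ρ²)^((n−1)/2) (1−ρr)^((3−2n)/2)
₂F₁(½, ½; n−½; (1+ρr)/2), with a flat prior on ρ (the β = 1 stretched
beta; other β are supported), integrated on a 4001-point grid with
trapezoid normalization in log space. Credible intervals for ρ are
central 95% posterior intervals (the highest-density convention is not
implemented; for these near-symmetric posteriors the difference is
second-order). Credible intervals for mean differences use the
improper flat prior and coincide with the frequentist t interval.
Evidence labels follow the conventional thresholds (1, 3, 10, 30, 100:
anecdotal, moderate, strong, very strong, extreme) applied to
whichever of BF₁₀/BF₀₁ exceeds 1.

## Problem sizes and numerical choices in the test suite

Unit tests run scaled-down conditions chosen as the package's own
desk-scale defaults: 120-trial blocks, 128 Hz, 3–12 subjects;
full-size (360-trial, 49-subject) conditions are exercised where the
claim depends on them (noise-free exactness, single-subject SEM
bounds). The calibration check runs 200 cohorts of 12 subjects with a
true load effect of zero and verifies 95% ± 3% CI coverage. Sequence
validators sweep 10,000 seeds. Analytic SEM bounds for AR(1) noise
drop the (positive) window–baseline covariance term, making the bound
conservative. Known limitations: the percentile cutoff assumes < 2.5%
gross artifacts; the AR(1) noise model understates alpha-band
rhythmicity; and between-subject amplitude distributions are normal by
assumption, not by evidence.
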