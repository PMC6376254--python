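# Methods

## Western-blot densitometry

A lane is quantified from its 1-D intensity profile: the mean over a
20-pixel-wide vertical sampling band centred on the lane (`width_px`
configurable).  Profiles are oriented so that bands are maxima; for images
where bands are darker than the membrane (chemiluminescence film), the
profile is computed on `image.max() − image` (`invert=True`).  Row 0 is the
top of the gel (highest molecular weight) throughout.

**Peak detection.**  Peaks are local maxima of the lightly smoothed profile
(3-px moving average, used only for localization, never for integration)
with prominence at least `max(min_prominence · max(corrected profile),
5 · σ̂)`, where `min_prominence` defaults to 0.05 and σ̂ is a robust noise
estimate (1.4826 · median |first difference| / √2).  The 5 % relative floor
admits faint non-specific bands on clean profiles; the noise floor prevents
correlated noise bumps from being counted as bands, which would otherwise
contaminate the total-area denominator of the specificity index.  Each peak
region extends 1.6 half-prominence widths either side of the apex (≈ ±3.8 σ
for a Gaussian band, > 99.9 % of its area) and is clipped at the valley
between adjacent apexes, so regions are disjoint.

**Baseline.**  Manual practice is to draw a segmented line under the peaks;
the automated equivalent anchors the baseline at the valley of every
inter-peak gap — specifically at the median-valued row within ±2 px of the
smoothed-profile minimum, which keeps the anchor on the profile while
resisting single-pixel noise troughs — and interpolates linearly across the
peak regions.  With no declared peaks the baseline is the profile itself; a
single region spanning the whole profile falls back to the profile minimum
at both ends (with a warning).  An explicit anchor list can be supplied by
constructing a `Baseline` directly, reproducing any manual segmented line.

**Integration.**  A peak's area is the trapezoidal integral of
`max(profile − baseline, 0)` over its half-open region, with the corrected
signal taken as zero immediately outside the region.  This equals the plain
sum of the corrected values over the region, so a rectangle of height *h*
over *w* rows integrates to exactly *h·w*, and the measurement agrees with
a brute-force Riemann sum to machine precision.  Whether the original
manual workflow used a sum or trapezoid over the sampled profile is not
specified anywhere; mean-profile + this integration rule is the package's
documented choice.

**Molecular weight.**  `log10(mw)` is fitted linearly against row from the
ladder anchors (≥ 2, strictly decreasing MW down the gel); the fit is
rejected if it cannot round-trip its own anchors within 2 %.

## Specificity index

The band of interest is the peak whose calibrated MW lies within ±20 % of
the expected size (default, configurable via `mw_tolerance`) and whose
matched KO peak — the closest-in-MW peak inside the same window — is absent
or has lost at least `min_reduction` (default 0.5) of the control area.
The 50 % default operationalizes "disappears or diminishes" strictly enough
that a stable non-specific band at the target size is not mistaken for the
target.  `min_reduction=None` disables the gate and matches purely by MW;
this is used when the band identity is known a priori (e.g. parameter
recovery on synthetic data, where the question is measurement accuracy, not
identification).  Ties between equally close candidates are an error;
lanes with no candidate, or no qualifying candidate, are flagged and ranked
last with an undefined index.

The index is `(A_poi/A_all)_control − (A_poi/A_all)_KO`.  When the KO lane
has no matched peak the KO term is 0 by construction; a KO lane with no
detected peaks at all is additionally flagged ("empty KO lane") but is not
an error — it is the expected outcome for a perfectly specific antibody.
Both fractions are ratios of areas from the same lane, so the index is
invariant under rescaling all intensities and, because baseline anchors
track any constant offset, approximately invariant under background shifts.
A loading-control normalization (e.g. target area / tubulin area) can be
computed from the peak tables but deliberately never enters the index,
which contains no loading term.

## Immunofluorescence scoring

Two binary criteria per antibody, each a numeric statistic with a threshold
(defaults in `IFThresholds`; chosen to separate the synthetic phenotype
panel cleanly, not fitted to any real dataset):

* **Pattern** — positive iff puncta per cell ≥ 10, the fraction of
  above-background (median-referenced) integrated signal inside detected
  puncta ≥ 0.3, and the punctum density in the perinuclear annulus (nucleus
  dilated by 15 px, minus the nucleus) is ≥ 2× the density in the remaining
  cytoplasm.  An all-in-annulus field reports the capped ratio 100; a field
  with no puncta is undefined and fails.
* **KO loss** — positive iff `(mean_KO − mean_sec) / (mean_WT − mean_sec)`
  ≤ 0.25 over the cell masks, clamped below at 0; undefined (and failing)
  when the WT mean does not exceed the secondary-only background.  The 0.25
  ceiling operationalizes "similar to the secondary-only control" while
  tolerating residual autofluorescence.

Puncta are local maxima of the scale-normalized negative
Laplacian-of-Gaussian response (σ = expected punctum scale, default 2 px)
exceeding the in-mask median response by 5 robust standard deviations, so
detections are invariant to contrast rescaling.  The search mask is eroded
by ~2 scales to keep cell-edge intensity steps from registering as puncta.
Cell and nucleus masks are inputs; segmentation is out of scope.

## Synthetic data

**Blots.**  Bands are vertical Gaussians (uniform across the lane width)
placed at the row implied by ladder calibration of their MW, over a smooth
2-D polynomial background, with additive Gaussian noise and optional
Poisson shot noise — covering both film and digital-scanner acquisition
statistics, which real acquisition metadata rarely pins down.  The profile
area of a band has the closed form `amplitude · σ · √(2π)`, the oracle for
all area tests.  The bundled ladder is a prestained-standard-like series
(98…14 kDa) placed exactly log-linearly.

Panel blots are parametrized by the ground-truth signal fractions
`(f_c, f_k)`: amplitudes are solved so the specific 25-kDa band (σ = 4 px)
carries fraction `f_c` of the control lane's total area and `f_k` of the
KO lane's, with one non-specific 50-kDa band (σ = 6 px) carrying the rest;
total control area is fixed at 2400 intensity·px.  The true index is then
`f_c − f_k`.  **SNR convention:** the Gaussian noise sd is set to
(smallest nonzero band amplitude)/SNR, so "SNR 20" guarantees every real
band is 20× the noise — without this, faint KO residual bands would be
undetectable by construction rather than by difficulty.  The 8-antibody
demo panel spans true indices 0.90 to 0.20 in steps of 0.10.

**IF fields.**  Cells are disks (radius 55 px) with disk nuclei (18 px) on
a jittered grid; the wild-type punctate phenotype places 50 puncta per cell
(Gaussian spots, σ = 2 px, amplitude 120) with 70 % in the perinuclear
annulus, over a diffuse cytoplasmic level of 15 above a camera background
of 8; default noise sd 12 (punctum SNR 10).  Puncta keep a 5-px minimum
separation (vesicles are resolvable objects; this also makes ground-truth
matching unambiguous).  The 2×2 phenotype panel crosses
{punctate, diffuse} × {KO-lost, KO-retained}; "retained" phenotypes repeat
the WT staining parameters in the KO field, "lost" phenotypes leave the KO
field at background like the secondary-only control.  A secondary-only
field specified with puncta or diffuse signal is rejected as
self-contradictory.

What the generator does *not* emulate: irregular cell shapes, lane
smiling, membrane stripping artifacts, intensity saturation, uneven
illumination beyond a smooth polynomial, punctum size heterogeneity, and
autofluorescence texture.  Passing tests therefore demonstrate that the
quantification logic is correct under the stated image model, not that the
detectors are robust to every real-world artifact.

## Problem sizes and numerics

The test suite and the acceptance script use 360×130-px two-lane blots
(seconds per hundred), 20 noise replicates for rank stability, and 10 seeds
× 4 phenotypes × 3 conditions for IF scoring — sizes at which the measured
errors (max index recovery error ≈ 0.03 at SNR 20; noiseless area error
< 0.05 %) are already dominated by method bias rather than sampling, so
larger simulations would not change the conclusions.  Images are float
internally; on disk they are 16-bit TIFF with an explicit white level
recorded in the TIFF description (`pixel = value · 65535 / white_level`),
lossless up to quantization.  All randomness flows through
`numpy.random.default_rng` seeds carried in the spec objects; rendering is
a pure function of the spec.

## Known limitations

* No automatic lane finding: lane x-centres and the ladder are config.
* Single-target logic: multi-isoform targets (several specific bands) are
  not supported; the tie-break errors instead of guessing.
* The IF thresholds are surrogates calibrated on the synthetic panel;
  applying them to real microscope data requires re-examining them against
  that instrument's background statistics.
* Replicate spread is reported, but no formal uncertainty is attached to
  the index.
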