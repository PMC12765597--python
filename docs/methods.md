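# Methods

This note records the models behind `batdialect`, the parameter choices
that matter, and what the synthetic data do and do not establish.

## The question and the design

The pipeline tests whether acoustic divergence among bat colonies tracks
genetic, geographic or morphological divergence, separately for four
vocalisation types. The contrast of interest is oral social calls
(chirp-trill, squabble) versus nasal calls (ultrasonic social,
echolocation): if dialects arise by drift, the oral calls should correlate
with genetic/geographic distance, while nasal calls — structurally coupled
to the echolocation apparatus and hence under stabilising selection —
should not. All colony-level comparisons are distance-matrix correlations,
so the inferential core is the Mantel family of permutation tests.

## Spectrogram and detector

* Spectrogram: Hann window of 1024 samples, hop 512 (50% overlap),
  one-sided power, no zero padding. At 256 kHz sampling this gives 250 Hz
  bins and 2 ms frames; frame count is floor((N−1024)/512)+1. dB
  conversions use 10·log10 with a −120 dB floor.
* Noise profile: per frequency bin, power is averaged over 2 s blocks
  hopped every 0.5 s, and the 20th percentile across blocks (linear
  interpolation between order statistics) is the background estimate. This
  estimator needs ≥20% of blocks to be signal-free in each band; synthetic
  scenes therefore space calls 3 s apart.
* Detection: the 2–80 kHz search band is scanned in overlapping 4 kHz
  sub-bands (hop = half width). A frame is *on* when any sub-band's
  integrated power is ≥ 10^(SNR/10) times that sub-band's integrated noise
  floor, SNR threshold 10 dB. On-runs separated by <0.1 s merge into one
  multi-element detection; merging happens before screening. Detections
  must last 0.02–5 s and have ≥40% occupancy (on-frame fraction of the
  merged extent).

Why sub-band integration rather than a per-bin test: the short-time power
of Gaussian noise is exponentially distributed per bin, so a "any bin
≥ 10 dB over its floor" rule fires on roughly 2% of pure-noise frames in a
312-bin band; those spurious on-frames chain into real detections through
the 0.1 s merge rule, destroy the occupancy statistic, and contaminate
detection bands. Integrating 16 bins before thresholding concentrates the
null statistic (gamma) so noise-only audio yields no detections at all,
while scanning sub-bands (rather than integrating the whole 78 kHz band)
avoids diluting narrowband calls — a 6 kHz-wide chirp-trill loses ~11 dB
of margin against a whole-band test. The sub-band width (4 kHz,
`subband_khz`) is exposed; halving or doubling it mainly trades narrowband
sensitivity against sensitivity to very broadband, quiet sounds.

## The seven measurements

Within a detection's time×band window: F_peak is the bin of the global
power maximum; the peak-frequency contour is the per-frame argmax bin,
traced over the detector's on-frames so silent inter-element gaps do not
inject noise argmaxes; F_max/F_min are the contour extrema; BW₉₀ (BW_IQR)
is the frequency span between the 5%/95% (25%/75%) points of the
cumulative in-band energy spectrum, interpolated linearly within bins;
length is the frame count; peak time is measured from detection start to
the frame holding the global maximum (so it shares the contour's time
base and can differ from a waveform-based definition by up to one hop).
All measurements are ratios of spectrogram quantities and are therefore
invariant to global amplitude scaling.

Note that a pure tone has BW₉₀ ≈ 2.4 bins, not 0: the Hann mainlobe
spreads a spectral delta over ±1 bin with power weights 0.25/1/0.25. Any
bandwidth below ~0.6 kHz at these settings is window-limited.

## Acoustic divergence

Per call type, each variable is screened with a one-way ANOVA across
colonies at α = 0.05; retained variables get Tukey–Kramer pairwise
comparisons (studentized-range, valid for unequal n). The discriminant
analysis solves B v = λ W v (count-weighted between-class scatter against
pooled within-class covariance), axes normalised to vᵀWv = 1; at most
min(k−1, p) axes. Classification is linear-Gaussian with the pooled
covariance and sample-proportional priors (uniform priors are available);
the holdout is a stratified, seeded 50% split — stratification is a
design choice to keep small colonies represented in both halves. If a
call type retains no informative variable (possible when colonies truly
share one acoustic distribution, as for the synthetic nasal calls), the
discriminant step falls back to all seven variables and flags the report;
its Mantel correlations are then honest noise.

Colony-level acoustic distance is the squared Mahalanobis distance between
colony centroids in (LD1, LD2) under the pooled within-colony covariance.
The field phrase "distance from each exemplar to the centroid of each
colony" does not by itself define a symmetric colony-pair scalar;
centroid-to-centroid is the default because Mantel requires symmetry, and
a symmetrised mean exemplar-to-other-centroid variant is available
(`pair_stat="mean_exemplar"`), along with the exemplar-level table as a
diagnostic. A singular pooled covariance is ridge-regularised with a
recorded epsilon, never silently.

## Genetics

Loci are filtered in a fixed order — call rate, then minor-allele
frequency, then monomorphism — so each removal is attributed to one rule.
A stated MAF threshold like "0.85" is read as its only coherent
interpretation, a cap on the major-allele frequency (retain MAF ≥ 0.15);
the filter itself is generic.

Pairwise F_ST is Weir & Cockerham's θ: per locus, variance components a
(among populations), b (among individuals within populations) and c
(within individuals) from sample allele frequencies and observed
heterozygosity; the multi-locus estimate is Σa/Σ(a+b+c) (ratio of
averages, the estimator's standard form), over loci genotyped in both
colonies of a pair. Negative estimates are reported as computed. PCoA is
classical metric scaling (Gower double-centring, eigendecomposition,
coordinates scaled by √eigenvalue); axes with negative eigenvalues are
dropped and counted. The individual-level distance feeding PCoA is
allele-sharing distance (1 − proportion of shared alleles), a standard
choice when no specific individual metric is mandated.

## Distances and Mantel tests

Geographic distances are haversine great-circle distances at Earth radius
6371.0088 km; the sphere-vs-ellipsoid error (<0.5%) is far below the
0.1-degree rounding of the published site coordinates (~10 km).
Morphological distance per feature is |colony mean difference|; combined
morphology uses colony means of LD1 from a discriminant fit on the four
measurements.

Mantel r correlates upper triangles; the null permutes one matrix's rows
and columns jointly. For n ≤ 7 sites the permutation set is enumerated
(exact p = tail fraction over n!, identity included, so p ≥ 1/n!);
otherwise 9999 permutations are sampled with the add-one convention
p = (1+exceedances)/(perms+1). The default tail is one-sided "greater"
(matching the convention of the R functions this analysis family uses);
two-sided is available. The partial Mantel statistic controls a third
matrix through the standard first-order partial correlation and permutes
the first matrix only (Smouse–Long–Sokal); with 5 sites the p-value
granularity is 1/120, so "marginal" p-values near 0.05–0.1 are expected
even for visually strong correlations.

## Synthetic data: what it emulates

* **Sites.** The five Northern Territory colonies at their published
  coordinates (Pungalina ~660–820 km from the northern cluster at the
  0.1-degree rounding), or random sites in a Top End bounding box.
* **Genotypes.** Hierarchical logit-normal spatial drift: per locus,
  ancestral frequency p ~ Beta(2,2) (clipped to [0.01, 0.99]); colony
  frequencies logit(p_c) = logit(p) + σ·G_c with G a zero-mean Gaussian
  field with covariance exp(−d/range) over great-circle distances;
  genotypes Binomial(2, p_c). Chosen over coalescent simulation because
  only the F_ST-versus-distance structure matters downstream and the
  delta method makes the calibration transparent:
  θ ≈ 0.25·σ²·(1−exp(−d/range)) near p = 0.5. Defaults σ = 0.4,
  range = 400 km put θ at ~0.004 for the 39 km Pine Creek–Claravale pair
  and ~0.03–0.05 for Pungalina pairs — the weak-differentiation band the
  analysis targets. σ = 0 gives exact panmixia (multi-locus θ within
  ±0.005 of 0 at 2000 loci). Duplicate sites are handled by a small
  diagonal jitter in the field covariance.
* **Morphometrics.** Baselines 105/44/22/9 mm (forearm/ear/tragus/
  noseleaf); forearm, ear and tragus grow 1.5 mm per degree of latitude
  south of the northernmost site; noseleaf is flat across sites; female
  forearms exceed male by 1.7 mm; Gaussian noise sd 3.3 mm (so the sex
  gap is a d ≈ 0.5 effect). Noseleaf noise is 0.3× the common sd, keeping
  it on its own ~1 mm scale.
* **Calls.** Four archetypes sized to pass the detector at its published
  settings: chirp-trill (descending intro + 6-element FM train,
  4.5–10.5 kHz, placed so the largest negative dialect offset stays above
  the detector's 2 kHz floor),
  squabble (5 broadband noise bursts, 3–25 kHz), ultrasonic social
  (two-element FM sweep, 40–55 kHz), echolocation (8 pulses of 2.5 ms with
  harmonics at 1×/0.6×/0.35×, fundamental 23–26 kHz). Dialect is an
  additive contour offset plus a bandwidth multiplier, applied to oral
  types only; in the end-to-end scenario the per-colony offset is
  proportional to the first principal component of the realized colony
  allele-frequency matrix, scaled by 1.5 kHz per standard deviation, so
  acoustic distance tracks genetic distance by construction. Per-call
  jitter: 0.3 kHz contour noise and ±10% element duration.
* **Soundscapes.** Calls mixed over white Gaussian noise (−60 dBFS floor)
  scaled so the in-band SNR of each call equals the target (20 dB
  default), 3 s spacing, ground truth recorded, overlaps flagged; WAV and
  Raven-style selection-table output.

What the synthetic data do **not** emulate: coloured or non-stationary
background noise (a low-frequency waterfall-like component exists as an
option but default scenes are white), echoes and reverberation,
atmospheric attenuation, individual vocal signatures, overlapping
choruses, and recorder frequency response. Passing tests therefore show
the *machinery* is correct under the stated statistical structure — not
that real recordings will yield any particular assignment accuracy or
correlation strength.

## Problem sizes

Default study scenario: 5 colonies; 16 individuals × 1000 loci for
genetics; 28 individuals per colony for morphometrics; 8 exemplars per
colony per call type rendered at 256 kHz, with up to 50 exemplars sampled
per cell when more are available (the sampling cap of the field design).
The end-to-end ranking study repeats the scenario over 20 seeds; one run
takes ~15 s on one CPU.

## Numerical choices and degenerate inputs

Seeds propagate through `numpy.random.SeedSequence.spawn`, one child per
stage, so a single master seed fixes the entire run report byte-for-byte.
Discriminant axes get a deterministic sign convention (largest-magnitude
loading positive). Singular covariances are ridge-regularised
(ε = 10⁻⁸·trace/p) with a warning. Constant features are excluded from
screening with a report entry rather than an error. Genotype loci with no
data in one member of a colony pair are excluded pairwise; a pair sharing
no genotyped loci is an error. Empty detection bands, zero-energy
measurement windows, all-removed locus filters, colonies with a single
exemplar and sub-block-length recordings all raise explicit errors naming
the offender.

## Known limitations

* The detector is not Raven Pro; it is a re-implementation of a
  band-limited energy detector from published settings, and its sub-band
  integration rule (above) is this package's own design.
* Exhaustive Mantel p-values at 5 sites have granularity 1/120; nothing
  below 0.0083 is observable, and power is inherently low.
* The Mahalanobis acoustic matrix assumes a shared within-colony
  covariance in LD space; heterogeneous within-colony scatter would bias
  colony-pair distances.
* Weir–Cockerham θ is reported without confidence intervals; bootstrap
  across loci would be the natural extension.
* The morphometric cline applies one rate to forearm, ear and tragus;
  real allometry differs by trait.
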