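# batdialect

Colony **dialect analysis for ghost bat (*Macroderma gigas*) vocalisations**:
a reusable Python pipeline that detects and measures calls in full-spectrum
audio, quantifies acoustic divergence among colonies, computes genetic,
geographic and morphological distances, and tests their correlations with
Mantel and partial Mantel permutation procedures.

It is written for bioacousticians and population geneticists who want to ask
*"do colonies that are genetically or geographically farther apart also sound
more different?"* — and to ask it of a multi-call-type repertoire, where
orally emitted social calls (chirp-trill, squabble) and nasally emitted calls
(ultrasonic social, echolocation) may evolve under different regimes (drift
versus stabilising selection on the echolocation apparatus).

A seeded synthetic-data module generates sites, SNP genotypes with
isolation-by-distance structure, morphometrics with a Bergmann-style size
cline, and annotated soundscapes built from four call archetypes — so every
stage of the pipeline is testable end to end without any field recordings.

## What it computes

**Detection and measurement.** A short-time power spectrogram (Hann window,
1024 samples, 50% overlap; 250 Hz × 2 ms cells at 256 kHz) feeds a
band-limited energy detector: per-bin background noise is the 20th
percentile of block-mean power (2 s blocks, 0.5 s hop); a frame is "on" when
any 4 kHz sub-band exceeds its integrated noise floor by 10 dB; on-runs
closer than 0.1 s merge into multi-element detections, screened at
0.02–5 s duration and ≥40% occupancy. Each detection yields seven
measurements: BW₉₀ and BW_IQR (5–95% and 25–75% energy-percentile
bandwidths), F_peak, F_max and F_min (extrema of the peak-frequency
contour), length in frames, and peak time.

**Acoustic divergence.** Per call type, one-way ANOVA with Tukey–Kramer post
hocs screens the seven variables; Fisher discriminant analysis on the
informative ones gives LD1/LD2 scores; colony distance is the squared
Mahalanobis distance between colony centroids under the pooled within-colony
covariance, `d²(i,j) = (μᵢ−μⱼ)ᵀ Σ_w⁻¹ (μᵢ−μⱼ)`; a stratified 50% holdout
reports percent-correct colony assignment.

**Genetics.** Loci are filtered by call rate, minor-allele frequency and
monomorphism; pairwise F_ST is the Weir–Cockerham (1984) θ, combined across
loci as the ratio of summed variance components Σa / Σ(a+b+c); PCoA
ordination operates on allele-sharing distances.

**Correlation.** Mantel r is the Pearson correlation of distance-matrix
triangles with a joint row/column permutation null (exhaustive enumeration
for ≤7 sites, 9999 sampled permutations otherwise, add-one p); the partial
Mantel statistic is `r₁₂.C = (r₁₂ − r₁C r₂C)/√((1−r₁C²)(1−r₂C²))`.

## Worked example

```python
import batdialect as bd

sites = bd.make_sites("paper_nt")               # the five NT colonies
geo   = bd.geographic_distance_matrix(sites)    # haversine km

geno  = bd.simulate_genotypes(sites, n_per_site=16, n_loci=1000, seed=11)
geno, _ = bd.filter_loci(geno, maf_min=0.05, call_rate_min=0.75)
fst   = bd.pairwise_fst(geno).matrix
res   = bd.mantel(fst, geo, seed=0)
print(f"Mantel r = {res.r_observed:.4f}, p = {res.p_value:.4f}")
```

prints

```
Mantel r = 0.9767, p = 0.0083 (120 permutations, exhaustive)
```

meaning genetic differentiation rises almost monotonically with great-circle
distance (isolation by distance); with 5 sites only 120 relabelings exist,
and one of them (the identity) reaches this correlation. The simulated F_ST
values span ~0.003 (Pine Creek–Claravale, 39 km apart) to ~0.03 (the
Pungalina outlier, 658–818 km from the rest), matching the weak-but-spatial
differentiation regime the analysis is designed for.

The `examples/` directory holds one narrative script per capability —
detection and measurement (`01`), isolation by distance (`02`),
morphometrics (`03`) and the full pipeline (`04`); each prints the numbers
it computes and says what they mean. A thin CLI mirrors the stages:

```bash
batdialect run --seed 1 --out runs/demo      # full pipeline, all artefacts
batdialect detect recording.wav --out sel.txt
batdialect correlate fst.csv geo.csv --seed 0
```

## Layout

```
src/batdialect/   sites, synth, calls, audioio, spectral, detect, measure,
                  screening, lda, geno, popgen, geodist, stats, mantel,
                  distmat, pipeline, cli
tests/            unit + property tests, acceptance battery
examples/         four narrative scripts
docs/methods.md   model assumptions, parameter choices, limitations
```
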