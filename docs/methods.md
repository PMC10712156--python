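# Methods

This note documents the models and numerical choices behind `seedtyper`, in
the order data flows through the pipeline, together with what the synthetic
data generator does and does not emulate.

## Data model

A **spectrum** is a profile trace over the 2–20 kDa acquisition window; all
m/z values are treated as neutral masses of singly-protonated ions
(linear-mode protein biotyping convention; no charge deconvolution). A
**peak list** holds the discrete picked peaks of one spectral reading; one
seed is measured as 10 technical replicates × 3 readings = 30 readings. A
**Main Spectrum (MSP)** is the consensus fingerprint of one seed: ≤70 peaks
with a mean normalized intensity and a replicate frequency each. A
**library** is a set of MSPs with a species synonym map; the default map
collapses *Amaranthus rudis* into *A. tuberculatus* (current consensus is
that they are one species) and normalizes the orthographic variant
"*Amaranthus powelli*" → "*A. powellii*".

The mass matching window is `max(ppm·1e-6·m/z, min_da)` with defaults
500 ppm / 1 Da — deliberately wider than the ±300 ppm calibration window,
because library and query spectra come from independent acquisitions whose
residual calibration errors add.

## Preprocessing

The instrument software behind the original workflow does not disclose its
algorithms, so standard open equivalents are used; they are replacements,
not reconstructions.

- **Smoothing**: Savitzky–Golay, order 2, default window 7 points
  (preserves symmetric apices and polynomial baselines); a moving-average
  fallback is available.
- **Baseline**: SNIP with log-log-sqrt compression, default half-window 40
  points, clipped at zero; rolling-minimum (min filter + boxcar, capped at
  the signal) as alternative. The half-window should exceed the half-width
  of the widest genuine peak (FWHM = m/z / resolution ≈ 29 Da at 20 kDa for
  resolution 700).
- **Peak picking**: local maxima with SNR ≥ 3, where the noise scale is
  1.4826 × MAD of the baseline-subtracted trace and SNR is measured above
  the median background — baseline estimators that clip at zero leave a
  small positive offset on noisy traces, and ignoring it floods the picker
  with false peaks. Peaks below 2% of the base peak are discarded
  (protein-fingerprint peaks that small are indistinguishable from baseline
  ripple); peaks closer than the matching window are thinned keeping the
  more intense, so picking and matching use one resolution.
- **Flatline**: an acquisition with fewer than 5 picked peaks. The
  threshold is a package choice; only the phenomenon itself (no usable
  protein spectrum) is externally given.
- **Calibration**: the bundled standard has 8 reference masses (3637.8,
  5096.8, 5381.4, 6255.4, 7274.5, 10300.2, 13683.2, 16952.3 Da). Each is
  searched among picked peaks within ±300 ppm; if all are found, a single
  multiplicative (constant-ppm) shift is fit by least squares and removed.
  With 8 anchors over one mass decade a constant relative shift is the
  simplest defensible model; a polynomial would fit calibration noise. An
  injected shift in ±300 ppm is recovered to well within 20 ppm.
- **Outlier replicates**: a replicate is dropped when its mean pairwise
  match-fraction (shared peaks / union, one-to-one matching) against its
  peers is below 0.5; flatlines are always dropped. The 0.5 default suits
  curated library material; strongly variable accessions can push typical
  Jaccard similarity to ~0.4, so callers working with such material should
  lower the threshold (the stress-test scenarios use 0.15–0.2).

## Consensus MSP construction

Replicate peak lists are base-peak normalized, pooled and sorted; a new bin
starts when the gap to the previous pooled peak exceeds the matching window
at that mass (greedy single linkage — identical to cutting a single-linkage
dendrogram at the window for a constant window, which is how it is tested).
Within a bin at most one peak per replicate counts (the most intense), so a
bin's frequency is a true fraction of replicates. Bin m/z is the
intensity-weighted mean of member peaks; mean intensity averages only over
contributing replicates — absence is encoded in the frequency, not as
zeros, which keeps the intensity scale interpretable.

Bins with frequency < 25% are discarded; survivors are ranked by frequency
(descending), then mean intensity (descending), then m/z, and the top 70
kept. Frequency-first ranking favours reproducible peaks, consistent with
the downstream validation rule; whether the original vendor ranks by
frequency or intensity is unknown, so the ranking is config-visible. At
least 20 usable readings are required in strict mode (the default); a
permissive mode exists for exploratory work.

Self-validation re-queries every MSP against the whole library. Because the
query is the MSP's own peak list, the self-score is exactly 3.0; the
informative outputs are whether anything outranks it (duplicate entries)
and whether the second hit is a conspecific accession.

## Identification score

`score = clamp(log10(1000·a·b·c), 0, 3)` with *a* = matched MSP-peak
fraction, *b* = matched query-peak fraction, *c* = Spearman rank
correlation of matched intensities clipped to [0, 1]. The form was chosen
because it (i) realizes the verbal description of commercial biotyper
scores (bidirectional peak counting plus peak-height concordance), (ii)
reproduces the documented 0–3 range with 3 as perfect self-match, and
(iii) gives the conventional 2.00 / 1.70 thresholds a concrete meaning
(score 2.0 ⇔ factor product 0.1). It does **not** reproduce vendor score
values numerically.

Numerical details: with fewer than 3 matched pairs *c* = 0 (insufficient
evidence must not inflate a score); degenerate rankings (constant
intensities) count as perfectly concordant, and rank correlations within
1e-9 of 1 are snapped to 1 so a self-match is exactly 3.0 in floating
point. Matching is greedy nearest-neighbour, one-to-one, with an
optimal-assignment variant (Hungarian algorithm) kept as a test oracle.
Rankings sort by score then label, so they are a total, reproducible order.
MSP peak frequencies are carried in the data model but unused by the
default scorer.

## Majority-rule calling

Synonyms are collapsed *before* voting. Each non-flatline replicate votes
with its top hit regardless of score; a species reaching 2 votes is called
and the reported score is the mean over exactly the agreeing replicates. All
replicates flatline → `FLATLINE`, score 0.00. No majority (including tied
modes) → `INCONCLUSIVE` — conservative; score-based tie-breaking was
rejected because the calling scheme is deliberately rank-based. Accession
calls repeat the rule over non-flatline, non-inconclusive seed calls;
flatline seeds leave the denominator but a call still needs 2 absolute
agreeing seeds. The seed- and accession-level rules are verified against a
brute-force enumeration of all 4³ replicate assignments.

## Accuracy evaluation

Correctness compares synonym-collapsed names; subspecies qualifiers and
dual designations ("A/B") are stripped first. Flatline calls count as
incorrect and are tallied separately; samples without a valid reference
identification never enter a denominator. Percentages round
half-away-from-zero to the nearest integer — the only scheme consistent
with all four headline figures on the packaged tables (87 from 86.67, 96
from 95.56, 97 from 96.67, 100).

The **seed-consistency** mode compares each seed's call with its own
accession's consensus while keeping *A. rudis* distinct (configurable via
`keep_distinct`). This mirrors how the original analysis counted a
rudis-labelled replicate as a divergent seed even though the accession call
was correct under the synonym rule; the package records this tension as a
distinct evaluation mode rather than resolving it.

## Clustering

Feature matrices align each sample's 70 most intense (base-peak normalized)
peaks on consensus bins built by the same greedy binning as the library.
The "PCA dendrogram" is realized as average-linkage hierarchical clustering
on Euclidean distances in the space of the first k = 10 principal
components (the vendor construction is undisclosed; k is a parameter). PCA
signs are fixed by making each component's largest-magnitude loading
positive so coordinates and trees are reproducible. Newick branch lengths
derive from merge heights, so trees are ultrametric.

## Synthetic data

The generator reproduces the *statistical shape* of the study, not the
physics of desorption/ionization:

- **Templates**: each species owns `peaks_per_species` (default 100) peaks
  drawn on a spaced grid over 2.1–19.9 kDa (global spacing keeps unrelated
  templates from colliding inside matching windows). Base intensity is
  log-normal (σ = 0.8 around 50) and belongs to the *peak position*, so
  species sharing a peak share its typical abundance — shared proteins do
  not change abundance arbitrarily between sister species, and without this
  the intensity-concordance factor would make cross-species scores
  artificially low. `sharing` as a float places a pool common to all
  species (every pairwise shared fraction equals the request exactly); as a
  `{(i, j): fraction}` dict it allocates per-pair pools, modelling sister
  taxa.
- **Noise model**: accessions draw per-peak presence probabilities
  (Beta(8, 1) by default) and log-normal intensity factors (σ = 0.3);
  readings apply dropout (10%), Gaussian m/z jitter (200 ppm — inside the
  500 ppm matching window, but wide enough that cross-bin collisions stay
  rare), log-normal technical intensity noise (σ = 0.4), Poisson spurious
  peaks (mean 3) and flatline failures (2%). Intensity noise is
  multiplicative throughout, the standard model for MALDI intensities.
  These defaults describe curated library material; none of them is
  estimated from real data — real accession-level variances are not
  knowable from published summaries, so the defaults are set to make the
  documented phenomena (flatlines, divergent replicates, sister-species
  confusion) reproducible at plausible rates.
- **Raw rendering**: Gaussian peaks with FWHM = m/z / resolution (default
  700) on a 1 Da grid, plus an exponential-decay baseline and white noise;
  the preprocessing chain recovers template apices within one grid step at
  SNR ≥ 10.
- **Study simulation**: the default design is 16 species × 3 accessions ×
  3 seeds, 30 library readings per seed, one blind seed with 3 technical
  replicates per accession, and a seeded shuffle of blind numbering.
  `blind_from_new_accessions` draws blind seeds from accessions the
  library never saw (how real blind material arrives), and `blind_noise`
  lets blind acquisitions be rougher than the curated library. All
  randomness flows from one master seed through named sub-streams, so any
  stage is reproducible in isolation.

### Stress scenarios (tests/_experiments.py)

Three statistical claims are exercised with scenario noise models chosen
once and fixed:

- **Perfect recovery**: 10 disjoint species × 2 accessions under default
  noise → 100% seed- and accession-level blind accuracy (20 accession
  units).
- **Sister confusion**: 4 species with one pair sharing 95% of peaks;
  blind seeds from unseen accessions under a high-variability model
  (presence Beta(1.5, 1), dropout 25%, accession σ 0.6). Misclassification
  is counted at the replicate (top-hit) level because the seed-level
  majority rule absorbs nearly all single-replicate errors — which is
  precisely why the rule exists. Pooled over 4 master seeds, essentially
  all misclassifications fall inside the sharing pair.
- **Enrichment**: mean blind accuracy is non-decreasing in
  accessions-per-species (1 → 3 → 5) averaged over 10 master seeds with
  common random numbers (same templates, same blind queries; only the
  library grows), on a deliberately hard problem (3 species sharing 95%,
  strongly variable unseen accessions) so the single-accession arm has
  headroom to fail.

Passing these tests shows the pipeline's rules behave as designed under the
assumed variance structure; it does not validate the noise magnitudes
against real instruments, does not model isotope patterns, detector
saturation, matrix effects or mass-dependent resolution changes, and says
nothing about wet-lab extraction efficiency.

## Known limitations

- The score is a faithful realization of a verbal description, not a
  numerical reproduction of any vendor formula; absolute score values are
  comparable only within this package.
- The greedy matcher can in principle pair one fewer peak than the optimal
  assignment; in practice (tested against the Hungarian oracle) the
  difference is at most one pair on realistic lists.
- Binning is single-linkage and can chain peaks across a dense region;
  with template spacing well above the matching window this does not occur
  in the shipped scenarios.
- The evaluation of printed blind-test tables starts from transcribed
  per-seed calls; the underlying replicate-level data for those tables were
  not published, so the per-replicate pipeline cannot be re-run on them.
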