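# seedtyper

Species identification of single seeds from their MALDI-TOF protein mass
fingerprints.

Weedy *Amaranthus* species (palmer's amaranth, tall waterhemp and their
relatives) are notoriously hard to tell apart at the seed stage, yet several
of them are regulated in international seed trade. Protein biotyping offers a
fast molecular alternative to morphology and DNA barcoding: the acid-soluble
protein fraction of a single seed is ionized and measured over 2–20 kDa,
giving a peak fingerprint that is characteristic of the species. `seedtyper`
implements the full analysis side of that workflow as an open, tested
pipeline for seed analysts and diagnostics labs:

1. **Preprocessing** — smoothing (Savitzky–Golay or moving average),
   baseline subtraction (SNIP or rolling minimum), base-peak/TIC
   normalization, MAD-based peak picking, flatline detection, replicate
   outlier removal, and mass calibration against the 8-peak bacterial test
   standard (BTS; 3637.8 … 16952.3 Da, ±300 ppm).
2. **Library construction** — replicate peak lists (10 technical replicates
   × 3 readings per seed) are merged by greedy single-linkage binning into a
   consensus **Main Spectrum (MSP)**: at most 70 peaks, each present in at
   least 25% of the ≥20 contributing readings, organized in a
   genus→species→accession→seed taxonomy with a species synonym map.
3. **Scoring** — a query peak list *q* is compared with an MSP *r* through
   one-to-one nearest-neighbour peak matching inside a mass window
   `max(500 ppm·m/z, 1 Da)` and scored as

   ```
   score = clamp( log10(1000 · a · b · c), 0, 3 )
   ```

   with *a* the matched fraction of MSP peaks, *b* the matched fraction of
   query peaks and *c* the (clipped) Spearman concordance of matched peak
   intensities. A perfect self-match scores exactly 3.0; by convention
   score > 2.00 means high relatedness and score < 1.70 low relatedness.
4. **Classification** — majority rule: 2 of 3 technical replicates fix a
   seed's species (the reported score is the mean over the agreeing
   replicates; a seed whose replicates all flatline is reported as
   `FLATLINE` with score 0.00), and 2 of 3 seeds fix an accession's species.
5. **Validation** — library self-validation (every MSP must match itself at
   ≥ 2.00 and ideally a conspecific accession as second hit) and accuracy
   reports against reference identifications, including the packaged blind
   test tables.
6. **Clustering** — 70-peak feature matrices, PCA and PCA-dendrograms
   (average linkage in PC space, Newick output).
7. **Simulation** — a synthetic-data generator that reproduces the whole
   study design (species templates with controllable peak sharing,
   accession-level variability, replicate noise, flatline failures, raw
   profile rendering), so every stage is testable without an instrument.

## Worked example

```python
from seedtyper import simulate_study
from seedtyper.pipeline import (
    build_reference_library, classify_blind_study, evaluate_blind_study,
)

study = simulate_study(n_species=4, accessions_per_species=2,
                       seeds_per_accession=2, blind_seeds_per_accession=3,
                       seed=17)
library = build_reference_library(study.library_peaklists)   # 16 MSPs
calls = classify_blind_study(study, library)
report = evaluate_blind_study(study, calls)
print(calls["blind-001"])
print(report.n_evaluated, report.n_correct, report.accuracy_percent)
```

prints

```
SeedCall(seed_id='blind-001', called_species='Species B',
         average_score=2.7351889755977807, n_replicates=3, n_agreeing=3)
24 24 100
```

i.e. blind seed 001 was identified as Species B because all 3 technical
replicates agreed, with a mean top-hit score of 2.74 (high relatedness), and
all 24 simulated blind seeds were identified correctly.

The same pipeline is available from the shell:

```bash
seedtyper simulate --species 4 --seed 17 --out study/
seedtyper build-library --peaklists study/library \
    --meta study/library/metadata.csv --out library.json
seedtyper validate-library --library library.json --report selfcheck.tsv
seedtyper classify --library library.json --peaklists study/blind --out hits.tsv
seedtyper call --hits hits.tsv --meta study/blind/metadata.csv --out calls.tsv
seedtyper evaluate --calls calls.tsv --truth study/truth.csv --out report.json
```

## Blind-test fixtures

`src/seedtyper/fixtures/` ships two transcribed blind-test result tables
(per-seed identification calls, scores, atypical flags and reference
identifications for 15 accessions × 3 seeds and for 60 single seeds plus 3
excluded samples). `seedtyper.load_blind_set_aafc()` /
`load_blind_set_ssst()` load them, and the evaluation module recomputes the
headline accuracy figures (accession-level, seed-consistency, seed-level and
spectra-production percentages) from the raw rows. See
`tests/test_report.py` and `tests/test_acceptance.py`.

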