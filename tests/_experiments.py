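"""Shared synthetic experiments used by the property and acceptance tests.

Each experiment is cached so that the pipeline-property tests and the
acceptance checks pay for a given simulation only once per session.  All
seeds are fixed; scenario noise models are deliberate design choices (see
docs/methods.md) and are not tuned per test.
"""

from functools import lru_cache

from seedtyper import LOW_NOISE, NoiseModel
from seedtyper.pipeline import (
    accession_calls_for_blind_study,
    build_reference_library,
    classify_blind_study,
    classify_seed_replicates,
    evaluate_blind_study,
)
from seedtyper.report import evaluate_accession_level
from seedtyper.scoring import rank_against_library
from seedtyper.simulate import (
    make_accession_effect,
    make_genus,
    simulate_peaklist,
    simulate_study,
)

#: Blind material of uncontrolled provenance: strongly variable accessions
#: and rougher acquisitions than the curated library.
HIGH_VARIABILITY = NoiseModel(
    accession_intensity_sd=0.6,
    peak_presence_beta=(1.5, 1.0),
    dropout_prob=0.25,
    mz_jitter_ppm=250.0,
    intensity_sd_tech=0.6,
    n_spurious_peaks=3.0,
    flatline_prob=0.02,
)

#: Harder variant used for the database-enrichment trend, where single-
#: accession libraries must fail often enough to leave headroom.
ENRICHMENT_NOISE = NoiseModel(
    accession_intensity_sd=0.7,
    peak_presence_beta=(1.5, 1.0),
    dropout_prob=0.25,
    mz_jitter_ppm=300.0,
    intensity_sd_tech=0.6,
    n_spurious_peaks=5.0,
    flatline_prob=0.0,
)


@lru_cache(maxsize=None)
def end_to_end_disjoint():
    """Full pipeline on 10 disjoint species × 2 accessions (20 units).

    Library: default study noise, 30 readings per seed.  Blind: 3 seeds per
    accession, majority-called and evaluated at seed and accession level.
    """
    study = simulate_study(
        n_species=10,
        accessions_per_species=2,
        seeds_per_accession=2,
        blind_seeds_per_accession=3,
        seed=101,
    )
    library = build_reference_library(study.library_peaklists)
    calls = classify_blind_study(study, library)
    seed_report = evaluate_blind_study(study, calls)
    acc_calls, acc_truth = accession_calls_for_blind_study(study, calls, library)
    accession_report = evaluate_accession_level(acc_calls, acc_truth)
    return seed_report, accession_report


@lru_cache(maxsize=None)
def sister_confusion():
    """Replicate-level misclassifications when two of four species share 95%.

    Blind seeds come from accessions the library never saw, acquired under
    the high-variability model.  Returns (n_misclassified, n_within_pair).
    """
    tot_mis = tot_within = 0
    for seed in (7, 13, 29, 42):
        study = simulate_study(
            n_species=4,
            accessions_per_species=1,
            seeds_per_accession=1,
            blind_seeds_per_accession=40,
            blind_from_new_accessions=True,
            sharing={(0, 1): 0.95},
            blind_noise=HIGH_VARIABILITY,
            seed=seed,
        )
        library = build_reference_library(study.library_peaklists)
        truth = dict(zip(study.truth.sample_id, study.truth.species))
        sisters = {study.templates[0].species, study.templates[1].species}
        for sample_id, reps in study.blind_peaklists.items():
            for pl in reps:
                result = rank_against_library(pl, library)
                if result.flatline:
                    continue
                called = result.hits[0].species
                if called != truth[sample_id]:
                    tot_mis += 1
                    tot_within += {truth[sample_id], called} <= sisters
    return tot_mis, tot_within


@lru_cache(maxsize=None)
def enrichment_trend(arms=(1, 3, 5), n_master_seeds=10):
    """Mean blind seed-level accuracy per accessions-per-species arm.

    Common random numbers: within one master seed the templates, accession
    effects and blind queries are shared across arms; only the library
    grows.  3 species sharing 95% of peaks; blind seeds from unseen
    accessions.
    """
    noise = ENRICHMENT_NOISE
    n_species, max_acc = 3, max(arms)
    sums = {arm: 0.0 for arm in arms}
    for master_seed in range(1, n_master_seeds + 1):
        templates = make_genus(n_species, peaks_per_species=60, sharing=0.95, seed=master_seed)
        effects = {
            (s, a): make_accession_effect(templates[s], noise, seed=master_seed * 1000 + s * 10 + a)
            for s in range(n_species)
            for a in range(max_acc)
        }
        blinds = []
        for s in range(n_species):
            for b in range(4):
                eff = make_accession_effect(templates[s], noise, seed=master_seed * 7000 + s * 50 + b)
                reps = [
                    simulate_peaklist(
                        templates[s], eff, noise, seed=master_seed * 90000 + s * 300 + b * 10 + r
                    )
                    for r in range(3)
                ]
                blinds.append((templates[s].species, reps))
        for arm in arms:
            groups = {}
            for s in range(n_species):
                for a in range(arm):
                    key = (templates[s].species, f"A{s}-{a}", 1)
                    groups[key] = [
                        simulate_peaklist(
                            templates[s],
                            effects[(s, a)],
                            noise,
                            seed=master_seed * 50000 + s * 700 + a * 25 + r,
                        )
                        for r in range(25)
                    ]
            library = build_reference_library(groups, outlier_min_similarity=0.15)
            n_ok = sum(
                classify_seed_replicates(reps, library, seed_id="blind")[0].called_species
                == species
                for species, reps in blinds
            )
            sums[arm] += n_ok / len(blinds)
    return {arm: total / n_master_seeds for arm, total in sums.items()}


@lru_cache(maxsize=None)
def low_noise_library():
    """Small clean library: 6 disjoint species × 2 accessions, 1 seed each."""
    study = simulate_study(
        n_species=6,
        accessions_per_species=2,
        seeds_per_accession=1,
        noise=LOW_NOISE,
        seed=5,
    )
    return build_reference_library(study.library_peaklists)
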