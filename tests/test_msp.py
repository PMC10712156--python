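"""Consensus binning, MSP construction rules and library self-validation."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from seedtyper import (
    Library,
    MassTolerance,
    Peak,
    PeakList,
    bin_replicate_peaks,
    build_msp,
    score,
    validate_library,
)
from seedtyper.msp import summarize_self_validation

from conftest import make_peaklist

WIDE = MassTolerance(ppm=500.0, min_da=1.0)
SEPARATED = np.arange(2500.0, 19500.0, 170.0)  # 100 positions, gaps >> window


class TestBinning:
    def test_single_list_three_peaks(self):
        bins = bin_replicate_peaks([make_peaklist([3000, 5000, 7000])])
        assert len(bins) == 3
        assert all(b.frequency == 1.0 for b in bins)

    def test_two_lists_merge_with_weighted_mean(self):
        a = make_peaklist([5000.0], [10.0])
        b = make_peaklist([5000.5], [30.0])
        bins = bin_replicate_peaks([a, b], MassTolerance(ppm=0.0, min_da=2.0))
        assert len(bins) == 1
        assert bins[0].frequency == 1.0
        expected = (5000.0 * 10 + 5000.5 * 30) / 40
        assert bins[0].mz == pytest.approx(expected)

    def test_frequency_is_exact_fraction(self):
        lists = [make_peaklist([5000.0]) if i < 5 else make_peaklist([9000.0]) for i in range(20)]
        bins = bin_replicate_peaks(lists)
        by_mz = {round(b.mz): b for b in bins}
        assert by_mz[5000].frequency == 0.25
        assert by_mz[9000].frequency == 0.75

    def test_one_peak_per_replicate_per_bin(self):
        # a replicate contributing two pooled peaks to one bin counts once
        a = PeakList([Peak(5000.0, 10.0), Peak(5000.4, 40.0)])
        b = make_peaklist([5000.2], [20.0])
        bins = bin_replicate_peaks([a, b], MassTolerance(ppm=0.0, min_da=1.0))
        assert len(bins) == 1
        assert bins[0].n_contributing == 2
        assert bins[0].mean_intensity == pytest.approx((40.0 + 20.0) / 2)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_single_linkage_oracle(self, rng, trial):
        # greedy gap-splitting == single-linkage clustering cut at the
        # tolerance, for a constant window
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 20))
        mzs = np.sort(rng.uniform(3000, 3200, size=n))
        mzs = mzs[np.concatenate([[True], np.diff(mzs) > 1e-6])]
        tol = MassTolerance(ppm=0.0, min_da=float(rng.uniform(0.5, 30.0)))
        bins = bin_replicate_peaks([make_peaklist(mzs)], tol)

        if len(mzs) == 1:
            assert len(bins) == 1
            return
        Z = linkage(mzs.reshape(-1, 1), method="single")
        labels = fcluster(Z, t=tol.min_da, criterion="distance")
        assert len(bins) == len(set(labels))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_replicate_peaks([])


class TestBuildMsp:
    def test_minimum_spectra_enforced_in_strict_mode(self):
        lists = [make_peaklist(SEPARATED[:10]) for _ in range(19)]
        with pytest.raises(ValueError, match="19"):
            build_msp(lists)
        msp = build_msp(lists, strict=False)
        assert msp.n_source == 19

    def test_identical_lists_reproduce_input(self):
        lists = [make_peaklist(SEPARATED[:10], range(10, 20)) for _ in range(20)]
        msp = build_msp(lists)
        assert len(msp) == 10
        assert all(p.frequency == 1.0 for p in msp.peaks)
        np.testing.assert_allclose(msp.mz, SEPARATED[:10])

    def test_identical_lists_truncate_to_most_intense(self, rng):
        intensities = rng.uniform(1, 100, size=100)
        lists = [make_peaklist(SEPARATED, intensities) for _ in range(20)]
        msp = build_msp(lists, max_peaks=70)
        assert len(msp) == 70
        expected = np.sort(SEPARATED[np.argsort(-intensities)[:70]])
        np.testing.assert_allclose(np.sort(msp.mz), expected, atol=1e-6)

    def test_universal_peak_cap_at_70(self):
        positions = np.arange(2500.0, 19500.0, 140.0)[:120]
        lists = [make_peaklist(positions, np.linspace(1, 120, 120)) for _ in range(30)]
        msp = build_msp(lists)
        assert len(msp) == 70

    def test_quarter_frequency_rule(self):
        universal = SEPARATED[:60]
        rare, borderline = 2600.05, 2770.05  # distinct bins near two gaps
        lists = []
        for i in range(20):
            mzs = list(universal)
            if i < 4:
                mzs.append(rare)        # 20% of replicates
            if i < 5:
                mzs.append(borderline)  # 25% of replicates
            lists.append(make_peaklist(sorted(mzs)))
        bins = bin_replicate_peaks([l for l in lists], WIDE)
        assert len(bins) == 62
        msp = build_msp(lists)
        assert len(msp) == 61
        assert not any(abs(p.mz - rare) < 1.0 for p in msp.peaks)
        assert any(abs(p.mz - borderline) < 1.0 for p in msp.peaks)

    def test_lowering_min_freq_never_drops_bins(self):
        rng = np.random.default_rng(3)
        lists = [
            make_peaklist(np.sort(rng.choice(SEPARATED, size=40, replace=False)))
            for _ in range(20)
        ]
        sizes = [
            len(build_msp(lists, min_freq=f, max_peaks=10_000))
            for f in (0.75, 0.5, 0.25, 0.1)
        ]
        assert sizes == sorted(sizes)


class TestSelfValidation:
    def test_single_msp_matches_itself_at_three(self):
        lists = [make_peaklist(SEPARATED[:10], range(10, 20)) for _ in range(20)]
        library = Library(msps=[build_msp(lists)])
        records = validate_library(library)
        assert len(records) == 1
        rec = records[0]
        assert rec.top_hit_label == rec.msp_label
        assert rec.top_score == pytest.approx(3.0)
        assert rec.second_hit_label is None
        assert rec.passed

    def test_clean_library_passes_with_conspecific_second_hits(self):
        from _experiments import low_noise_library

        library = low_noise_library()
        records = validate_library(library)
        assert all(r.passed for r in records)
        assert all(r.second_hit_same_species for r in records)
        summary = summarize_self_validation(records)
        assert summary["n_failed"] == 0
        assert summary["n_second_hit_other_species"] == 0

    def test_shared_peaks_produce_cross_species_second_hits(self):
        # strongly variable accessions let a sister-species MSP overtake the
        # conspecific accession as the second-best hit
        from seedtyper import NoiseModel, simulate_study
        from seedtyper.pipeline import build_reference_library

        noise = NoiseModel(
            accession_intensity_sd=0.6,
            peak_presence_beta=(2.0, 1.0),
            dropout_prob=0.1,
            mz_jitter_ppm=200.0,
            intensity_sd_tech=0.4,
            n_spurious_peaks=3.0,
            flatline_prob=0.0,
        )
        study = simulate_study(
            n_species=4,
            accessions_per_species=2,
            seeds_per_accession=1,
            sharing={(0, 1): 0.95},
            noise=noise,
            seed=5,
        )
        library = build_reference_library(
            study.library_peaklists, outlier_min_similarity=0.2
        )
        records = validate_library(library)
        assert all(r.passed for r in records)
        cross = [r for r in records if not r.second_hit_same_species]
        sisters = {study.templates[0].species, study.templates[1].species}
        sister_labels = {
            m.label for m in library.msps if m.taxonomy.species in sisters
        }
        assert cross, "95% template sharing should blur second hits"
        assert all(r.msp_label in sister_labels for r in cross)
        assert all(r.second_hit_species in sisters for r in cross)
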