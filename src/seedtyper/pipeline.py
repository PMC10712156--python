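"""High-level glue: peak lists → library → calls → accuracy.

These helpers string the modules together the way the CLI (and the tests)
use them; every step is the corresponding module function with its default
parameters unless overridden.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .classification import AccessionCall, SeedCall, call_accession, call_seed
from .msp import build_msp
from .preprocessing import filter_outlier_replicates
from .report import TruthRecord, ValidationReport, evaluate_seed_level
from .scoring import MatchResult, rank_against_library
from .types import (
    DEFAULT_TOLERANCE,
    Library,
    MassTolerance,
    PeakList,
    Taxonomy,
)
from .simulate import StudyData


def build_reference_library(
    groups: Mapping[tuple[str, str, int], Sequence[PeakList]],
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    genus: str = "",
    max_peaks: int = 70,
    min_freq: float = 0.25,
    min_spectra: int = 20,
    strict: bool = True,
    outlier_min_similarity: float = 0.5,
    synonym_map: Optional[dict] = None,
) -> Library:
    """Build one MSP per (species, accession, seed) group of replicate readings.

    Flatline and outlier replicates are removed before consensus building.
    """
    msps = []
    for (species, accession_id, seed_index), readings in groups.items():
        retained, _ = filter_outlier_replicates(
            readings, min_similarity=outlier_min_similarity, tolerance=tolerance
        )
        taxonomy = Taxonomy(genus, species, accession_id, seed_index)
        msps.append(
            build_msp(
                retained,
                max_peaks=max_peaks,
                min_freq=min_freq,
                min_spectra=min_spectra,
                tolerance=tolerance,
                strict=strict,
                taxonomy=taxonomy,
            )
        )
    kwargs = {} if synonym_map is None else {"synonym_map": synonym_map}
    return Library(msps=msps, **kwargs)


def classify_seed_replicates(
    replicates: Sequence[PeakList],
    library: Library,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    majority_min: int = 2,
    seed_id: Optional[str] = None,
) -> tuple[SeedCall, list[MatchResult]]:
    """Rank every technical replicate and apply the seed majority rule."""
    results = [rank_against_library(pl, library, tolerance) for pl in replicates]
    call = call_seed(
        results,
        majority_min=majority_min,
        synonym_map=library.synonym_map,
        seed_id=seed_id,
    )
    return call, results


def classify_blind_study(
    study: StudyData,
    library: Library,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
) -> dict[str, SeedCall]:
    """Per-seed calls for every blind sample of a simulated study."""
    calls: dict[str, SeedCall] = {}
    for sample_id, replicates in study.blind_peaklists.items():
        call, _ = classify_seed_replicates(
            replicates, library, tolerance, seed_id=sample_id
        )
        calls[sample_id] = call
    return calls


def evaluate_blind_study(
    study: StudyData,
    calls: Mapping[str, SeedCall],
    synonym_map: Optional[dict] = None,
) -> ValidationReport:
    """Seed-level accuracy of blind calls against the simulation truth."""
    truth = [
        TruthRecord(row.sample_id, row.species)
        for row in study.truth.itertuples(index=False)
    ]
    return evaluate_seed_level(list(calls.values()), truth, synonym_map)


def accession_calls_for_blind_study(
    study: StudyData,
    calls: Mapping[str, SeedCall],
    library: Library,
) -> tuple[list[AccessionCall], list[TruthRecord]]:
    """Group blind seed calls by their true source accession and vote.

    Returns the accession calls plus matching truth records, for
    accession-level evaluation of a simulated study.
    """
    by_accession: dict[str, list[SeedCall]] = {}
    species_of: dict[str, str] = {}
    for row in study.truth.itertuples(index=False):
        by_accession.setdefault(row.accession_id, []).append(calls[row.sample_id])
        species_of[row.accession_id] = row.species
    accession_calls = [
        call_accession(seed_calls, synonym_map=library.synonym_map, accession_id=acc)
        for acc, seed_calls in by_accession.items()
    ]
    truth = [TruthRecord(acc, species_of[acc]) for acc in by_accession]
    return accession_calls, truth
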