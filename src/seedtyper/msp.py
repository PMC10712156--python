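"""Consensus Main Spectrum (MSP) construction and library self-validation.

An MSP summarizes the 20-30 replicate readings of one seed as at most 70
reproducible peaks.  Replicate peaks are pooled and merged by greedy
single-linkage binning; a bin survives only if at least 25% of the
replicates contributed to it; survivors are ranked by replicate frequency,
then mean intensity, and the top 70 are kept.

Library self-validation re-queries every MSP against the full library: a
valid entry must match itself as the top hit with a score of at least 2.00,
and ideally match another accession of the same species as the second hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .preprocessing import normalize
from .scoring import rank_against_library
from .types import (
    DEFAULT_TOLERANCE,
    Library,
    MainSpectrum,
    MassTolerance,
    MspPeak,
    PeakList,
    Taxonomy,
)


@dataclass(frozen=True)
class ConsensusBin:
    """One merged peak position across replicates."""

    mz: float                # intensity-weighted mean of member peaks
    mean_intensity: float    # mean over contributing replicates only
    frequency: float         # contributing replicates / total replicates
    n_contributing: int


@dataclass(frozen=True)
class SelfValidationRecord:
    msp_label: str
    top_hit_label: str
    top_score: float
    second_hit_label: Optional[str]
    second_hit_species: Optional[str]
    second_hit_same_species: bool
    passed: bool


def bin_replicate_peaks(
    peaklists: Sequence[PeakList],
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
) -> list[ConsensusBin]:
    """Merge the pooled peaks of replicate readings into consensus bins.

    All peaks are pooled and sorted by m/z; a new bin starts whenever the
    gap to the previous pooled peak exceeds the tolerance window at that
    mass (greedy single linkage).  Within a bin at most one peak per
    replicate is counted (the most intense); frequency is the fraction of
    replicates contributing to the bin.
    """
    if len(peaklists) == 0:
        raise ValueError("no peak lists to bin")
    pooled: list[tuple[float, float, int]] = []  # (mz, intensity, replicate index)
    for rep, pl in enumerate(peaklists):
        for p in pl.peaks:
            pooled.append((p.mz, p.intensity, rep))
    pooled.sort()

    n_total = len(peaklists)
    bins: list[ConsensusBin] = []
    group: list[tuple[float, float, int]] = []

    def flush(members: list[tuple[float, float, int]]) -> None:
        best: dict[int, tuple[float, float]] = {}
        for mz, inten, rep in members:
            if rep not in best or inten > best[rep][1]:
                best[rep] = (mz, inten)
        total_int = sum(i for _, i in best.values())
        if total_int > 0:
            mz_mean = sum(m * i for m, i in best.values()) / total_int
        else:
            mz_mean = sum(m for m, _ in best.values()) / len(best)
        bins.append(
            ConsensusBin(
                mz=mz_mean,
                mean_intensity=sum(i for _, i in best.values()) / len(best),
                frequency=len(best) / n_total,
                n_contributing=len(best),
            )
        )

    for entry in pooled:
        if group and entry[0] - group[-1][0] > tolerance.window(entry[0]):
            flush(group)
            group = []
        group.append(entry)
    if group:
        flush(group)
    return bins


def build_msp(
    peaklists: Sequence[PeakList],
    max_peaks: int = 70,
    min_freq: float = 0.25,
    min_spectra: int = 20,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    strict: bool = True,
    taxonomy: Optional[Taxonomy] = None,
    label: Optional[str] = None,
    prenormalize: bool = True,
) -> MainSpectrum:
    """Build the consensus Main Spectrum of one seed from replicate readings.

    Flatline replicates are excluded.  In strict mode (the default, matching
    standard database practice) at least ``min_spectra`` usable replicates
    are required.  Each replicate is base-peak normalized before binning so
    mean intensities are comparable; bins below ``min_freq`` replicate
    frequency are discarded; the survivors are ranked by (frequency desc,
    mean intensity desc, m/z asc) and the top ``max_peaks`` retained.
    """
    usable = [pl for pl in peaklists if not pl.flatline and len(pl) > 0]
    if len(usable) < min_spectra:
        msg = (
            f"only {len(usable)} usable replicate spectra "
            f"(minimum {min_spectra} required to build an MSP)"
        )
        if strict:
            raise ValueError(msg)
    if not usable:
        raise ValueError("no usable replicate spectra at all")
    if prenormalize:
        usable = [normalize(pl, "base_peak") for pl in usable]

    bins = bin_replicate_peaks(usable, tolerance)
    survivors = [b for b in bins if b.frequency >= min_freq]
    survivors.sort(key=lambda b: (-b.frequency, -b.mean_intensity, b.mz))
    kept = sorted(survivors[:max_peaks], key=lambda b: b.mz)

    if taxonomy is None:
        meta = usable[0].meta
        taxonomy = (
            Taxonomy(meta.genus, meta.species, meta.accession_id, meta.seed_index)
            if meta is not None
            else Taxonomy("", "unknown", "", 1)
        )
    if label is None:
        label = f"{taxonomy.species} {taxonomy.accession_id} seed{taxonomy.seed_index}".strip()

    return MainSpectrum(
        peaks=[MspPeak(b.mz, b.mean_intensity, b.frequency) for b in kept],
        n_source=len(usable),
        taxonomy=taxonomy,
        label=label,
    )


def validate_library(
    library: Library,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    min_self_score: float = 2.00,
) -> list[SelfValidationRecord]:
    """Self-validate every MSP against the full library.

    Each MSP's consensus peak list is treated as an unknown query.  An entry
    passes when it matches itself as the top hit with a score of at least
    ``min_self_score``; the second hit is recorded and checked for being a
    conspecific accession (after synonym collapse).
    """
    if len(library) == 0:
        raise ValueError("cannot validate an empty library")
    from .classification import apply_synonyms

    records: list[SelfValidationRecord] = []
    for msp in library.msps:
        result = rank_against_library(
            msp.as_peaklist(), library, tolerance, query_id=msp.label
        )
        top = result.hits[0]
        second = result.hits[1] if len(result.hits) > 1 else None
        own = apply_synonyms(msp.taxonomy.species, library.synonym_map)
        same = (
            second is not None
            and apply_synonyms(second.species, library.synonym_map) == own
        )
        records.append(
            SelfValidationRecord(
                msp_label=msp.label,
                top_hit_label=top.label,
                top_score=top.score,
                second_hit_label=second.label if second else None,
                second_hit_species=second.species if second else None,
                second_hit_same_species=same,
                passed=(top.label == msp.label and top.score >= min_self_score),
            )
        )
    return records


def summarize_self_validation(records: Sequence[SelfValidationRecord]) -> dict:
    """Counts of failed entries and cross-species second hits."""
    return {
        "n_records": len(records),
        "n_passed": sum(r.passed for r in records),
        "n_failed": sum(not r.passed for r in records),
        "n_second_hit_other_species": sum(
            1 for r in records if r.second_hit_label is not None and not r.second_hit_same_species
        ),
    }
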