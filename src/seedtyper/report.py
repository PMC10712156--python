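"""Accuracy evaluation of identification calls against reference identities.

Three granularities are supported:

``seed``
    each seed's call against the analyst's reference identification
    (flatline counts as incorrect);
``accession``
    each accession's majority consensus against its reference;
``seed-consistency``
    each seed's call against its own accession's consensus, with
    waterhemp's historical name kept distinct — this is the per-seed
    success rate that penalizes any biological replicate diverging from
    the accession outcome.

Percentages are rounded half-away-from-zero to the nearest integer, the
only scheme consistent with all the headline figures on the packaged
fixtures.  Records with no valid reference identification are excluded
from every denominator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classification import (
    FLATLINE,
    NON_SPECIES_CALLS,
    AccessionCall,
    SeedCall,
    apply_synonyms,
    call_accession,
)
from .types import DEFAULT_SYNONYMS

#: Score below which a hit is conventionally read as "low relatedness".
LOW_RELATEDNESS_THRESHOLD = 1.70

#: Names kept distinct (exempt from synonym collapse) in seed-consistency
#: mode, where a historical-name replicate counts as a divergent seed.
CONSISTENCY_KEEP_DISTINCT = frozenset({"Amaranthus rudis"})


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    reference_species: str
    atypical: bool = False
    excluded: bool = False


@dataclass(frozen=True)
class ComparisonRow:
    sample_id: str
    called_species: str
    reference_species: str
    score: float
    correct: bool
    flatline: bool
    atypical: bool = False
    note: str = ""


@dataclass
class ValidationReport:
    n_evaluated: int
    n_correct: int
    n_flatline: int
    n_mismatch: int
    accuracy_percent: int
    spectra_success_percent: int
    rows: list[ComparisonRow] = field(default_factory=list)


def round_percent(numerator: float, denominator: float) -> int:
    """Percentage rounded half-away-from-zero to the nearest integer."""
    if denominator == 0:
        raise ValueError("empty denominator")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def canonicalize_species(name: str, synonym_map: Optional[Mapping[str, str]] = None) -> str:
    """Normalize a species name for comparison.

    Strips subspecies qualifiers ("X subsp. y" → "X"), resolves dual
    designations ("A/B" → "A"), and applies the synonym map.
    """
    name = name.strip()
    name = re.sub(r"\s+subsp\..*$", "", name)
    if "/" in name:
        name = name.split("/")[0].strip()
    return apply_synonyms(name, synonym_map)


def _evaluate(
    triples: Sequence[tuple[str, str, float, bool]],
    truth_by_id: Mapping[str, TruthRecord],
    synonym_map: Optional[Mapping[str, str]],
) -> ValidationReport:
    """Shared core: triples are (sample_id, called_species, score, atypical-ignored)."""
    rows: list[ComparisonRow] = []
    n_correct = n_flatline = n_mismatch = 0
    seen: set[str] = set()
    for sample_id, called, score_value, _ in triples:
        truth = truth_by_id.get(sample_id)
        if truth is None:
            raise KeyError(f"no reference identification for call {sample_id!r}")
        if truth.excluded:
            continue
        seen.add(sample_id)
        is_flat = called == FLATLINE
        if is_flat or called in NON_SPECIES_CALLS:
            correct = False
        else:
            correct = canonicalize_species(called, synonym_map) == canonicalize_species(
                truth.reference_species, synonym_map
            )
        if correct:
            n_correct += 1
        elif is_flat:
            n_flatline += 1
        else:
            n_mismatch += 1
        note = ""
        if not correct:
            if is_flat:
                note = "no protein spectra (flatline)"
            elif score_value < LOW_RELATEDNESS_THRESHOLD:
                note = f"low relatedness (score < {LOW_RELATEDNESS_THRESHOLD:.2f})"
        rows.append(
            ComparisonRow(
                sample_id=sample_id,
                called_species=called,
                reference_species=truth.reference_species,
                score=score_value,
                correct=correct,
                flatline=is_flat,
                atypical=truth.atypical,
                note=note,
            )
        )
    missing = [
        t.sample_id for t in truth_by_id.values() if not t.excluded and t.sample_id not in seen
    ]
    if missing:
        raise KeyError(f"reference record(s) without a call: {sorted(missing)}")
    n_eval = len(rows)
    if n_eval == 0:
        raise ValueError("nothing to evaluate")
    return ValidationReport(
        n_evaluated=n_eval,
        n_correct=n_correct,
        n_flatline=n_flatline,
        n_mismatch=n_mismatch,
        accuracy_percent=round_percent(n_correct, n_eval),
        spectra_success_percent=round_percent(n_eval - n_flatline, n_eval),
        rows=rows,
    )


def evaluate_seed_level(
    calls: Sequence[SeedCall],
    truth: Sequence[TruthRecord],
    synonym_map: Optional[Mapping[str, str]] = None,
) -> ValidationReport:
    """Per-seed accuracy: call versus reference, flatline counted incorrect."""
    truth_by_id = {t.sample_id: t for t in truth}
    triples = [(c.seed_id, c.called_species, c.average_score, False) for c in calls]
    return _evaluate(triples, truth_by_id, synonym_map)


def evaluate_accession_level(
    accession_calls: Sequence[AccessionCall],
    truth: Sequence[TruthRecord],
    synonym_map: Optional[Mapping[str, str]] = None,
) -> ValidationReport:
    """Per-accession accuracy: majority consensus versus reference."""
    truth_by_id = {t.sample_id: t for t in truth}
    triples = []
    for ac in accession_calls:
        scores = [
            c.average_score for c in ac.seed_calls if c.called_species not in NON_SPECIES_CALLS
        ]
        mean_score = sum(scores) / len(scores) if scores else 0.0
        triples.append((ac.accession_id, ac.consensus_species, mean_score, False))
    return _evaluate(triples, truth_by_id, synonym_map)


def evaluate_seed_consistency(
    seed_calls_by_accession: Mapping[str, Sequence[SeedCall]],
    synonym_map: Optional[Mapping[str, str]] = None,
    keep_distinct: frozenset = CONSISTENCY_KEEP_DISTINCT,
) -> ValidationReport:
    """Per-seed success against the accession's own consensus call.

    The consensus is computed with the full synonym map, but each seed's
    call is compared with names in ``keep_distinct`` left uncollapsed, so a
    replicate identified under a historical species name counts as a
    divergent seed even when the accession call is correct.
    """
    if synonym_map is None:
        synonym_map = DEFAULT_SYNONYMS
    strict_map = {k: v for k, v in synonym_map.items() if k not in keep_distinct}

    rows: list[ComparisonRow] = []
    n_correct = n_flatline = n_mismatch = 0
    for accession_id, calls in seed_calls_by_accession.items():
        consensus = call_accession(
            calls, synonym_map=synonym_map, accession_id=accession_id
        ).consensus_species
        for c in calls:
            is_flat = c.called_species == FLATLINE
            correct = (
                not is_flat
                and c.called_species not in NON_SPECIES_CALLS
                and canonicalize_species(c.called_species, strict_map) == consensus
            )
            if correct:
                n_correct += 1
            elif is_flat:
                n_flatline += 1
            else:
                n_mismatch += 1
            rows.append(
                ComparisonRow(
                    sample_id=f"{accession_id}[{c.seed_id}]",
                    called_species=c.called_species,
                    reference_species=consensus,
                    score=c.average_score,
                    correct=correct,
                    flatline=is_flat,
                )
            )
    n_eval = len(rows)
    if n_eval == 0:
        raise ValueError("nothing to evaluate")
    return ValidationReport(
        n_evaluated=n_eval,
        n_correct=n_correct,
        n_flatline=n_flatline,
        n_mismatch=n_mismatch,
        accuracy_percent=round_percent(n_correct, n_eval),
        spectra_success_percent=round_percent(n_eval - n_flatline, n_eval),
        rows=rows,
    )


def mismatch_table(report: ValidationReport) -> pd.DataFrame:
    """One row per mismatch or flatline, with score and relationship note."""
    rows = [
        {
            "sample_id": r.sample_id,
            "called_species": r.called_species,
            "reference_species": r.reference_species,
            "score": r.score,
            "note": r.note,
        }
        for r in report.rows
        if not r.correct
    ]
    return pd.DataFrame(rows, columns=["sample_id", "called_species", "reference_species", "score", "note"])


# ---------------------------------------------------------------------------
# packaged blind-test fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return files("seedtyper") / "fixtures" / name


def load_blind_set_aafc() -> tuple[dict[str, list[SeedCall]], list[TruthRecord]]:
    """The first blind set: 15 accessions × 3 seeds with per-seed calls.

    Returns ``(seed_calls_by_accession, accession_truth)``.
    """
    df = pd.read_csv(_fixture_path("table1.csv"))
    by_acc: dict[str, list[SeedCall]] = {}
    truth: dict[str, TruthRecord] = {}
    for _, row in df.iterrows():
        acc = row["sample_id"]
        by_acc.setdefault(acc, []).append(
            SeedCall(
                seed_id=f"{acc}.seed{int(row['seed_index'])}",
                called_species=row["called_species"],
                average_score=float(row["average_score"]),
                n_replicates=3,
                n_agreeing=3,
            )
        )
        truth[acc] = TruthRecord(acc, row["original_identification"])
    return by_acc, list(truth.values())


def load_blind_set_ssst() -> tuple[list[SeedCall], list[TruthRecord]]:
    """The second blind set: 60 evaluated single seeds plus 3 excluded ids.

    Returns ``(seed_calls, truth)`` where excluded records carry no call.
    """
    df = pd.read_csv(_fixture_path("table2.csv"))
    calls: list[SeedCall] = []
    truth: list[TruthRecord] = []
    for _, row in df.iterrows():
        excluded = bool(int(row["excluded"]))
        truth.append(
            TruthRecord(
                sample_id=row["sample_id"],
                reference_species="" if excluded else row["reference_species"],
                atypical=bool(int(row["atypical"])),
                excluded=excluded,
            )
        )
        if not excluded:
            calls.append(
                SeedCall(
                    seed_id=row["sample_id"],
                    called_species=row["called_species"],
                    average_score=float(row["average_score"]),
                    n_replicates=3,
                    n_agreeing=0 if row["called_species"] == FLATLINE else 2,
                )
            )
    return calls, truth
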