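"""Majority-rule species calling.

A seed is measured as three technical replicates; each non-flatline
replicate votes with its (synonym-collapsed) top library hit.  If at least
two replicates agree, the seed is called as that species and the reported
score is the mean of the agreeing replicates' top scores.  A seed whose
replicates all flatline is reported as FLATLINE with score 0.00; three-way
disagreement is reported as INCONCLUSIVE.  Accessions are called the same
way by majority over their seeds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .scoring import MatchResult
from .types import DEFAULT_SYNONYMS

FLATLINE = "FLATLINE"
INCONCLUSIVE = "INCONCLUSIVE"

#: Calls that never carry a species vote.
NON_SPECIES_CALLS = frozenset({FLATLINE, INCONCLUSIVE})


@dataclass(frozen=True)
class SeedCall:
    seed_id: str
    called_species: str
    average_score: float
    n_replicates: int
    n_agreeing: int


@dataclass
class AccessionCall:
    accession_id: str
    consensus_species: str
    seed_calls: list[SeedCall] = field(default_factory=list)
    n_agreeing_seeds: int = 0


def apply_synonyms(species_name: str, synonym_map: Optional[Mapping[str, str]] = None) -> str:
    """Map a species name to its canonical form; unknown names pass through."""
    if synonym_map is None:
        synonym_map = DEFAULT_SYNONYMS
    return synonym_map.get(species_name, species_name)


def _majority(votes: Sequence[str], majority_min: int) -> Optional[str]:
    """The unique modal value reaching ``majority_min``, else None."""
    if not votes:
        return None
    counts = Counter(votes).most_common()
    top_label, top_count = counts[0]
    if top_count < majority_min:
        return None
    if len(counts) > 1 and counts[1][1] == top_count:
        return None  # tied mode
    return top_label


def call_seed(
    replicate_results: Sequence[MatchResult],
    majority_min: int = 2,
    synonym_map: Optional[Mapping[str, str]] = None,
    seed_id: Optional[str] = None,
) -> SeedCall:
    """Aggregate replicate-level top hits into one per-seed call."""
    if len(replicate_results) == 0:
        raise ValueError("no replicate results")
    if seed_id is None:
        seed_id = replicate_results[0].query_id
    usable = [r for r in replicate_results if not r.flatline and r.hits]
    if not usable:
        return SeedCall(seed_id, FLATLINE, 0.0, len(replicate_results), 0)

    votes = [apply_synonyms(r.hits[0].species, synonym_map) for r in usable]
    winner = _majority(votes, majority_min)
    if winner is None:
        return SeedCall(seed_id, INCONCLUSIVE, 0.0, len(replicate_results), 0)
    agreeing = [r.hits[0].score for r, v in zip(usable, votes) if v == winner]
    return SeedCall(
        seed_id=seed_id,
        called_species=winner,
        average_score=sum(agreeing) / len(agreeing),
        n_replicates=len(replicate_results),
        n_agreeing=len(agreeing),
    )


def call_accession(
    seed_calls: Sequence[SeedCall],
    majority_min: int = 2,
    synonym_map: Optional[Mapping[str, str]] = None,
    accession_id: str = "",
) -> AccessionCall:
    """Majority vote over non-flatline, non-inconclusive seed calls."""
    if len(seed_calls) == 0:
        raise ValueError("no seed calls")
    votes = [
        apply_synonyms(c.called_species, synonym_map)
        for c in seed_calls
        if c.called_species not in NON_SPECIES_CALLS
    ]
    winner = _majority(votes, majority_min)
    if winner is None:
        return AccessionCall(accession_id, INCONCLUSIVE, list(seed_calls), 0)
    return AccessionCall(
        accession_id=accession_id,
        consensus_species=winner,
        seed_calls=list(seed_calls),
        n_agreeing_seeds=sum(1 for v in votes if v == winner),
    )
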