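"""Leave-one-out distance-based specimen identification.

Three criteria, applied to each accession queried against all others in
the same (possibly concatenated) alignment:

* **best match** — assign the query to the species of the nearest
  reference(s), regardless of how far away they are; a tie spanning
  several species is ambiguous.
* **best close match** — as best match, but if even the nearest
  reference lies beyond a distance threshold the query is unidentified
  (``no_match``).  The threshold defaults to the 95th nearest-rank
  percentile of the pooled intraspecific distances.
* **all species barcodes** — the query is correct only when the set of
  references within the threshold is exactly the full set of its
  conspecific references and contains at least two of them; queries
  with fewer than two conspecific references are scored
  ``no_conspecific``.

Undefined (masked) distances are treated as farther than any defined
distance: a query can never match through a masked entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignments import MarkerAlignment
from .distances import DistanceMatrix, build_distance_matrix, partition_distances

__all__ = [
    "CRITERIA",
    "IdentificationResult",
    "SuccessRates",
    "intraspecific_threshold",
    "identify_query",
    "identification_success_rates",
]

CRITERIA = ("best_match", "best_close_match", "all_species_barcodes")
OUTCOMES = ("correct", "ambiguous", "incorrect", "no_match", "no_conspecific")


@dataclass(frozen=True)
class IdentificationResult:
    query: str
    criterion: str
    outcome: str
    best_distance: float | None
    matched_species: frozenset[str]


def intraspecific_threshold(intra: Sequence[float], percentile: float = 95.0) -> float:
    """Nearest-rank percentile of the intraspecific distance pool.

    rank = ceil(percentile/100 * n) over the sorted pool (1-based).
    """
    if not len(intra):
        raise ValueError("intraspecific pool is empty; threshold unavailable")
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must be in (0, 100]")
    pool = sorted(float(v) for v in intra)
    rank = math.ceil(percentile / 100.0 * len(pool))
    return pool[rank - 1]


def _best_match_outcome(
    query_species: str, best_species: frozenset[str]
) -> str:
    if best_species == {query_species}:
        return "correct"
    if query_species in best_species:
        return "ambiguous"
    return "incorrect"


def identify_query(
    query: str,
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    criterion: str,
    threshold: float | None = None,
) -> IdentificationResult:
    """Classify one leave-one-out query under one criterion."""
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion != "best_match" and threshold is None:
        raise ValueError(f"{criterion} requires a distance threshold")
    qi = dm.index_of(query)
    q_species = species_of[query]

    refs: list[tuple[str, float]] = []  # defined distances only
    conspecifics: set[str] = set()
    for j, label in enumerate(dm.labels):
        if j == qi:
            continue
        if species_of[label] == q_species:
            conspecifics.add(label)
        if dm.defined[qi, j]:
            refs.append((label, float(dm.values[qi, j])))

    if not refs:
        return IdentificationResult(query, criterion, "no_match", None, frozenset())

    best_d = min(d for _, d in refs)
    best_set = frozenset(lab for lab, d in refs if d == best_d)
    best_species = frozenset(species_of[lab] for lab in best_set)

    if criterion == "best_match":
        outcome = _best_match_outcome(q_species, best_species)
        return IdentificationResult(query, criterion, outcome, best_d, best_species)

    if criterion == "best_close_match":
        if best_d > threshold:
            return IdentificationResult(
                query, criterion, "no_match", best_d, frozenset()
            )
        outcome = _best_match_outcome(q_species, best_species)
        return IdentificationResult(query, criterion, outcome, best_d, best_species)

    # all_species_barcodes
    if len(conspecifics) < 2:
        return IdentificationResult(
            query, criterion, "no_conspecific", best_d, frozenset()
        )
    within = {lab for lab, d in refs if d <= threshold}
    within_species = frozenset(species_of[lab] for lab in within)
    if not within:
        return IdentificationResult(query, criterion, "no_match", best_d, frozenset())
    if within == conspecifics:
        return IdentificationResult(
            query, criterion, "correct", best_d, within_species
        )
    if within <= conspecifics:
        # strict subset of conspecifics: some conspecific barcodes unmatched
        return IdentificationResult(
            query, criterion, "incorrect", best_d, within_species
        )
    # heterospecific references inside the threshold
    outcome = "ambiguous" if (within & conspecifics) else "incorrect"
    return IdentificationResult(query, criterion, outcome, best_d, within_species)


@dataclass
class SuccessRates:
    """Aggregated leave-one-out outcomes for one marker combination."""

    combo: list[str]
    threshold: float | None
    per_criterion: dict[str, dict] = field(default_factory=dict)

    def pct_correct(self, criterion: str) -> float:
        return self.per_criterion[criterion]["pct_correct"]


def identification_success_rates(
    alignment: MarkerAlignment,
    species_of: Mapping[str, str] | None = None,
    criteria: Sequence[str] = CRITERIA,
    percentile: float = 95.0,
    dm: DistanceMatrix | None = None,
    combo: Sequence[str] | None = None,
) -> SuccessRates:
    """Leave-one-out identification of every accession in an alignment.

    The distance matrix is built once; the threshold is the nearest-rank
    percentile of the full intraspecific distance pool of this
    alignment.  When no intraspecific distances exist, threshold-using
    criteria degrade to threshold = +inf (no query can be ``no_match``)
    and this is recorded on the result.
    """
    if species_of is None:
        species_of = alignment.species_of
    if dm is None:
        dm = build_distance_matrix(alignment)
    intra, _ = partition_distances(dm, species_of)
    threshold: float | None
    if intra:
        threshold = intraspecific_threshold(intra, percentile)
    else:
        threshold = math.inf

    result = SuccessRates(
        combo=list(combo) if combo is not None else [alignment.marker],
        threshold=None if threshold == math.inf else threshold,
    )
    for criterion in criteria:
        counts = {k: 0 for k in OUTCOMES}
        for query in dm.labels:
            res = identify_query(query, dm, species_of, criterion, threshold)
            counts[res.outcome] += 1
        n_queries = len(dm.labels)
        result.per_criterion[criterion] = {
            "n_queries": n_queries,
            "n_correct": counts["correct"],
            "n_ambiguous": counts["ambiguous"],
            "n_incorrect": counts["incorrect"],
            "n_no_match": counts["no_match"],
            "n_no_conspecific": counts["no_conspecific"],
            "pct_correct": round(100.0 * counts["correct"] / n_queries, 2),
        }
    return result
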