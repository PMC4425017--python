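"""Best-match and best-close-match species identification.

Both rules score a dataset by leave-one-out self-identification: each record
in turn is the *query*, its candidates are all other records with a defined
K2P distance to it, and the query is identified by the species of its nearest
candidate(s).

Best match (BM) categories:

* ``correct`` — every tied nearest candidate is conspecific with the query;
* ``ambiguous`` — the tie spans the query's species and at least one other;
* ``incorrect`` — no tied nearest candidate is conspecific (including ties
  among two or more foreign species).

Best close match (BCM) adds a distance ceiling: queries whose nearest
candidate lies strictly above the dataset's 95th-percentile intraspecific
threshold become ``no_match``; the rest are categorised exactly as BM. BCM is
therefore never more permissive than BM: its correct (and incorrect)
percentages are bounded above by BM's.

Singleton species are legitimate queries under both rules — they simply have
no conspecific candidate, so the best they can achieve is ``incorrect`` under
BM and ``no_match`` under BCM. Queries with no defined distance at all are
tallied separately as *uncomparable* and excluded from the denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, PairwiseSummary

DEFAULT_TIE_TOLERANCE = 1e-10

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_match")


@dataclass(frozen=True)
class MatchVerdict:
    """Outcome of identifying one query record against the rest of the dataset."""

    query: tuple[str, str]  # (species, sample_id)
    best_distance: float | None
    best_match_species: frozenset[str]
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class IdentificationReport:
    """Per-query verdicts plus dataset-level percentages for one method."""

    method: str  # "BM" or "BCM"
    verdicts: list[MatchVerdict]
    uncomparable: list[tuple[str, str]] = field(default_factory=list)
    threshold_used: float | None = None

    @property
    def n_queries(self) -> int:
        return len(self.verdicts)

    def _pct(self, category: str) -> float:
        if not self.verdicts:
            return float("nan")
        n = sum(1 for v in self.verdicts if v.category == category)
        return 100.0 * n / self.n_queries

    @property
    def pct_correct(self) -> float:
        return self._pct("correct")

    @property
    def pct_ambiguous(self) -> float:
        return self._pct("ambiguous")

    @property
    def pct_incorrect(self) -> float:
        return self._pct("incorrect")

    @property
    def pct_no_match(self) -> float:
        return self._pct("no_match")

    def to_frame(self) -> pd.DataFrame:
        """Per-query verdict table (one row per query, tie set sorted)."""
        return pd.DataFrame(
            {
                "query_species": [v.query[0] for v in self.verdicts],
                "sample_id": [v.query[1] for v in self.verdicts],
                "best_distance": [v.best_distance for v in self.verdicts],
                "tied_species": [
                    ";".join(sorted(v.best_match_species)) for v in self.verdicts
                ],
                "category": [v.category for v in self.verdicts],
            }
        )


def _classify(query_species: str, tied: frozenset[str]) -> str:
    if tied == {query_species}:
        return "correct"
    if query_species in tied:
        return "ambiguous"
    return "incorrect"


def _leave_one_out(
    dm: DistanceMatrix, tie_tolerance: float, threshold: float | None
) -> tuple[list[MatchVerdict], list[tuple[str, str]]]:
    n = len(dm)
    species = dm.species
    verdicts: list[MatchVerdict] = []
    uncomparable: list[tuple[str, str]] = []
    for i in range(n):
        mask = dm.defined[i].copy()
        mask[i] = False
        if not mask.any():
            uncomparable.append(dm.labels[i])
            continue
        dists = dm.values[i]
        best = float(np.min(dists[mask]))
        tied = frozenset(species[mask & (dists <= best + tie_tolerance)])
        if threshold is not None and best > threshold:
            category = "no_match"
        else:
            category = _classify(species[i], tied)
        verdicts.append(
            MatchVerdict(
                query=dm.labels[i],
                best_distance=best,
                best_match_species=tied,
                category=category,
            )
        )
    return verdicts, uncomparable


def best_match(
    dm: DistanceMatrix, tie_tolerance: float = DEFAULT_TIE_TOLERANCE
) -> IdentificationReport:
    """Leave-one-out best-match identification over a distance matrix.

    Candidates within ``tie_tolerance`` of the minimum distance are pooled
    into the tie set, making verdicts independent of record order.
    """
    verdicts, uncomp = _leave_one_out(dm, tie_tolerance, threshold=None)
    return IdentificationReport(method="BM", verdicts=verdicts, uncomparable=uncomp)


def best_close_match(
    dm: DistanceMatrix,
    ps: PairwiseSummary,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> IdentificationReport:
    """Best close match: BM restricted to queries at or below the 95% threshold.

    Queries whose nearest defined candidate lies strictly above
    ``ps.threshold`` are classified ``no_match``; the remainder are
    categorised exactly as under BM.
    """
    verdicts, uncomp = _leave_one_out(dm, tie_tolerance, threshold=ps.threshold)
    return IdentificationReport(
        method="BCM", verdicts=verdicts, uncomparable=uncomp, threshold_used=ps.threshold
    )


def summarize_by_dataset(
    reports: Iterable[tuple[str, IdentificationReport]]
) -> pd.DataFrame:
    """Comparison table: one row per (dataset, method) with the standard columns.

    The threshold column reports the dataset's 95th-percentile intraspecific
    distance expressed in percent (BCM rows only).
    """
    rows = []
    for dataset, rep in reports:
        rows.append(
            {
                "dataset": dataset,
                "method": rep.method,
                "n_queries": rep.n_queries,
                "n_uncomparable": len(rep.uncomparable),
                "correct_pct": round(rep.pct_correct, 2),
                "ambiguous_pct": round(rep.pct_ambiguous, 2),
                "incorrect_pct": round(rep.pct_incorrect, 2),
                "no_match_pct": round(rep.pct_no_match, 2)
                if rep.method == "BCM"
                else None,
                "threshold_pct": round(100.0 * rep.threshold_used, 2)
                if rep.threshold_used is not None
                else None,
            }
        )
    return pd.DataFrame(rows)
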