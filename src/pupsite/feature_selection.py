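"""Pearson-correlation ranking of amino-acid pairs and stepwise selection.

The 20 amino acids are correlated through their composition (AAC) profiles
across training samples; an ordered pair (a, b) inherits the correlation of
columns a and b.  The 20 self-pairs (AA ... YY) have correlation exactly 1
and are pinned to the top of the ranking; cross pairs follow in descending
score with lexicographic tie-breaking.  Dipeptide (AAPC) feature subsets are
then grown in steps of 20 ranked pairs and scored by a supplied evaluator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_PAIRS, AMINO_ACIDS
from .peptide_io import FeatureMatrix

logger = logging.getLogger(__name__)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Raises on length mismatch, length < 2, or zero variance (the
    coefficient is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    return float((xc @ yc) / math.sqrt(sx * sy))


@dataclass(frozen=True)
class RankEntry:
    pair: str
    score: float  # NaN marks an undefined correlation
    rank: int


@dataclass
class PairRanking:
    """All 400 ordered amino-acid pairs with scores and 1-based ranks."""

    entries: list[RankEntry]

    def __post_init__(self) -> None:
        if len(self.entries) != 400:
            raise ValueError(f"expected 400 pairs, got {len(self.entries)}")
        if sorted(e.pair for e in self.entries) != sorted(AA_PAIRS):
            raise ValueError("entries must cover all 400 ordered pairs once")
        finite = [e.score for e in self.entries if not math.isnan(e.score)]
        if any(b > a + 1e-12 for a, b in zip(finite, finite[1:])):
            raise ValueError("scores must be non-increasing with rank")

    def top(self, n: int) -> list[str]:
        return [e.pair for e in self.entries[:n]]

    def score_of(self, pair: str) -> float:
        for e in self.entries:
            if e.pair == pair:
                return e.score
        raise KeyError(pair)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pair, e.score, e.rank) for e in self.entries],
            columns=["pair", "score", "rank"],
        )


def write_ranking(ranking: PairRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ranking(path: str | Path) -> PairRanking:
    # keep_default_na: the pair "NA" is a dipeptide, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return PairRanking(
        [
            RankEntry(str(r.pair), float(r.score) if r.score != "" else math.nan,
                      int(r.rank))
            for r in df.itertuples()
        ]
    )


def rank_amino_acid_pairs(aac: FeatureMatrix) -> PairRanking:
    """Rank the 400 ordered pairs by Pearson correlation of AAC columns.

    Self-pairs are pinned to the top with score exactly 1.  A zero-variance
    amino-acid column makes every cross pair containing it undefined; those
    pairs are ranked last with a NaN score and a logged warning.
    """
    if aac.n_features != 20 or list(aac.feature_names) != list(AMINO_ACIDS):
        raise ValueError("expected a 20-column AAC matrix in alphabet order")
    if aac.n_samples < 2:
        raise ValueError("need at least 2 training samples")
    X = aac.values
    degenerate = {
        AMINO_ACIDS[i] for i in range(20) if np.ptp(X[:, i]) == 0.0
    }
    if degenerate:
        logger.warning(
            "zero-variance AAC columns %s: their cross pairs ranked last",
            sorted(degenerate),
        )
    scored: list[tuple[int, float, str]] = []
    for pair in AA_PAIRS:
        a, b = pair[0], pair[1]
        if a == b:
            scored.append((0, 1.0, pair))  # pinned self-pair
        elif a in degenerate or b in degenerate:
            scored.append((2, math.nan, pair))
        else:
            s = pearson(X[:, AMINO_ACIDS.index(a)], X[:, AMINO_ACIDS.index(b)])
            scored.append((1, s, pair))
    scored.sort(key=lambda t: (t[0], -t[1] if not math.isnan(t[1]) else 0.0, t[2]))
    return PairRanking(
        [RankEntry(pair, score, i + 1) for i, (_, score, pair) in enumerate(scored)]
    )


STEP_GRID = tuple(range(20, 401, 20))


def select_aapc_features(
    aapc: FeatureMatrix, ranking: PairRanking, n: int
) -> FeatureMatrix:
    """The n top-ranked pairs' AAPC columns, in ranking order."""
    if n not in STEP_GRID:
        raise ValueError(f"n must be a multiple of 20 in [20, 400], got {n}")
    return aapc.select(ranking.top(n))


@dataclass
class SelectionResult:
    """Stepwise-search table over n = 20, 40, ..., 400 plus the winner."""

    table: pd.DataFrame  # columns: n_features, Sn, Sp, Acc, MCC
    best_n: int

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def stepwise_search(
    aapc: FeatureMatrix,
    labels: np.ndarray,
    ranking: PairRanking,
    evaluator: Callable[[FeatureMatrix, np.ndarray], "object"],
) -> SelectionResult:
    """Grow the ranked AAPC subset by steps of 20 and score each size.

    ``evaluator(features, labels)`` must return an object with ``sn``,
    ``sp``, ``acc`` and ``mcc`` attributes (e.g. an EvalMetrics from a
    jackknife or k-fold run).  The winner maximizes Acc, ties broken by
    larger MCC then smaller n.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("dataset must contain both classes")
    rows = []
    for n in STEP_GRID:
        sub = select_aapc_features(aapc, ranking, n)
        try:
            m = evaluator(sub, labels)
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at n={n}: {exc}") from exc
        rows.append((n, m.sn, m.sp, m.acc, m.mcc))
    table = pd.DataFrame(rows, columns=["n_features", "Sn", "Sp", "Acc", "MCC"])
    best = max(rows, key=lambda r: (r[3], r[4], -r[0]))
    return SelectionResult(table=table, best_n=int(best[0]))
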