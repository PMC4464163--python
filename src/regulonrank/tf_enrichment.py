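"""Per-TF Fisher exact enrichment of DEGs among regulon targets.

For each TF the gene universe is partitioned into the 2x2 table

    a = |targets ∩ DEGs|      b = |targets \\ DEGs|
    c = |DEGs \\ targets|     d = |universe \\ (targets ∪ DEGs)|

with n = a+b+c+d = |universe|.  The exact test conditions on both margins,
so the a-cell follows a hypergeometric distribution.  The two-sided P-value
uses the minimum-likelihood convention: the total probability of all tables
(margins fixed) whose point probability does not exceed that of the observed
table, with a relative slack of 1e-7 for floating-point ties.  Point
probabilities are evaluated in log space via log-gamma and accumulated with
compensated summation from the nearer tail inward, so P-values at the
1e-17 scale (and far below) are computed accurately rather than underflowing
or collapsing to the nearest tail.

A table can be *depleted* (a·d < b·c) and still earn a very small two-sided
P; both directions are reported.  TFs are ranked by ascending P with
lexicographic tie-breaking; significance is a raw P threshold (default
0.01) with a BH-adjusted column emitted alongside for reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .deg_stats import adjust_fdr
from .errors import ConsistencyError

logger = logging.getLogger(__name__)

DEFAULT_TF_ALPHA = 0.01
ALTERNATIVES = ("two-sided", "greater", "less")
_TIE_SLACK = math.log1p(1e-7)

RESULT_COLUMNS = (
    "tf",
    "a",
    "b",
    "c",
    "d",
    "p_value",
    "fdr",
    "rank",
    "significant",
    "direction",
)


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells of one TF's DEG-by-target partition of the universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def direction(self) -> str:
        """'enriched' when the odds ratio exceeds 1 (a·d > b·c), else 'depleted'."""
        return "enriched" if self.a * self.d >= self.b * self.c else "depleted"


@dataclass
class TFEnrichmentResult:
    tf_id: str
    table: ContingencyTable
    p_value: float
    rank: int
    significant: bool
    direction: str
    fdr: float = float("nan")

    def to_row(self) -> dict:
        return {
            "tf": self.tf_id,
            "a": self.table.a,
            "b": self.table.b,
            "c": self.table.c,
            "d": self.table.d,
            "p_value": self.p_value,
            "fdr": self.fdr,
            "rank": self.rank,
            "significant": self.significant,
            "direction": self.direction,
        }


def build_contingency(
    targets: set[str], degs: set[str], universe: set[str]
) -> ContingencyTable:
    """Partition the universe into the four Fisher cells for one TF."""
    targets, degs, universe = set(targets), set(degs), set(universe)
    if not targets <= universe:
        raise ConsistencyError(
            f"{len(targets - universe)} target(s) outside the universe; "
            "intersect first"
        )
    if not degs <= universe:
        raise ConsistencyError(
            f"{len(degs - universe)} DEG(s) outside the universe; intersect first"
        )
    a = len(targets & degs)
    b = len(targets) - a
    c = len(degs) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# log-space hypergeometric machinery

_logfact: list[float] = [0.0]


def _lf(m: int) -> float:
    """log(m!) from a growing cache (exact relative error of lgamma)."""
    cache = _logfact
    while len(cache) <= m:
        cache.append(cache[-1] + math.log(len(cache)))
    return cache[m]


def _log_pmf_support(table: ContingencyTable):
    """Support of the a-cell and its log hypergeometric pmf, margins fixed."""
    n = table.n
    r = table.a + table.b  # targets margin
    s = table.a + table.c  # DEG margin
    lo = max(0, r + s - n)
    hi = min(r, s)
    const = _lf(r) + _lf(n - r) + _lf(s) + _lf(n - s) - _lf(n)
    logpmf = [
        const - _lf(k) - _lf(r - k) - _lf(s - k) - _lf(n - r - s + k)
        for k in range(lo, hi + 1)
    ]
    return lo, hi, logpmf


def fisher_exact(
    table: ContingencyTable | Sequence[int], alternative: str = "two-sided"
) -> float:
    """Exact hypergeometric P-value for one 2x2 table.

    ``two-sided`` sums the probabilities of every table in the support whose
    point probability is at most the observed one (relative tie slack 1e-7);
    ``greater`` / ``less`` are the upper / lower tails on the a-cell, each
    including the observed point's mass.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*(int(x) for x in table))
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if table.n < 1:
        raise ValueError("table must contain at least one observation")
    lo, hi, logpmf = _log_pmf_support(table)
    idx = table.a - lo
    if alternative == "greater":
        terms = logpmf[idx:]
    elif alternative == "less":
        terms = logpmf[: idx + 1]
    else:
        threshold = logpmf[idx] + _TIE_SLACK
        terms = [lp for lp in logpmf if lp <= threshold]
    # smallest terms first: exact tails are dominated by the near end, and
    # fsum compensates the rest
    p = math.fsum(math.exp(lp) for lp in sorted(terms))
    return min(p, 1.0)


def rank_tfs(
    tf_sets: Mapping[str, Iterable[str]],
    degs: set[str],
    universe: set[str],
    tf_alpha: float = DEFAULT_TF_ALPHA,
    alternative: str = "two-sided",
) -> list[TFEnrichmentResult]:
    """Rank every TF with a non-empty in-universe target set by ascending P.

    The TF itself need not be a DEG (nor in the universe) to be tested.
    Ties in P are broken by lexicographic TF id.  ``significant`` compares
    the raw P strictly against ``tf_alpha``; a BH-adjusted value is attached
    for reference but does not drive the flag.
    """
    universe = set(universe)
    degs = set(degs) & universe
    if not tf_sets:
        logger.warning("rank_tfs: empty TF set mapping; returning no results")
        return []
    entries: list[tuple[str, ContingencyTable, float]] = []
    for tf_id in tf_sets:
        targets = set(tf_sets[tf_id]) & universe
        if not targets:
            continue
        tab = build_contingency(targets, degs, universe)
        entries.append((tf_id, tab, fisher_exact(tab, alternative)))
    entries.sort(key=lambda e: (e[2], e[0]))
    fdrs = adjust_fdr([e[2] for e in entries]) if entries else []
    results = [
        TFEnrichmentResult(
            tf_id=tf_id,
            table=tab,
            p_value=p,
            rank=i + 1,
            significant=p < tf_alpha,
            direction=tab.direction,
            fdr=float(q),
        )
        for i, ((tf_id, tab, p), q) in enumerate(zip(entries, fdrs))
    ]
    logger.info(
        "rank_tfs: tested %d TF(s); %d significant at P < %g",
        len(results),
        sum(r.significant for r in results),
        tf_alpha,
    )
    return results


class ConditionComparison(NamedTuple):
    shared: set[str]
    only_a: set[str]
    only_b: set[str]


def compare_conditions(
    ranked_a: Sequence[TFEnrichmentResult],
    ranked_b: Sequence[TFEnrichmentResult],
    top_k: int = 10,
) -> ConditionComparison:
    """Set algebra on the top-k TF ids of two ranked condition lists."""
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if top_k > len(ranked_a) or top_k > len(ranked_b):
        logger.warning(
            "compare_conditions: top_k=%d exceeds a list length (%d / %d); "
            "using the full list(s)",
            top_k,
            len(ranked_a),
            len(ranked_b),
        )
    ids_a = {r.tf_id for r in ranked_a[:top_k]}
    ids_b = {r.tf_id for r in ranked_b[:top_k]}
    return ConditionComparison(ids_a & ids_b, ids_a - ids_b, ids_b - ids_a)
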