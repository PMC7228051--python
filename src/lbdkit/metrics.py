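"""Co-occurrence association metrics over 2x2 contingency counts.

Eight scores are exposed: raw sentence and document co-occurrence counts,
Jaccard index, symmetric conditional probability (SCP), normalised pointwise
mutual information (NPMI), Pearson chi-squared, the collocation t statistic,
and the log-likelihood ratio (LLR).  All probability-based scores are driven
by sentence-level counts; only ``doc_count`` reads the document-level cell.
Natural logarithms are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ContingencyCounts",
    "UndefinedScoreError",
    "METRICS",
    "get_metric",
    "count",
    "doc_count",
    "jaccard",
    "scp",
    "npmi",
    "chi_squared",
    "t_test",
    "llr",
]


class UndefinedScoreError(ValueError):
    """Raised when a metric is undefined for the given counts."""


@dataclass(frozen=True)
class ContingencyCounts:
    """Sufficient statistics for one entity pair.

    ``n_*`` are sentence-level counts (``n_xy`` sentences containing both
    entities, ``n_x``/``n_y`` sentences containing each, ``N`` total
    sentences); ``d_*`` are the document-level analogues.
    """

    n_xy: int
    n_x: int
    n_y: int
    N: int
    d_xy: int = 0
    d_x: int = 0
    d_y: int = 0
    D: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.n_xy <= min(self.n_x, self.n_y) <= max(self.n_x, self.n_y) <= self.N):
            raise ValueError(
                f"invalid sentence counts: n_xy={self.n_xy} n_x={self.n_x} "
                f"n_y={self.n_y} N={self.N}"
            )
        if self.N < 1:
            raise ValueError("N must be >= 1")
        doc_ok = (
            0 <= self.d_xy <= min(self.d_x, self.d_y)
            and max(self.d_x, self.d_y) <= self.D
        )
        if not doc_ok:
            raise ValueError(
                f"invalid document counts: d_xy={self.d_xy} d_x={self.d_x} "
                f"d_y={self.d_y} D={self.D}"
            )


def count(c: ContingencyCounts) -> int:
    """Number of sentences in which both entities co-occur."""
    return c.n_xy


def doc_count(c: ContingencyCounts) -> int:
    """Number of documents in which both entities co-occur."""
    return c.d_xy


def jaccard(c: ContingencyCounts) -> float:
    """|sentences(x) ∩ sentences(y)| / |sentences(x) ∪ sentences(y)|."""
    denom = c.n_x + c.n_y - c.n_xy
    if denom <= 0:
        raise UndefinedScoreError("jaccard undefined: both entities unseen")
    return c.n_xy / denom


def scp(c: ContingencyCounts) -> float:
    """Symmetric conditional probability p(x|y) * p(y|x) = n_xy^2/(n_x*n_y)."""
    if c.n_x == 0 or c.n_y == 0:
        raise UndefinedScoreError("scp undefined: zero marginal")
    return (c.n_xy * c.n_xy) / (c.n_x * c.n_y)


def npmi(c: ContingencyCounts) -> float:
    """Pointwise mutual information normalised by -ln p_xy, in [-1, 1].

    The n_xy = 0 limit is -1 (the infimum), which keeps rankings total.
    """
    if c.n_xy == 0:
        return -1.0
    if c.n_x == 0 or c.n_y == 0:
        raise UndefinedScoreError("npmi undefined: zero marginal")
    p_xy = c.n_xy / c.N
    p_x = c.n_x / c.N
    p_y = c.n_y / c.N
    if p_xy == 1.0:
        # ln p_xy = 0: the normaliser vanishes; pmi is <= 0 here and the
        # distributions are maximally dependent, so return the supremum.
        return 1.0
    return math.log(p_xy / (p_x * p_y)) / (-math.log(p_xy))


def _cells(c: ContingencyCounts) -> tuple[list[float], list[float]]:
    """Observed and expected cell counts of the 2x2 sentence table."""
    o11 = c.n_xy
    o12 = c.n_x - c.n_xy
    o21 = c.n_y - c.n_xy
    o22 = c.N - c.n_x - c.n_y + c.n_xy
    if o22 < 0:
        raise UndefinedScoreError("inconsistent table: n_x + n_y - n_xy > N")
    n = c.N
    e11 = c.n_x * c.n_y / n
    e12 = c.n_x * (n - c.n_y) / n
    e21 = (n - c.n_x) * c.n_y / n
    e22 = (n - c.n_x) * (n - c.n_y) / n
    return [o11, o12, o21, o22], [e11, e12, e21, e22]


def chi_squared(c: ContingencyCounts) -> float:
    """Pearson chi-squared statistic of the 2x2 sentence table."""
    obs, exp = _cells(c)
    if any(e == 0 for e in exp):
        raise UndefinedScoreError("chi-squared undefined: zero expected cell")
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


def t_test(c: ContingencyCounts) -> float:
    """Collocation t statistic: (p_xy - p_x*p_y) / sqrt(p_xy / N).

    For n_xy = 0 the denominator vanishes; 0.0 is returned so that rankings
    stay total (stored graph edges always have n_xy >= 1).
    """
    if c.n_xy == 0:
        return 0.0
    p_xy = c.n_xy / c.N
    p_x = c.n_x / c.N
    p_y = c.n_y / c.N
    return (p_xy - p_x * p_y) / math.sqrt(p_xy / c.N)


def llr(c: ContingencyCounts) -> float:
    """Log-likelihood ratio 2 * sum O*ln(O/E), with 0*ln(0) = 0."""
    obs, exp = _cells(c)
    if any(e == 0 for e in exp):
        raise UndefinedScoreError("llr undefined: zero expected cell")
    total = 0.0
    for o, e in zip(obs, exp):
        if o > 0:
            total += o * math.log(o / e)
    return 2.0 * total


METRICS = {
    "count": count,
    "doc-count": doc_count,
    "jaccard": jaccard,
    "scp": scp,
    "npmi": npmi,
    "chi2": chi_squared,
    "ttest": t_test,
    "llr": llr,
}


def get_metric(name: str):
    """Look up a metric function by its (case-insensitive) CLI name."""
    key = name.strip().lower().replace("_", "-")
    if key == "chi-2":
        key = "chi2"
    try:
        return METRICS[key]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; choose from {sorted(METRICS)}"
        ) from None
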