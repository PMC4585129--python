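"""qPCR quantification of ANME subclades and group-comparison statistics.

Absolute quantification follows the usual chain: a standard curve
Cq = slope * log10(copies) + intercept is fitted on 10-fold plasmid
dilutions, a sample Cq is inverted to copies in the reaction, and copies
are normalized both per ng of template DNA and per gram wet sediment
(via the extract's total DNA and the extracted sample mass).  Growth over
the incubation is read as the fold change of copies between day 0 and
day 344; a ratio strictly above 1 is called growth.

Group comparisons use Welch's unequal-variance t-test on biological
triplicates, and pairwise outcomes at alpha = 0.05 are condensed into a
compact letter display (conditions share a letter iff they are not
significantly different).  No multiple-testing correction is applied to
the letters; Holm-adjusted p-values are available separately.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CLADES",
    "StandardPoint",
    "QpcrStandardCurve",
    "CladeQuant",
    "FoldChange",
    "ExtrapolationWarning",
    "DegenerateVarianceError",
    "fit_standard_curve",
    "quantify",
    "fold_change",
    "welch_t",
    "holm_adjust",
    "letter_groups",
]

CLADES = ("ANME1", "ANME2ab", "ANME2c")


class ExtrapolationWarning(UserWarning):
    """A sample Cq fell outside the calibrated standard-curve range."""


class DegenerateVarianceError(ValueError):
    """Welch's test is undefined: zero variance with unequal means."""


@dataclass(frozen=True)
class StandardPoint:
    """One standard-curve point: known copies per uL template and its Cq."""

    copies_per_ul: float
    cq: float

    def __post_init__(self) -> None:
        if self.copies_per_ul <= 0:
            raise ValueError("standard copies must be positive")


@dataclass(frozen=True)
class QpcrStandardCurve:
    """Fitted calibration Cq = slope*log10(copies) + intercept.

    ``efficiency`` is the per-cycle amplification gain minus one,
    10**(-1/slope) - 1 (1.0 means perfect doubling).  ``cq_range`` is the
    calibrated Cq interval used to flag extrapolation.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    cq_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has negative slope")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class CladeQuant:
    """Absolute abundance of one clade in one bottle at one time point."""

    clade: str
    bottle_id: str
    day: float
    copies_per_g_wet: float
    copies_per_ng_dna: float

    def __post_init__(self) -> None:
        if self.copies_per_g_wet < 0 or self.copies_per_ng_dna < 0:
            raise ValueError("abundances must be >= 0")


@dataclass(frozen=True)
class FoldChange:
    clade: str
    condition: str
    ratio: float
    growth: bool


def fit_standard_curve(points: Sequence[StandardPoint]) -> QpcrStandardCurve:
    """Least-squares calibration line of Cq on log10(copies per uL)."""
    if len({p.copies_per_ul for p in points}) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    x = np.log10([p.copies_per_ul for p in points])
    y = np.array([p.cq for p in points])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("degenerate standard curve: non-negative slope")
    return QpcrStandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / fit.slope) - 1.0),
        cq_range=(float(y.min()), float(y.max())),
    )


def quantify(
    cq: float,
    curve: QpcrStandardCurve,
    template_ng: float = 5.0,
    extract_ng_per_ul: float = 20.0,
    elution_ul: float = 50.0,
    sample_g_wet: float = 2.0,
    clade: str = "",
    bottle_id: str = "",
    day: float = np.nan,
) -> CladeQuant:
    """Back-calculate absolute abundances from a sample Cq.

    Copies in the reaction are 10**((cq - intercept)/slope) (the curve's
    x-axis, copies per uL of standard, equals copies per reaction under
    the 1 uL standard-loading convention).  Division by the template mass
    gives copies per ng DNA; multiplying by the extract's total DNA
    (extract_ng_per_ul * elution_ul) and dividing by the extracted wet
    mass gives copies per gram wet weight.

    A Cq outside the calibrated range raises an
    :class:`ExtrapolationWarning` (warning, not error).
    """
    if min(template_ng, extract_ng_per_ul, elution_ul, sample_g_wet) <= 0:
        raise ValueError("masses and volumes must be positive")
    lo, hi = curve.cq_range
    if not lo <= cq <= hi:
        warnings.warn(
            f"Cq {cq:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]; "
            "quantification is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    copies_rxn = 10.0 ** ((cq - curve.intercept) / curve.slope)
    copies_per_ng = copies_rxn / template_ng
    total_ng = extract_ng_per_ul * elution_ul
    copies_per_g = copies_per_ng * total_ng / sample_g_wet
    return CladeQuant(
        clade=clade,
        bottle_id=bottle_id,
        day=day,
        copies_per_g_wet=copies_per_g,
        copies_per_ng_dna=copies_per_ng,
    )


def fold_change(
    final: CladeQuant, initial: CladeQuant, condition: str = ""
) -> FoldChange:
    """Ratio of final to initial abundance; strictly > 1 is growth."""
    if final.clade != initial.clade:
        raise ValueError("fold change requires matching clades")
    if initial.copies_per_g_wet == 0:
        raise ValueError(
            f"fold change undefined: zero initial abundance for {initial.clade}"
        )
    ratio = final.copies_per_g_wet / initial.copies_per_g_wet
    return FoldChange(
        clade=final.clade, condition=condition, ratio=ratio, growth=ratio > 1.0
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).  When both groups
    have zero variance and equal means the conventional (0, n1+n2-2, 1)
    is returned; zero variance in both groups with unequal means is an
    error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise DegenerateVarianceError(
            "zero variance in both groups with unequal means"
        )
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def _cliques(adj: np.ndarray) -> list[tuple[int, ...]]:
    """All maximal cliques of a small undirected graph, sorted."""
    n = adj.shape[0]
    cliques = []
    for r in range(1, n + 1):
        for members in itertools.combinations(range(n), r):
            if all(adj[i, j] for i, j in itertools.combinations(members, 2)):
                cliques.append(members)
    maximal = [
        c
        for c in cliques
        if not any(set(c) < set(other) for other in cliques)
    ]
    return sorted(maximal)


def letter_groups(
    pairwise_p: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Compact letter display from a symmetric pairwise p-value matrix.

    Two conditions share a letter iff they are *not* significantly
    different (p > alpha).  Letters correspond to cliques of the
    not-significantly-different graph; a minimal clique cover of all
    vertices and edges is found exhaustively (condition counts are small)
    with a lexicographic tie-break, so the output is deterministic given
    the input order.  Returns one letter string per condition.
    """
    p = np.asarray(pairwise_p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("pairwise_p must be a square matrix")
    if not np.allclose(p, p.T, atol=1e-12):
        raise ValueError("pairwise_p must be symmetric")
    if not np.allclose(np.diag(p), 1.0):
        raise ValueError("pairwise_p must have unit diagonal")
    n = p.shape[0]
    adj = p > alpha
    np.fill_diagonal(adj, True)
    maximal = _cliques(adj)
    edges = {
        (i, j) for i, j in itertools.combinations(range(n), 2) if adj[i, j]
    }
    # smallest subfamily of maximal cliques covering every vertex and edge;
    # first hit in lexicographic order wins (deterministic)
    cover: Sequence[tuple[int, ...]] | None = None
    for k in range(1, len(maximal) + 1):
        for combo in itertools.combinations(maximal, k):
            covered_vertices = set().union(*combo)
            covered_edges = {
                (i, j)
                for c in combo
                for i, j in itertools.combinations(c, 2)
            }
            if covered_vertices == set(range(n)) and edges <= covered_edges:
                cover = combo
                break
        if cover is not None:
            break
    assert cover is not None  # singletons alone always cover in the worst case
    ordered = sorted(cover, key=lambda c: (min(c), c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(n)]
    for letter, clique in zip(alphabet, ordered):
        for idx in clique:
            letters[idx] += letter
    return letters
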