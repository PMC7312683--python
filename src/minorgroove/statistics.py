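"""Composition statistics and the one-sided Mann-Whitney width-testing scheme.

The testing design: amino acids are split into a hydrophobic group (Leu, Ala,
Ile, Val, Gly, Phe, Trp, Tyr, Met) and a non-hydrophobic group (Asp, His,
Glu, Gln, Asn, Thr, Ser, Lys, Cys, Pro); arginine is excluded outright
(its abundance and narrow-groove preference dominate the width
distributions).  Each hydrophobic amino acid's associated width distribution
is compared against the pooled non-hydrophobic widths; each non-hydrophobic
amino acid against the pooled widths of the *other* non-hydrophobic amino
acids.  The alternative hypothesis is that the first median is greater.

The U statistic uses midranks for ties.  The one-sided p-value is exact (full
enumeration over all labelings of the pooled sample) whenever the smaller
sample has at most :data:`EXACT_MIN_N` observations and the number of
labelings is at most :data:`EXACT_MAX_COMBINATIONS`; otherwise a normal
approximation with tie-corrected variance and a 0.5 continuity correction is
used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from ._tables import AMINO_ACIDS

__all__ = [
    "AminoAcidDistribution",
    "GroupDefinition",
    "WidthTestResult",
    "category_frequencies",
    "relative_entropy",
    "mann_whitney_one_sided",
    "run_width_tests",
    "percentile_thresholds",
    "boxplot_stats",
]

EXACT_MIN_N = 8
EXACT_MAX_COMBINATIONS = 200_000

HYDROPHOBIC: frozenset[str] = frozenset(
    {"LEU", "ALA", "ILE", "VAL", "GLY", "PHE", "TRP", "TYR", "MET"}
)
NON_HYDROPHOBIC: frozenset[str] = frozenset(
    {"ASP", "HIS", "GLU", "GLN", "ASN", "THR", "SER", "LYS", "CYS", "PRO"}
)
EXCLUDED: frozenset[str] = frozenset({"ARG"})


@dataclass
class GroupDefinition:
    hydrophobic: frozenset[str] = HYDROPHOBIC
    non_hydrophobic: frozenset[str] = NON_HYDROPHOBIC
    excluded: frozenset[str] = EXCLUDED

    def __post_init__(self) -> None:
        if self.hydrophobic & self.non_hydrophobic:
            raise ValueError("groups must be disjoint")
        if set(self.hydrophobic | self.non_hydrophobic | self.excluded) != set(AMINO_ACIDS):
            raise ValueError("groups plus exclusions must cover the 20 amino acids")


@dataclass
class AminoAcidDistribution:
    """Counts (and derived frequencies) over the 20 amino acids."""

    counts: dict[str, int]
    context: str = ""
    flagged_empty: bool = False

    @classmethod
    def from_types(cls, types: Iterable[str], context: str = "") -> "AminoAcidDistribution":
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for t in types:
            if t in counts:
                counts[t] += 1
        dist = cls(counts=counts, context=context)
        dist.flagged_empty = dist.total == 0
        return dist

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> np.ndarray:
        arr = np.array([self.counts[aa] for aa in AMINO_ACIDS], dtype=float)
        total = arr.sum()
        return arr / total if total > 0 else arr

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[aa] for aa in AMINO_ACIDS], dtype=float)


def category_frequencies(table) -> dict[str, AminoAcidDistribution]:
    """Amino-acid distributions of the narrow / standard / wide categories."""
    out: dict[str, AminoAcidDistribution] = {}
    for category in ("narrow", "standard", "wide"):
        types = [r.residue_type for r in table if r.width_category == category]
        out[category] = AminoAcidDistribution.from_types(types, context=category)
    return out


def relative_entropy(p, q, pseudocount: float = 0.0) -> float:
    """Kullback-Leibler divergence D(p || q) in bits.

    ``p`` and ``q`` may be :class:`AminoAcidDistribution` objects or count /
    frequency arrays on a common support.  ``pseudocount`` is added to every
    entry of the *reference* distribution ``q`` before renormalization, so a
    positive pseudocount keeps the divergence finite in the presence of
    zero reference counts without distorting ``p``.
    """
    p_arr = p.as_array() if isinstance(p, AminoAcidDistribution) else np.asarray(p, float)
    q_arr = q.as_array() if isinstance(q, AminoAcidDistribution) else np.asarray(q, float)
    if p_arr.shape != q_arr.shape:
        raise ValueError("distributions must share a support")
    if p_arr.sum() <= 0 or (q_arr.sum() + pseudocount * q_arr.size) <= 0:
        raise ValueError("empty distribution")
    p_arr = p_arr / p_arr.sum()
    q_arr = q_arr + pseudocount
    q_arr = q_arr / q_arr.sum()
    mask = p_arr > 0
    if np.any(q_arr[mask] <= 0):
        raise ValueError("q has zero mass where p is positive; use a pseudocount")
    return float(np.sum(p_arr[mask] * np.log2(p_arr[mask] / q_arr[mask])))


@dataclass
class WidthTestResult:
    amino_acid: str
    comparison: str
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # exact-permutation | normal-approximation
    significant: Optional[bool] = None
    degenerate: bool = False
    skipped_reason: str = ""


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    u = r1 - len(x) * (len(x) + 1) / 2.0
    return float(u), ranks


def mann_whitney_one_sided(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> WidthTestResult:
    """One-sided Mann-Whitney U test of median(x) > median(y).

    ``method`` is ``auto`` (see module docstring), ``exact`` or ``normal``.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u_obs, ranks = _u_statistic(x, y)
    n = n1 + n2

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return WidthTestResult(
            "", "", u_obs, 1.0, n1, n2, method="degenerate", degenerate=True
        )

    if method == "auto":
        n_comb = math.comb(n, min(n1, n2))
        exact = min(n1, n2) <= EXACT_MIN_N and n_comb <= EXACT_MAX_COMBINATIONS
    elif method == "exact":
        exact = True
    elif method == "normal":
        exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if exact:
        # enumerate all assignments of n1 pooled ranks to x
        offset = n1 * (n1 + 1) / 2.0
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if u >= u_obs - 1e-9:
                count += 1
        p = count / total
        used = "exact-permutation"
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return WidthTestResult("", "", u_obs, 1.0, n1, n2, "degenerate", degenerate=True)
        z = (u_obs - mu - 0.5) / math.sqrt(var)
        p = float(norm.sf(z))
        used = "normal-approximation"
    return WidthTestResult("", "", u_obs, float(p), n1, n2, used)


def run_width_tests(
    table,
    groups: Optional[GroupDefinition] = None,
    alpha: float = 0.05,
    method: str = "auto",
) -> list[WidthTestResult]:
    """The per-amino-acid width-shift tests (19 tests; arginine excluded)."""
    groups = groups or GroupDefinition()
    widths_by_aa: dict[str, list[float]] = {}
    for rec in table:
        if rec.minor_groove_width is None:
            continue
        widths_by_aa.setdefault(rec.residue_type, []).append(float(rec.minor_groove_width))

    non_hyd_pool: dict[str, list[float]] = {
        aa: widths_by_aa.get(aa, []) for aa in groups.non_hydrophobic
    }
    results: list[WidthTestResult] = []
    for aa in sorted(set(AMINO_ACIDS) - set(groups.excluded)):
        x = widths_by_aa.get(aa, [])
        if aa in groups.hydrophobic:
            y = [w for other, ws in non_hyd_pool.items() for w in ws]
            comparison = "pooled non-hydrophobic"
        else:
            y = [w for other, ws in non_hyd_pool.items() if other != aa for w in ws]
            comparison = "other non-hydrophobic"
        if not x or not y:
            results.append(
                WidthTestResult(
                    aa, comparison, math.nan, math.nan, len(x), len(y),
                    method="skipped", skipped_reason="no records",
                )
            )
            continue
        res = mann_whitney_one_sided(x, y, method=method)
        res.amino_acid = aa
        res.comparison = comparison
        res.significant = (not res.degenerate) and res.p_value < alpha
        results.append(res)
    return results


def percentile_thresholds(
    table, percentiles: tuple[float, float] = (15.0, 85.0)
) -> tuple[float, float]:
    """Linear-interpolation percentiles of the table's width multiset."""
    widths = [r.minor_groove_width for r in table if r.minor_groove_width is not None]
    if not widths:
        raise ValueError("no widths in table")
    lo, hi = np.percentile(np.asarray(widths, float), list(percentiles), method="linear")
    return float(lo), float(hi)


def boxplot_stats(values: Sequence[float]) -> dict:
    """Five-number summary with 1.5·IQR whiskers (Fig-style boxplot data)."""
    arr = np.sort(np.asarray(list(values), float))
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(arr.size - inside.size),
        "n": int(arr.size),
    }
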