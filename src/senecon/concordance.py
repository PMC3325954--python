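"""Directional overlap of two signatures and 2x2 contingency concordance.

Given two directional signatures over a shared probe universe, the overlap
(probes significant in both) is partitioned into four quadrants by the pair
of directions.  Concordance is tested with a Pearson chi-squared on the 2x2
quadrant table (df = 1, no continuity correction), with expected counts from
the row/column marginals; a marginal-conditioned permutation test provides an
exact-style companion p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expr_de import SignificantSet

__all__ = [
    "DirectionalOverlap",
    "ConcordanceResult",
    "directional_overlap",
    "concordance_chisq",
    "permutation_null",
    "triple_overlap_venn",
]


@dataclass(frozen=True)
class DirectionalOverlap:
    """Quadrant counts of co-significant probes (direction in A x direction in B).

    ``o_uu`` counts probes up in both, ``o_ud`` up in A / down in B, etc.
    ``a_only_up``/``a_only_down`` count probes significant only in A, split by
    their direction in A (similarly for B).
    """

    o_uu: int
    o_ud: int
    o_du: int
    o_dd: int
    a_only_up: int = 0
    a_only_down: int = 0
    b_only_up: int = 0
    b_only_down: int = 0

    def __post_init__(self) -> None:
        for name in ("o_uu", "o_ud", "o_du", "o_dd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.o_uu + self.o_ud + self.o_du + self.o_dd

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.o_uu, self.o_ud], [self.o_du, self.o_dd]], dtype=float)

    @property
    def quadrants(self) -> tuple[int, int, int, int]:
        return (self.o_uu, self.o_ud, self.o_du, self.o_dd)


@dataclass(frozen=True)
class ConcordanceResult:
    overlap: DirectionalOverlap
    expected: np.ndarray
    chi2: float
    df: int
    p_asymptotic: float
    degenerate: bool = False
    low_expected: bool = False
    p_permutation: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "quadrants": list(self.overlap.quadrants),
            "n": self.overlap.n,
            "expected": np.asarray(self.expected).tolist(),
            "chi2": self.chi2,
            "df": self.df,
            "p_asymptotic": self.p_asymptotic,
            "degenerate": self.degenerate,
            "low_expected": self.low_expected,
        }
        if self.p_permutation is not None:
            out.update(
                {"p_permutation": self.p_permutation, "n_perm": self.n_perm, "seed": self.seed}
            )
        return out


def directional_overlap(a: SignificantSet, b: SignificantSet) -> DirectionalOverlap:
    """Partition ``A ∩ B`` by the (sign in A, sign in B) pair."""
    if a.universe and b.universe and a.universe != b.universe:
        raise ValueError("signatures have mismatched probe universes")
    shared = set(a.members) & set(b.members)
    o_uu = o_ud = o_du = o_dd = 0
    for probe in shared:
        da, db = a.members[probe], b.members[probe]
        if da == 1 and db == 1:
            o_uu += 1
        elif da == 1:
            o_ud += 1
        elif db == 1:
            o_du += 1
        else:
            o_dd += 1
    a_only = set(a.members) - shared
    b_only = set(b.members) - shared
    return DirectionalOverlap(
        o_uu=o_uu,
        o_ud=o_ud,
        o_du=o_du,
        o_dd=o_dd,
        a_only_up=sum(1 for p in a_only if a.members[p] == 1),
        a_only_down=sum(1 for p in a_only if a.members[p] == -1),
        b_only_up=sum(1 for p in b_only if b.members[p] == 1),
        b_only_down=sum(1 for p in b_only if b.members[p] == -1),
    )


def _chi2_stat(table: np.ndarray) -> tuple[np.ndarray, float]:
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return expected, float(terms.sum())


def concordance_chisq(ov: DirectionalOverlap, *, yates: bool = False) -> ConcordanceResult:
    """Pearson chi-squared (df = 1) on the quadrant table.

    ``yates=True`` applies the continuity correction (off by default).  A zero
    row or column marginal makes the statistic undefined; the result is then
    flagged ``degenerate`` with ``chi2 = nan``.  Any expected count below 5
    sets ``low_expected`` as a hint to prefer :func:`permutation_null`.
    """
    if ov.n == 0:
        raise ValueError("empty overlap: N = 0")
    table = ov.table
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        expected = np.full((2, 2), np.nan)
        return ConcordanceResult(
            overlap=ov, expected=expected, chi2=float("nan"), df=1,
            p_asymptotic=float("nan"), degenerate=True,
        )
    expected, chi2 = _chi2_stat(table)
    if yates:
        with np.errstate(divide="ignore", invalid="ignore"):
            adj = (np.abs(table - expected) - 0.5).clip(min=0.0)
            chi2 = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    if chi2 == 0.0:
        p = 1.0
    return ConcordanceResult(
        overlap=ov,
        expected=expected,
        chi2=chi2,
        df=1,
        p_asymptotic=p,
        low_expected=bool((expected < 5).any()),
    )


def permutation_null(ov: DirectionalOverlap, n_perm: int = 10000, seed: int = 0) -> float:
    """Empirical p-value by permuting B directions among overlap members.

    The permutation fixes both direction marginals, so the permuted ``o_uu``
    follows a hypergeometric law, which is sampled directly.  Returns
    ``(1 + #{chi2_perm >= chi2_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    table = ov.table
    n = int(table.sum())
    row = table.sum(axis=1).astype(int)  # A-direction counts
    col = table.sum(axis=0).astype(int)  # B-direction counts
    if n == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate marginals: permutation null undefined")
    _, chi2_obs = _chi2_stat(table)

    rng = np.random.default_rng(seed)
    uu = rng.hypergeometric(col[0], col[1], row[0], size=n_perm).astype(float)
    perm = np.empty((n_perm, 2, 2))
    perm[:, 0, 0] = uu
    perm[:, 0, 1] = row[0] - uu
    perm[:, 1, 0] = col[0] - uu
    perm[:, 1, 1] = n - row[0] - col[0] + uu
    expected = np.outer(row, col) / n
    chi2_perm = ((perm - expected) ** 2 / expected).sum(axis=(1, 2))
    hits = int((chi2_perm >= chi2_obs - 1e-12).sum())
    return (1 + hits) / (1 + n_perm)


def triple_overlap_venn(sets: Sequence[SignificantSet]) -> pd.Series:
    """Counts of the seven Venn regions of three signatures, plus set totals.

    Region keys use 'a', 'b', 'c' for the three sets in order, e.g. 'ab' is
    the region in A and B but not C.
    """
    if len(sets) != 3:
        raise ValueError("exactly three signatures required")
    a, b, c = sets
    for s in (b, c):
        if a.universe and s.universe and s.universe != a.universe:
            raise ValueError("signatures have mismatched probe universes")
    sa, sb, sc = set(a.members), set(b.members), set(c.members)
    regions = {
        "a": len(sa - sb - sc),
        "b": len(sb - sa - sc),
        "c": len(sc - sa - sb),
        "ab": len((sa & sb) - sc),
        "ac": len((sa & sc) - sb),
        "bc": len((sb & sc) - sa),
        "abc": len(sa & sb & sc),
        "total_a": len(sa),
        "total_b": len(sb),
        "total_c": len(sc),
        "union": len(sa | sb | sc),
    }
    return pd.Series(regions, dtype=int)
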