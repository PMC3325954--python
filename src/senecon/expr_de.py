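"""Differential expression on normalized log2 matrices and cutoff signatures.

The statistics here are deliberately plain: a per-probe two-sample t-test on
log2 values (equal-variance by default, Welch behind a flag) and hard
fold-change / p-value cutoffs.  No multiple-testing correction is applied:
signatures are defined by raw per-probe p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "SignificantSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "pairwise_de",
    "select_significant",
    "union_significant",
    "collapse_to_genes",
]

#: default fold-change cutoff (log2 units) and p-value cutoffs
DEFAULT_LFC_CUT = 0.5
DEFAULT_P_CUT = 1e-4
ALTERNATE_P_CUT = 1e-3


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated log2 expression matrix plus its sample-to-condition design.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, probe IDs as the index, sample IDs as
        columns.
    design
        DataFrame with columns ``sample_id``, ``condition`` and (optionally)
        ``replicate``; one row per sample.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate probe IDs: {dups[:5]}")
        if "sample_id" not in self.design.columns or "condition" not in self.design.columns:
            raise ValueError("design table must have 'sample_id' and 'condition' columns")
        design_samples = set(self.design["sample_id"])
        matrix_samples = set(self.values.columns)
        missing = sorted(matrix_samples - design_samples)
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        extra = sorted(design_samples - matrix_samples)
        if extra:
            raise ValueError(f"design samples missing from matrix: {extra}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if np.asarray(self.values.isna()).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.loc[self.design["condition"] == condition, "sample_id"]
        if sel.empty:
            raise KeyError(f"unknown condition: {condition!r}")
        return list(sel)


@dataclass(frozen=True)
class DEResult:
    """Per-probe differential expression for one ordered contrast.

    ``lfc`` is ``mean(first) - mean(second)`` in log2 units.  ``degenerate``
    marks probes with zero pooled variance but unequal means, whose p-value is
    reported as the smallest positive float.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame  # index probe_id; columns lfc, p, degenerate

    @property
    def lfc(self) -> pd.Series:
        return self.table["lfc"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]


@dataclass(frozen=True)
class SignificantSet:
    """A directional signature: probes passing cutoffs, with sign of change."""

    contrast: tuple[str, str]
    lfc_cut: float
    p_cut: float
    members: Mapping[str, int]  # probe_id -> +1 / -1
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = [d for d in self.members.values() if d not in (-1, 1)]
        if bad:
            raise ValueError("directions must be +1 or -1")
        if self.universe and not set(self.members) <= self.universe:
            raise ValueError("members not contained in probe universe")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def up(self) -> set[str]:
        return {p for p, d in self.members.items() if d == 1}

    @property
    def down(self) -> set[str]:
        return {p for p, d in self.members.items() if d == -1}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": list(self.members), "direction": list(self.members.values())}
        )


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = probe ID) and a CSV design."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in expression matrix: {exc}") from exc
    design = pd.read_csv(design_path)
    return ExpressionMatrix(values=values, design=design)


def write_expression_matrix(em: ExpressionMatrix, matrix_path: str | Path, design_path: str | Path) -> None:
    em.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    em.design.to_csv(design_path, index=False)


# ---------------------------------------------------------------------------
# statistics


def pairwise_de(
    matrix: ExpressionMatrix,
    first: str,
    second: str,
    *,
    equal_var: bool = True,
) -> DEResult:
    """Per-probe t-test between two conditions.

    lfc follows the orientation contract ``mean(first) - mean(second)`` so a
    contrast named ``null - P3`` is called as ``pairwise_de(m, "null", "P3")``.
    """
    a = np.asarray(matrix.values[matrix.samples_for(first)], dtype=float)
    b = np.asarray(matrix.values[matrix.samples_for(second)], dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >=2 replicates per condition (got {a.shape[1]} for {first!r}, "
            f"{b.shape[1]} for {second!r})"
        )
    lfc = a.mean(axis=1) - b.mean(axis=1)
    # zero/near-zero variance probes are handled explicitly below, so the
    # precision-loss warning scipy raises for them is suppressed
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)

    # zero pooled variance: equal means -> p = 1; unequal -> smallest positive
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    zero_var = (va == 0) & (vb == 0)
    degenerate = zero_var & (lfc != 0)
    p = np.where(zero_var & (lfc == 0), 1.0, p)
    p = np.where(degenerate, np.finfo(float).tiny, p)
    p = np.where(np.isnan(p), 1.0, p)

    table = pd.DataFrame(
        {"lfc": lfc, "p": p, "degenerate": degenerate}, index=matrix.probe_ids
    )
    return DEResult(contrast=(first, second), table=table)


def select_significant(
    de: DEResult,
    lfc_cut: float = DEFAULT_LFC_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> SignificantSet:
    """Apply cutoffs: ``|lfc| >= lfc_cut`` (inclusive) and ``p < p_cut`` (strict)."""
    if lfc_cut <= 0 or p_cut <= 0:
        raise ValueError("cutoffs must be positive")
    mask = (de.table["lfc"].abs() >= lfc_cut) & (de.table["p"] < p_cut)
    sel = de.table.loc[mask, "lfc"]
    members = {probe: (1 if v > 0 else -1) for probe, v in sel.items()}
    return SignificantSet(
        contrast=de.contrast,
        lfc_cut=lfc_cut,
        p_cut=p_cut,
        members=members,
        universe=frozenset(de.table.index),
    )


def union_significant(sets: Iterable[SignificantSet]) -> pd.DataFrame:
    """Union of signatures with per-contrast directions.

    Returns a DataFrame indexed by probe ID with one column per contrast
    (named ``first-second``), entries +1/-1 for selected probes and 0
    otherwise.  All sets must share a probe universe.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no signatures given")
    universe = sets[0].universe
    for s in sets[1:]:
        if s.universe != universe:
            raise ValueError("signatures have mismatched probe universes")
    cols: dict[str, pd.Series] = {}
    union_probes: set[str] = set()
    for s in sets:
        union_probes |= set(s.members)
    index = sorted(union_probes)
    for s in sets:
        name = f"{s.contrast[0]}-{s.contrast[1]}"
        cols[name] = pd.Series({p: s.members.get(p, 0) for p in index}, dtype=int)
    return pd.DataFrame(cols, index=pd.Index(index, name="probe_id"))


def collapse_to_genes(de: DEResult, annotation: pd.DataFrame) -> DEResult:
    """Collapse probes to genes using a probe->gene table.

    Keeps the probe with the largest ``|lfc|`` per gene; probes without an
    annotation row are dropped.  ``annotation`` needs columns ``probe_id`` and
    ``gene``.
    """
    if not {"probe_id", "gene"} <= set(annotation.columns):
        raise ValueError("annotation needs 'probe_id' and 'gene' columns")
    ann = annotation.dropna(subset=["gene"]).set_index("probe_id")["gene"]
    tab = de.table.join(ann, how="inner")
    tab = tab.loc[tab["lfc"].abs().sort_values(ascending=False).index]
    tab = tab[~tab["gene"].duplicated()].drop(columns="gene")
    return DEResult(contrast=de.contrast, table=tab.sort_index())
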