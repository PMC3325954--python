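"""Small deterministic quantifications: serial-passage growth, delta-Ct
relative expression with two reference genes, and replicate proportion tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cumulative_growth",
    "relative_expression_delta_ct",
    "proportion_summary",
]


def cumulative_growth(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Relative cumulative cell number per passage under a fixed-replating protocol.

    ``records`` needs columns ``passage``, ``plated``, ``counted`` (and
    optionally a group column).  Per passage, ``fold = counted / plated``; the
    cumulative value at passage p is the running product of folds, with the
    starting plating defined as 1.  Passages must be contiguous within each
    group.
    """
    required = {"passage", "plated", "counted"}
    if not required <= set(records.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")
    groups = records.groupby(group_col) if group_col in records.columns else [(None, records)]
    out = []
    for group, sub in groups:
        sub = sub.sort_values("passage")
        passages = np.asarray(sub["passage"], int)
        if len(passages) == 0:
            raise ValueError("empty growth series")
        if not np.array_equal(passages, np.arange(passages[0], passages[0] + len(passages))):
            raise ValueError(f"passages not contiguous: {passages.tolist()}")
        plated = np.asarray(sub["plated"], float)
        counted = np.asarray(sub["counted"], float)
        if (plated <= 0).any():
            raise ValueError("plated counts must be positive")
        if (counted < 0).any():
            raise ValueError("counted must be >= 0")
        fold = counted / plated
        cumulative = np.cumprod(fold)
        res = sub.copy()
        res["fold"] = fold
        res["cumulative"] = cumulative
        if group is not None:
            res[group_col] = group
        out.append(res)
    return pd.concat(out, ignore_index=True)


def relative_expression_delta_ct(
    records: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Delta-Ct relative expression with multiple reference genes.

    Per sample, ``dCt = Ct_target - mean(Ct of reference genes)`` (arithmetic
    mean of reference Cts = geometric mean on the linear scale) and
    ``expression = 2 ** (-dCt)``; expression is then rescaled per gene so the
    control-group mean equals 1.  Returns per-gene per-group mean, sd and n
    over samples.
    """
    required = {"sample", "group", "gene", "ct", "is_reference"}
    if not required <= set(records.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    if control_group not in set(records["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    refs = records[records["is_reference"].astype(bool)]
    ref_genes = set(refs["gene"])
    if not ref_genes:
        raise ValueError("no reference genes present")
    ref_mean = refs.groupby("sample")["ct"].agg(["mean", "count"])
    n_refs = len(ref_genes)
    incomplete = ref_mean.index[ref_mean["count"] != n_refs]
    targets = records[~records["is_reference"].astype(bool)].copy()
    missing = set(targets["sample"]) - set(ref_mean.index)
    if missing or len(incomplete):
        raise ValueError(
            f"samples missing reference Cts: {sorted(missing | set(incomplete))}"
        )
    targets["dct"] = targets["ct"] - targets["sample"].map(ref_mean["mean"])
    targets["expression"] = 2.0 ** (-targets["dct"])
    # scale so the control-group mean is 1 per gene
    ctrl = (
        targets[targets["group"] == control_group]
        .groupby("gene")["expression"]
        .mean()
    )
    zero = ctrl.index[ctrl <= 0]
    if len(zero):
        raise ValueError(f"control-group expression non-positive for genes {list(zero)}")
    targets["relative"] = targets["expression"] / targets["gene"].map(ctrl)
    if targets["relative"].isna().any():
        bad = sorted(targets.loc[targets["relative"].isna(), "gene"].unique())
        raise ValueError(f"genes missing from control group: {bad}")
    out = (
        targets.groupby(["gene", "group"])["relative"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    return out


def proportion_summary(records: pd.DataFrame) -> dict:
    """Replicate-culture percent-positive summary and two-group t-test.

    ``records`` needs columns ``group``, ``replicate``, ``positive``,
    ``total``.  Percentages are computed per replicate culture; each group is
    summarized as mean +/- sd, and when exactly two groups are present a
    two-sided two-sample t-test on the replicate percentages is included.
    """
    required = {"group", "replicate", "positive", "total"}
    if not required <= set(records.columns):
        raise ValueError(f"proportions table needs columns {sorted(required)}")
    if (np.asarray(records["total"], float) <= 0).any():
        raise ValueError("replicate totals must be positive")
    rec = records.copy()
    rec["percent"] = 100.0 * rec["positive"] / rec["total"]
    per_group = (
        rec.groupby("group")["percent"].agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    )
    result: dict = {"per_group": per_group, "per_replicate": rec}
    groups = list(per_group.index)
    if len(groups) == 2:
        xa = rec.loc[rec["group"] == groups[0], "percent"]
        xb = rec.loc[rec["group"] == groups[1], "percent"]
        if len(xa) >= 2 and len(xb) >= 2:
            if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
                p = 1.0 if xa.mean() == xb.mean() else float(np.finfo(float).tiny)
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
            result["ttest"] = {"groups": groups, "p": p}
    return result
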