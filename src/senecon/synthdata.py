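"""Seeded generators producing every input format the pipeline consumes.

Each generator takes a frozen "truth" parameter object and a single seed, and
fans the seed out to independent sub-streams per data facet so that, e.g.,
the class assignment of nuclei does not shift when only the foci model
changes.  Identical truth + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytoprofile import CLASSES, FOCI_BINS
from .damage_kinetics import recovery_model
from .expr_de import ExpressionMatrix

__all__ = [
    "ExpressionTruth",
    "PloidyTruth",
    "CometTruth",
    "simulate_expression",
    "simulate_nuclei",
    "simulate_comet_timecourse",
    "simulate_growth_series",
    "simulate_qpcr",
]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionTruth:
    """Design of a planted two-contrast differential-expression experiment.

    The first condition is the shared baseline; the second and third define
    the two contrasts (each condition vs baseline).  ``shared_fraction`` is
    the proportion of each contrast's DE probes planted in both contrasts;
    ``concordance`` is the probability a shared probe changes in the same
    direction in both.
    """

    n_probes: int = 10000
    conditions: tuple[str, str, str] = ("base", "c1", "c2")
    replicates: int = 3
    de_fraction_per_contrast: float = 0.05
    shared_fraction: float = 0.5
    concordance: float = 0.5
    effect_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.replicates < 2:
            raise ValueError("need n_probes > 0 and replicates >= 2")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0 <= self.concordance <= 1:
            raise ValueError("concordance must lie in [0, 1]")
        if not 0 <= self.de_fraction_per_contrast <= 1:
            raise ValueError("de_fraction_per_contrast must lie in [0, 1]")
        if self.effect_range[0] > self.effect_range[1] or self.effect_range[0] < 0:
            raise ValueError("invalid effect_range")
        if len(self.conditions) != 3:
            raise ValueError("exactly three conditions: baseline plus two perturbed")
        n_de = round(self.de_fraction_per_contrast * self.n_probes)
        n_shared = round(self.shared_fraction * n_de)
        if 2 * n_de - n_shared > self.n_probes:
            raise ValueError("DE design exceeds the probe universe")


def simulate_expression(truth: ExpressionTruth) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a log2 expression matrix with a planted two-contrast signature.

    Returns the matrix (with design table) and a per-probe truth frame with
    columns ``dir_c1`` and ``dir_c2`` in {-1, 0, +1} (0 = not planted).
    """
    rng_assign, rng_effect, rng_base, rng_noise = _streams(truth.seed, 4)
    n = truth.n_probes
    n_de = round(truth.de_fraction_per_contrast * n)
    n_shared = round(truth.shared_fraction * n_de)
    n_only = n_de - n_shared

    order = rng_assign.permutation(n)
    shared = order[:n_shared]
    only1 = order[n_shared : n_shared + n_only]
    only2 = order[n_shared + n_only : n_shared + 2 * n_only]

    dir1 = np.zeros(n, dtype=int)
    dir2 = np.zeros(n, dtype=int)
    dir1[shared] = rng_assign.choice([-1, 1], size=n_shared)
    same = rng_assign.random(n_shared) < truth.concordance
    dir2[shared] = np.where(same, dir1[shared], -dir1[shared])
    dir1[only1] = rng_assign.choice([-1, 1], size=n_only)
    dir2[only2] = rng_assign.choice([-1, 1], size=n_only)

    lo, hi = truth.effect_range
    eff1 = dir1 * rng_effect.uniform(lo, hi, size=n)
    eff2 = dir2 * rng_effect.uniform(lo, hi, size=n)

    base = rng_base.normal(truth.baseline_mean, truth.baseline_sd, size=n)
    cond_effect = {
        truth.conditions[0]: np.zeros(n),
        truth.conditions[1]: eff1,
        truth.conditions[2]: eff2,
    }

    probe_ids = [f"probe_{i:06d}" for i in range(n)]
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for cond in truth.conditions:
        for r in range(1, truth.replicates + 1):
            sid = f"{cond}_r{r}"
            columns[sid] = base + cond_effect[cond] + rng_noise.normal(0, truth.noise_sd, size=n)
            design_rows.append({"sample_id": sid, "condition": cond, "replicate": r})

    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    design = pd.DataFrame(design_rows)
    labels = pd.DataFrame(
        {"dir_c1": dir1, "dir_c2": dir2}, index=pd.Index(probe_ids, name="probe_id")
    )
    return ExpressionMatrix(values=values, design=design), labels


# ---------------------------------------------------------------------------
# nuclei


@dataclass(frozen=True)
class PloidyTruth:
    """Planted ploidy-mixture parameters for per-nucleus simulation.

    ``fractions`` maps class names (see ``cytoprofile.CLASSES``) to mixture
    proportions summing to 1.  The 4N mode is implied at twice the 2N mode and
    the 8N upper limit at four times it.  Bracket sub-ranges follow the same
    geometry the classifier uses: the >4N region spans
    ``((1 + band_tol) * mu_4N, mu_8N]`` and is halved at its midpoint, so
    planted bracket classes are recoverable landmarks rather than arbitrary
    spans.
    """

    fractions: Mapping[str, float]
    mu_2n: float = 100.0
    intensity_cv: float = 0.08
    edu_positive_rates: Mapping[str, float] = field(default_factory=dict)
    binucleate_rate: float = 0.0
    foci_model: Mapping[str, Sequence[float]] | None = None
    n_cells: int = 5000
    band_tol: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown ploidy classes: {sorted(unknown)}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be >= 0")
        if self.mu_2n <= 0 or self.intensity_cv < 0 or self.n_cells <= 0:
            raise ValueError("mu_2n and n_cells must be positive, cv >= 0")
        if self.foci_model is not None:
            for group, probs in self.foci_model.items():
                if len(probs) != len(FOCI_BINS):
                    raise ValueError(f"foci model for {group!r} needs 4 bin probabilities")
                if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                    raise ValueError(f"foci bin probabilities for {group!r} must sum to 1")

    @property
    def mu_4n(self) -> float:
        return 2.0 * self.mu_2n

    @property
    def mu_8n(self) -> float:
        return 4.0 * self.mu_2n

    @property
    def gt4n_start(self) -> float:
        return (1 + self.band_tol) * self.mu_4n

    @property
    def bracket_split(self) -> float:
        return 0.5 * (self.gt4n_start + self.mu_8n)

    @property
    def groups(self) -> tuple[str, ...]:
        if self.foci_model is not None:
            return tuple(self.foci_model)
        return ("wt",)


_FOCI_DRAW_RANGES = {"0": (0, 0), "1-5": (1, 5), "6-10": (6, 10), ">10": (11, 20)}


def simulate_nuclei(truth: PloidyTruth) -> pd.DataFrame:
    """Draw ``n_cells`` nucleus records per group from the planted mixture.

    Output columns: cell_id, group, true_class, dna_intensity, area,
    edu_positive, binucleate, and foci_count when a foci model is given.
    """
    rng_class, rng_int, rng_edu, rng_foci, rng_misc = _streams(truth.seed, 5)
    probs = np.array([truth.fractions.get(c, 0.0) for c in CLASSES])
    cv = truth.intensity_cv
    frames = []
    for group in truth.groups:
        klass = rng_class.choice(len(CLASSES), size=truth.n_cells, p=probs)
        labels = np.array(CLASSES)[klass]
        intensity = np.empty(truth.n_cells)
        modes = {"sub2n": 0.5 * truth.mu_2n, "2n": truth.mu_2n, "4n": truth.mu_4n}
        for name, mu in modes.items():
            m = labels == name
            intensity[m] = rng_int.normal(mu, cv * mu, size=m.sum())
        spans = {
            "s": (truth.mu_2n, truth.mu_4n),
            "bracket1": (truth.gt4n_start, truth.bracket_split),
            "bracket2": (truth.bracket_split, truth.mu_8n),
        }
        for name, (lo, hi) in spans.items():
            m = labels == name
            intensity[m] = rng_int.uniform(lo, hi, size=m.sum())
        intensity = np.clip(intensity, 1e-6, None)

        edu = np.zeros(truth.n_cells, dtype=bool)
        for name in CLASSES:
            rate = truth.edu_positive_rates.get(name, 0.0)
            m = labels == name
            edu[m] = rng_edu.random(m.sum()) < rate

        frame = pd.DataFrame(
            {
                "cell_id": [f"{group}_{i:05d}" for i in range(truth.n_cells)],
                "group": group,
                "true_class": labels,
                "dna_intensity": intensity,
                "area": intensity * rng_misc.lognormal(0.0, 0.1, size=truth.n_cells),
                "edu_positive": edu,
                "binucleate": rng_misc.random(truth.n_cells) < truth.binucleate_rate,
            }
        )
        if truth.foci_model is not None:
            bin_idx = rng_foci.choice(
                len(FOCI_BINS), size=truth.n_cells, p=np.asarray(truth.foci_model[group], float)
            )
            los = np.array([_FOCI_DRAW_RANGES[b][0] for b in FOCI_BINS])
            his = np.array([_FOCI_DRAW_RANGES[b][1] for b in FOCI_BINS])
            frame["foci_count"] = rng_foci.integers(los[bin_idx], his[bin_idx] + 1)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# comet


@dataclass(frozen=True)
class CometTruth:
    """Exponential-recovery ground truth for a damage-pulse time-course."""

    d0: float = 60.0
    d_inf: float = 10.0
    k: float = 0.05
    baseline: float = 5.0
    cell_noise: float = 15.0
    timepoints: tuple[float, ...] = (0.0, 20.0, 40.0, 80.0, 160.0)
    n_cells: int = 200
    group: str = "wt"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.d_inf <= self.d0 <= 100:
            raise ValueError("need 0 <= d_inf <= d0 <= 100")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 0 <= self.baseline <= 100:
            raise ValueError("baseline must lie in [0, 100]")
        if self.cell_noise < 0 or self.n_cells <= 0:
            raise ValueError("cell_noise >= 0 and n_cells > 0 required")


def simulate_comet_timecourse(truth: CometTruth) -> pd.DataFrame:
    """Per-cell percent tail DNA along the recovery time-course.

    Per-cell dispersion is symmetric-beta-scaled around the model mean (a
    Beta(2,2) draw rescaled to +/- ``cell_noise``), chosen because tail
    percent is bounded; values are additionally clipped to [0, 100].
    Includes an untreated reference sample at time 0.
    """
    (rng,) = _streams(truth.seed, 1)
    rows = []

    def cells(mean: float, treatment: str, t: float) -> None:
        noise = (rng.beta(2.0, 2.0, size=truth.n_cells) - 0.5) * 2.0 * truth.cell_noise
        vals = np.clip(mean + noise, 0.0, 100.0)
        for i, v in enumerate(vals):
            rows.append(
                {
                    "cell_id": f"{truth.group}_{treatment}_{t:g}_{i:04d}",
                    "group": truth.group,
                    "treatment": treatment,
                    "time_min": t,
                    "tail_percent": v,
                }
            )

    cells(truth.baseline, "untreated", 0.0)
    for t in truth.timepoints:
        mean = float(recovery_model(np.array([t]), truth.d0, truth.d_inf, truth.k)[0])
        cells(mean, "H2O2", float(t))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth and qPCR


def simulate_growth_series(
    per_passage_folds: Sequence[float],
    plated: int = 300_000,
    group: str = "wt",
    start_passage: int = 2,
) -> pd.DataFrame:
    """Growth table where each passage counts exactly ``plated * fold`` cells."""
    folds = np.asarray(per_passage_folds, float)
    if (folds <= 0).any():
        raise ValueError("per-passage folds must be positive")
    if plated <= 0:
        raise ValueError("plated must be positive")
    return pd.DataFrame(
        {
            "group": group,
            "passage": np.arange(start_passage, start_passage + len(folds)),
            "plated": plated,
            "counted": plated * folds,
        }
    )


def simulate_qpcr(
    true_relative_expression: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    reference_genes: tuple[str, ...] = ("ref_a", "ref_b"),
    ct_offset: float = 20.0,
) -> pd.DataFrame:
    """Ct table for target genes at planted relative expression levels.

    ``true_relative_expression`` maps gene -> group -> positive expression.
    Target Ct = offset - log2(expression) + noise; both reference genes share
    the offset (expression 1) within each sample, so the two-reference
    delta-Ct readout recovers the planted ratios exactly at zero noise.
    """
    (rng,) = _streams(seed, 1)
    genes = list(true_relative_expression)
    if not genes:
        raise ValueError("no target genes given")
    groups: list[str] = sorted({g for v in true_relative_expression.values() for g in v})
    for gene, per_group in true_relative_expression.items():
        if any(v <= 0 for v in per_group.values()):
            raise ValueError(f"non-positive expression for gene {gene!r}")
        if set(per_group) != set(groups):
            raise ValueError(f"gene {gene!r} missing groups")
    rows = []
    for group in groups:
        for r in range(1, replicates + 1):
            sample = f"{group}_r{r}"
            for ref in reference_genes:
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": ref,
                        "ct": ct_offset + rng.normal(0, ct_noise_sd),
                        "is_reference": True,
                    }
                )
            for gene in genes:
                expr = true_relative_expression[gene][group]
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "ct": ct_offset - np.log2(expr) + rng.normal(0, ct_noise_sd),
                        "is_reference": False,
                    }
                )
    return pd.DataFrame(rows)
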