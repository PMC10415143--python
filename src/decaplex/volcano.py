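"""Volcano statistics for label-free proximity-labelling interactomics.

Implements the statistical stage of the pipeline: log2 transform, minimum
quantification-count filtering, downshifted-normal imputation of missing
values, pooled-variance (Student) t-tests of bait vs control groups, linear
enrichment ratios, and classification into significance classes bounded by
s0 cut-off curves calibrated by label permutation to a target false
discovery rate.

The s0 curve is realised as a SAM-style modified statistic

    t' = d / (se + s0 * k),     k = mean(se) over the table,

where ``d`` is the difference of group means on the log2 scale and ``se``
the pooled standard error of that difference. At s0 = 0 the statistic
reduces to the ordinary t ratio so only the p-value matters; at non-zero s0
the absolute difference of means contributes, producing the familiar
hyperbolic boundary in (difference, -log10 p) space. The rejection
threshold on |t'| is chosen as the smallest observed |t'| at which the
permutation-estimated FDR (median null exceedance count divided by observed
exceedance count) stays at or below the class's target FDR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lfq_io import LfqMatrix, write_table

__all__ = [
    "CutoffSpec",
    "SIG_A",
    "SIG_B",
    "SIG_C",
    "DEFAULT_CUTOFFS",
    "VolcanoTable",
    "log_transform",
    "filter_min_values",
    "impute_downshifted",
    "pooled_ttest",
    "two_sample_ttest",
    "enrichment_ratio",
    "classify_significance",
    "pearson_between",
    "write_volcano_table",
    "plot_volcano",
]


@dataclass(frozen=True)
class CutoffSpec:
    """A significance class: a target FDR plus the s0 curve parameter."""

    name: str
    fdr: float
    s0: float

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")


# the three classes used throughout, ordered strongest to weakest evidence
SIG_A = CutoffSpec("SigA", fdr=0.01, s0=0.1)
SIG_B = CutoffSpec("SigB", fdr=0.05, s0=0.1)
SIG_C = CutoffSpec("SigC", fdr=0.05, s0=2.0)
DEFAULT_CUTOFFS: tuple[CutoffSpec, ...] = (SIG_A, SIG_B, SIG_C)


@dataclass
class VolcanoTable:
    """Per-protein test results for one bait-vs-control comparison.

    ``data`` columns: ``diff`` (mean log2 bait - control), ``se`` (pooled
    standard error of the difference), ``p``, ``neglog10p``, ``ratio``
    (linear enrichment), plus for each classified cutoff ``<name>``
    (significant on the bait-enriched, positive-difference side) and
    ``<name>_depleted`` (negative side).
    """

    data: pd.DataFrame
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    cutoffs: dict[str, CutoffSpec] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    def class_names(self) -> list[str]:
        return list(self.cutoffs)

    def significant(self, class_name: str, side: str = "enriched") -> set[str]:
        """Protein ids significant in ``class_name`` on the requested side."""
        if class_name not in self.cutoffs:
            raise KeyError(f"class {class_name!r} not classified in this table")
        col = class_name if side == "enriched" else f"{class_name}_depleted"
        return set(self.data.index[self.data[col]])


# ---------------------------------------------------------------------------
# transform / filter / impute
# ---------------------------------------------------------------------------

def log_transform(matrix: LfqMatrix) -> LfqMatrix:
    """Log2-transform observed intensities; missing cells stay missing."""
    if matrix.log_transformed:
        raise ValueError("matrix is already log-transformed")
    values = np.log2(matrix.values)
    return replace(matrix, values=values, log_transformed=True)


def filter_min_values(
    matrix: LfqMatrix,
    min_count: int,
    samples: Sequence[str] | None = None,
):
    """Drop proteins with fewer than ``min_count`` observed quantifications.

    Counts are taken on observed (never imputed) values, over all samples or
    over the subset ``samples`` (e.g. the bait group only). Returns the
    filtered matrix together with a list of :class:`~decaplex.filters.FilterTrace`
    records documenting each protein's count and outcome.
    """
    from .filters import FilterTrace  # local import: filters depends on this module's types

    scope = list(samples) if samples is not None else matrix.sample_names
    if min_count > len(scope):
        raise ValueError(
            f"min_count {min_count} exceeds the {len(scope)} samples in scope"
        )
    counts = matrix.observed_counts(scope)
    keep = counts >= min_count
    traces = [
        FilterTrace(protein_id=pid).add(
            "min_values",
            f"{int(counts[pid])}/{len(scope)} observed, need >= {min_count}",
            bool(keep[pid]),
        )
        for pid in matrix.protein_ids
    ]
    filtered = replace(
        matrix,
        values=matrix.values.loc[keep],
        gene_names=None if matrix.gene_names is None else matrix.gene_names.loc[keep],
    )
    return filtered, traces


def impute_downshifted(
    matrix: LfqMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | None = None,
) -> LfqMatrix:
    """Impute missing log2 values from a downshifted normal distribution.

    For each sample column with observed mean ``mu`` and standard deviation
    ``sigma``, missing cells are drawn from
    ``Normal(mu - downshift * sigma, (width * sigma)^2)`` — i.e. from around
    the detection limit, emulating values censored for low abundance. The
    defaults (width 0.3, downshift 1.8 column-SD units) are the conventional
    ones for this workflow.
    """
    if not matrix.log_transformed:
        raise ValueError("impute_downshifted expects a log2-transformed matrix")
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float, copy=True)
    for j, name in enumerate(matrix.sample_names):
        col = values[:, j]
        observed = col[~np.isnan(col)]
        if observed.size < 2:
            raise ValueError(
                f"sample {name!r} has {observed.size} observed value(s); "
                "cannot estimate an imputation distribution"
            )
        mu, sigma = observed.mean(), observed.std(ddof=1)
        missing = np.isnan(col)
        col[missing] = rng.normal(
            mu - downshift * sigma, width * sigma, size=int(missing.sum())
        )
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=out)


# ---------------------------------------------------------------------------
# t-test and enrichment
# ---------------------------------------------------------------------------

def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """Two-sample pooled-variance (homoscedastic) t-test on two 1-D arrays.

    Returns ``(diff, se, t, p)`` with ``diff = mean(a) - mean(b)`` and a
    two-tailed p-value. Degenerate inputs: if the pooled variance is zero the
    p-value is defined as 1 when the difference is also zero, and an error is
    raised otherwise (no finite statistic exists).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = a.mean() - b.mean()
    dof = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / dof
    se = math.sqrt(pooled_var * (1 / a.size + 1 / b.size))
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 0.0, 0.0, 1.0
        raise ValueError("degenerate variance: zero pooled variance with nonzero difference")
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return diff, se, t, min(p, 1.0)


def two_sample_ttest(
    matrix: LfqMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> VolcanoTable:
    """Per-protein pooled t-test of ``group_a`` (bait) vs ``group_b`` (control).

    Requires complete (post-imputation) values for both groups. Also fills
    the linear enrichment ratio column ``ratio = 2**diff``.
    """
    sub_a = matrix.values[list(group_a)].to_numpy(dtype=float)
    sub_b = matrix.values[list(group_b)].to_numpy(dtype=float)
    if np.isnan(sub_a).any() or np.isnan(sub_b).any():
        raise ValueError("t-test requires complete values; impute missing cells first")

    na, nb = sub_a.shape[1], sub_b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicates")
    diff = sub_a.mean(axis=1) - sub_b.mean(axis=1)
    dof = na + nb - 2
    pooled_var = ((na - 1) * sub_a.var(axis=1, ddof=1)
                  + (nb - 1) * sub_b.var(axis=1, ddof=1)) / dof
    se = np.sqrt(pooled_var * (1 / na + 1 / nb))

    zero_se = se == 0.0
    if np.any(zero_se & (diff != 0.0)):
        bad = matrix.values.index[zero_se & (diff != 0.0)][0]
        raise ValueError(f"degenerate variance for protein {bad!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, 0.0, diff / np.where(zero_se, 1.0, se))
    p = np.where(zero_se, 1.0, np.minimum(2.0 * stats.t.sf(np.abs(t), dof), 1.0))

    data = pd.DataFrame(
        {
            "diff": diff,
            "se": se,
            "p": p,
            "neglog10p": -np.log10(p),
            "ratio": np.exp2(diff),
        },
        index=matrix.values.index,
    )
    return VolcanoTable(data=data, group_a=tuple(group_a), group_b=tuple(group_b))


def enrichment_ratio(
    matrix: LfqMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """Linear enrichment ratio ``2**(mean log2 a - mean log2 b)`` per protein."""
    if not matrix.log_transformed:
        raise ValueError("enrichment_ratio expects a log2-transformed matrix")
    mean_a = matrix.values[list(group_a)].mean(axis=1)
    mean_b = matrix.values[list(group_b)].mean(axis=1)
    return np.exp2(mean_a - mean_b).rename("ratio")


# ---------------------------------------------------------------------------
# s0 significance curves
# ---------------------------------------------------------------------------

def _tprime(diff: np.ndarray, se: np.ndarray, s0: float, k: float) -> np.ndarray:
    return diff / (se + s0 * k)


def _group_stats(values: np.ndarray, na: int) -> tuple[np.ndarray, np.ndarray]:
    """diff and pooled se for a (proteins x pooled-samples) array split at na."""
    a, b = values[:, :na], values[:, na:]
    nb = b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    dof = na + nb - 2
    pooled = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / dof
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    return diff, se


def classify_significance(
    table: VolcanoTable,
    matrix: LfqMatrix,
    cutoffs: Iterable[CutoffSpec] = DEFAULT_CUTOFFS,
    permutations: int = 250,
    seed: int | None = None,
) -> VolcanoTable:
    """Assign significance classes bounded by permutation-calibrated s0 curves.

    For each cutoff the modified statistic ``t' = diff / (se + s0*k)`` is
    computed for every protein, the group labels are permuted ``permutations``
    times (whole sample columns, preserving between-protein correlation) to
    build a null distribution of |t'|, and the rejection threshold is the
    smallest observed |t'| whose estimated FDR — median null exceedance count
    over observed exceedance count — does not exceed the cutoff's target.
    Proteins are reported per side: ``<name>`` for the bait-enriched
    (positive-difference) side used downstream, ``<name>_depleted`` for the
    other side.
    """
    cutoffs = list(cutoffs)
    if permutations < 10:
        raise ValueError("at least 10 permutations are required")
    pooled_cols = list(table.group_a) + list(table.group_b)
    na = len(table.group_a)
    n = len(pooled_cols)
    if math.comb(n, na) <= 2:
        raise ValueError("groups too small to permute distinctly")

    values = matrix.values.loc[table.data.index, pooled_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("classification requires complete (imputed) values")

    diff = table.data["diff"].to_numpy()
    se = table.data["se"].to_numpy()
    k = float(se.mean())

    rng = np.random.default_rng(seed)
    # with few samples the distinct label splits are enumerable: use each
    # exactly once for a clean null; otherwise sample random permutations
    if math.comb(n, na) <= permutations:
        perm_idx = []
        for combo in itertools.combinations(range(n), na):
            rest = [i for i in range(n) if i not in combo]
            perm_idx.append(list(combo) + rest)
        perm_idx = np.array(perm_idx)
    else:
        perm_idx = np.stack([rng.permutation(n) for _ in range(permutations)])
    n_perm = perm_idx.shape[0]
    null_diff = np.empty((n_perm, values.shape[0]))
    null_se = np.empty_like(null_diff)
    for b in range(n_perm):
        null_diff[b], null_se[b] = _group_stats(values[:, perm_idx[b]], na)

    out = table.data.copy()
    thresholds = dict(table.thresholds)
    cutoff_map = dict(table.cutoffs)
    for spec in cutoffs:
        obs = np.abs(_tprime(diff, se, spec.s0, k))
        null = np.abs(_tprime(null_diff, null_se, spec.s0, k))
        threshold = _calibrate_threshold(obs, null, spec.fdr)
        sig = obs >= threshold
        out[spec.name] = sig & (diff > 0)
        out[f"{spec.name}_depleted"] = sig & (diff < 0)
        thresholds[spec.name] = threshold
        cutoff_map[spec.name] = spec

    return replace(table, data=out, cutoffs=cutoff_map, thresholds=thresholds)


def _calibrate_threshold(obs: np.ndarray, null: np.ndarray, fdr: float) -> float:
    """Smallest candidate threshold with median-estimated FDR <= target.

    ``null`` has shape (permutations, proteins). Candidates are the observed
    |t'| values; returns ``inf`` when no threshold achieves the target.
    """
    candidates = np.sort(obs)
    # observed exceedances: obs count >= c for each candidate (descending rank)
    obs_sorted = candidates
    obs_counts = obs.size - np.searchsorted(obs_sorted, candidates, side="left")
    null_sorted = np.sort(null, axis=1)
    # per permutation, count of null values >= each candidate
    null_counts = null.shape[1] - np.stack(
        [np.searchsorted(null_sorted[b], candidates, side="left")
         for b in range(null.shape[0])]
    )
    median_null = np.median(null_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = median_null / np.maximum(obs_counts, 1)
    ok = fdr_hat <= fdr
    if not ok.any():
        return float("inf")
    return float(candidates[np.argmax(ok)])


# ---------------------------------------------------------------------------
# cross-experiment correlation
# ---------------------------------------------------------------------------

def pearson_between(
    table_x: VolcanoTable,
    table_y: VolcanoTable,
    subset: Iterable[str] | None = None,
    statistic: str = "diff",
) -> float:
    """Pearson correlation of a per-protein statistic across two experiments.

    ``subset`` restricts to a protein set (default: the intersection of the
    two tables); fewer than 3 shared proteins is an error.
    """
    ids = set(table_x.data.index) & set(table_y.data.index)
    if subset is not None:
        ids &= set(subset)
    ids = sorted(ids)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 shared proteins, got {len(ids)}")
    x = table_x.data.loc[ids, statistic].to_numpy(dtype=float)
    y = table_y.data.loc[ids, statistic].to_numpy(dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_volcano_table(table: VolcanoTable, path, params: Mapping[str, object] | None = None) -> None:
    meta: dict[str, object] = {
        "group_a": ",".join(table.group_a),
        "group_b": ",".join(table.group_b),
    }
    for name, spec in table.cutoffs.items():
        meta[f"cutoff.{name}"] = (
            f"fdr={spec.fdr} s0={spec.s0} "
            f"threshold={table.thresholds.get(name, float('nan')):.4g} "
            "statistic=diff/(se+s0*mean(se)) calibration=permutation-median-FDR"
        )
    if params:
        meta.update(params)
    write_table(table.data, path, params=meta)


def plot_volcano(
    tables: Mapping[str, VolcanoTable],
    path,
    class_name: str = "SigB",
    highlight: Iterable[str] = (),
):
    """Volcano panel per bait (a Hawaii plot when several tables are given)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    highlight = set(highlight)
    n = len(tables)
    fig, axes = plt.subplots(1, n, figsize=(4.2 * n, 4.0), squeeze=False, sharey=True)
    for ax, (name, table) in zip(axes[0], tables.items()):
        d = table.data
        sig = d[class_name] | d.get(f"{class_name}_depleted", False) \
            if class_name in d.columns else pd.Series(False, index=d.index)
        ax.scatter(d["diff"][~sig], d["neglog10p"][~sig], s=6, c="0.7", lw=0)
        ax.scatter(d["diff"][sig], d["neglog10p"][sig], s=8, c="crimson", lw=0)
        for pid in highlight & set(d.index):
            ax.annotate(pid.split(";")[0], (d.at[pid, "diff"], d.at[pid, "neglog10p"]),
                        fontsize=6)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("t-test difference (log2)")
    axes[0][0].set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
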