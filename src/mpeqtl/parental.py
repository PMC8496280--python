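"""Parental differential expression, replicate QC, and transgression.

Differential expression between the four parental isolates uses a
per-gene one-way ANOVA feeding Tukey-Kramer studentized-range p-values
for all six founder pairs.  Transgression counts how many mpRILs fall
beyond an envelope of the most extreme parental line means +/- k pooled
within-line SDs.  Both statistics come with permutation false-positive
rates built by relabeling samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .stats import studentized_range_sf

PAIR_SEP = "-"


def _group_stats(Y: np.ndarray, labels: Sequence[str]):
    """Per-group means and the pooled within-group variance (MSE)."""
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))  # preserve order
    sizes = np.array([(labels == g).sum() for g in groups])
    if (sizes < 2).any():
        bad = [g for g, n in zip(groups, sizes) if n < 2]
        raise ValueError(f"every group needs >= 2 replicates; offending group(s): {bad}")
    means = np.stack([Y[:, labels == g].mean(axis=1) for g in groups], axis=1)  # G x k
    ss_within = np.zeros(Y.shape[0])
    for j, g in enumerate(groups):
        sub = Y[:, labels == g]
        ss_within += ((sub - means[:, [j]]) ** 2).sum(axis=1)
    df = len(labels) - len(groups)
    mse = ss_within / df
    return groups, sizes, means, mse, df


def tukey_pairwise(Y: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Tukey-Kramer adjusted p-values for all group pairs, per gene.

    ``Y`` is genes x samples; ``labels`` assigns each sample to a
    parental line.  Returns a genes x pairs DataFrame with columns like
    ``"JU1511-JU1926"``; p-values are symmetric in pair order.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    groups, sizes, means, mse, df = _group_stats(Y, labels)
    k = len(groups)
    cols = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = np.abs(means[:, i] - means[:, j]) / se
            nan_mask = np.isnan(q)  # 0/0: identical values within and between groups
            inf_mask = np.isinf(q)  # nonzero difference with zero within-group spread
            p = studentized_range_sf(np.where(nan_mask | inf_mask, 1.0, q), k, df)
            p[inf_mask] = 0.0
            p[nan_mask] = 1.0
            cols[f"{gi}{PAIR_SEP}{gj}"] = p
    return pd.DataFrame(cols)


def tukey_q_critical(alpha: float, k: int, df: int) -> float:
    """Critical studentized-range value: p < alpha iff q > this value."""
    from scipy.stats import studentized_range

    return float(studentized_range.isf(alpha, k, df))


def _max_q(Y: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Per-gene maximum pairwise q statistic (equal group sizes or Kramer)."""
    groups, sizes, means, mse, _ = _group_stats(Y, labels)
    qmax = np.zeros(Y.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        for (i, _), (j, _) in combinations(enumerate(groups), 2):
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = np.abs(means[:, i] - means[:, j]) / se
            q = np.where(np.isnan(q), 0.0, q)
            qmax = np.maximum(qmax, q)
    return qmax


def deg_count(Y: np.ndarray, labels: Sequence[str], alpha: float = 0.001) -> int:
    """Number of genes significant in at least one Tukey pair at ``alpha``."""
    groups = list(dict.fromkeys(labels))
    qcrit = tukey_q_critical(alpha, len(groups), len(labels) - len(groups))
    return int((_max_q(np.atleast_2d(Y), labels) > qcrit).sum())


@dataclass
class PairwiseDeResult:
    """Tukey HSD result over all genes: p-values, flags, and UpSet counts."""

    pvalues: pd.DataFrame  # genes x 6 pairs
    significant: pd.DataFrame  # boolean, same shape
    per_pair_counts: pd.Series
    intersection_counts: pd.Series  # indexed by '&'-joined pair combinations
    alpha: float

    @property
    def n_deg(self) -> int:
        return int(self.significant.any(axis=1).sum())


def pairwise_de(expr_log2: ExpressionMatrix, alpha: float = 0.001) -> PairwiseDeResult:
    """Differential expression between parental lines (Tukey HSD, all pairs)."""
    parents = expr_log2.parental_samples()
    if not parents:
        raise ValueError("no parental samples in matrix")
    ids = [s.id for s in parents]
    labels = [s.line for s in parents]
    Y = expr_log2.values[ids].to_numpy(dtype=float)
    pv = tukey_pairwise(Y, labels)
    pv.index = expr_log2.values.index
    sig = pv < alpha
    per_pair = sig.sum(axis=0)
    any_sig = sig.any(axis=1)
    patterns = sig.loc[any_sig].apply(lambda r: "&".join(sig.columns[r.values]), axis=1)
    inter = patterns.value_counts().sort_index() if len(patterns) else pd.Series(dtype=int)
    return PairwiseDeResult(pv, sig, per_pair, inter, alpha)


def deg_fpr(
    expr_log2: ExpressionMatrix,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float = 0.001,
) -> tuple[float, int, np.ndarray]:
    """Permutation FPR of the DEG count.

    Line labels are shuffled over the 8 parental samples; the DEG count
    is recomputed per permutation and FPR = mean permuted count /
    observed count.  Returns (fpr, observed_count, permuted_counts);
    fpr is NaN (with a warning) when the observed count is zero.
    """
    parents = expr_log2.parental_samples()
    ids = [s.id for s in parents]
    labels = np.array([s.line for s in parents])
    Y = expr_log2.values[ids].to_numpy(dtype=float)
    observed = deg_count(Y, list(labels), alpha)
    perm_counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm_counts[b] = deg_count(Y, list(rng.permutation(labels)), alpha)
    if observed == 0:
        warnings.warn("observed DEG count is 0; FPR undefined")
        return float("nan"), observed, perm_counts
    return float(perm_counts.mean() / observed), observed, perm_counts


def replicate_correlation(expr_log2: ExpressionMatrix) -> pd.Series:
    """Pearson correlation over genes between the two replicates of each parent."""
    parents = expr_log2.parental_samples()
    by_line: dict[str, list[str]] = {}
    for s in parents:
        by_line.setdefault(s.line, []).append(s.id)
    out = {}
    for line, ids in by_line.items():
        if len(ids) != 2:
            raise ValueError(f"parental line {line} needs exactly 2 replicates, found {len(ids)}")
        a = expr_log2.values[ids[0]].to_numpy(dtype=float)
        b = expr_log2.values[ids[1]].to_numpy(dtype=float)
        out[line] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="replicate_r")


# ---------------------------------------------------------------------------
# Transgression
# ---------------------------------------------------------------------------


def _transgression_counts(
    ril_Y: np.ndarray,
    parent_Y: np.ndarray,
    parent_labels: Sequence[str],
    k_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (n_over, n_under, upper, lower) against the parental envelope."""
    _, _, means, mse, _ = _group_stats(parent_Y, parent_labels)
    pooled_sd = np.sqrt(mse)
    upper = means.max(axis=1) + k_sd * pooled_sd
    lower = means.min(axis=1) - k_sd * pooled_sd
    n_over = (ril_Y > upper[:, None]).sum(axis=1)
    n_under = (ril_Y < lower[:, None]).sum(axis=1)
    return n_over, n_under, upper, lower


def transgression(
    expr_log2: ExpressionMatrix,
    k_sd: float = 2.0,
    count_threshold: int = 50,
) -> pd.DataFrame:
    """Count mpRILs beyond the parental expression envelope, per gene.

    The envelope is [min parental line mean - k_sd * SD, max + k_sd * SD]
    with SD pooled over the within-line variation of the parental
    replicates.  A gene is transgressive when strictly more than
    ``count_threshold`` mpRILs fall outside (strict inequalities
    throughout).
    """
    parents = expr_log2.parental_samples()
    rils = expr_log2.ril_samples()
    if not parents or not rils:
        raise ValueError("need both parental and mpRIL samples")
    pY = expr_log2.values[[s.id for s in parents]].to_numpy(dtype=float)
    rY = expr_log2.values[[s.id for s in rils]].to_numpy(dtype=float)
    n_over, n_under, upper, lower = _transgression_counts(
        rY, pY, [s.line for s in parents], k_sd
    )
    total = n_over + n_under
    return pd.DataFrame(
        {
            "n_over": n_over,
            "n_under": n_under,
            "upper": upper,
            "lower": lower,
            "transgressive": total > count_threshold,
        },
        index=expr_log2.values.index,
    )


def transgression_fpr(
    expr_log2: ExpressionMatrix,
    n_perm: int,
    rng: np.random.Generator,
    k_sd: float = 2.0,
    count_threshold: int = 50,
) -> tuple[float, int, np.ndarray]:
    """Permutation FPR of the transgressive-gene count.

    Each permutation picks 8 random samples to act as the 4 x 2 parental
    replicates (all remaining samples act as mpRILs) and recomputes the
    transgressive-gene count.  FPR = mean permuted count / observed
    count; NaN with a warning when the observed count is zero.
    """
    obs = transgression(expr_log2, k_sd, count_threshold)
    observed = int(obs["transgressive"].sum())
    all_ids = [s.id for s in expr_log2.samples]
    Y = expr_log2.values[all_ids].to_numpy(dtype=float)
    n = len(all_ids)
    pseudo_labels = [f"P{j}" for j in range(4) for _ in range(2)]
    perm_counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        order = rng.permutation(n)
        p_idx, r_idx = order[:8], order[8:]
        n_over, n_under, _, _ = _transgression_counts(
            Y[:, r_idx], Y[:, p_idx], pseudo_labels, k_sd
        )
        perm_counts[b] = int(((n_over + n_under) > count_threshold).sum())
    if observed == 0:
        warnings.warn("observed transgressive-gene count is 0; FPR undefined")
        return float("nan"), observed, perm_counts
    return float(perm_counts.mean() / observed), observed, perm_counts
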