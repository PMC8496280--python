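"""Genome-wide single-marker eQTL mapping with permutation FPR control.

Each gene's log2-ratio expression is regressed on one binary SNP marker
at a time (OLS); the marker p-value comes from the F(1, n-2) test of the
slope.  The most significant marker per gene is its peak (one eQTL per
gene).  The genome-wide threshold is set by one round of per-gene
permutations: the smallest grid value T where the number of permuted
peaks above T divided by the number of observed peaks above T drops
below the target ratio (0.01 by default).  Significant peaks are
classified cis when they lie within 1 Mbp of the gene start on the same
chromosome, and tabulated by SNP-distribution pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import GeneAnnotation, GenotypeMatrix, chromosome_order
from .sdp import SDP_LABELS
from .stats import f_test_neglog10p


@dataclass
class EqtlProfile:
    """Per-marker association profile of one gene."""

    gene: str
    neglogp: np.ndarray
    slope: np.ndarray

    def __post_init__(self) -> None:
        if (self.neglogp < 0).any():
            raise ValueError("-log10(p) values must be >= 0")


@dataclass
class EqtlRecord:
    """The peak-marker eQTL call of one gene."""

    gene: str
    marker: str
    chromosome: str
    position: int
    sdp: str
    neglogp: float
    slope: float
    significant: bool
    type: Optional[str] = None  # "cis" | "trans", set for significant records


class ThresholdNotFound(RuntimeError):
    """No grid threshold achieves the requested FP/TP ratio."""

    def __init__(self, best_ratio: float):
        self.best_ratio = best_ratio
        super().__init__(
            f"no -log10(p) threshold achieves the requested FP/TP ratio; best achievable "
            f"ratio is {best_ratio:.4g}"
        )


def _class_counts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Non-missing counts of genotype classes 1 and 0 per marker row."""
    M = ~np.isnan(X)
    n1 = np.where(M, X, 0.0).sum(axis=1)
    n0 = M.sum(axis=1) - n1
    return n0, n1


def scan_many(
    Y: pd.DataFrame,
    genos: GenotypeMatrix,
    min_class: int = 5,
    return_slopes: bool = False,
):
    """Single-marker scans for all genes at once.

    ``Y`` is genes x lines (log2 ratios) with columns matching genotype
    lines.  Returns a genes x markers -log10(p) DataFrame (and slopes
    when requested).  Markers that are monomorphic, near-monomorphic
    (fewer than ``min_class`` lines in either genotype class) or missing
    in some lines are handled per marker; degenerate markers score 0.
    """
    lines = [l for l in Y.columns]
    X = genos.alleles[lines].to_numpy(dtype=float)  # markers x lines
    Yarr = Y.to_numpy(dtype=float)  # genes x lines
    G, n = Yarr.shape
    m = X.shape[0]

    n0, n1 = _class_counts(X)
    valid = (n0 >= min_class) & (n1 >= min_class)
    neglogp = np.zeros((G, m))
    slopes = np.full((G, m), np.nan)

    complete = ~np.isnan(X).any(axis=1)
    Yc = Yarr - Yarr.mean(axis=1, keepdims=True)
    sy = np.sqrt((Yc**2).sum(axis=1))
    const_gene = sy == 0

    # fully observed markers: one dense pass
    idx = np.flatnonzero(complete & valid)
    if len(idx):
        Xc = X[idx] - X[idx].mean(axis=1, keepdims=True)
        sx = np.sqrt((Xc**2).sum(axis=1))
        cov = Yc @ Xc.T  # G x m_sub
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / np.outer(sy, sx)
            r[const_gene, :] = 0.0  # constant gene: no association, p = 1
            neglogp[:, idx] = f_test_neglog10p(r**2, n)
            slopes[:, idx] = cov / (sx**2)[None, :]

    # markers with missing genotypes: per-marker masked pass
    for j in np.flatnonzero(~complete & valid):
        mask = ~np.isnan(X[j])
        nj = int(mask.sum())
        if nj < 3:
            continue
        x = X[j, mask]
        xc = x - x.mean()
        sx2 = float((xc**2).sum())
        if sx2 == 0:
            continue
        Yj = Yarr[:, mask]
        Yjc = Yj - Yj.mean(axis=1, keepdims=True)
        cov = Yjc @ xc
        syj = np.sqrt((Yjc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(syj > 0, cov / (syj * np.sqrt(sx2)), 0.0)
        neglogp[:, j] = f_test_neglog10p(r**2, nj)
        slopes[:, j] = cov / sx2

    if not valid.any():
        warnings.warn("all markers are degenerate; profiles are all zero")
    out = pd.DataFrame(neglogp, index=Y.index, columns=genos.alleles.index)
    if return_slopes:
        return out, pd.DataFrame(slopes, index=Y.index, columns=genos.alleles.index)
    return out


def scan_gene(
    y: pd.Series, genos: GenotypeMatrix, min_class: int = 5
) -> EqtlProfile:
    """Association profile of a single gene (see :func:`scan_many`)."""
    name = str(y.name) if y.name is not None else "gene"
    Y = y.to_frame().T
    nlp, slope = scan_many(Y, genos, min_class, return_slopes=True)
    return EqtlProfile(name, nlp.iloc[0].to_numpy(), slope.iloc[0].to_numpy())


def _peak_index(neglogp: np.ndarray, markers) -> int:
    """Argmax with ties broken by chromosome order then lowest position."""
    top = neglogp.max()
    ties = np.flatnonzero(neglogp == top)
    if len(ties) == 1:
        return int(ties[0])
    return int(min(ties, key=lambda i: (chromosome_order(markers[i].chromosome), markers[i].position)))


def call_peak(
    profile: EqtlProfile, genos: GenotypeMatrix, threshold: float
) -> EqtlRecord:
    """Peak call of one gene: most significant marker, strict threshold."""
    i = _peak_index(profile.neglogp, genos.markers)
    m = genos.markers[i]
    return EqtlRecord(
        gene=profile.gene,
        marker=m.id,
        chromosome=m.chromosome,
        position=m.position,
        sdp=m.sdp,
        neglogp=float(profile.neglogp[i]),
        slope=float(profile.slope[i]),
        significant=bool(profile.neglogp[i] > threshold),
    )


def call_peaks_frame(
    neglogp: pd.DataFrame,
    slopes: pd.DataFrame,
    genos: GenotypeMatrix,
    threshold: float,
) -> pd.DataFrame:
    """Vectorized peak calling over a genes x markers profile matrix.

    Markers are stored sorted by (chromosome, position), so the first
    index attaining the row maximum realizes the declared tie-break
    (chromosome order I<II<III<IV<V<X, then lowest position).
    """
    arr = neglogp.to_numpy()
    slope_arr = slopes.to_numpy()
    top = arr.max(axis=1)
    idx = np.argmax(arr == top[:, None], axis=1)
    rows = []
    for row, (g, i, t) in enumerate(zip(neglogp.index, idx, top)):
        m = genos.markers[int(i)]
        rows.append(
            {
                "gene": g,
                "marker": m.id,
                "chromosome": m.chromosome,
                "position": m.position,
                "sdp": m.sdp,
                "neglogp": float(t),
                "slope": float(slope_arr[row, int(i)]),
                "significant": bool(t > threshold),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def permuted_peaks(
    Y: pd.DataFrame,
    genos: GenotypeMatrix,
    rng: np.random.Generator,
    min_class: int = 5,
) -> np.ndarray:
    """Peak -log10(p) per gene after permuting each gene across lines."""
    arr = Y.to_numpy(dtype=float)
    perm = np.empty_like(arr)
    n = arr.shape[1]
    for g in range(arr.shape[0]):
        perm[g] = arr[g, rng.permutation(n)]
    Yp = pd.DataFrame(perm, index=Y.index, columns=Y.columns)
    return scan_many(Yp, genos, min_class).to_numpy().max(axis=1)


def permutation_fpr_threshold(
    observed_peaks: np.ndarray,
    permuted: np.ndarray,
    ratio: float = 0.01,
    grid_step: float = 0.05,
) -> float:
    """Smallest grid threshold T with #{permuted >= T} / #{observed >= T} < ratio.

    ``permuted`` may hold several permutation rounds stacked; the false
    positive count is then averaged per round.  Raises
    :class:`ThresholdNotFound` (carrying the best achievable ratio) when
    the permuted and observed distributions cannot be separated.
    """
    observed = np.asarray(observed_peaks, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    n_rounds = max(1, round(len(permuted) / len(observed)))
    top = max(observed.max(), permuted.max())
    grid = np.arange(grid_step, top + 2 * grid_step, grid_step)
    best = np.inf
    for T in grid:
        tp = int((observed >= T).sum())
        if tp == 0:
            break
        fp = float((permuted >= T).sum()) / n_rounds
        best = min(best, fp / tp)
        if fp / tp < ratio:
            return float(round(T / grid_step) * grid_step)
    raise ThresholdNotFound(best)


def classify_cis_trans(
    rec: EqtlRecord, ann: dict[str, GeneAnnotation], window: int = 1_000_000
) -> str:
    """"cis" iff the peak is within ``window`` bp of the gene start on the same chromosome."""
    a = ann.get(rec.gene)
    if a is None:
        raise KeyError(f"no annotation for gene {rec.gene}")
    if a.chromosome == rec.chromosome and abs(rec.position - a.start) <= window:
        return "cis"
    return "trans"


def classify_records_frame(
    records: pd.DataFrame, ann: dict[str, GeneAnnotation], window: int = 1_000_000
) -> pd.DataFrame:
    """Add a cis/trans ``type`` column to a significant-records frame."""
    missing = [g for g in records.index if g not in ann]
    if missing:
        raise KeyError(f"no annotation for gene(s): {missing[:5]}{'...' if len(missing) > 5 else ''}")
    types = []
    for g, r in records.iterrows():
        a = ann[g]
        same = a.chromosome == r["chromosome"] and abs(int(r["position"]) - a.start) <= window
        types.append("cis" if same else "trans")
    out = records.copy()
    out["type"] = types
    return out


def tabulate_sdp(records: pd.DataFrame) -> pd.DataFrame:
    """Count significant eQTLs per SDP x chromosome x cis/trans.

    ``records`` needs ``sdp``, ``chromosome`` and ``type`` columns.
    Returns a 7-SDP x (cis chromosomes + Tot, trans chromosomes + Tot)
    table with a Total row; grand totals equal the number of cis and
    trans records.
    """
    from .data import CHROMOSOMES

    cols = pd.MultiIndex.from_tuples(
        [(t, c) for t in ("cis", "trans") for c in CHROMOSOMES + ("Tot",)]
    )
    table = pd.DataFrame(0, index=list(SDP_LABELS) + ["Total"], columns=cols)
    if len(records):
        grp = records.groupby(["sdp", "type", "chromosome"], observed=True).size()
        for (sdp, typ, chrom), cnt in grp.items():
            table.loc[sdp, (typ, chrom)] += int(cnt)
    for t in ("cis", "trans"):
        table[(t, "Tot")] = table[[(t, c) for c in CHROMOSOMES]].sum(axis=1)
    table.loc["Total"] = table.iloc[:-1].sum(axis=0)
    return table
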