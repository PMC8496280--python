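"""Core data containers, file IO, expression normalization, and PCA QC.

The in-memory model follows the field's tabular conventions: a genotype
matrix is markers x lines with per-marker chromosome/position/SDP
metadata, an expression matrix is genes x samples with an explicit
"layer" recording what the values are (raw fpkm, depth-normalized fpkm,
log2, or gene-centered log2 ratio).  All tables round-trip through plain
tab-delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .sdp import SDP_LABELS

CHROMOSOMES: tuple[str, ...] = ("I", "II", "III", "IV", "V", "X")
_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

LAYERS = ("raw_fpkm", "normalized", "log2", "log2_ratio")


def chromosome_order(chrom: str) -> int:
    """Rank of a chromosome in the canonical I < II < III < IV < V < X order."""
    try:
        return _CHROM_ORDER[chrom]
    except KeyError:
        raise ValueError(f"unknown chromosome {chrom!r}; expected one of {CHROMOSOMES}") from None


@dataclass(frozen=True)
class MarkerInfo:
    """A SNP marker: identifier, genomic location, and SDP class."""

    id: str
    chromosome: str
    position: int
    sdp: str

    def __post_init__(self) -> None:
        chromosome_order(self.chromosome)
        if self.position < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1 (1-based bp)")
        if self.sdp not in SDP_LABELS:
            raise ValueError(f"marker {self.id}: {self.sdp!r} is not one of the 7 SDP labels")


@dataclass(frozen=True)
class SampleInfo:
    """An RNA-seq sample: one replicate of an mpRIL or a parental isolate."""

    id: str
    role: str  # "mpRIL" | "parent"
    line: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ("mpRIL", "parent"):
            raise ValueError(f"sample {self.id}: role must be 'mpRIL' or 'parent'")


@dataclass
class GenotypeMatrix:
    """Binary marker x line genotypes with marker metadata.

    ``alleles`` is a float DataFrame (markers x lines) with values in
    {0, 1, NaN}; 1 means the line carries the non-reference allele.
    Markers are kept sorted by (chromosome, position).
    """

    alleles: pd.DataFrame
    markers: list[MarkerInfo]

    def __post_init__(self) -> None:
        if len(self.markers) != self.alleles.shape[0]:
            raise ValueError("marker metadata and allele rows disagree in length")
        ids = [m.id for m in self.markers]
        if list(self.alleles.index) != ids:
            raise ValueError("allele row index must equal marker ids, in order")
        keys = [(chromosome_order(m.chromosome), m.position) for m in self.markers]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("markers must be sorted by (chromosome, position)")
        if self.alleles.columns.duplicated().any():
            raise ValueError("line identifiers must be unique")
        vals = self.alleles.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("genotypes must be 0, 1, or missing")

    @property
    def lines(self) -> list[str]:
        return list(self.alleles.columns)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[0]

    def marker_frame(self) -> pd.DataFrame:
        """Marker metadata as a DataFrame indexed by marker id."""
        return pd.DataFrame(
            {
                "chromosome": [m.chromosome for m in self.markers],
                "position": [m.position for m in self.markers],
                "sdp": [m.sdp for m in self.markers],
            },
            index=pd.Index([m.id for m in self.markers], name="marker"),
        )

    def subset_lines(self, lines: Sequence[str]) -> "GenotypeMatrix":
        missing = set(lines) - set(self.alleles.columns)
        if missing:
            raise KeyError(f"unknown line(s): {sorted(missing)}")
        return GenotypeMatrix(self.alleles.loc[:, list(lines)], self.markers)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit layer tag."""

    values: pd.DataFrame
    samples: list[SampleInfo]
    layer: str = "raw_fpkm"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        ids = [s.id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("value columns must equal sample ids, in order")
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if self.layer in ("raw_fpkm", "normalized"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"negative values are not allowed in the {self.layer} layer")
        counts: dict[tuple[str, str], int] = {}
        for s in self.samples:
            counts[(s.role, s.line)] = counts.get((s.role, s.line), 0) + 1
        for (role, line), n in counts.items():
            if role == "parent" and n != 2:
                raise ValueError(f"parental line {line} must have exactly 2 replicates, found {n}")
            if role == "mpRIL" and n != 1:
                raise ValueError(f"mpRIL {line} must have exactly 1 replicate, found {n}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "role": [s.role for s in self.samples],
                "line": [s.line for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            },
            index=pd.Index([s.id for s in self.samples], name="sample"),
        )

    def parental_samples(self) -> list[SampleInfo]:
        return [s for s in self.samples if s.role == "parent"]

    def ril_samples(self) -> list[SampleInfo]:
        return [s for s in self.samples if s.role == "mpRIL"]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples, self.layer)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        by_id = {s.id: s for s in self.samples}
        keep = [by_id[i] for i in sample_ids]
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], keep, self.layer)


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic location of a gene (chromosome and 1-based start)."""

    gene: str
    chromosome: str
    start: int

    def __post_init__(self) -> None:
        chromosome_order(self.chromosome)
        if self.start < 1:
            raise ValueError(f"gene {self.gene}: start must be >= 1")


# ---------------------------------------------------------------------------
# Expression transforms
# ---------------------------------------------------------------------------


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize fpkm: per sample, fpkm per million total fpkm.

    Every output sample column sums to 1e6.  A sample with zero total
    expression cannot be normalized and raises ``ValueError``.
    """
    if raw.layer != "raw_fpkm":
        raise ValueError(f"expected raw_fpkm layer, got {raw.layer!r}")
    totals = raw.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total fpkm: {list(zero.index)}")
    out = raw.values / totals * 1e6
    return ExpressionMatrix(out, raw.samples, "normalized")


def log2_and_ratio(
    norm: ExpressionMatrix, pseudocount: float = 2.0**-10
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Log2-transform and gene-center a normalized matrix.

    The pseudocount is added to exact zeros only; with ``pseudocount=0``
    any zero value raises.  The ratio layer subtracts each gene's mean
    log2 value over all samples, so every ratio row has mean 0.
    """
    if norm.layer != "normalized":
        raise ValueError(f"expected normalized layer, got {norm.layer!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = norm.values.to_numpy(dtype=float).copy()
    if (vals == 0).any():
        if pseudocount == 0:
            raise ValueError("zero expression value with pseudocount 0")
        vals[vals == 0] = pseudocount
    log2 = pd.DataFrame(np.log2(vals), index=norm.values.index, columns=norm.values.columns)
    ratio = log2.sub(log2.mean(axis=1), axis=0)
    return (
        ExpressionMatrix(log2, norm.samples, "log2"),
        ExpressionMatrix(ratio, norm.samples, "log2_ratio"),
    )


def log2_fpkm(raw: ExpressionMatrix, pseudocount: float = 2.0**-10) -> ExpressionMatrix:
    """Log2 of raw fpkm (pseudocount on exact zeros), used for gene filtering."""
    if raw.layer != "raw_fpkm":
        raise ValueError(f"expected raw_fpkm layer, got {raw.layer!r}")
    vals = raw.values.to_numpy(dtype=float).copy()
    if (vals == 0).any():
        if pseudocount == 0:
            raise ValueError("zero expression value with pseudocount 0")
        vals[vals == 0] = pseudocount
    return ExpressionMatrix(
        pd.DataFrame(np.log2(vals), index=raw.values.index, columns=raw.values.columns),
        raw.samples,
        "log2",
    )


def filter_expressed_genes(log2m: ExpressionMatrix, threshold: float = -5.0) -> list[str]:
    """Genes with mean log2 expression strictly above ``threshold``.

    Mirrors the consistently-detected-transcript filter (default -5 on
    the log2 fpkm scale).  Returns gene ids in matrix order.
    """
    if log2m.layer != "log2":
        raise ValueError(f"expected log2 layer, got {log2m.layer!r}")
    means = log2m.values.mean(axis=1)
    return list(means.index[means > threshold])


def pca_qc(ratios: ExpressionMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component scores of the gene-centered matrix.

    Samples are the observations (points in gene space).  Returns a
    samples x components score DataFrame and the variance-explained
    fractions (non-increasing, summing to <= 1).
    """
    if ratios.layer != "log2_ratio":
        raise ValueError(f"expected log2_ratio layer, got {ratios.layer!r}")
    n_samples = ratios.values.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > n_samples:
        raise ValueError(f"n_components={n_components} exceeds the {n_samples} samples")
    X = ratios.values.to_numpy(dtype=float).T  # samples x genes
    cols = [f"PC{i + 1}" for i in range(n_components)]
    if np.allclose(X, X.mean(axis=0)):  # identical samples: no variance to explain
        frame = pd.DataFrame(
            np.zeros((n_samples, n_components)), index=[s.id for s in ratios.samples], columns=cols
        )
        return frame, np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(scores, index=[s.id for s in ratios.samples], columns=cols)
    return frame, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Tab-delimited IO
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, samples: list[SampleInfo], layer: str = "raw_fpkm") -> ExpressionMatrix:
    """Read a gene x sample table (first column gene id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    order = [s.id for s in samples]
    missing = set(order) - set(df.columns)
    if missing:
        raise ValueError(f"expression table lacks sample column(s): {sorted(missing)}")
    return ExpressionMatrix(df.loc[:, order], samples, layer)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_samples(path: str | Path) -> list[SampleInfo]:
    """Read a sample sheet with columns sample/role/line/replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "line": str})
    return [
        SampleInfo(str(r["sample"]), str(r["role"]), str(r["line"]), int(r["replicate"]))
        for _, r in df.iterrows()
    ]


def write_samples(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [s.id for s in samples],
            "role": [s.role for s in samples],
            "line": [s.line for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a marker table: marker, chromosome, position, sdp, then one column per line."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str, "sdp": str})
    meta_cols = ["marker", "chromosome", "position", "sdp"]
    markers = [
        MarkerInfo(str(r["marker"]), str(r["chromosome"]), int(r["position"]), str(r["sdp"]))
        for _, r in df.iterrows()
    ]
    alleles = df.drop(columns=meta_cols)
    alleles.index = pd.Index([m.id for m in markers], name="marker")
    return GenotypeMatrix(alleles.astype(float), markers)


def write_genotypes(genos: GenotypeMatrix, path: str | Path) -> None:
    meta = genos.marker_frame().reset_index()
    body = genos.alleles.reset_index(drop=True)
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read gene/chromosome/start annotation into a dict keyed by gene id."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    return {
        str(r["gene"]): GeneAnnotation(str(r["gene"]), str(r["chromosome"]), int(r["start"]))
        for _, r in df.iterrows()
    }


def write_annotation(ann: dict[str, GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [a.gene for a in ann.values()],
            "chromosome": [a.chromosome for a in ann.values()],
            "start": [a.start for a in ann.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene id, GO term id) association table -> term -> genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str, comment="!")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(term, set()).add(gene)
    return out


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for t in sorted(go_map) for g in sorted(go_map[t])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
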