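"""Synthetic mpRIL genotype and expression data with a known truth ledger.

The generator emulates the statistical structure of a four-founder
*C. elegans* multiparental RIL population: each line's chromosome is a
mosaic of founder haplotypes (Poisson breakpoints, uniform positions),
markers carry SNP-distribution-pattern (SDP) structure drawn from the
seven informative founder partitions, and expression is built on the
log2 scale from a per-gene baseline, planted cis/trans genetic effects,
a shared per-line developmental covariate, and Gaussian noise.  A
:class:`SyntheticTruth` ledger records the founder mosaics, realized
planted effects and per-gene true heritability so downstream stages can
be tested for parameter recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    MarkerInfo,
    SampleInfo,
    write_annotation,
    write_expression,
    write_genotypes,
    write_go_map,
    write_samples,
)
from .sdp import FOUNDERS, SDP_LABELS, sdp_from_display

#: C. elegans chromosome lengths (bp), rounded to 0.1 Mbp.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("I", 15_100_000),
    ("II", 15_300_000),
    ("III", 13_800_000),
    ("IV", 17_500_000),
    ("V", 20_900_000),
    ("X", 17_700_000),
)

#: Default SDP class weights; skewed toward the JU1511-, JU1941- and
#: 14-linked classes with JU1926-specific SNPs rare, reflecting the
#: pronounced founder imbalance of the real marker map.
DEFAULT_SDP_WEIGHTS: dict[str, float] = {
    "12": 0.06,
    "13": 0.07,
    "14": 0.22,
    "JU1511": 0.25,
    "JU1926": 0.04,
    "JU1931": 0.12,
    "JU1941": 0.24,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A genetic effect planted into the simulated expression data.

    ``effect_size`` is in units of the residual (noise) SD.  For ``cis``
    effects with ``target_genes=None`` the generator targets the gene
    nearest the locus (relocating it onto the locus); for ``trans_band``
    effects with ``target_genes=None`` it samples ``n_targets`` genes
    from other chromosomes.  ``sdp`` forces the SDP class of the marker
    nearest the locus so the planted regulator has a known pattern.
    """

    kind: str  # "cis" | "trans_band"
    locus: tuple[str, int]
    effect_size: float
    sdp: str
    target_genes: Optional[tuple[str, ...]] = None
    n_targets: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("cis", "trans_band"):
            raise ValueError(f"effect kind must be 'cis' or 'trans_band', got {self.kind!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.sdp not in SDP_LABELS:
            raise ValueError(f"{self.sdp!r} is not one of the 7 SDP labels")
        if self.target_genes is None and self.n_targets < 1:
            raise ValueError("trans_band effects need at least one target")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic population.

    Defaults mirror the mpRIL study design: 200 lines plus the four
    founders (two replicates each), ~9000 SDP-structured markers and
    ~12,000 expressed genes on the six *C. elegans* chromosomes.
    """

    n_lines: int = 200
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    n_markers: int = 9000
    n_genes: int = 12000
    breakpoints_per_chromosome_mean: float = 1.5
    sdp_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDP_WEIGHTS))
    effects: tuple[PlantedEffect, ...] = ()
    dev_covariate_sd: float = 0.3
    noise_sd: float = 0.5
    baseline_mean: float = 3.0
    baseline_sd: float = 2.0
    low_expressed_fraction: float = 0.05
    n_go_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce YAML-friendly forms (lists / dicts) into the native types
        self.chromosomes = tuple((str(c), int(L)) for c, L in self.chromosomes)
        effects = []
        for e in self.effects:
            if isinstance(e, dict):
                e = dict(e)
                e["locus"] = (str(e["locus"][0]), int(e["locus"][1]))
                if e.get("target_genes") is not None:
                    e["target_genes"] = tuple(e["target_genes"])
                e = PlantedEffect(**e)
            effects.append(e)
        self.effects = tuple(effects)
        if self.n_lines <= 0 or self.n_markers <= 0 or self.n_genes <= 0:
            raise ValueError("n_lines, n_markers and n_genes must be positive")
        if min(self.n_markers, self.n_genes) < len(self.chromosomes):
            raise ValueError("need at least one marker and one gene per chromosome")
        unknown = set(self.sdp_weights) - set(SDP_LABELS)
        if unknown:
            raise ValueError(f"unknown SDP label(s) in weights: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of one simulated dataset.

    ``mosaics[line][chrom]`` is a list of ``(start, end, founder)``
    segments tiling the chromosome exactly.  ``true_h2`` holds each
    gene's additive variance fraction; ``effects_realized`` records the
    marker, SDP and target genes each planted effect resolved to.
    """

    mosaics: dict[str, dict[str, list[tuple[int, int, str]]]]
    founder_alleles: pd.DataFrame  # markers x 4 founders
    true_h2: pd.Series
    effects_realized: list[dict]
    seed: int


def _rng(seed: int, name: str) -> np.random.Generator:
    """A named, independent substream of the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


def _allocate(counts_total: int, lengths: Sequence[int]) -> list[int]:
    """Split a total count over chromosomes proportional to length (>=1 each)."""
    total = sum(lengths)
    raw = [counts_total * L / total for L in lengths]
    out = [max(1, int(round(x))) for x in raw]
    # adjust rounding drift on the largest chromosome
    drift = counts_total - sum(out)
    out[int(np.argmax(lengths))] += drift
    if min(out) < 1:
        raise ValueError("chromosome ended up with zero markers; increase n_markers")
    return out


def simulate_genomes(config: SimConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate founder alleles, line mosaics, and the resulting genotypes.

    The returned matrix has one column per mpRIL line plus one per
    founder (pure parental genotypes).  The truth ledger carries the
    mosaics and the founder allele table; expression-level fields are
    filled in by :func:`simulate_expression`.
    """
    chrom_names = [c for c, _ in config.chromosomes]
    lengths = [L for _, L in config.chromosomes]
    per_chrom = _allocate(config.n_markers, lengths)

    rng_m = _rng(config.seed, "markers")
    markers: list[MarkerInfo] = []
    for (chrom, L), n_c in zip(config.chromosomes, per_chrom):
        pos = np.sort(rng_m.choice(np.arange(1, L + 1), size=n_c, replace=False))
        for i, p in enumerate(pos):
            markers.append(MarkerInfo(f"{chrom}_{int(p)}", chrom, int(p), "14"))

    # SDP classes per marker
    labels = list(config.sdp_weights.keys())
    w = np.array([config.sdp_weights[l] for l in labels], dtype=float)
    w = w / w.sum()
    rng_s = _rng(config.seed, "sdp")
    drawn = rng_s.choice(len(labels), size=len(markers), p=w)
    markers = [replace(m, sdp=labels[d]) for m, d in zip(markers, drawn)]

    # planted effects pin the SDP of their nearest marker
    effect_marker_idx: list[int] = []
    for eff in config.effects:
        chrom, pos = eff.locus
        idx = [i for i, m in enumerate(markers) if m.chromosome == chrom]
        if not idx:
            raise ValueError(f"effect locus on unknown/empty chromosome {chrom!r}")
        nearest = min(idx, key=lambda i: abs(markers[i].position - pos))
        markers[nearest] = replace(markers[nearest], sdp=eff.sdp)
        effect_marker_idx.append(nearest)

    # founder allele table from the SDP carrier sets
    founder_alleles = np.zeros((len(markers), 4), dtype=float)
    for j, f in enumerate(FOUNDERS):
        founder_alleles[:, j] = [1.0 if f in sdp_from_display(m.sdp).carriers else 0.0 for m in markers]

    # line mosaics
    rng_x = _rng(config.seed, "mosaics")
    line_names = [f"mpRIL{i + 1:03d}" for i in range(config.n_lines)]
    mosaics: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    chrom_marker_pos = {
        chrom: np.array([m.position for m in markers if m.chromosome == chrom]) for chrom in chrom_names
    }
    chrom_marker_rows = {
        chrom: np.array([i for i, m in enumerate(markers) if m.chromosome == chrom]) for chrom in chrom_names
    }
    geno = np.zeros((len(markers), config.n_lines + 4), dtype=float)
    for li, line in enumerate(line_names):
        mosaics[line] = {}
        for chrom, L in config.chromosomes:
            k = rng_x.poisson(config.breakpoints_per_chromosome_mean)
            cuts = np.sort(rng_x.uniform(1, L, size=k)).astype(int) if k else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [L]])
            founders_seg = rng_x.integers(0, 4, size=len(bounds) - 1)
            segs = [
                (int(bounds[s]) + 1, int(bounds[s + 1]), FOUNDERS[int(founders_seg[s])])
                for s in range(len(bounds) - 1)
            ]
            # drop zero-length segments from coincident cuts
            segs = [(a, b, f) for a, b, f in segs if b >= a]
            mosaics[line][chrom] = segs
            pos = chrom_marker_pos[chrom]
            rows = chrom_marker_rows[chrom]
            seg_of_marker = np.searchsorted(bounds[1:], pos, side="left")
            seg_of_marker = np.clip(seg_of_marker, 0, len(founders_seg) - 1)
            geno[rows, li] = founder_alleles[rows, founders_seg[seg_of_marker]]
    # pure founder columns
    for j, f in enumerate(FOUNDERS):
        geno[:, config.n_lines + j] = founder_alleles[:, j]
        mosaics[f] = {chrom: [(1, L, f)] for chrom, L in config.chromosomes}

    cols = line_names + list(FOUNDERS)
    alleles = pd.DataFrame(geno, index=pd.Index([m.id for m in markers], name="marker"), columns=cols)
    truth = SyntheticTruth(
        mosaics=mosaics,
        founder_alleles=pd.DataFrame(
            founder_alleles, index=alleles.index, columns=list(FOUNDERS)
        ),
        true_h2=pd.Series(dtype=float),
        effects_realized=[
            {
                "kind": eff.kind,
                "marker": markers[mi].id,
                "chromosome": markers[mi].chromosome,
                "position": markers[mi].position,
                "sdp": markers[mi].sdp,
                "effect_size": eff.effect_size,
            }
            for eff, mi in zip(config.effects, effect_marker_idx)
        ],
        seed=config.seed,
    )
    return GenotypeMatrix(alleles, markers), truth


def simulate_annotation(config: SimConfig) -> dict[str, GeneAnnotation]:
    """Place genes uniformly on the chromosomes, density proportional to length."""
    lengths = [L for _, L in config.chromosomes]
    per_chrom = _allocate(config.n_genes, lengths)
    rng = _rng(config.seed, "genes")
    ann: dict[str, GeneAnnotation] = {}
    i = 0
    for (chrom, L), n_c in zip(config.chromosomes, per_chrom):
        starts = np.sort(rng.choice(np.arange(1, L + 1), size=n_c, replace=False))
        for s in starts:
            i += 1
            g = f"g{i:05d}"
            ann[g] = GeneAnnotation(g, chrom, int(s))
    return ann


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _resolve_targets(
    eff: PlantedEffect,
    realized: dict,
    ann: dict[str, GeneAnnotation],
    rng: np.random.Generator,
) -> tuple[list[str], dict[str, GeneAnnotation]]:
    """Resolve an effect's target genes; cis targets are moved onto the locus."""
    genes = list(ann)
    if eff.target_genes is not None:
        missing = set(eff.target_genes) - set(ann)
        if missing:
            raise ValueError(f"effect references unknown gene(s): {sorted(missing)}")
        return list(eff.target_genes), ann
    chrom, pos = eff.locus
    if eff.kind == "cis":
        local = [g for g in genes if ann[g].chromosome == chrom]
        target = min(local, key=lambda g: abs(ann[g].start - pos))
        ann = dict(ann)
        ann[target] = GeneAnnotation(target, chrom, realized["position"])
        return [target], ann
    away = [g for g in genes if ann[g].chromosome != chrom]
    if len(away) < eff.n_targets:
        raise ValueError("not enough genes on other chromosomes for trans_band targets")
    picked = rng.choice(len(away), size=eff.n_targets, replace=False)
    return [away[i] for i in sorted(picked)], ann


def simulate_expression(
    genos: GenotypeMatrix,
    truth: SyntheticTruth,
    config: SimConfig,
    annotation: Optional[dict[str, GeneAnnotation]] = None,
) -> tuple[ExpressionMatrix, dict[str, GeneAnnotation]]:
    """Simulate fpkm expression for all mpRIL and parental samples.

    On the log2 scale each gene is baseline + planted genetic effects +
    developmental-covariate loading + Gaussian noise; fpkm is 2 to that
    value.  Parental replicates share their line's genetics and
    covariate and differ only by noise.  Fills ``truth.true_h2`` and the
    per-effect target lists.
    """
    if annotation is None:
        annotation = simulate_annotation(config)
    lines = [l for l in genos.lines if l not in FOUNDERS]
    if not all(f in genos.lines for f in FOUNDERS):
        raise ValueError("genotype matrix must include the four founder columns")

    rng_b = _rng(config.seed, "baseline")
    rng_c = _rng(config.seed, "covariate")
    rng_n = _rng(config.seed, "noise")
    rng_t = _rng(config.seed, "targets")

    genes = list(annotation)
    n_genes = len(genes)
    gi = {g: i for i, g in enumerate(genes)}

    baseline = rng_b.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    low = rng_b.random(n_genes) < config.low_expressed_fraction
    baseline[low] = rng_b.normal(-7.0, 1.0, size=int(low.sum()))
    loading = rng_c.normal(0.0, 1.0, size=n_genes)

    all_lines = lines + list(FOUNDERS)
    covariate = pd.Series(
        rng_c.normal(0.0, config.dev_covariate_sd, size=len(all_lines)), index=all_lines
    )

    # genetic values per gene x line from planted effects
    genetic = np.zeros((n_genes, len(all_lines)))
    marker_rows = {m.id: i for i, m in enumerate(genos.markers)}
    geno_arr = genos.alleles[all_lines].to_numpy(dtype=float)
    for eff, realized in zip(config.effects, truth.effects_realized):
        targets, annotation = _resolve_targets(eff, realized, annotation, rng_t)
        realized["targets"] = list(targets)
        x = geno_arr[marker_rows[realized["marker"]]]
        # effect sizes are in residual-SD units; with no residual noise the
        # unit falls back to 1 so a planted effect of size d shifts by d
        scale = config.noise_sd if config.noise_sd > 0 else 1.0
        for g in targets:
            genetic[gi[g]] += eff.effect_size * scale * x

    # true narrow-sense heritability over the mpRIL lines
    ril_idx = [all_lines.index(l) for l in lines]
    var_g = genetic[:, ril_idx].var(axis=1, ddof=0)
    var_env = loading**2 * config.dev_covariate_sd**2 + config.noise_sd**2
    with np.errstate(invalid="ignore"):
        truth.true_h2 = pd.Series(var_g / (var_g + var_env), index=genes).fillna(0.0)

    samples: list[SampleInfo] = [SampleInfo(l, "mpRIL", l, 1) for l in lines]
    for f in FOUNDERS:
        samples += [SampleInfo(f"{f}_r1", "parent", f, 1), SampleInfo(f"{f}_r2", "parent", f, 2)]

    cols = np.empty((n_genes, len(samples)))
    for j, s in enumerate(samples):
        li = all_lines.index(s.line)
        log2val = (
            baseline
            + genetic[:, li]
            + loading * covariate[s.line]
            + rng_n.normal(0.0, config.noise_sd, size=n_genes)
        )
        cols[:, j] = np.exp2(log2val)
    expr = ExpressionMatrix(
        pd.DataFrame(cols, index=pd.Index(genes, name="gene"), columns=[s.id for s in samples]),
        samples,
        "raw_fpkm",
    )
    return expr, annotation


def simulate_go(
    annotation: dict[str, GeneAnnotation], truth: SyntheticTruth, config: SimConfig
) -> dict[str, set[str]]:
    """Random GO-style gene sets, plus one coherent term per planted trans-band.

    Each trans-band gets a term covering ~60% of its target genes so
    that enrichment on a recovered band is detectable.
    """
    rng = _rng(config.seed, "go")
    genes = list(annotation)
    go_map: dict[str, set[str]] = {}
    for t in range(config.n_go_terms):
        size = int(np.exp(rng.uniform(np.log(5), np.log(200))))
        size = min(size, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        go_map[f"GO:{7000000 + t}"] = {genes[i] for i in members}
    band_i = 0
    for realized in truth.effects_realized:
        if realized["kind"] != "trans_band" or "targets" not in realized:
            continue
        targets = realized["targets"]
        k = max(1, int(0.6 * len(targets)))
        members = rng.choice(len(targets), size=k, replace=False)
        go_map[f"GO:{8000000 + band_i}"] = {targets[i] for i in members}
        band_i += 1
    return go_map


def simulate_dataset(config: SimConfig):
    """Run the full generator: genotypes, truth, expression, annotation, GO map."""
    genos, truth = simulate_genomes(config)
    expr, annotation = simulate_expression(genos, truth, config)
    go_map = simulate_go(annotation, truth, config)
    return genos, expr, annotation, go_map, truth


def simulate_polygenic_phenotypes(
    K: np.ndarray, h2: float, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw phenotypes with a given narrow-sense heritability on a kinship.

    y = g + e with g ~ N(0, h2 * K) and e ~ N(0, (1 - h2) * I); returns
    an n_lines x n_genes array.  Used for heritability calibration.
    """
    n = K.shape[0]
    w, U = np.linalg.eigh((K + K.T) / 2)
    w = np.clip(w, 0.0, None)
    root = U * np.sqrt(w)
    g = root @ rng.standard_normal((n, n_genes))
    e = rng.standard_normal((n, n_genes))
    return np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_dataset(
    outdir: str | Path,
    genos: GenotypeMatrix,
    expr: ExpressionMatrix,
    annotation: dict[str, GeneAnnotation],
    go_map: dict[str, set[str]],
    truth: SyntheticTruth,
) -> None:
    """Write the simulated dataset in the pipeline's tab-delimited formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(genos, outdir / "genotypes.tsv")
    write_expression(expr, outdir / "expression.tsv")
    write_samples(expr.samples, outdir / "samples.tsv")
    write_annotation(annotation, outdir / "annotation.tsv")
    write_go_map(go_map, outdir / "go_associations.tsv")
    rows = []
    for r in truth.effects_realized:
        for g in r.get("targets", []):
            rows.append(
                {
                    "kind": r["kind"],
                    "marker": r["marker"],
                    "chromosome": r["chromosome"],
                    "position": r["position"],
                    "sdp": r["sdp"],
                    "effect_size": r["effect_size"],
                    "target": g,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
    truth.true_h2.rename("true_h2").to_csv(outdir / "truth_h2.tsv", sep="\t", index_label="gene")
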