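"""End-to-end pipeline driver.

Stage order follows the analysis design: filter consistently detected
genes on log2 fpkm, depth-normalize the survivors, build log2 and
gene-centered log2-ratio layers, then run parental differential
expression and transgression, kinship/REML heritability, the eQTL scan
with its permutation threshold, cis/trans classification and SDP
tabulation, trans-band detection and GO enrichment.  All tables are
tab-delimited; a JSON manifest records the configuration, seeds, and
per-stage counts.  Every stage draws randomness from a named substream
of the master seed, so reruns with the same seed are byte-identical and
stages can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .data import (
    ExpressionMatrix,
    GenotypeMatrix,
    filter_expressed_genes,
    log2_and_ratio,
    log2_fpkm,
    normalize_expression,
    pca_qc,
    read_annotation,
    read_expression,
    read_genotypes,
    read_go_map,
    read_samples,
)
from .eqtl import (
    ThresholdNotFound,
    call_peaks_frame,
    classify_records_frame,
    permutation_fpr_threshold,
    permuted_peaks,
    scan_many,
    tabulate_sdp,
)
from .heritability import KinshipEigen, heritability_analysis, kinship
from .parental import deg_fpr, pairwise_de, replicate_correlation, transgression, transgression_fpr
from .sdp import FOUNDERS
from .simulate import SimConfig, _rng, simulate_dataset, write_dataset
from .transbands import bands_frame, detect_trans_bands, go_enrichment

log = logging.getLogger("mpeqtl")


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        genos, expr, annotation, go_map, truth = simulate_dataset(sim)
        chrom_lengths = {c: L for c, L in sim.chromosomes}
        return genos, expr, annotation, go_map, truth, chrom_lengths
    for key in ("genotypes", "expression", "samples", "annotation"):
        if getattr(config, key) is None:
            raise ValueError(f"config must set '{key}' (or a 'simulate' block)")
    genos = read_genotypes(config.genotypes)
    samples = read_samples(config.samples)
    expr = read_expression(config.expression, samples, "raw_fpkm")
    annotation = read_annotation(config.annotation)
    go_map = read_go_map(config.go_associations) if config.go_associations else {}
    lengths: dict[str, int] = {}
    for m in genos.markers:
        lengths[m.chromosome] = max(lengths.get(m.chromosome, 0), m.position)
    return genos, expr, annotation, go_map, None, lengths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; write tables and return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    a = config.analysis
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {},
    }

    genos, raw, annotation, go_map, truth, chrom_lengths = _load_inputs(config)
    if config.simulate is not None:
        write_dataset(out / "simulated", genos, raw, annotation, go_map, truth)

    # --- filtering and normalization -----------------------------------
    log2_raw = log2_fpkm(raw, a.pseudocount)
    kept = filter_expressed_genes(log2_raw, a.expression_filter)
    if not kept:
        raise RuntimeError("stage filter: no genes pass the expression filter")
    manifest["counts"]["genes_total"] = len(raw.genes)
    manifest["counts"]["genes_expressed"] = len(kept)
    raw_f = raw.subset_genes(kept)
    norm = normalize_expression(raw_f)
    log2m, ratios = log2_and_ratio(norm, a.pseudocount)

    scores, varfrac = pca_qc(ratios, n_components=min(4, len(ratios.samples)))
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
    pd.Series(varfrac, index=scores.columns, name="variance_fraction").to_csv(
        out / "pca_variance.tsv", sep="\t", index_label="component"
    )

    ril_lines = [s.line for s in ratios.ril_samples()]
    ril_ids = [s.id for s in ratios.ril_samples()]

    # --- parental analysis ---------------------------------------------
    if config.run_parental:
        log.info("stage parental: Tukey HSD, replicate QC, transgression")
        de = pairwise_de(log2m, a.tukey_alpha)
        de.pvalues.to_csv(out / "parental_tukey_p.tsv", sep="\t", index_label="gene")
        de.per_pair_counts.rename("n_deg").to_csv(out / "parental_deg_counts.tsv", sep="\t", index_label="pair")
        de.intersection_counts.rename("n_genes").to_csv(
            out / "parental_deg_intersections.tsv", sep="\t", index_label="pairs"
        )
        fpr, n_deg, _ = deg_fpr(log2m, a.deg_fpr_permutations, _rng(config.seed, "deg_fpr"), a.tukey_alpha)
        manifest["counts"]["deg"] = n_deg
        manifest["counts"]["deg_fpr"] = None if np.isnan(fpr) else round(float(fpr), 6)
        replicate_correlation(log2m).to_csv(out / "parental_replicate_r.tsv", sep="\t", index_label="line")
        tg = transgression(log2m, a.transgression_k_sd, a.transgression_count)
        tg.to_csv(out / "transgression.tsv", sep="\t", index_label="gene")
        tg_fpr, n_tg, _ = transgression_fpr(
            log2m,
            a.transgression_fpr_permutations,
            _rng(config.seed, "transgression_fpr"),
            a.transgression_k_sd,
            a.transgression_count,
        )
        manifest["counts"]["transgressive"] = n_tg
        manifest["counts"]["transgression_fpr"] = None if np.isnan(tg_fpr) else round(float(tg_fpr), 6)

    # --- heritability ---------------------------------------------------
    ril_geno = genos.subset_lines([l for l in genos.lines if l not in FOUNDERS])
    if config.run_heritability:
        log.info("stage heritability: kinship + REML with %d permutations", a.h2_permutations)
        K = kinship(ril_geno.alleles)
        K.to_csv(out / "kinship.tsv", sep="\t", index_label="line")
        eig = KinshipEigen.from_kinship(K)
        Y = ratios.values[ril_ids].copy()
        Y.columns = ril_lines
        h2 = heritability_analysis(
            Y, eig, a.h2_permutations, _rng(config.seed, "h2_perm"), a.h2_quantile
        )
        h2.to_csv(out / "heritability.tsv", sep="\t", index_label="gene")
        manifest["counts"]["h2_significant"] = int(h2["significant"].sum())

    # --- eQTL mapping ---------------------------------------------------
    records = None
    if config.run_eqtl:
        log.info("stage eqtl: single-marker scan over %d markers", ril_geno.n_markers)
        Y = ratios.values[ril_ids].copy()
        Y.columns = ril_lines
        nlp, slopes = scan_many(Y, ril_geno, a.eqtl_min_class, return_slopes=True)
        observed_peaks = nlp.to_numpy().max(axis=1)
        if a.eqtl_threshold_override is not None:
            threshold = float(a.eqtl_threshold_override)
        else:
            perm = permuted_peaks(Y, ril_geno, _rng(config.seed, "eqtl_perm"), a.eqtl_min_class)
            threshold = permutation_fpr_threshold(
                observed_peaks, perm, a.eqtl_fpr_ratio, a.eqtl_grid_step
            )
        manifest["counts"]["eqtl_threshold"] = threshold
        peaks = call_peaks_frame(nlp, slopes, ril_geno, threshold)
        sig = peaks[peaks["significant"]]
        records = classify_records_frame(sig, annotation, a.window)
        peaks.join(records["type"]).to_csv(out / "eqtl_records.tsv", sep="\t", index_label="gene")
        if config.write_profiles:
            nlp.to_csv(out / "eqtl_profiles.tsv", sep="\t", index_label="gene")
        table = tabulate_sdp(records)
        table.to_csv(out / "eqtl_sdp_table.tsv", sep="\t")
        n_cis = int((records["type"] == "cis").sum())
        n_trans = int((records["type"] == "trans").sum())
        manifest["counts"].update(
            {"eqtl": len(records), "eqtl_cis": n_cis, "eqtl_trans": n_trans}
        )
        if len(records) != n_cis + n_trans:
            raise RuntimeError("stage eqtl: cis + trans does not equal total eQTLs")

    # --- trans-bands and enrichment ------------------------------------
    if config.run_trans_bands:
        if records is None:
            raise RuntimeError("stage trans_bands requires the eqtl stage")
        log.info("stage trans_bands: hotspot detection + GO enrichment")
        bands = detect_trans_bands(
            records, ril_geno, a.trans_band_min_count, a.window, chrom_lengths
        )
        bf = bands_frame(bands)
        bf.to_csv(out / "trans_bands.tsv", sep="\t", index_label="band")
        manifest["counts"]["trans_bands"] = len(bands)
        manifest["counts"]["trans_eqtls_in_bands"] = int(sum(b.count for b in bands))
        background = set(kept)
        enrich_rows = []
        for name, band in zip(bf.index, bands):
            if not go_map or not band.genes:
                continue
            res = go_enrichment(
                set(band.genes) & background, go_map, background, a.go_p, a.go_min_set
            )
            res = res.reset_index()
            res.insert(0, "band", name)
            enrich_rows.append(res)
        enr = (
            pd.concat(enrich_rows, ignore_index=True)
            if enrich_rows
            else pd.DataFrame(
                columns=["band", "term", "overlap", "term_size", "test_size", "background_size", "p_value"]
            )
        )
        enr.to_csv(out / "trans_band_go.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
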