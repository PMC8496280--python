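# mpeqtl

Expression genetics for multiparental recombinant inbred lines (mpRILs).

`mpeqtl` implements an end-to-end analysis pipeline for gene-expression
variation in a four-founder *Caenorhabditis elegans* cross (wild isolates
JU1511, JU1926, JU1931, JU1941):

- **Parental differential expression** — per-gene one-way ANOVA with
  Tukey–Kramer studentized-range p-values over all six founder pairs, with a
  label-permutation false-positive rate (FPR) for the DEG count, plus
  replicate-correlation QC.
- **Transgressive segregation** — counts of mpRILs whose expression falls
  outside the parental envelope (extreme parental line means ± *k* pooled
  within-line SDs), again with a permutation FPR.
- **Narrow-sense heritability** — allele-sharing kinship matrix plus
  profile-REML fits of the mixed model *y* = μ + *g* + *e* per gene, with
  per-gene permutation significance thresholds.
- **eQTL mapping** — single-marker linear-model scans over all genes and
  markers, peak calling (one eQTL per gene), a genome-wide significance
  threshold set by a permutation FP/TP criterion, and cis/trans
  classification by a 1-Mbp window around the gene start.
- **Trans-band detection** — hotspots where many trans-eQTLs of one SNP
  distribution pattern (SDP) co-locate, with hypergeometric GO-term
  enrichment of band members.
- **Cross-study comparison** — per-gene overlap of eQTL calls against
  external experiments.
- **Synthetic data generator** — founder-mosaic genomes, SDP-weighted
  markers, and expression with planted cis effects, trans-band regulators,
  a shared developmental covariate, and noise — all with a ground-truth
  ledger, so every stage can be validated by parameter recovery.

With four founders a biallelic SNP partitions the strains into 7
informative carrier patterns (a subset and its complement are
indistinguishable): three balanced splits (labeled `12`, `13`, `14` after
the founders grouped with JU1511) and four singleton patterns labeled by
the isolate name.

## Quick start

Everything is driven by a YAML config. The example below simulates a small
population with one planted cis-eQTL and one planted trans-band, then runs
every stage:

```yaml
# config.yaml
outdir: results/demo
seed: 7
simulate:
  n_lines: 100
  n_markers: 400
  n_genes: 800
  effects:
    - {kind: cis, locus: [II, 7000000], effect_size: 6.0, sdp: JU1941}
    - {kind: trans_band, locus: [V, 10000000], effect_size: 2.0, sdp: JU1931, n_targets: 60}
analysis:
  h2_permutations: 100
  trans_band_min_count: 30
  transgression_count: 10
  go_p: 1.0e-3
```

```
$ mpeqtl run-all --config config.yaml
wrote results/demo/manifest.json; counts: {'genes_total': 800, 'genes_expressed': 767,
'deg': 0, 'deg_fpr': None, 'transgressive': 174, 'transgression_fpr': 0.515517,
'h2_significant': 120, 'eqtl_threshold': 6.65, 'eqtl': 43, 'eqtl_cis': 1,
'eqtl_trans': 42, 'trans_bands': 1, 'trans_eqtls_in_bands': 42}

$ column -t results/demo/trans_bands.tsv
band  sdp     chromosome  peak_bp   left_bp  right_bp  peak_mbp  left_mbp  right_mbp  n_eqtls
TB1   JU1931  V           10063809  9063809  11063809  10.06     9.06      11.06      42
```

Both planted effects surface: the cis-eQTL as the single cis call, the
regulator as a JU1931-pattern trans-band within one marker spacing of the
planted locus. (At this small scale the parental DEG count is 0 — with two
replicates per founder the studentized-range critical value at α = 0.001 is
16.8, which modest planted effects do not reach; the manifest reports the
FPR as undefined rather than dividing by zero.)

Real data comes in as tab-delimited tables instead of a `simulate` block:
`genotypes` (marker, chromosome, position, SDP, one column per line, `NA`
for missing), `expression` (fpkm, genes × samples), `samples` (id, role
`parent`/`mpRIL`, line, replicate), `annotation` (gene, chromosome, start),
and optional `go_associations` (gene, term).

Other subcommands run single stages over the same config: `mpeqtl
simulate`, `parental`, `heritability`, `map-eqtl`, `trans-bands`, and
`mpeqtl compare --ours a.tsv --theirs b.tsv` for cross-study overlap.
Python APIs mirror the stages (`mpeqtl.parental`, `mpeqtl.heritability`,
`mpeqtl.eqtl`, `mpeqtl.transbands`, `mpeqtl.crossstudy`,
`mpeqtl.simulate`); see `docs/methods.md` for the statistical definitions
and parameter defaults.

## Reproducibility

Every stage draws randomness from a named substream of the single master
seed, so `run-all` with the same config and seed is byte-identical, and the
manifest records version, seed, config, and per-stage counts.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the pipeline plus the calibration and recovery studies (null h²
flag-rate calibration, null eQTL threshold behavior, planted cis
power/localization, trans-band recovery, transgression FPRs) and writes the
headline quantities as JSON.

## Testing

```
pytest -q
```

The suite covers unit oracles (every statistical kernel checked against an
independent implementation: scipy Tukey HSD, dense-grid REML with direct
matrices, closed-form regression t-tests, exact hypergeometric
enumeration), property-based invariants, and an acceptance layer
(`tests/test_acceptance.py`) with published-table arithmetic, null
calibration, parameter recovery, and end-to-end determinism.
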