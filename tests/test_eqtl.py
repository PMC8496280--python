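"""Single-marker eQTL scans, peak calling, thresholding, cis/trans tables."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import make_genotypes

from mpeqtl.data import CHROMOSOMES, GeneAnnotation
from mpeqtl.eqtl import (
    ThresholdNotFound,
    call_peaks_frame,
    classify_cis_trans,
    classify_records_frame,
    permutation_fpr_threshold,
    permuted_peaks,
    scan_gene,
    scan_many,
    tabulate_sdp,
    EqtlRecord,
)
from mpeqtl.sdp import SDP_LABELS


def _frame(Y, n):
    return pd.DataFrame(
        np.atleast_2d(Y), index=[f"g{i}" for i in range(np.atleast_2d(Y).shape[0])],
        columns=[f"L{j}" for j in range(n)],
    )


class TestScan:
    def test_matches_linregress_t_test(self):
        rng = np.random.default_rng(31)
        n = 30
        X = rng.integers(0, 2, size=(12, n)).astype(float)
        genos = make_genotypes(X)
        Y = rng.normal(size=(8, n))
        nlp = scan_many(_frame(Y, n), genos)
        for g in range(8):
            for m in range(12):
                if min((X[m] == 0).sum(), (X[m] == 1).sum()) < 5:
                    continue
                res = scipy.stats.linregress(X[m], Y[g])
                assert nlp.iloc[g, m] == pytest.approx(
                    -np.log10(res.pvalue), abs=1e-10
                )

    def test_perfect_separation_scores_high(self):
        n = 30
        X = np.zeros((1, n))
        X[0, : n // 2] = 1.0
        y = X[0] * 2.0
        nlp = scan_many(_frame(y, n), make_genotypes(X))
        assert nlp.iloc[0, 0] > 15

    def test_affine_transform_of_phenotype_preserves_p(self):
        rng = np.random.default_rng(32)
        n = 24
        X = rng.integers(0, 2, size=(6, n)).astype(float)
        Y = rng.normal(size=(4, n))
        genos = make_genotypes(X)
        a = scan_many(_frame(Y, n), genos)
        b = scan_many(_frame(-3.0 * Y + 2.0, n), genos)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_monomorphic_and_small_class_markers_score_zero(self):
        n = 20
        X = np.stack([np.zeros(n), np.r_[np.ones(4), np.zeros(n - 4)],
                      np.r_[np.ones(10), np.zeros(10)]])
        y = np.r_[np.ones(10), np.zeros(10)] + 0.01 * np.arange(n)
        nlp = scan_many(_frame(y, n), make_genotypes(X), min_class=5)
        assert nlp.iloc[0, 0] == 0.0
        assert nlp.iloc[0, 1] == 0.0
        assert nlp.iloc[0, 2] > 3

    def test_missing_genotypes_use_complete_lines_only(self):
        rng = np.random.default_rng(33)
        n = 40
        x = rng.integers(0, 2, size=n).astype(float)
        y = rng.normal(size=n)
        X = np.stack([x, x.copy()])
        X[1, :6] = np.nan
        nlp = scan_many(_frame(y, n), make_genotypes(X))
        res = scipy.stats.linregress(x[6:], y[6:])
        assert nlp.iloc[0, 1] == pytest.approx(-np.log10(res.pvalue), abs=1e-10)
        assert nlp.iloc[0, 0] != nlp.iloc[0, 1]

    def test_constant_gene_scores_zero_everywhere(self):
        n = 20
        X = np.r_[np.ones(10), np.zeros(10)][None, :]
        nlp = scan_many(_frame(np.full(n, 5.0), n), make_genotypes(X))
        assert (nlp.to_numpy() == 0.0).all()

    def test_scan_gene_matches_scan_many(self):
        rng = np.random.default_rng(34)
        n = 26
        X = rng.integers(0, 2, size=(9, n)).astype(float)
        y = pd.Series(rng.normal(size=n), index=[f"L{j}" for j in range(n)], name="gX")
        genos = make_genotypes(X)
        prof = scan_gene(y, genos)
        nlp = scan_many(y.to_frame().T, genos)
        assert np.allclose(prof.neglogp, nlp.iloc[0].to_numpy())
        assert prof.gene == "gX"


class TestPeaks:
    def test_tie_breaks_chromosome_order_then_position(self):
        n = 20
        x = np.r_[np.ones(10), np.zeros(10)]
        X = np.stack([x, x, x])  # identical markers -> identical p
        genos = make_genotypes(
            X, chroms=["II", "II", "V"], positions=[500, 900, 100], sdps=["14", "13", "12"]
        )
        # identical markers tie on p; the II:500 one wins (chromosome, then position)
        nlp, slopes = scan_many(
            _frame(x + np.random.default_rng(35).normal(0, 0.1, n), n),
            genos, return_slopes=True,
        )
        rec = call_peaks_frame(nlp, slopes, genos, threshold=1.0)
        assert rec.iloc[0]["chromosome"] == "II"
        assert rec.iloc[0]["position"] == 500

    def test_significance_is_strict(self):
        nlp = pd.DataFrame([[5.35]], index=["g0"], columns=["m0"])
        slopes = pd.DataFrame([[1.0]], index=["g0"], columns=["m0"])
        genos = make_genotypes(np.zeros((1, 10)))
        assert not call_peaks_frame(nlp, slopes, genos, threshold=5.35)["significant"].iloc[0]
        nlp.iloc[0, 0] = 5.36
        assert call_peaks_frame(nlp, slopes, genos, threshold=5.35)["significant"].iloc[0]


class TestThreshold:
    def test_separated_distributions_give_smallest_sufficient_grid_value(self):
        observed = np.r_[np.full(300, 8.0), np.full(700, 1.0)]
        permuted = np.full(1000, 2.0)
        # at T in (2, 8]: fp = 0, tp = 300 -> ratio 0 < 0.01; smallest grid T above 2
        t = permutation_fpr_threshold(observed, permuted, ratio=0.01, grid_step=0.05)
        assert t == pytest.approx(2.05)

    def test_ratio_counts_average_over_rounds(self):
        observed = np.r_[np.full(100, 8.0), np.full(900, 1.0)]
        # 5 rounds stacked: 20 permuted peaks at 7.0 per round -> fp=20 above 6
        permuted = np.r_[np.full(100, 7.0), np.full(4900, 0.5)]
        # at T slightly above 7: fp = 0 -> passes; below 7: fp/round = 20, tp=100 -> 0.2
        t = permutation_fpr_threshold(observed, permuted, ratio=0.01, grid_step=0.05)
        assert t == pytest.approx(7.05)

    def test_inseparable_distributions_raise_with_best_ratio(self):
        observed = np.full(50, 3.0)
        permuted = np.full(50, 3.0)
        with pytest.raises(ThresholdNotFound) as exc:
            permutation_fpr_threshold(observed, permuted, ratio=0.01)
        assert exc.value.best_ratio == pytest.approx(1.0)

    def test_permuted_peaks_reproducible_and_null_like(self):
        rng = np.random.default_rng(36)
        n = 60
        X = rng.integers(0, 2, size=(40, n)).astype(float)
        genos = make_genotypes(X)
        x = X[0]
        Y = np.tile(x * 3.0, (20, 1)) + rng.normal(0, 0.3, size=(20, n))
        Yf = _frame(Y, n)
        obs = scan_many(Yf, genos).to_numpy().max(axis=1)
        p1 = permuted_peaks(Yf, genos, np.random.default_rng(9))
        p2 = permuted_peaks(Yf, genos, np.random.default_rng(9))
        assert np.array_equal(p1, p2)
        assert np.median(obs) > np.median(p1) + 3


class TestCisTrans:
    ann = {
        "g0": GeneAnnotation("g0", "II", 5_000_000),
        "g1": GeneAnnotation("g1", "III", 5_000_000),
    }

    def _rec(self, gene, chrom, pos):
        return EqtlRecord(gene, "m", chrom, pos, "12", 10.0, 1.0, True)

    @pytest.mark.parametrize(
        "chrom, pos, expect",
        [
            ("II", 5_000_000, "cis"),
            ("II", 6_000_000, "cis"),      # exactly 1 Mbp away: inclusive
            ("II", 4_000_000, "cis"),
            ("II", 6_000_001, "trans"),
            ("III", 5_000_000, "trans"),   # same position, other chromosome
        ],
    )
    def test_window_boundaries(self, chrom, pos, expect):
        assert classify_cis_trans(self._rec("g0", chrom, pos), self.ann) == expect

    def test_missing_annotation_rejected(self):
        with pytest.raises(KeyError, match="gX"):
            classify_cis_trans(self._rec("gX", "II", 1), self.ann)

    def test_frame_classification_matches_scalar(self):
        recs = pd.DataFrame(
            {
                "marker": ["a", "b"],
                "chromosome": ["II", "II"],
                "position": [5_500_000, 5_500_000],
                "sdp": ["12", "14"],
                "neglogp": [9.0, 9.0],
                "slope": [1.0, 1.0],
                "significant": [True, True],
            },
            index=pd.Index(["g0", "g1"], name="gene"),
        )
        out = classify_records_frame(recs, self.ann)
        assert list(out["type"]) == ["cis", "trans"]


class TestSdpTable:
    def test_counts_partition_and_totals(self):
        rng = np.random.default_rng(37)
        n = 200
        sdps = rng.choice(SDP_LABELS, size=n)
        chroms = rng.choice(CHROMOSOMES, size=n)
        types = rng.choice(["cis", "trans"], size=n, p=[0.3, 0.7])
        recs = pd.DataFrame(
            {"sdp": sdps, "chromosome": chroms, "type": types},
            index=[f"g{i}" for i in range(n)],
        )
        table = tabulate_sdp(recs)
        assert table.loc["Total", ("cis", "Tot")] == (types == "cis").sum()
        assert table.loc["Total", ("trans", "Tot")] == (types == "trans").sum()
        for sdp in SDP_LABELS:
            for t in ("cis", "trans"):
                want = ((sdps == sdp) & (types == t)).sum()
                assert table.loc[sdp, (t, "Tot")] == want
        body = table.loc[list(SDP_LABELS), [(t, c) for t in ("cis", "trans") for c in CHROMOSOMES]]
        assert body.to_numpy().sum() == n

    def test_empty_records_give_zero_table(self):
        recs = pd.DataFrame(columns=["sdp", "chromosome", "type"])
        table = tabulate_sdp(recs)
        assert (table.to_numpy() == 0).all()


def test_planted_cis_eqtl_is_recovered(planted_dataset):
    from mpeqtl.data import filter_expressed_genes, log2_and_ratio, log2_fpkm, normalize_expression

    cfg, genos, expr, annotation, go_map, truth = planted_dataset
    log2 = log2_fpkm(expr)
    kept = filter_expressed_genes(log2, threshold=-5.0)
    norm = normalize_expression(expr.subset_genes(kept))
    _, ratio = log2_and_ratio(norm)
    rils = ratio.ril_samples()
    Y = ratio.values[[s.id for s in rils]]
    Y.columns = [s.line for s in rils]
    cis = truth.effects_realized[0]
    target = cis["targets"][0]
    assert target in Y.index
    nlp, slopes = scan_many(Y, genos.subset_lines(list(Y.columns)), return_slopes=True)
    recs = call_peaks_frame(nlp, slopes, genos, threshold=5.0)
    peak = recs.loc[target]
    assert peak["significant"]
    assert peak["chromosome"] == "II"
    assert abs(peak["position"] - 7_000_000) < 2_000_000
    assert classify_cis_trans(
        EqtlRecord(target, peak["marker"], peak["chromosome"], int(peak["position"]),
                   peak["sdp"], peak["neglogp"], peak["slope"], True),
        annotation,
    ) == "cis"
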