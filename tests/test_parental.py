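"""Tukey HSD between parental lines, replicate QC, and transgression."""

import numpy as np
import pytest
import scipy.stats

from conftest import make_expression, parental_samples

from mpeqtl.data import ExpressionMatrix, SampleInfo
from mpeqtl.parental import (
    deg_fpr,
    pairwise_de,
    replicate_correlation,
    transgression,
    transgression_fpr,
    tukey_pairwise,
    tukey_q_critical,
)
from mpeqtl.sdp import FOUNDERS

LABELS = [f for f in FOUNDERS for _ in range(2)]


def _parental_matrix(values, layer="log2"):
    return make_expression(values, layer=layer, roles=parental_samples())


class TestTukey:
    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(42)
        Y = rng.normal(size=(50, 8)) + rng.normal(scale=2, size=(50, 1))
        ours = tukey_pairwise(Y, LABELS)
        for g in range(50):
            groups = [Y[g, 2 * i : 2 * i + 2] for i in range(4)]
            res = scipy.stats.tukey_hsd(*groups)
            for col in ours.columns:
                a, b = col.split("-")
                i, j = FOUNDERS.index(a), FOUNDERS.index(b)
                assert ours.iloc[g][col] == pytest.approx(
                    res.pvalue[i, j], abs=1e-6
                )

    def test_shifted_group_drives_only_its_pairs(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0.0, 0.01, size=(5, 8))
        Y[:, 2:4] += 100.0  # shift JU1926 only
        p = tukey_pairwise(Y, LABELS)
        involves = [c for c in p.columns if "JU1926" in c]
        others = [c for c in p.columns if "JU1926" not in c]
        assert (p[involves].to_numpy() < 1e-4).all()
        assert (p[others].to_numpy() > 1e-4).all()

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 8))
        p1 = tukey_pairwise(Y, LABELS)
        p2 = tukey_pairwise(3.5 * Y - 7.0, LABELS)
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)

    def test_identical_values_everywhere_give_p_one(self):
        p = tukey_pairwise(np.full((3, 8), 2.0), LABELS)
        assert (p.to_numpy() == 1.0).all()

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            tukey_pairwise(np.zeros((2, 4)), list(FOUNDERS))

    def test_critical_value_is_scipy_isf(self):
        assert tukey_q_critical(0.001, 4, 4) == pytest.approx(
            scipy.stats.studentized_range.isf(0.001, 4, 4), rel=1e-12
        )


class TestPairwiseDe:
    def test_counts_and_intersections_on_constructed_genes(self):
        # gene 0: JU1511 hugely shifted -> significant in its 3 pairs
        # gene 1: pure tiny noise -> nothing significant
        rng = np.random.default_rng(3)
        Y = rng.normal(0.0, 0.01, size=(2, 8))
        Y[0, :2] += 100.0
        res = pairwise_de(_parental_matrix(Y), alpha=0.001)
        assert res.n_deg == 1
        sig_pairs = set(res.significant.columns[res.significant.iloc[0]])
        assert sig_pairs == {
            "JU1511-JU1926",
            "JU1511-JU1931",
            "JU1511-JU1941",
        }
        assert res.per_pair_counts.sum() == 3
        assert res.intersection_counts.sum() == 1
        key = res.intersection_counts.index[0]
        assert set(key.split("&")) == sig_pairs

    def test_requires_parental_samples(self):
        with pytest.raises(ValueError, match="parental"):
            pairwise_de(make_expression(np.zeros((2, 3)), layer="log2"))


class TestDegFpr:
    def test_null_fpr_near_one(self):
        """Under exchangeable labels, permuted counts match observed on average."""
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(20000, 8))
        fpr, observed, perm = deg_fpr(
            _parental_matrix(Y), n_perm=40, rng=np.random.default_rng(0), alpha=0.05
        )
        assert observed > 100
        assert 0.7 < fpr < 1.3

    def test_strong_signal_gives_small_fpr(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 0.05, size=(300, 8))
        Y[:, :2] += 10.0  # every gene differs in JU1511
        fpr, observed, perm = deg_fpr(
            _parental_matrix(Y), n_perm=20, rng=np.random.default_rng(1)
        )
        assert observed == 300
        assert fpr < 0.3

    def test_zero_observed_warns_and_returns_nan(self):
        Y = np.random.default_rng(9).normal(0, 1e-6, size=(3, 8))
        with pytest.warns(UserWarning, match="FPR undefined"):
            fpr, observed, _ = deg_fpr(
                _parental_matrix(Y), n_perm=3, rng=np.random.default_rng(2)
            )
        assert observed == 0 and np.isnan(fpr)

    def test_same_rng_seed_reproduces(self):
        Y = np.random.default_rng(10).normal(size=(200, 8))
        m = _parental_matrix(Y)
        r1 = deg_fpr(m, 5, np.random.default_rng(11), alpha=0.05)
        r2 = deg_fpr(m, 5, np.random.default_rng(11), alpha=0.05)
        assert r1[0] == r2[0] and np.array_equal(r1[2], r2[2])


class TestReplicateCorrelation:
    def test_exact_correlations(self):
        g = np.arange(10.0)
        Y = np.stack(
            [
                g, g,                       # JU1511: r = 1
                g, -g,                      # JU1926: r = -1
                g, 2 * g + 5,               # JU1931: r = 1 (affine)
                g, g[::-1].copy() * 0 + np.random.default_rng(4).normal(size=10),
            ],
            axis=1,
        )
        r = replicate_correlation(_parental_matrix(Y))
        assert r["JU1511"] == pytest.approx(1.0)
        assert r["JU1926"] == pytest.approx(-1.0)
        assert r["JU1931"] == pytest.approx(1.0)
        assert abs(r["JU1941"]) < 0.6

    def test_missing_replicate_rejected_at_construction(self):
        roles = parental_samples()[:-1] + [SampleInfo("x", "mpRIL", "x", 1)]
        with pytest.raises(ValueError, match="JU1941"):
            make_expression(np.zeros((4, 8)), layer="log2", roles=roles)


def _mixed_matrix(parent_Y, ril_Y):
    roles = parental_samples() + [
        SampleInfo(f"R{j}", "mpRIL", f"R{j}", 1) for j in range(ril_Y.shape[1])
    ]
    return make_expression(np.hstack([parent_Y, ril_Y]), layer="log2", roles=roles)


class TestTransgression:
    def test_hand_computed_envelope_and_counts(self):
        # line means 1,2,3,4; every line's replicates are mean +/- 0.5
        # pooled SD = sqrt(4 * 2 * 0.25 / 4) = sqrt(0.5)... use exact dev 0.5
        parent = np.array([[0.5, 1.5, 1.5, 2.5, 2.5, 3.5, 3.5, 4.5]])
        # pooled SD: SS = 8 * 0.25 = 2, df = 4 -> sd = sqrt(0.5)
        sd = np.sqrt(0.5)
        upper, lower = 4 + 2 * sd, 1 - 2 * sd
        rils = np.array([[upper + 0.1, upper + 1, lower - 0.1, 0.0, upper, lower]])
        res = transgression(_mixed_matrix(parent, rils), k_sd=2.0, count_threshold=2)
        assert res["upper"].iloc[0] == pytest.approx(upper)
        assert res["lower"].iloc[0] == pytest.approx(lower)
        # strictly beyond: 2 over, 1 under; values exactly on the envelope don't count
        assert res["n_over"].iloc[0] == 2
        assert res["n_under"].iloc[0] == 1
        assert bool(res["transgressive"].iloc[0]) is True

    def test_count_threshold_is_strict(self):
        parent = np.tile(np.array([[-0.1, 0.1]]), (1, 4))
        over = np.full((1, 51), 100.0)
        m51 = _mixed_matrix(parent, over)
        m50 = _mixed_matrix(parent, over[:, :50])
        assert bool(transgression(m51, count_threshold=50)["transgressive"].iloc[0])
        assert not bool(transgression(m50, count_threshold=50)["transgressive"].iloc[0])

    def test_wider_envelope_never_increases_counts(self):
        rng = np.random.default_rng(12)
        parent = rng.normal(size=(30, 8))
        rils = rng.normal(scale=3, size=(30, 60))
        m = _mixed_matrix(parent, rils)
        a = transgression(m, k_sd=1.0)
        b = transgression(m, k_sd=3.0)
        assert ((a["n_over"] + a["n_under"]) >= (b["n_over"] + b["n_under"])).all()

    def test_requires_both_roles(self):
        with pytest.raises(ValueError, match="mpRIL"):
            transgression(make_expression(np.zeros((2, 8)), layer="log2",
                                          roles=parental_samples()))


class TestTransgressionFpr:
    def test_null_fpr_near_one_and_planted_excess_below(self):
        rng = np.random.default_rng(13)
        null = _mixed_matrix(rng.normal(size=(400, 8)), rng.normal(size=(400, 40)))
        fpr0, obs0, _ = transgression_fpr(
            null, n_perm=30, rng=np.random.default_rng(5), k_sd=0.5, count_threshold=5
        )
        assert obs0 > 20
        assert 0.6 < fpr0 < 1.4

        # planted: mpRILs far outside a tight parental envelope
        parent = rng.normal(0, 0.05, size=(400, 8))
        rils = rng.normal(0, 0.05, size=(400, 40))
        rils[:200, :30] += 50.0
        planted = _mixed_matrix(parent, rils)
        fpr1, obs1, _ = transgression_fpr(
            planted, n_perm=30, rng=np.random.default_rng(6), k_sd=2.0,
            count_threshold=5,
        )
        assert obs1 >= 200
        assert fpr1 < fpr0

    def test_zero_observed_warns(self):
        rng = np.random.default_rng(14)
        m = _mixed_matrix(rng.normal(size=(5, 8)), rng.normal(size=(5, 10)))
        with pytest.warns(UserWarning, match="FPR undefined"):
            fpr, obs, _ = transgression_fpr(
                m, n_perm=2, rng=np.random.default_rng(7), k_sd=50.0
            )
        assert obs == 0 and np.isnan(fpr)
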