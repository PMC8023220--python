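"""Differential engines: normalization, NB Wald, MPV, TE, m6A rule."""
import numpy as np
import pandas as pd
import pytest

from trilayer.config import RunConfig
from trilayer.differential import (
    m6a_diff,
    mpv_contrast,
    nb_test,
    size_factors,
    te_test,
)
from trilayer.io import ExpressionMatrix, SampleMeta
from conftest import make_matrix, nb_counts, two_group_matrices


def median_of_ratios_oracle(counts: np.ndarray) -> np.ndarray:
    """Independently coded reference: per-gene geometric-mean reference over
    all-positive genes, per-sample median ratio, normalized to geomean 1."""
    import math
    import statistics

    keep = [g for g in range(counts.shape[0]) if all(counts[g] > 0)]
    factors = []
    for s in range(counts.shape[1]):
        log_ratios = []
        for g in keep:
            log_ref = math.fsum(math.log(counts[g, t]) for t in range(counts.shape[1]))
            log_ref /= counts.shape[1]
            log_ratios.append(math.log(counts[g, s]) - log_ref)
        factors.append(math.exp(statistics.median(log_ratios)))
    log_gm = math.fsum(math.log(f) for f in factors) / len(factors)
    return np.array([f / math.exp(log_gm) for f in factors])


class TestSizeFactors:
    def metas(self, n):
        return [SampleMeta(f"s{i}", "P1", "mrna_input", i + 1) for i in range(n)]

    def test_identical_samples_give_unit_factors(self):
        c = np.array([5, 10, 20])
        m = make_matrix({"s0": c, "s1": c}, self.metas(2), genes=list("abc"))
        np.testing.assert_allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_sample_gives_ratio_two(self):
        c = np.array([5, 10, 20])
        m = make_matrix({"s0": c, "s1": 2 * c}, self.metas(2), genes=list("abc"))
        sf = size_factors(m)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 500, size=(60, 4))
        counts[:40] += 1  # ensure some all-positive genes
        m = make_matrix({f"s{i}": counts[:, i] for i in range(4)}, self.metas(4))
        np.testing.assert_allclose(size_factors(m), median_of_ratios_oracle(counts))

    def test_matches_pydeseq2_size_factors(self):
        # independent cross-check against the DESeq2 reimplementation
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 800, size=(100, 6))
        m = make_matrix({f"s{i}": counts[:, i] for i in range(6)}, self.metas(6))
        ours = size_factors(m).to_numpy()
        _, theirs = pydeseq2.deseq2_norm(counts.T)
        # both conventions fix the geometric mean differently; compare ratios
        np.testing.assert_allclose(ours / ours[0], theirs / theirs[0], rtol=1e-6)

    def test_fallback_to_totals_when_no_common_gene(self, caplog):
        c1 = np.array([10, 0])
        c2 = np.array([0, 30])
        m = make_matrix({"s0": c1, "s1": c2}, self.metas(2), genes=list("ab"))
        with caplog.at_level("WARNING", logger="trilayer"):
            sf = size_factors(m)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(3.0)
        assert any("total-count" in r.message for r in caplog.records)


class TestNbTest:
    def test_identical_groups_null(self, cfg):
        c = np.array([50, 200, 1000, 5, 0])
        metas = [SampleMeta(f"{g}_{r}", g, "mrna_input", r)
                 for g in ("P1", "P2") for r in (1, 2)]
        m = make_matrix({f"{g}_{r}": c for g in ("P1", "P2") for r in (1, 2)}, metas,
                        genes=list("abcde"))
        res = nb_test(m, ("P1", "P2"), cfg)
        assert np.allclose(res["log2fc"].dropna(), 0.0)
        assert (res["p"].dropna() > 0.9).all()
        assert not res["significant"].any()
        assert not res.loc["e", "tested"]  # all-zero gene excluded

    def test_null_simulation_type_one_error(self, cfg):
        # NB null, dispersion 0.1, n=3/side, 2000 genes: p<0.05 in [0.03, 0.07]
        rng = np.random.default_rng(42)
        mu = np.exp(rng.normal(5, 1, 2000))
        m = two_group_matrices(rng, 2000, 3, mu, mu, 0.1)
        res = nb_test(m, ("P1", "P2"), cfg)
        rate = float((res["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_planted_fourfold_power(self, cfg):
        # 4-fold genes at mean 200, dispersion 0.05, n=3/side: >=95% significant
        rng = np.random.default_rng(43)
        mu = np.exp(rng.normal(5, 1, 2000))
        mu[:100] = 200.0
        mu_b = mu.copy()
        mu_b[:100] = 800.0
        m = two_group_matrices(rng, 2000, 3, mu, mu_b, 0.05)
        res = nb_test(m, ("P1", "P2"), cfg)
        assert res["significant"][:100].mean() >= 0.95

    def test_fold_change_recovery_error(self, cfg):
        # planted log2fc re-estimated with median abs error < 0.25
        rng = np.random.default_rng(44)
        mu = np.full(1000, 300.0)
        mu_b = mu * 2 ** rng.uniform(-2, 2, 1000)
        m = two_group_matrices(rng, 1000, 3, mu_b, mu, 0.05)
        res = nb_test(m, ("P1", "P2"), cfg)
        true = np.log2(mu_b / mu)
        assert np.median(np.abs(res["log2fc"] - true)) < 0.25

    def test_swapping_sides_negates_log2fc(self, cfg):
        rng = np.random.default_rng(45)
        mu = np.exp(rng.normal(4, 1, 300))
        m = two_group_matrices(rng, 300, 3, mu, mu * 1.5, 0.05)
        fwd = nb_test(m, ("P1", "P2"), cfg)
        rev = nb_test(m, ("P2", "P1"), cfg)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_bh_monotone_and_bounded(self, cfg):
        rng = np.random.default_rng(46)
        mu = np.exp(rng.normal(5, 1, 500))
        m = two_group_matrices(rng, 500, 3, mu, mu * rng.uniform(1, 3, 500), 0.1)
        res = nb_test(m, ("P1", "P2"), cfg).dropna()
        srt = res.sort_values("p")
        assert srt["p_adj"].is_monotonic_increasing or (
            np.diff(srt["p_adj"].to_numpy()) >= -1e-12
        ).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert (res["p_adj"] <= 1.0).all()


def trio_matrix(rng, n, reps, mu_p1, mu_p2, mu_f1, disp, assay="mrna_input"):
    metas, cols = [], {}
    for geno, mu in (("P1", mu_p1), ("P2", mu_p2), ("F1", mu_f1)):
        for r in range(1, reps + 1):
            sid = f"{geno}_{r}"
            metas.append(SampleMeta(sid, geno, assay, r))
            cols[sid] = nb_counts(rng, mu, disp, (n,))
    return make_matrix(cols, metas)


class TestMpvContrast:
    def test_f1_equal_to_parental_mean_is_null(self, cfg):
        rng = np.random.default_rng(50)
        mu1 = np.exp(rng.normal(5, 0.5, 800))
        mu2 = mu1 * 2.0 ** rng.choice([-1.0, 1.0], 800)
        m = trio_matrix(rng, 800, 3, mu1, mu2, (mu1 + mu2) / 2, 0.05)
        res = mpv_contrast(m, cfg)
        assert res["significant"].mean() < 0.01

    def test_planted_threefold_recovery(self, cfg):
        # F1 = 3 x MPV for 100 genes at mean 300, dispersion 0.05, n=3: >=90%
        rng = np.random.default_rng(51)
        mu = np.exp(rng.normal(5, 0.5, 1000))
        mu[:100] = 300.0
        f1 = mu.copy()
        f1[:100] = 3 * mu[:100]
        m = trio_matrix(rng, 1000, 3, mu, mu, f1, 0.05)
        res = mpv_contrast(m, cfg)
        assert res["significant"][:100].mean() >= 0.90

    def test_parent_label_swap_invariance(self, cfg):
        rng = np.random.default_rng(52)
        mu1 = np.exp(rng.normal(5, 0.5, 300))
        mu2 = mu1 * rng.uniform(0.5, 2, 300)
        m = trio_matrix(rng, 300, 2, mu1, mu2, (mu1 + mu2) / 2 * 1.5, 0.05)
        swapped_metas = []
        for s in m.samples:
            g = {"P1": "P2", "P2": "P1"}.get(s.genotype, s.genotype)
            swapped_metas.append(SampleMeta(s.sample_id, g, s.assay, s.replicate))
        m_sw = ExpressionMatrix(m.counts, swapped_metas)
        res = mpv_contrast(m, cfg)
        res_sw = mpv_contrast(m_sw, cfg)
        np.testing.assert_allclose(res["log2fc"], res_sw["log2fc"])
        np.testing.assert_allclose(res["p"], res_sw["p"], rtol=1e-9)


def te_pair(rng, n, reps, mu, te_by_geno, disp, genotypes=("P1", "P2")):
    poly_m, inp_m, poly_c, inp_c = [], [], {}, {}
    for geno in genotypes:
        for r in range(1, reps + 1):
            pid, iid = f"{geno}_p{r}", f"{geno}_i{r}"
            poly_m.append(SampleMeta(pid, geno, "polysome", r))
            inp_m.append(SampleMeta(iid, geno, "mrna_input", r))
            poly_c[pid] = nb_counts(rng, mu * te_by_geno[geno], disp, (n,))
            inp_c[iid] = nb_counts(rng, mu, disp, (n,))
    return make_matrix(poly_c, poly_m), make_matrix(inp_c, inp_m)


class TestTeTest:
    def test_identical_te_is_null(self, cfg):
        rng = np.random.default_rng(60)
        mu = np.exp(rng.normal(6, 0.5, 1000))
        poly, inp = te_pair(rng, 1000, 3, mu, {"P1": 1.0, "P2": 1.0}, 0.05)
        res = te_test(poly, inp, ("P1", "P2"), cfg)
        assert abs(res["log2fc"].mean()) < 0.05
        assert not res["significant"].any()

    def test_null_type_one_error(self, cfg):
        rng = np.random.default_rng(61)
        mu = np.exp(rng.normal(5, 1, 2000))
        poly, inp = te_pair(rng, 2000, 3, mu, {"P1": 1.0, "P2": 1.0}, 0.1)
        res = te_test(poly, inp, ("P1", "P2"), cfg)
        rate = float((res["p"] < 0.05).mean())
        assert 0.025 <= rate <= 0.075

    def test_planted_shift_recovery(self, cfg):
        # 2.5-fold TE shift at ~10% measurement CV: >=90% detected
        rng = np.random.default_rng(62)
        n = 2000
        mu = np.full(n, 2000.0)
        te_a = np.ones(n)
        te_a[:200] = 2.5
        poly, inp = te_pair(rng, n, 3, mu, {"P1": te_a, "P2": np.ones(n)}, 0.005)
        res = te_test(poly, inp, ("P1", "P2"), cfg)
        assert res["significant"][:200].mean() >= 0.90
        assert res["significant"][200:].mean() < 0.01

    def test_polysome_library_scaling_changes_no_calls(self, cfg):
        rng = np.random.default_rng(63)
        mu = np.exp(rng.normal(6, 0.5, 500))
        te_a = 2 ** rng.uniform(-1.5, 1.5, 500)
        poly, inp = te_pair(rng, 500, 3, mu, {"P1": te_a, "P2": np.ones(500)}, 0.02)
        res1 = te_test(poly, inp, ("P1", "P2"), cfg)
        doubled = ExpressionMatrix(poly.counts * 2, poly.samples)
        res2 = te_test(doubled, inp, ("P1", "P2"), cfg)
        pd.testing.assert_series_equal(res1["significant"], res2["significant"])

    def test_unexpressed_genes_reported_na(self, cfg):
        rng = np.random.default_rng(64)
        mu = np.full(50, 100.0)
        poly, inp = te_pair(rng, 50, 2, mu, {"P1": 1.0, "P2": 1.0}, 0.05)
        expressed = {("P1", "mrna_input"): {"g0", "g1"}, ("P2", "mrna_input"): {"g1"}}
        res = te_test(poly, inp, ("P1", "P2"), cfg, expressed)
        assert res.loc["g1", "tested"]
        assert not res.loc["g0", "tested"]  # missing in P2
        assert res.loc["g2", "p"] != res.loc["g2", "p"]  # NaN


class TestM6aDiff:
    def test_presence_change_is_differential(self, cfg):
        res = m6a_diff(pd.Series({"gA": 6.0}), pd.Series(dtype=float), cfg)
        assert res.loc["gA", "significant"]
        assert res.loc["gA", "direction"] == "gain"

    @pytest.mark.parametrize(
        "la,lb,expect",
        [(6.0, 4.5, False),   # ratio 1.33 below 1.5
         (9.0, 4.0, True),    # ratio 2.25
         (4.0, 9.0, True),    # loss direction also counts
         (5.0, 5.0, False)],
    )
    def test_ratio_threshold(self, cfg, la, lb, expect):
        res = m6a_diff(pd.Series({"g": la}), pd.Series({"g": lb}), cfg)
        assert bool(res.loc["g", "significant"]) is expect

    def test_direction_labels(self, cfg):
        res = m6a_diff(pd.Series({"g": 4.0}), pd.Series({"g": 9.0}), cfg)
        assert res.loc["g", "direction"] == "loss"
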