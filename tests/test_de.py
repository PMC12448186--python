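"""Differential-expression engine: TPM, filtering, log-CPM, empirical-Bayes
shrinkage, moderated t, and BH adjustment, checked against closed forms and
independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import clinepar as cp
from clinepar import de as de_mod


def _dataset(counts, lengths=None, populations=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if lengths is None:
        lengths = np.full(n_genes, 1000.0)
    if populations is None:
        populations = ["Maine"] * n_samples
    reps: dict[str, int] = {}
    samples = []
    for i, pop in enumerate(populations):
        reps[pop] = reps.get(pop, 0) + 1
        samples.append(cp.SampleInfo(f"s{i}", "A", pop, "AG", reps[pop]))
    return cp.CountsDataset(genes=[f"g{i}" for i in range(n_genes)],
                            lengths=np.asarray(lengths, float),
                            samples=samples, counts=counts)


class TestTpm:
    def test_single_gene_gets_full_million(self):
        tm = cp.compute_tpm(_dataset([[7]]))
        assert tm.tpm[0, 0] == pytest.approx(1e6)

    def test_length_normalization_hand_value(self):
        tm = cp.compute_tpm(_dataset([[10], [10]], lengths=[1000, 2000]))
        # rates 10/1, 10/2 -> shares 2/3, 1/3 of a million
        np.testing.assert_allclose(tm.tpm[:, 0], [666666.6667, 333333.3333],
                                   rtol=1e-6)

    def test_all_zero_column_stays_zero(self):
        tm = cp.compute_tpm(_dataset([[0], [0]]))
        np.testing.assert_array_equal(tm.tpm, 0.0)

    def test_columns_sum_to_million(self, small_sim):
        _, res = small_sim
        tm = cp.compute_tpm(res.datasets["A"])
        np.testing.assert_allclose(tm.tpm.sum(axis=0), 1e6, rtol=1e-9)


class TestMedianAndFilter:
    def test_median_odd_and_single_replicate(self):
        ds = _dataset([[0, 0, 0, 0], [0, 0, 0, 0]],
                      populations=["Maine"] * 3 + ["Panama"])
        tpm = np.array([[1e5, 2e5, 9e5, 4e5],
                        [9e5, 8e5, 1e5, 6e5]])
        tm = cp.TpmMatrix(ds.genes, ds.samples, tpm)
        med = cp.median_population_tpm(tm, "A", "AG", ["Maine", "Panama"])
        assert med.loc["g0", "Maine"] == 2e5  # median of (1,2,9)e5
        assert med.loc["g0", "Panama"] == 4e5  # single replicate

    def test_even_replicate_count_mean_of_central_two(self):
        # definition check against a sorting oracle
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 100, size=(5, 4)).astype(float)
        med = np.median(vals, axis=1)
        srt = np.sort(vals, axis=1)
        np.testing.assert_allclose(med, (srt[:, 1] + srt[:, 2]) / 2)

    def test_missing_population_is_error(self, small_sim):
        _, res = small_sim
        tm = cp.compute_tpm(res.datasets["A"])
        with pytest.raises(ValueError, match="Atlantis"):
            cp.median_population_tpm(tm, "A", "AG", ["Atlantis"])

    def test_filter_is_strict_at_threshold(self):
        med = pd.DataFrame({"Maine": [1.0, 0.0], "Panama": [1.0, 1.5]},
                           index=["g_at", "g_in"])
        assert cp.filter_expressed(med, 1.0) == {"g_in"}

    def test_filter_matches_brute_force_recount(self, small_sim):
        _, res = small_sim
        tm = cp.compute_tpm(res.datasets["A"].select(tissue="AG"))
        med = cp.median_population_tpm(tm, "A", "AG", ["Maine", "Panama"])
        got = cp.filter_expressed(med, 1.0)
        brute = {g for g in med.index
                 if med.loc[g, "Maine"] > 1.0 or med.loc[g, "Panama"] > 1.0}
        assert got == brute


class TestLogCpm:
    def test_zero_count_closed_form(self):
        ds = _dataset([[0], [999_999], [1]])
        lc = cp.log_cpm(ds, prior_count=0.5)
        lib = 1_000_000
        expected = math.log2(0.5 / (lib + 1.0) * 1e6)
        assert lc[0, 0] == pytest.approx(expected, abs=1e-5)
        assert expected == pytest.approx(-1.0, abs=1e-5)

    def test_scale_invariance_at_large_counts(self):
        rng = np.random.default_rng(1)
        c = rng.integers(1000, 5000, size=(20, 3))
        a = cp.log_cpm(_dataset(c))
        b = cp.log_cpm(_dataset(2 * c))
        np.testing.assert_allclose(a, b, atol=2e-3)

    def test_monotone_in_count(self):
        ds1 = _dataset([[10], [1000]])
        ds2 = _dataset([[20], [990]])
        assert cp.log_cpm(ds2)[0, 0] > cp.log_cpm(ds1)[0, 0]


class TestEBHyperparams:
    def test_equal_variances_give_infinite_prior_df(self):
        eb = cp.estimate_eb_hyperparams(np.full(50, 0.2), d_g=4)
        assert math.isinf(eb.d0)
        assert eb.s0_sq == pytest.approx(0.2, rel=1e-9)

    def test_recovery_from_implied_prior(self):
        """Variances simulated from the scaled inverse-chi-square prior with
        (d0=4, s0_sq=0.05) recover d0 and s0_sq within 15%."""
        rng = np.random.default_rng(5)
        d0_true, s0_true, d_g, n = 4.0, 0.05, 4, 20000
        sigma_sq = s0_true * d0_true / rng.chisquare(d0_true, n)
        s_sq = sigma_sq * rng.chisquare(d_g, n) / d_g
        eb = cp.estimate_eb_hyperparams(s_sq, d_g)
        assert abs(eb.d0 - d0_true) / d0_true < 0.15
        assert abs(eb.s0_sq - s0_true) / s0_true < 0.15

    def test_larger_spread_gives_smaller_d0(self):
        rng = np.random.default_rng(6)
        base = rng.chisquare(4, 5000) / 4 * 0.1
        narrow = cp.estimate_eb_hyperparams(base ** 0.5, d_g=4)
        wide = cp.estimate_eb_hyperparams(base ** 2.0, d_g=4)
        assert wide.d0 < narrow.d0


def _ordinary_t_oracle(x, groups):
    """Plain pooled two-sample t, written independently of the engine."""
    g = np.asarray(groups, bool)
    out = []
    for row in np.asarray(x, float):
        a, b = row[g], row[~g]
        n1, n2 = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        t = (a.mean() - b.mean()) / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        out.append((t, p))
    return np.array(out)


class TestModeratedT:
    def test_identical_group_means_give_null_statistic(self):
        x = np.tile([1.0, 2.0, 1.0, 2.0], (3, 1))
        tbl = cp.moderated_t_test(x, [1, 1, 0, 0],
                                  cp.EBHyperparams(d0=4.0, s0_sq=0.1))
        np.testing.assert_allclose(tbl["t_mod"], 0.0)
        np.testing.assert_allclose(tbl["p_raw"], 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_d0_zero_limit_equals_ordinary_t(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(30, 6))
        groups = [1, 1, 1, 0, 0, 0]
        oracle = _ordinary_t_oracle(x, groups)
        tbl = cp.moderated_t_test(x, groups, cp.EBHyperparams(d0=0.0, s0_sq=1.0))
        np.testing.assert_allclose(tbl["t_mod"], oracle[:, 0], atol=1e-10)
        np.testing.assert_allclose(tbl["p_raw"], oracle[:, 1], atol=1e-10)

    def test_planted_large_effect_is_significant(self):
        cfg = cp.SimConfig(n_genes=200, species_list=("A", "B"), tissues=("AG",),
                           effect_sd=0.0, shared_outlier_fraction=0.1,
                           outlier_effect=2.0, seed=2)
        res = cp.simulate_dataset(cfg)
        tbl = cp.de_pipeline(res.datasets["A"], "A", "AG", "Panama", "Maine")
        truth = res.truth.query("species == 'A' and tissue == 'AG'") \
            .set_index("gene_id")
        merged = tbl.set_index("gene_id").join(truth["true_log2_effect"])
        planted = merged[np.abs(merged.true_log2_effect) >= 2.0]
        assert len(planted) > 5
        assert (planted["p_raw"] < 1e-4).mean() > 0.9

    def test_group_with_one_sample_rejected(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            cp.moderated_t_test(np.zeros((3, 3)), [1, 0, 0],
                                cp.EBHyperparams(4.0, 0.1))


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(cp.adjust_bh(np.array([0.03])), [0.03])

    def test_hand_applied_step_up(self):
        got = cp.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-8, 1.0, 200)
        got = cp.adjust_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=60))
    def test_adjusted_at_least_raw_and_rank_preserving(self, ps):
        p = np.array(ps)
        adj = cp.adjust_bh(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cp.adjust_bh(np.array([0.0, 0.5]))


class TestCallDe:
    @pytest.mark.parametrize("n_de,n_expr,expected", [
        (798, 8023, 9.9), (1568, 7687, 20.4), (928, 8299, 11.2),
        (39, 10888, 0.4), (757, 10483, 7.2), (472, 10433, 4.5),
    ])
    def test_percent_de_printed_precision(self, n_de, n_expr, expected):
        assert cp.percent_de(n_de, n_expr) == expected

    def test_alpha_zero_calls_nothing(self, de_tables_pair):
        tbl = de_tables_pair["A"].drop(columns=["is_de"])
        called = cp.call_de(tbl, alpha=1e-300)
        assert called["is_de"].sum() <= (tbl["p_adj"] <= 1e-300).sum()

    def test_de_flag_matches_threshold(self, de_tables_pair):
        tbl = de_tables_pair["A"]
        assert (tbl["is_de"] == (tbl["p_adj"] <= 0.1)).all()
        assert (tbl["p_adj"] >= tbl["p_raw"] - 1e-15).all()


def test_null_simulation_respects_bh_control():
    """Under a no-effect simulation the fraction of (false) DE calls stays
    consistent with BH control at alpha = 0.1 across seeds."""
    n_seeds = 12
    any_call = 0
    total_calls = 0
    total_genes = 0
    for seed in range(n_seeds):
        cfg = cp.SimConfig(n_genes=300, species_list=("A", "B"), tissues=("AG",),
                           effect_sd=0.0, shared_outlier_fraction=0.0, seed=seed)
        res = cp.simulate_dataset(cfg)
        tbl = cp.de_pipeline(res.datasets["A"], "A", "AG", "Panama", "Maine")
        n_de = int(tbl["is_de"].sum())
        any_call += n_de > 0
        total_calls += n_de
        total_genes += len(tbl)
    # under the global null BH bounds P(any rejection) by alpha
    assert any_call <= 5
    assert total_calls / total_genes <= 0.15
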