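"""TMM factors, dispersion estimation, the exact NB test, BH adjustment,
contrast set algebra and replicate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rootmir.differential_abundance import (
    bh_adjust,
    compare_contrasts,
    estimate_dispersion,
    load_published_contrast,
    nb_test,
    replicate_qc,
    run_de,
    tmm_factors,
)
from rootmir.synthetic_data import simulate_spike_benchmark

LIBS8 = [f"L{i}" for i in range(8)]
GROUPS8 = {f"L{i}": ("A" if i < 4 else "B") for i in range(8)}


def nb_matrix(rng, mu, phi, n_libs):
    lam = (
        rng.gamma(1 / phi, np.outer(mu, np.ones(n_libs)) * phi)
        if phi > 0
        else np.outer(mu, np.ones(n_libs))
    )
    return pd.DataFrame(rng.poisson(lam), columns=[f"L{i}" for i in range(n_libs)])


class TestTMM:
    def test_identical_libraries_unit_factors(self, rng):
        col = rng.poisson(50, 200)
        counts = pd.DataFrame({f"L{i}": col for i in range(4)})
        assert np.allclose(tmm_factors(counts).factors, 1.0)

    def test_pure_depth_scaling_unit_factors(self, rng):
        col = rng.poisson(1000, 500)
        counts = pd.DataFrame({"L0": col, "L1": col * 2})
        assert np.allclose(tmm_factors(counts).factors, 1.0, atol=1e-6)

    def test_matches_edger_frozen_oracle(self):
        # factors for this exact matrix computed once with
        # edgeR::calcNormFactors (method="TMM") and frozen
        rng = np.random.default_rng(42)
        mu = 10 ** rng.uniform(0.5, 3.5, 60)
        counts = pd.DataFrame(
            {f"L{j}": rng.poisson(mu * s) for j, s in enumerate([1.0, 0.7, 1.4, 1.1])}
        )
        expected = [0.989619, 1.001412, 1.006902, 1.002149]
        assert np.allclose(tmm_factors(counts).factors, expected, atol=1e-6)

    def test_toy_table_matches_bruteforce(self):
        """Independent dense re-derivation of the trimmed weighted mean
        on a table small enough to enumerate."""
        counts = pd.DataFrame(
            {"L0": [100, 200, 50, 400, 80], "L1": [120, 150, 60, 500, 70]}
        )
        n0, n1 = counts.sum()
        # reference library selection by 75th percentile of count fractions
        f75 = [np.quantile(counts[c] / counts[c].sum(), 0.75) for c in counts]
        ref = int(np.argmin(np.abs(np.array(f75) - np.mean(f75))))
        obs_col, ref_col = (1, 0) if ref == 0 else (0, 1)
        obs, refc = counts.iloc[:, obs_col], counts.iloc[:, ref_col]
        n_obs, n_ref = obs.sum(), refc.sum()
        m = np.log2((obs / n_obs) / (refc / n_ref))
        a = 0.5 * (np.log2(obs / n_obs) + np.log2(refc / n_ref))
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - refc) / (n_ref * refc)
        n = len(m)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1 / v[keep]))
        expected = np.ones(2)
        expected[obs_col] = f
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(tmm_factors(counts).factors, expected)

    def test_zero_total_library_rejected(self):
        counts = pd.DataFrame({"L0": [1, 2], "L1": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestDispersion:
    def test_poisson_counts_give_near_zero_phi(self, rng):
        mu = 10 ** rng.uniform(1.5, 3, 2000)
        counts = nb_matrix(rng, mu, 0.0, 8)
        est = estimate_dispersion(counts, GROUPS8)
        assert est.common <= 0.05

    def test_nb_phi_recovered(self, rng):
        mu = 10 ** rng.uniform(1.5, 3, 2000)
        counts = nb_matrix(rng, mu, 0.2, 8)
        est = estimate_dispersion(counts, GROUPS8)
        assert abs(est.common - 0.2) <= 0.05

    def test_identical_replicates_shrink_to_common(self, rng):
        mu = 10 ** rng.uniform(1.5, 3, 300)
        counts = nb_matrix(rng, mu, 0.3, 8)
        # a feature with identical counts everywhere carries no
        # dispersion information of its own
        counts.iloc[0] = 100
        est = estimate_dispersion(counts, GROUPS8)
        assert abs(np.log(est.per_feature.iloc[0] + 1e-8)
                   - np.log(est.common + 1e-8)) < np.log(3)

    def test_single_replicate_group_rejected(self, rng):
        counts = nb_matrix(rng, np.full(10, 100.0), 0.1, 3)
        with pytest.raises(ValueError):
            estimate_dispersion(counts, {"L0": "A", "L1": "A", "L2": "B"})


class TestNBTest:
    def test_null_pvalues_uniform(self, rng):
        mu = 10 ** rng.uniform(1.5, 3, 2000)
        counts = nb_matrix(rng, mu, 0.2, 8)
        state = tmm_factors(counts)
        disp = estimate_dispersion(counts, GROUPS8, state)
        res = nb_test(counts, state, disp, LIBS8[:4], LIBS8[4:])
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_all_zero_group_finite_logfc_small_p(self, rng):
        mu = np.full(200, 200.0)
        counts = nb_matrix(rng, mu, 0.05, 8)
        counts.iloc[0, 4:] = 0  # group B all zeros, like a silenced miRNA
        state = tmm_factors(counts)
        disp = estimate_dispersion(counts, GROUPS8, state)
        res = nb_test(counts, state, disp, LIBS8[:4], LIBS8[4:])
        assert np.isfinite(res["log2FC"].iloc[0])
        assert res["log2FC"].iloc[0] < -3
        assert res["pvalue"].iloc[0] < 0.01

    def test_logfc_sign_matches_normalized_means(self, rng):
        mu = 10 ** rng.uniform(1, 3, 500)
        counts = nb_matrix(rng, mu, 0.2, 8)
        state = tmm_factors(counts)
        disp = estimate_dispersion(counts, GROUPS8, state)
        res = nb_test(counts, state, disp, LIBS8[:4], LIBS8[4:])
        eff = state.effective_sizes
        norm = counts / eff
        mean_a = norm[LIBS8[:4]].mean(axis=1)
        mean_b = norm[LIBS8[4:]].mean(axis=1)
        both = (mean_a > 0) & (mean_b > 0) & (mean_a != mean_b)
        assert (
            np.sign(res.loc[both, "log2FC"])
            == np.sign((mean_b - mean_a)[both])
        ).all()

    def test_overlapping_groups_rejected(self, rng):
        counts = nb_matrix(rng, np.full(10, 50.0), 0.1, 4)
        state = tmm_factors(counts)
        disp = estimate_dispersion(
            counts, {"L0": "A", "L1": "A", "L2": "B", "L3": "B"}, state
        )
        with pytest.raises(ValueError):
            nb_test(counts, state, disp, ["L0", "L1"], ["L1", "L2"])


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_stepup(self, pvals):
        p = np.array(pvals)
        m = p.size
        # direct step-up definition: adj_(i) = min_{j>=i} p_(j) m / j
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            tail = [
                p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
            ]
            expected[idx] = min(1.0, min(tail))
        assert np.allclose(bh_adjust(p), expected)

    def test_monotone_in_rank(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestCompareContrasts:
    def test_published_tables_set_logic(self):
        mild = load_published_contrast("mild")
        severe = load_published_contrast("severe")
        summary = compare_contrasts(mild, severe)
        assert summary["union_count"] == 34
        assert summary["shared_count"] == 7
        assert summary["mild_only_count"] == 3
        assert summary["severe_only_count"] == 24
        assert summary["discordant_sign_count"] == 0

    def test_empty_severe_gives_empty_shared(self):
        mild = load_published_contrast("mild")
        empty = pd.DataFrame(columns=["log2FC", "pvalue", "FDR"])
        summary = compare_contrasts(mild, empty)
        assert summary["shared"] == []
        assert summary["union_count"] == 10

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"m{i}" for i in range(40)]
        mk = lambda: pd.DataFrame(
            {"log2FC": rng.normal(size=40), "FDR": rng.random(40)}, index=ids
        )
        a, b = mk(), mk()
        s = compare_contrasts(a, b, alpha=0.1)
        sig_a = {i for i in ids if a.loc[i, "FDR"] < 0.1}
        sig_b = {i for i in ids if b.loc[i, "FDR"] < 0.1}
        assert set(s["shared"]) == sig_a & sig_b
        assert set(s["mild_only"]) == sig_a - sig_b
        assert s["union_count"] == len(sig_a | sig_b)
        assert s["discordant_sign_count"] == sum(
            np.sign(a.loc[i, "log2FC"]) != np.sign(b.loc[i, "log2FC"])
            for i in sig_a & sig_b
        )


class TestReplicateQC:
    def _counts(self, rng, n_reps=6):
        mu = 10 ** rng.uniform(1, 3.5, 300)
        cols, groups = {}, {}
        for g in ("WW", "mild", "severe"):
            for r in range(1, n_reps + 1):
                lib = f"{g}R{r}"
                lam = rng.gamma(5, mu / 5)
                cols[lib] = rng.poisson(lam)
                groups[lib] = g
        return pd.DataFrame(cols), groups

    def test_duplicated_library_zero_distance(self, rng):
        counts, groups = self._counts(rng)
        counts["WWtwin"] = counts["WWR1"]
        groups["WWtwin"] = "WW"
        qc = replicate_qc(counts, groups)
        assert qc.distances.loc["WWtwin", "WWR1"] == 0.0

    def test_planted_outlier_flagged(self, rng):
        counts, groups = self._counts(rng)
        counts["mildR3"] = rng.permutation(counts["mildR3"].to_numpy())
        qc = replicate_qc(counts, groups)
        assert "mildR3" in qc.outliers

    def test_library_order_invariance(self, rng):
        counts, groups = self._counts(rng)
        qc1 = replicate_qc(counts, groups)
        perm = list(counts.columns)[::-1]
        qc2 = replicate_qc(counts[perm], groups)
        assert set(qc1.outliers) == set(qc2.outliers)
        assert qc1.bcv == pytest.approx(qc2.bcv)

    def test_bcv_reflects_dispersion(self, rng):
        counts, groups = self._counts(rng)
        qc = replicate_qc(counts, groups)
        # gamma shape 5 -> phi = 0.2 -> BCV ~ 0.45
        assert 0.2 < qc.bcv < 0.8


def test_full_pipeline_recall_and_fdr():
    """Spiked 8-fold changes at mean 200 are recovered with high recall
    and controlled empirical FDR, with correct signs."""
    recalls, fdrs = [], []
    for seed in range(3):
        counts, groups, is_de, sign = simulate_spike_benchmark(seed, n_de=100)
        res = run_de(counts, groups, control="A", treatment="B")
        sig = res["significant"].to_numpy()
        recalls.append((sig & is_de).sum() / is_de.sum())
        fdrs.append((sig & ~is_de).sum() / max(sig.sum(), 1))
        called_de = sig & is_de
        assert (
            np.sign(res["log2FC"].to_numpy()[called_de]) == sign[called_de]
        ).all()
    assert np.mean(recalls) >= 0.9
    assert np.mean(fdrs) <= 0.1
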