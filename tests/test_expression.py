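"""Measurement-statistics pipeline: correction, CVs, correlations, gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sigvar.expression import (AbundanceTable, batch_cv, bimodal_threshold,
                               bootstrap_cv, classify_by_threshold,
                               compare_extremes, correction_factors, gate_g1,
                               integrated_activity, normalize_by_mass,
                               pairwise_correlations, technical_vs_biological)


def table_from(values, **kw):
    return AbundanceTable(values=pd.DataFrame(values), **kw)


from tests.oracles import bh_step_up_oracle


class TestCorrectionFactors:
    def test_uniform_sample_scaling_is_removed(self):
        rng = np.random.default_rng(0)
        pattern = rng.uniform(0.5, 2.0, 8)
        base = np.tile(pattern, (5, 1))  # consistent samples
        scaled = base.copy()
        scaled[2] *= 1.1
        factors, corrected = correction_factors(table_from(scaled))
        assert factors[2] == pytest.approx(1.1, rel=1e-9)
        assert np.allclose(corrected.values.to_numpy()[2], base[2], rtol=1e-9)

    def test_identical_samples_give_unit_factors(self):
        factors, _ = correction_factors(table_from(np.ones((4, 6)) * 2.5))
        assert np.allclose(factors, 1.0)

    def test_hand_computed_three_by_three(self):
        vals = [[1, 2, 4], [1.2, 2.4, 4.8], [0.9, 1.8, 3.6]]
        factors, _ = correction_factors(table_from(vals))
        assert np.allclose(factors, [1.0, 1.2, 0.9])

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 0.3, (10, 12))
        _, once = correction_factors(table_from(vals))
        factors2, _ = correction_factors(once)
        assert np.allclose(factors2, 1.0, atol=1e-12)

    def test_only_reference_proteins_drive_the_factor(self):
        vals = np.ones((4, 3))
        vals[1, 2] = 50.0  # huge excursion in a non-reference protein
        meta = pd.DataFrame({
            "is_reference": [True, True, False],
            "is_cell_cycle_regulated": [False, False, True],
        }, index=[0, 1, 2])
        factors, _ = correction_factors(table_from(vals, protein_meta=meta))
        assert np.allclose(factors, 1.0)


class TestCV:
    def test_known_column_cv(self):
        t = table_from({"a": [9.0, 10.0, 11.0], "b": [5.0, 5.0, 5.0]})
        report = batch_cv(t)
        assert report.set_index("protein").loc["a", "cv"] == pytest.approx(0.1)
        assert report.set_index("protein").loc["b", "cv"] == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.01, 1000.0), st.integers(0, 100))
    def test_cv_is_scale_invariant(self, scale, seed):
        rng = np.random.default_rng(seed)
        col = rng.lognormal(0, 0.2, 8)
        t1 = table_from({"p": col})
        t2 = table_from({"p": col * scale})
        assert batch_cv(t1)["cv"][0] == pytest.approx(batch_cv(t2)["cv"][0], rel=1e-12)

    def test_bootstrap_ci_of_constant_column_is_degenerate(self):
        cv, lo, hi = bootstrap_cv(np.full(10, 3.0), rng=np.random.default_rng(0))
        assert (cv, lo, hi) == (0.0, 0.0, 0.0)

    def test_bootstrap_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(1)
        x60 = rng.lognormal(0, 0.09, 60)
        widths = []
        for n in (10, 60):
            _, lo, hi = bootstrap_cv(x60[:n], rng=np.random.default_rng(2))
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_bootstrap_ci_covers_the_generating_cv(self):
        """Percentile CI contains the true lognormal sigma in >=90% of repeats."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            x = rng.lognormal(0, 0.09, 60)
            _, lo, hi = bootstrap_cv(x, n_boot=2000, rng=rng)
            hits += lo <= 0.09 <= hi
        assert hits >= 90


class TestCorrelations:
    def test_duplicated_column_is_perfectly_correlated(self):
        rng = np.random.default_rng(4)
        col = rng.lognormal(0, 0.1, 30)
        rep = pairwise_correlations(table_from({"a": col, "b": col.copy(),
                                                "c": rng.lognormal(0, 0.1, 30)}))
        row = rep.query("protein_a == 'a' and protein_b == 'b'").iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-20

    def test_bh_adjustment_matches_hand_example(self):
        adj = bh_step_up_oracle([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 1000), st.integers(0, 10_000))
    def test_bh_equals_brute_force_oracle(self, m, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, m)
        assert np.allclose(multipletests(p, method="fdr_bh")[1],
                           bh_step_up_oracle(p), atol=1e-12)

    def test_pearson_p_matches_permutation_null(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 0.1, 25)
        y = x * np.exp(rng.standard_normal(25) * 0.08)
        rep = pairwise_correlations(table_from({"x": x, "y": y}))
        r_obs, p_t = rep.loc[0, "r"], rep.loc[0, "p"]
        perm = np.empty(10_000)
        ly = np.log(y)
        lx = np.log(x)
        for i in range(10_000):
            perm[i] = np.corrcoef(lx, rng.permutation(ly))[0, 1]
        # correlate raw values for the permutation too
        perm_raw = np.empty(10_000)
        for i in range(10_000):
            perm_raw[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = np.mean(np.abs(perm_raw) >= abs(r_obs))
        assert p_perm == pytest.approx(p_t, abs=3 * np.sqrt(p_t * (1 - p_t) / 10_000) + 1e-3)

    def test_planted_pair_is_detected_and_others_are_not(self):
        rng = np.random.default_rng(6)
        hits, false_hits = 0, 0
        for _ in range(50):
            n, p = 120, 10
            z = rng.standard_normal((n, p))
            z[:, 1] = 0.7 * z[:, 0] + np.sqrt(1 - 0.49) * z[:, 1]
            vals = np.exp(z * 0.1)
            rep = pairwise_correlations(table_from(vals))
            planted = rep.query("protein_a == 0 and protein_b == 1")["significant"]
            hits += bool(planted.iloc[0])
            false_hits += int(rep["significant"].sum()) - int(planted.iloc[0])
        assert hits >= 48          # >=95% detection
        assert false_hits <= 25    # BH keeps false positives rare

    def test_zero_variance_column_reported_undefined(self):
        rep = pairwise_correlations(table_from({"a": [1.0, 1.0, 1.0, 1.0],
                                                "b": [1.0, 2.0, 3.0, 4.0]}))
        assert np.isnan(rep.loc[0, "r"])


class TestTechnicalVsBiological:
    def test_identical_reports_are_floor_limited(self):
        rep = pd.DataFrame({"protein": ["a", "b"], "cv": [0.05, 0.06],
                            "ci_low": [0.04, 0.05], "ci_high": [0.06, 0.07]})
        out = technical_vs_biological(rep, rep.copy())
        assert np.allclose(out["ratio"], 1.0)
        assert out["floor_limited"].all()

    def test_clearly_separated_cvs_are_not_flagged(self):
        tech = pd.DataFrame({"protein": ["a"], "cv": [0.05],
                             "ci_low": [0.045], "ci_high": [0.055]})
        bio = pd.DataFrame({"protein": ["a"], "cv": [0.10],
                            "ci_low": [0.09], "ci_high": [0.11]})
        out = technical_vs_biological(tech, bio)
        assert not out["floor_limited"].any()
        assert out["ratio"][0] == pytest.approx(2.0)

    def test_mismatched_protein_sets_rejected(self):
        a = pd.DataFrame({"protein": ["a"], "cv": [0.05]})
        b = pd.DataFrame({"protein": ["b"], "cv": [0.05]})
        with pytest.raises(ValueError):
            technical_vs_biological(a, b)


class TestCellGating:
    def test_two_n_mode_is_kept_and_four_n_dropped(self):
        rng = np.random.default_rng(7)
        n = 4000
        is_2n = rng.random(n) < 0.5
        dna = np.where(is_2n, 2.0, 4.0) * np.exp(rng.standard_normal(n) * 0.05)
        cells = pd.DataFrame({"dna": dna})
        kept = gate_g1(cells, max_radius=None)
        frac = len(kept) / n
        assert 0.42 < frac < 0.55
        assert (kept["dna"] < 3.0).all()

    def test_single_mode_population_is_fully_retained(self):
        cells = pd.DataFrame({"dna": np.full(100, 2.0)})
        assert len(gate_g1(cells, max_radius=None)) == 100

    def test_peripheral_cells_dropped_regardless_of_dna(self):
        cells = pd.DataFrame({
            "dna": [2.0, 2.0], "x": [540.0, 0.0], "y": [540.0, 0.0],
        })
        kept = gate_g1(cells, center=(540.0, 540.0), max_radius=350.0)
        assert len(kept) == 1

    def test_mass_normalization_cancels_common_scaling(self):
        cells = pd.DataFrame({"mass_stain": [1.0, 2.0], "MEK": [3.0, 6.0]})
        conc = normalize_by_mass(cells, "MEK")
        assert np.allclose(conc, 3.0)


class TestActivityScoring:
    def test_constant_trace_auc_is_a_rectangle(self):
        t = np.arange(0, 61, 2.0)
        auc = integrated_activity(t, np.full_like(t, 1.5), stim_time=10.0)
        assert auc == pytest.approx(1.5 * 50.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            integrated_activity(np.array([0.0, 2.0]), np.array([1.0, 1.0]),
                                stim_time=5.0)

    def test_bimodal_threshold_separates_two_populations(self):
        rng = np.random.default_rng(8)
        low = rng.normal(50, 3, 400)
        high = rng.normal(90, 4, 600)
        auc = np.concatenate([low, high])
        thr = bimodal_threshold(auc)
        assert 60 < thr < 80
        labels = classify_by_threshold(auc)
        truth = np.concatenate([np.zeros(400, bool), np.ones(600, bool)])
        assert np.mean(labels == truth) >= 0.98

    def test_unimodal_distribution_fails_loudly(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            bimodal_threshold(rng.normal(0, 1, 500))


class TestCompareExtremes:
    def test_deterministic_split_of_sorted_values(self):
        act = np.arange(10.0)
        conc = np.arange(10.0) * 2
        out = compare_extremes(act, conc, fraction=0.5)
        assert out["top"]["n"] == out["bottom"]["n"] == 5
        assert out["top"]["median"] == np.median(conc[5:])
        assert out["bottom"]["median"] == np.median(conc[:5])

    def test_activity_linked_concentration_separates_groups(self):
        rng = np.random.default_rng(10)
        n = 1000
        conc = rng.lognormal(0, 0.15, n)
        activity = np.log(conc) * 2 + rng.standard_normal(n) * 0.1
        out = compare_extremes(activity, conc, fraction=0.15)
        assert out["top"]["median"] > out["bottom"]["median"]
        assert out["rank_sum_p"] < 1e-6

    def test_identical_distributions_show_no_separation(self):
        rng = np.random.default_rng(11)
        out = compare_extremes(rng.random(400), rng.lognormal(0, 0.1, 400))
        notch = out["top"]["notch"] + out["bottom"]["notch"]
        assert abs(out["top"]["median"] - out["bottom"]["median"]) < notch

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            compare_extremes(np.arange(5.0), np.arange(5.0), fraction=0.15)
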