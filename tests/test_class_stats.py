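"""Class-level statistics: contrasts, exact tests, correlations, qPCR."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import lncprio
from lncprio import class_stats, qc


class TestVariability:
    def test_constant_gene_has_zero_sd(self):
        df = pd.DataFrame(
            {"s1": [100.0, 1e6 - 100], "s2": [100.0, 1e6 - 100]},
            index=pd.Index(["Gc", "Gf"], name="gene_id"),
        )
        classes = pd.Series(["lncRNA", "PCG"], index=df.index)
        # bypass the 2-genes-per-class guard by adding replicas
        df = pd.concat([df, df.rename(index={"Gc": "Gc2", "Gf": "Gf2"})])
        classes = pd.concat([classes, classes.rename({"Gc": "Gc2", "Gf": "Gf2"})])
        table, _ = class_stats.variability_by_class(df, classes)
        assert table.loc["Gc", "sd_log2cpm"] == 0.0

    def test_planted_dispersion_difference_detected(self, sim_sn):
        """lncRNAs are generated with twice the PCG dispersion, so their
        per-gene SD of log2(CPM+1) across samples is larger (the class
        contrast is confined to expressed genes to avoid the all-zero
        floor)."""
        _, counts, catalog, samples, _ = sim_sn
        cpm = lncprio.compute_cpm(counts)
        cs = qc.call_expressed(cpm, samples, "SN")
        expr = [g for g in cpm.gene_ids if g in cs.expressed_genes]
        table, summary = class_stats.variability_by_class(
            cpm.cpm.loc[expr], counts.biotype
        )
        assert summary["median_lncRNA"] > summary["median_PCG"]
        assert summary["p"] < 0.01

    def test_shuffled_labels_give_uniform_p(self, sim_sn):
        _, counts, catalog, samples, _ = sim_sn
        cpm = lncprio.compute_cpm(counts)
        sd = np.log2(cpm.cpm + 1.0).std(axis=1, ddof=1).to_numpy()
        rng = np.random.default_rng(0)
        n_lnc = int((counts.biotype == "lncRNA").sum())
        hits = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            perm = rng.permutation(len(sd))
            a, b = sd[perm[:n_lnc]], sd[perm[n_lnc:]]
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            hits += p < 0.05
        # binomial(200, 0.05): mean 10, 3 sigma ~ 9
        assert hits <= 20

    def test_tiny_class_rejected(self):
        df = pd.DataFrame(np.ones((3, 4)), index=pd.Index(list("abc"), name="g"))
        classes = pd.Series(["lncRNA", "PCG", "PCG"], index=df.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            class_stats.variability_by_class(df, classes)


class TestLfcContrast:
    def _de(self, lfc_a, lfc_b):
        n = len(lfc_a) + len(lfc_b)
        idx = pd.Index([f"G{i:03d}" for i in range(n)], name="gene_id")
        de = pd.DataFrame(
            {
                "log2fc": list(lfc_a) + list(lfc_b),
                "mean_cpm": 50.0,
                "p": 0.5,
                "q": 0.9,
            },
            index=idx,
        )
        classes = pd.Series(["lncRNA"] * len(lfc_a) + ["PCG"] * len(lfc_b), index=idx)
        return de, classes

    def test_identical_distributions_ci_covers_zero(self):
        vals = np.random.default_rng(0).normal(0, 1, 150)
        de, classes = self._de(vals, vals)
        c = class_stats.lfc_class_contrast(de, classes, n_boot=2000, seed=0)
        assert c.ci[0] <= 0.0 <= c.ci[1]
        assert np.isclose(c.difference, 0.0)

    def test_planted_class_difference_separates(self, de_sn, sim_sn):
        _, counts, _, _, _ = sim_sn
        for subset in ("all", "cpm_gt_10", "p_lt_0.05"):
            c = class_stats.lfc_class_contrast(
                de_sn, counts.biotype, subset=subset, n_boot=3000, seed=1
            )
            assert c.difference > 0  # lncRNA |log2FC| exceeds PCG
        c_all = class_stats.lfc_class_contrast(
            de_sn, counts.biotype, subset="all", n_boot=3000, seed=1
        )
        assert c_all.ci[0] > 0  # 99% CI of the difference excludes 0

    def test_single_resample_degenerates_with_warning(self):
        de, classes = self._de([1.0, 2.0, 3.0], [0.5, 1.5])
        with pytest.warns(UserWarning, match="n_boot"):
            c = class_stats.lfc_class_contrast(de, classes, n_boot=1, seed=0)
        assert c.ci == (c.difference, c.difference)

    def test_empty_subset_rejected(self):
        de, classes = self._de([1.0, 2.0], [0.5, 1.5])
        de["mean_cpm"] = 1.0
        with pytest.raises(ValueError, match="non-empty"):
            class_stats.lfc_class_contrast(de, classes, subset="cpm_gt_10")


class TestFisherExact:
    def test_cohort_scale_table_is_overwhelming(self):
        odds, p = class_stats.fisher_exact([[1120, 2598], [708, 14218]])
        assert p < 1e-4

    def test_balanced_table_p_one(self):
        _, p = class_stats.fisher_exact([[1, 1], [1, 1]])
        assert p == 1.0

    def test_diagonal_table_exact_value(self):
        _, p = class_stats.fisher_exact([[5, 0], [0, 5]])
        assert np.isclose(p, 2 / comb(10, 5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            class_stats.fisher_exact([[0, 0], [3, 4]])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_scipy_on_random_tables(self, a, b, c, d):
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if min(r1, r2, c1, c2) == 0:
            return
        odds, p = class_stats.fisher_exact([[a, b], [c, d]])
        odds_sp, p_sp = sps.fisher_exact([[a, b], [c, d]])
        assert np.isclose(p, p_sp, rtol=1e-7, atol=1e-12)
        if b * c > 0:
            assert np.isclose(odds, odds_sp)


class TestEnrichmentFold:
    def test_sn_specific_worked_example(self):
        res = class_stats.enrichment_fold(1120, 3718, 708, 14926)
        assert res.fold > 6.0
        assert np.isclose(res.fold, (1120 / 3718) / (708 / 14926))

    @pytest.mark.parametrize(
        "k1,n1,k2,n2,fold,p_one",
        [(5, 10, 5, 10, 1.0, True), (10, 20, 5, 20, 2.0, False)],
    )
    def test_arithmetic(self, k1, n1, k2, n2, fold, p_one):
        res = class_stats.enrichment_fold(k1, n1, k2, n2)
        assert np.isclose(res.fold, fold)
        if p_one:
            assert res.p == 1.0

    def test_zero_reference_is_infinite(self):
        res = class_stats.enrichment_fold(3, 10, 0, 10)
        assert res.fold == float("inf")


class TestPrc2:
    def test_random_targets_show_no_enrichment(self, de_sn):
        rng = np.random.default_rng(0)
        folds, ps = [], []
        for _ in range(20):
            targets = rng.choice(de_sn.index, size=200, replace=False)
            out = class_stats.prc2_target_analysis(de_sn, targets)
            ps.append(out["mannwhitney_p"])
            if np.isfinite(out["down_enrichment"].fold):
                folds.append(out["down_enrichment"].fold)
        assert np.mean(ps) > 0.2  # roughly uniform, not systematically small
        if folds:
            assert 0.3 < np.mean(folds) < 2.5

    def test_planted_down_enrichment_recovered(self):
        """Pooled over replicate cohorts, PRC2 targets planted with a 2x
        relative risk of downregulation show a ~2-fold enrichment among
        significantly downregulated genes (real-data analogs: 1.6-
        and 1.9-fold)."""
        from lncprio import diffexp

        k1 = n1 = k2 = n2 = 0
        for seed in range(6):
            cfg = lncprio.SimConfig(regions=("SN",), n_cases=20, n_controls=20)
            counts, catalog, samples, truth = lncprio.simulate_dataset(cfg, seed)
            cpm = lncprio.compute_cpm(counts)
            scores = lncprio.marker_scores(cpm, catalog.marker_sets())
            design = diffexp.build_design(samples, scores)
            disp = lncprio.estimate_dispersions(counts, design)
            de = diffexp.test_differential_expression(counts, design, disp)
            is_t = de.index.isin(catalog.prc2_set())
            ds = (de["log2fc"] < 0) & (de["q"] < 0.05)
            k1 += int((ds & is_t).sum()); n1 += int(is_t.sum())
            k2 += int((ds & ~is_t).sum()); n2 += int((~is_t).sum())
        pooled = (k1 / n1) / (k2 / n2)
        assert 1.4 <= pooled <= 2.8

    def test_all_targets_rejected(self, de_sn):
        with pytest.raises(ValueError, match="complement"):
            class_stats.prc2_target_analysis(de_sn, set(de_sn.index))

    def test_disjoint_targets_rejected(self, de_sn):
        with pytest.raises(ValueError, match="intersect"):
            class_stats.prc2_target_analysis(de_sn, {"NOT_A_GENE"})


class TestCorrelation:
    def test_linear_relation_perfect(self):
        x = np.arange(10.0)
        res_p = class_stats.correlation(x, 2 * x + 1, method="pearson")
        res_s = class_stats.correlation(x, 2 * x + 1, method="spearman")
        assert np.isclose(res_p.coefficient, 1.0)
        assert np.isclose(res_s.coefficient, 1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(5.0)
        res = class_stats.correlation(x, x[::-1], method="spearman")
        assert np.isclose(res.coefficient, -1.0)

    def test_hand_computed_rank_formula(self):
        # rho = 1 - 6 * sum(d^2) / (n (n^2-1)) with d^2 sum = 4 at n = 5
        res = class_stats.correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert np.isclose(res.coefficient, 0.8)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(-500, 500), min_size=4, max_size=30, unique=True))
    def test_spearman_invariant_under_monotone_transform(self, x):
        x = np.asarray(x, dtype=float) / 10.0
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(x))
        base = class_stats.correlation(x, y).coefficient
        trans = class_stats.correlation(np.exp(x / 50), y).coefficient
        assert np.isclose(base, trans)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            class_stats.correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            class_stats.correlation([1, 2], [3, 4])


class TestCrossRegionCorrelation:
    def test_matched_donor_correlation_detected(self):
        donors = [f"d{i}" for i in range(13)]
        rng = np.random.default_rng(0)
        base = rng.normal(5, 2, size=(3, 13))
        a = pd.DataFrame(base + rng.normal(0, 0.1, base.shape),
                         index=["g1", "g2", "g3"], columns=donors)
        b = pd.DataFrame(base + rng.normal(0, 0.1, base.shape),
                         index=["g1", "g2", "g3"], columns=donors)
        out = class_stats.cross_region_correlation({"SN": a, "MTG": b})
        assert len(out) == 3
        assert (out["coefficient"] > 0.8).all()
        assert out["significant"].all()

    def test_constant_gene_flagged_nan(self):
        donors = ["d0", "d1", "d2", "d3"]
        a = pd.DataFrame([[1.0, 1, 1, 1]], index=["g1"], columns=donors)
        b = pd.DataFrame([[1.0, 2, 3, 4]], index=["g1"], columns=donors)
        out = class_stats.cross_region_correlation({"SN": a, "MTG": b})
        assert np.isnan(out["coefficient"].iloc[0])


class TestAgeTrend:
    def _tables(self, slope_brain, slope_peri, noise=0.8, seed=0):
        rng = np.random.default_rng(seed)
        tables, cls = {}, {}
        for i in range(13):
            ages = rng.uniform(50, 90, 12)
            tables[f"brain_{i}"] = (ages, slope_brain * ages + rng.normal(0, noise, 12))
            cls[f"brain_{i}"] = "brain"
        for i in range(35):
            ages = rng.uniform(50, 90, 12)
            tables[f"peri_{i}"] = (ages, slope_peri * ages + rng.normal(0, noise, 12))
            cls[f"peri_{i}"] = "periphery"
        return tables, cls

    def test_opposite_trends_detected(self):
        tables, cls = self._tables(-0.02, +0.02)
        summary, contrast = class_stats.age_trend_contrast(tables, cls)
        assert contrast["mean_r_brain"] < 0 < contrast["mean_r_periphery"]
        assert contrast["p"] < 0.01
        assert contrast["n_brain"] == 13 and contrast["n_periphery"] == 35

    def test_null_trends_not_systematically_significant(self):
        ps = []
        for seed in range(20):
            tables, cls = self._tables(0.0, 0.0, seed=seed)
            _, contrast = class_stats.age_trend_contrast(tables, cls)
            ps.append(contrast["p"])
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_binned_ages_mapped_to_midpoints(self):
        ages = ["50-59", "60-69", "70-79", "80-89"] * 3
        rng = np.random.default_rng(0)
        tables = {
            f"t{i}": (ages, np.linspace(0, 1, 12) + rng.normal(0, 0.01, 12))
            for i in range(4)
        }
        cls = {"t0": "brain", "t1": "brain", "t2": "periphery", "t3": "periphery"}
        summary, contrast = class_stats.age_trend_contrast(tables, cls)
        assert summary["r"].notna().all()

    def test_constant_tissue_excluded(self):
        tables, cls = self._tables(-0.02, +0.02)
        tables["brain_0"] = (tables["brain_0"][0], np.ones(12))
        summary, contrast = class_stats.age_trend_contrast(tables, cls)
        assert summary.loc[summary["tissue"] == "brain_0", "excluded"].iloc[0]
        assert contrast["n_brain"] == 12


class TestQpcr:
    def _records(self):
        return pd.DataFrame(
            {
                "sample_id": ["r1", "r2", "x1", "x2"],
                "group": ["control", "control", "treated", "treated"],
                "ct_target": [25.0, 26.0, 24.5, 23.5],
                "ct_hk1": [20.0, 21.0, 20.0, 20.0],
            }
        )

    def test_reference_median_maps_to_unity(self):
        out = class_stats.delta_delta_ct(self._records(), "control")
        # reference median dCt = 5.0; r1 has dCt exactly 5.0
        assert np.isclose(out.loc[out["sample_id"] == "r1", "relative_expression"], 1.0)
        assert np.isclose(out.loc[out["sample_id"] == "r1", "pct_of_reference"], 100.0)

    def test_minus_one_ddct_doubles(self):
        rec = self._records()
        out = class_stats.delta_delta_ct(rec, "control")
        x2 = out.loc[out["sample_id"] == "x2"].iloc[0]
        assert np.isclose(x2["ddCt"], -1.5)
        assert np.isclose(x2["relative_expression"], 2.0 ** 1.5)

    def test_two_housekeeping_genes_averaged(self):
        rec = self._records().assign(ct_hk2=[22.0, 23.0, 22.0, 22.0])
        out = class_stats.delta_delta_ct(rec, "control")
        # housekeeping Ct for r1 = mean(20, 22) = 21 -> dCt = 4
        assert np.isclose(out.loc[out["sample_id"] == "r1", "dCt"], 4.0)

    def test_missing_housekeeping_rejected(self):
        rec = self._records()
        rec.loc[0, "ct_hk1"] = np.nan
        with pytest.raises(ValueError, match="housekeeping"):
            class_stats.delta_delta_ct(rec, "control")

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            class_stats.delta_delta_ct(self._records(), "ghost")


class TestRelativeChange:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(15.0, 45.0, 200 / 3), (45.0, 45.0, 0.0), (0.0, 45.0, 100.0)],
    )
    def test_closed_form(self, treated, control, expected):
        assert np.isclose(class_stats.relative_change(treated, control), expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            class_stats.relative_change(10.0, 0.0)
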