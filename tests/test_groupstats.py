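"""ANOVA, Tukey-Kramer, clinical correlations, and the end-to-end pipeline."""

import numpy as np
import pytest
from scipy import stats

from adnetworks.groupstats import (
    PipelineConfig,
    anova_oneway,
    benjamini_hochberg,
    correlate_metric_clinical,
    run_group_pipeline,
    tukey_hsd,
)
from adnetworks.synthetic import CohortSpec, generate_cohort, generate_subject
from adnetworks.connectivity import build_mi_matrix
from adnetworks.netbuild import threshold_to_density
from adnetworks.graphmetrics import local_efficiency


class TestAnova:
    def test_textbook_three_groups_f_is_three(self):
        f, p = anova_oneway({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert f == pytest.approx(3.0, abs=1e-12)  # SSB=6 (df 2), SSW=6 (df 6)
        assert 0 < p < 1

    def test_all_equal_values_give_zero_f(self):
        f, p = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert f == 0.0 and p == 1.0

    def test_distinct_constant_groups_flagged(self):
        with pytest.raises(ValueError, match="within-group variance"):
            anova_oneway({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_power_at_two_sd_shift(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30) + 2.0
            hits += anova_oneway({"a": a, "b": b})[1] < 0.05
        assert hits >= 0.99 * n_sim


class TestTukey:
    def test_identical_groups_have_zero_diff_high_p(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = tukey_hsd({"a": g, "b": list(g), "c": [10.0, 11.0, 12.0, 13.0]})
        diff, p, sig = res[("a", "b")]
        assert diff == 0.0 and p > 0.9 and not sig

    def test_balanced_example_matches_studentized_range(self):
        # independent route: q statistic by hand + studentized-range sf
        groups = {"a": [24.0, 28.0, 21.0, 25.0],
                  "b": [31.0, 30.0, 34.0, 33.0],
                  "c": [22.0, 26.0, 20.0, 24.0]}
        res = tukey_hsd(groups)
        arrs = [np.asarray(v) for v in groups.values()]
        n = 4
        mse = np.mean([a.var(ddof=1) for a in arrs])
        df = sum(a.size for a in arrs) - len(arrs)
        for (ga, gb), (diff, p, _) in res.items():
            q = abs(diff) / np.sqrt(mse / n)
            expected = stats.studentized_range.sf(q, len(arrs), df)
            assert p == pytest.approx(expected, abs=1e-3)

    def test_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = {g: rng.standard_normal(rng.integers(5, 15))
                      for g in "abcd"}
            res = tukey_hsd(groups)
            for (ga, gb), (_, p_adj, _) in res.items():
                p_t = stats.ttest_ind(groups[ga], groups[gb]).pvalue
                assert p_adj >= p_t - 1e-9

    def test_familywise_error_under_global_null_unequal_n(self):
        # the cohort's group sizes; FWER must stay near or below 0.05.
        # Small replicate count here — the full 2000-replicate check runs
        # with the acceptance suite.
        sizes = (31, 50, 25, 36, 10)
        rng = np.random.default_rng(99)
        n_rep, fw = 200, 0
        for _ in range(n_rep):
            groups = {str(i): rng.standard_normal(n) for i, n in enumerate(sizes)}
            res = tukey_hsd(groups)
            fw += any(p < 0.05 for _, p, _ in res.values())
        assert fw / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


class TestCorrelation:
    def test_exact_line_gives_unit_r(self):
        x = np.arange(10.0)
        res = correlate_metric_clinical(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.R2 == pytest.approx(1.0)
        assert res.p < 1e-9

    def test_r_squared_consistency_and_sign(self, rng):
        x = rng.standard_normal(40)
        y = -0.5 * x + rng.standard_normal(40)
        res = correlate_metric_clinical(x, y)
        assert res.R2 == pytest.approx(res.r**2)
        assert res.r < 0

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(17)
        n_sim, hits = 1000, 0
        for _ in range(n_sim):
            res = correlate_metric_clinical(rng.standard_normal(50),
                                            rng.standard_normal(50))
            hits += res.p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r0 = correlate_metric_clinical(x, y).r
        r1 = correlate_metric_clinical(3 * x + 7, 0.5 * y - 2).r
        assert r1 == pytest.approx(r0)

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        res = correlate_metric_clinical(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_constant_input_flagged_not_crashed(self):
        res = correlate_metric_clinical([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.r)

    def test_simpson_style_scope_divergence(self):
        # two groups with positive within-group slope but group means
        # arranged so the pooled correlation flips negative
        rng = np.random.default_rng(23)
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40) + 8
        y1 = x1 + 10 + 0.3 * rng.standard_normal(40)
        y2 = x2 - 18 + 0.3 * rng.standard_normal(40)
        within1 = correlate_metric_clinical(x1, y1).r
        within2 = correlate_metric_clinical(x2, y2).r
        pooled = correlate_metric_clinical(np.r_[x1, x2], np.r_[y1, y2]).r
        assert within1 > 0.8 and within2 > 0.8 and pooled < 0

    def test_negative_clinical_effect_recovered_from_network_metric(self):
        # generator regression check: local efficiency of the thresholded
        # network should correlate negatively with a coupled score
        hits, n_seeds = 0, 10
        for seed in range(n_seeds):
            spec = CohortSpec(seed=300 + seed, group_sizes={"aMCI": 50},
                              clinical_effect=-8.0)
            eff, score = [], []
            for i in range(50):
                ts, rec = generate_subject(spec, "aMCI", i)
                net = threshold_to_density(build_mi_matrix(ts), 0.07)
                eff.append(local_efficiency(net)[0])
                score.append(rec.clinical_scores["COWAT_semantic"])
            hits += correlate_metric_clinical(eff, score).r < 0
        assert hits >= 0.9 * n_seeds


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.2, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)


def small_cohort(seed=0):
    return generate_cohort(CohortSpec(
        seed=seed, group_sizes={"HS": 3, "aMCI": 3, "CDR0.5": 3,
                                "CDR1": 3, "CDR2": 3}))


def fast_config(seed=0):
    return PipelineConfig(n_random=10, modularity_restarts=3, seed=seed)


class TestPipeline:
    def test_bundle_contents_on_five_group_cohort(self):
        bundle = run_group_pipeline(small_cohort(), fast_config())
        whole = bundle["comparisons"].query("scope == 'whole_brain'")
        assert whole["metric"].nunique() == 7
        # 10 unordered group pairs per metric
        assert (whole.groupby("metric").size() == 10).all()
        assert bundle["metrics"].shape[0] == 15
        assert bundle["richclub"]["group"].nunique() == 5
        assert set(bundle["summary"]["groups"]) == {"HS", "aMCI", "CDR0.5",
                                                    "CDR1", "CDR2"}
        lobar = bundle["lobar"]
        assert lobar.groupby(["metric", "lobe", "hemisphere"]).ngroups == 50

    def test_single_group_skips_comparisons(self):
        subjects = generate_cohort(CohortSpec(group_sizes={"HS": 4}))
        bundle = run_group_pipeline(subjects, fast_config())
        assert bundle["comparisons"].empty
        assert bundle["metrics"].shape[0] == 4

    def test_rerun_writes_byte_identical_tables(self, tmp_path):
        for sub in ("a", "b"):
            run_group_pipeline(small_cohort(), fast_config(),
                               out_dir=tmp_path / sub)
        for name in ("metrics", "comparisons", "correlations", "richclub",
                     "lobar"):
            fa = (tmp_path / "a" / f"{name}.tsv").read_bytes()
            fb = (tmp_path / "b" / f"{name}.tsv").read_bytes()
            assert fa == fb

    def test_screen_reports_exclusions(self):
        subjects = small_cohort()
        config = fast_config()
        config.screen_tau = 0.8
        bundle = run_group_pipeline(subjects, config)
        assert bundle["summary"]["n_subjects_input"] == 15
        assert (bundle["summary"]["n_subjects_analyzed"]
                + bundle["summary"]["n_excluded_by_screen"] == 15)
        assert len(bundle["exclusions"]) == 15
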