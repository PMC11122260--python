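"""Fold-change indices, classification, ANOVA, BH and qPCR reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from caricature import (
    CohortDesign,
    Target,
    ThresholdConfig,
    anova_pvalue,
    bh_adjust,
    classify_matrix,
    classify_transcript,
    compute_fc_indices,
    group_means,
    linear_fold_change,
    qpcr_relative_expression,
)

log2_means = st.floats(min_value=2.0, max_value=14.0)


def make_design(n_normal=3, n_selected=3, n_control=3, n_excluded=0):
    normals = frozenset(f"n{i}" for i in range(n_normal))
    sel = frozenset(f"s{i}" for i in range(n_selected))
    ctrl = frozenset(f"c{i}" for i in range(n_control))
    excl = frozenset(f"x{i}" for i in range(n_excluded))
    return CohortDesign(
        target=Target("20", frozenset({"q", "w"}), "gain"),
        normal_ids=normals,
        all_crc_ids=sel | ctrl | excl,
        selected_ids=sel,
        control_ids=ctrl,
        excluded_ids=excl,
    )


def random_matrix(rng, design, n_transcripts=10):
    cols = sorted(design.normal_ids | design.all_crc_ids)
    return pd.DataFrame(
        rng.normal(6, 1, size=(n_transcripts, len(cols))),
        index=[f"tr{i}" for i in range(n_transcripts)],
        columns=cols,
    )


class TestLinearFoldChange:
    @pytest.mark.parametrize(
        "study,control,expected",
        [(7.0, 6.0, 2.0), (6.0, 6.0, 1.0), (6.0, 7.0, -2.0)],
    )
    def test_two_branch_formula(self, study, control, expected):
        assert linear_fold_change(study, control) == pytest.approx(expected)

    def test_downregulation_magnitude(self):
        # 6.585 - 5.0 = 1.585 log2 units, i.e. a 3-fold drop
        assert linear_fold_change(5.0, 6.585) == pytest.approx(-3.0, abs=1e-2)

    @given(a=log2_means, b=log2_means)
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        if a != b:
            assert linear_fold_change(a, b) == -linear_fold_change(b, a)

    @given(a=log2_means, b=log2_means)
    @settings(max_examples=200, deadline=None)
    def test_magnitude_at_least_one(self, a, b):
        assert abs(linear_fold_change(a, b)) >= 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            linear_fold_change(np.nan, 6.0)


class TestGroupMeansAndIndices:
    def test_means_match_naive_loop(self):
        rng = np.random.default_rng(0)
        design = make_design(4, 3, 5)
        matrix = random_matrix(rng, design)
        means = group_means(matrix, design)
        for tid in matrix.index:
            for col, ids in [
                ("avg_normal", design.normal_ids),
                ("avg_all_crc", design.all_crc_ids),
                ("avg_selected", design.selected_ids),
                ("avg_control", design.control_ids),
            ]:
                naive = sum(matrix.loc[tid, s] for s in sorted(ids)) / len(ids)
                assert means.loc[tid, col] == pytest.approx(naive, rel=1e-12)

    def test_single_sample_group_is_identity(self):
        design = make_design(1, 1, 1)
        matrix = random_matrix(np.random.default_rng(1), design, 3)
        means = group_means(matrix, design)
        assert (means["avg_normal"] == matrix["n0"]).all()

    def test_empty_group_flags_not_zeroes(self):
        design = make_design(2, 2, 2, 0)
        empty_sel = CohortDesign(
            target=design.target,
            normal_ids=design.normal_ids,
            all_crc_ids=design.control_ids,
            selected_ids=frozenset(),
            control_ids=design.control_ids,
            excluded_ids=frozenset(),
            flagged=True,
        )
        matrix = random_matrix(np.random.default_rng(2), design)
        means = group_means(matrix, empty_sel)
        fc = compute_fc_indices(means)
        assert means["avg_selected"].isna().all()
        assert fc["incomputable"].all()
        assert fc["fc2"].isna().all()

    def test_worked_example(self):
        means = pd.DataFrame(
            {
                "avg_normal": [6.0],
                "avg_all_crc": [7.29],
                "avg_selected": [7.585],
                "avg_control": [7.0],
            },
            index=["t"],
        )
        fc = compute_fc_indices(means)
        assert fc.loc["t", "fc3"] == pytest.approx(2.0)
        assert fc.loc["t", "fc2"] == pytest.approx(1.5, abs=1e-3)
        assert fc.loc["t", "fc4"] == pytest.approx(3.0, abs=2e-3)

    def test_all_groups_equal_gives_unity(self):
        means = pd.DataFrame(
            {c: [6.0] for c in ("avg_normal", "avg_all_crc", "avg_selected", "avg_control")},
            index=["t"],
        )
        fc = compute_fc_indices(means)
        assert (fc[["fc1", "fc2", "fc3", "fc4"]] == 1.0).all().all()

    def test_descending_means_all_negative(self):
        means = pd.DataFrame(
            {
                "avg_normal": [8.0],
                "avg_all_crc": [7.0],
                "avg_selected": [6.0],
                "avg_control": [7.0],
            },
            index=["t"],
        )
        fc = compute_fc_indices(means)
        assert (fc[["fc2", "fc3", "fc4"]] < 0).all().all()

    def test_ratio_multiplicativity_random(self):
        rng = np.random.default_rng(3)
        design = make_design()
        for _ in range(50):
            means = group_means(random_matrix(rng, design), design)
            fc = compute_fc_indices(means)
            assert np.allclose(
                fc["ratio4"], fc["ratio2"] * fc["ratio3"], rtol=1e-12, atol=0
            )


class TestClassification:
    @pytest.mark.parametrize(
        "fc2,fc3,fc4,expected",
        [
            (1.1, 1.6, 1.8, "UpT"),
            (1.4, 1.6, 2.2, "Over-UpT"),
            (1.1, 1.5, 1.8, "none"),       # FC3 boundary exact -> fails
            (1.1, 1.6, 1.5, "none"),       # FC4 boundary exact -> fails
            (1.4, 1.2, 1.1, "OverT"),
            (1.3, 1.6, 1.8, "UpT"),        # FC2 boundary exact -> not Over
            (-2.0, -2.0, -2.0, "none"),    # negative FCs never pass
            (1.0, 1.0, 1.0, "none"),
        ],
    )
    def test_threshold_predicates(self, fc2, fc3, fc4, expected):
        assert classify_transcript(fc2, fc3, fc4) == expected

    def test_matches_brute_force_predicates(self):
        rng = np.random.default_rng(4)
        t = ThresholdConfig()
        for _ in range(500):
            fc2, fc3, fc4 = rng.uniform(-3, 3, size=3)
            got = classify_transcript(fc2, fc3, fc4, t)
            over_upt = fc2 > 1.3 and fc3 > 1.5
            upt = fc3 > 1.5 and fc4 > 1.5
            overt = fc2 > 1.3
            want = (
                "Over-UpT" if over_upt else "UpT" if upt else "OverT" if overt else "none"
            )
            assert got == want

    def test_over_upt_subset_relations(self):
        """Over-UpT implies OverT's FC2 criterion and the FC3 criterion."""
        rng = np.random.default_rng(8)
        for _ in range(300):
            fc2, fc3, fc4 = rng.uniform(-3, 3, size=3)
            if classify_transcript(fc2, fc3, fc4) == "Over-UpT":
                assert fc2 > 1.3 and fc3 > 1.5
                if fc4 > 1.5:
                    assert classify_transcript(1.0, fc3, fc4) == "UpT"

    def test_require_upt_narrows_over_upt(self):
        strict = ThresholdConfig(require_upt=True)
        # with FC4 below 1.5 the subset reading demotes Over-UpT
        assert classify_transcript(1.4, 1.6, 1.4, strict) != "Over-UpT"
        assert classify_transcript(1.4, 1.6, 2.0, strict) == "Over-UpT"

    def test_incomputable_labels_none(self):
        assert classify_transcript(np.nan, 2.0, 2.0) == "none"


class TestAnova:
    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        t, p_t = stats.ttest_ind(a, b)
        assert anova_pvalue([a, b]) == pytest.approx(p_t, rel=1e-10)

    def test_matches_sum_of_squares_oracle(self):
        groups = [[6.1, 5.9, 6.3], [7.0, 7.2, 6.8, 7.1], [5.5, 5.8]]
        arrays = [np.asarray(g) for g in groups]
        grand = np.concatenate(arrays).mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        k, n = len(arrays), sum(len(a) for a in arrays)
        f = (ssb / (k - 1)) / (ssw / (n - k))
        p_oracle = stats.f.sf(f, k - 1, n - k)
        assert anova_pvalue(groups) == pytest.approx(p_oracle, rel=1e-10)

    def test_degenerate_identical_values_reports_one(self):
        assert anova_pvalue([[5.0, 5.0], [5.0, 5.0]]) == 1.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_pvalue([[1.0], [2.0, 3.0]])


class TestBenjaminiHochberg:
    @staticmethod
    def quadratic_oracle(p):
        """Literal step-up definition: adj_i = min over ranks >= rank(i)."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for pos, idx in enumerate(order, start=1):
            candidates = [
                p[order[k - 1]] * m / k for k in range(pos, m + 1)
            ]
            adj[idx] = min(1.0, min(candidates))
        return adj

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_quadratic_oracle(self, ps):
        got = bh_adjust(ps)
        want = self.quadratic_oracle(ps)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
        # monotone in rank, bounded by [max(p) after adjustment, 1]
        order = np.argsort(ps, kind="stable")
        assert (np.diff(got[order]) >= -1e-12).all()
        assert (got <= 1.0).all() and (got >= np.asarray(ps) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestQpcr:
    @pytest.mark.parametrize("ct_t,ct_r,expected", [(25.0, 20.0, 0.2), (22.0, 20.0, 0.5)])
    def test_reciprocal_delta_ct(self, ct_t, ct_r, expected):
        assert qpcr_relative_expression(ct_t, ct_r) == pytest.approx(expected)

    def test_zero_delta_ct_undefined(self):
        with pytest.raises(ZeroDivisionError):
            qpcr_relative_expression(20.0, 20.0)

    def test_negative_delta_ct_warns_but_returns(self):
        assert qpcr_relative_expression(18.0, 20.0) == pytest.approx(-0.5)


class TestClassifyMatrix:
    def test_annotation_biotype_filter(self):
        rng = np.random.default_rng(6)
        design = make_design()
        matrix = random_matrix(rng, design, 4)
        ann = pd.DataFrame(
            {
                "chrom": ["20"] * 4,
                "start": [0, 10, 20, 30],
                "end": [5, 15, 25, 35],
                "biotype": ["lncRNA", "mRNA", "lncRNA", "pri_mirna"],
            },
            index=matrix.index,
        )
        result = classify_matrix(
            matrix, design, annotation=ann, biotype_allowlist=["lncRNA"]
        )
        assert set(result.index) == {"tr0", "tr2"}

    def test_fdr_filter_demotes_nonsignificant(self):
        rng = np.random.default_rng(9)
        design = make_design(5, 5, 5)
        cols = sorted(design.normal_ids | design.all_crc_ids)
        # flat transcript: big FCs impossible, but construct one with a
        # strong effect and one pure-noise transcript
        strong = np.where([c.startswith("n") for c in cols], 6.0, 8.0)
        noise = rng.normal(6, 0.01, len(cols))
        matrix = pd.DataFrame([strong + rng.normal(0, 0.01, len(cols)), noise],
                              index=["hit", "null"], columns=cols)
        res_plain = classify_matrix(matrix, design)
        res_fdr = classify_matrix(matrix, design, fdr_filter=True)
        assert res_plain.loc["hit", "class_label"] == "UpT"
        assert res_fdr.loc["hit", "class_label"] == "UpT"
        assert res_fdr.loc["null", "class_label"] == "none"
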