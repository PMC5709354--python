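"""Moderated t, the three marker filters, and template derivation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ntpkit
from ntpkit.errors import DegenerateDataWarning, DerivationError, ValidationError


def emat_from(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestModeratedT:
    def test_identical_groups_give_zero_t_unit_p(self):
        values = np.vstack([
            np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),   # identical in both groups
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        ])
        emat = emat_from(values)
        de = ntpkit.moderated_t_test(emat, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert de.loc["g0", "lfc"] == 0
        assert de.loc["g0", "t_stat"] == 0
        assert de.loc["g0", "p"] == 1

    def test_homogeneous_variance_reduces_to_ordinary_t(self):
        """When every gene shares one residual variance there is nothing to
        shrink: moderated t must equal the ordinary pooled t."""
        rng = np.random.default_rng(0)
        n_genes, n_a, n_b = 60, 4, 4
        pattern = np.array([-1.5, -0.5, 0.5, 1.5])  # same within-group shape everywhere
        mu_a = rng.normal(5, 2, size=n_genes)
        mu_b = rng.normal(5, 2, size=n_genes)
        A = mu_a[:, None] + pattern[None, :]
        B = mu_b[:, None] + pattern[None, :]
        emat = emat_from(np.hstack([A, B]))
        ga = [f"s{j}" for j in range(n_a)]
        gb = [f"s{j}" for j in range(n_a, n_a + n_b)]
        with pytest.warns(DegenerateDataWarning, match="ordinary"):
            de = ntpkit.moderated_t_test(emat, ga, gb)
        t_ref = sps.ttest_ind(A, B, axis=1, equal_var=True)
        assert np.max(np.abs(de["t_stat"].to_numpy() - t_ref.statistic)) < 1e-8
        assert np.max(np.abs(de["p"].to_numpy() - t_ref.pvalue)) < 1e-8

    def test_recovers_planted_fold_change(self):
        rng = np.random.default_rng(1)
        n_genes, planted, lfc, sd = 2000, 100, 2.0, 0.5
        base = rng.normal(7, 1, size=n_genes)
        A = base[:, None] + rng.normal(0, sd, size=(n_genes, 10))
        B = base[:, None] + rng.normal(0, sd, size=(n_genes, 10))
        A[:planted] += lfc
        emat = emat_from(np.hstack([A, B]))
        de = ntpkit.moderated_t_test(
            emat, [f"s{j}" for j in range(10)], [f"s{j}" for j in range(10, 20)]
        )
        assert abs(de["lfc"].iloc[:planted].mean() - lfc) < 0.15
        assert (de["adj_p"] >= de["p"]).all()

    def test_small_group_rejected(self):
        emat = emat_from(np.ones((3, 4)))
        with pytest.raises(ValidationError, match=">= 2"):
            ntpkit.moderated_t_test(emat, ["s0"], ["s1", "s2", "s3"])

    def test_overlapping_groups_rejected(self):
        emat = emat_from(np.ones((3, 4)))
        with pytest.raises(ValidationError, match="disjoint"):
            ntpkit.moderated_t_test(emat, ["s0", "s1"], ["s1", "s2"])


class TestCandidateMarkers:
    def test_planted_markers_recovered(self):
        emat, truth = ntpkit.simulate_cohort(
            n_samples=80, n_genes=1000, markers_per_class=25, marker_lfc=3.0,
            stromal_present=False, seed=7,
        )
        found = ntpkit.candidate_markers(emat, truth.labels)
        for cls, planted in truth.marker_map.items():
            hits = set(found[cls]) & set(planted)
            recall = len(hits) / len(planted)
            precision = len(hits) / len(found[cls])
            assert recall >= 0.95, f"{cls}: recall {recall}"
            assert precision >= 0.9, f"{cls}: precision {precision}"

    def test_noise_yields_essentially_no_candidates(self):
        emat, truth = ntpkit.simulate_cohort(
            n_samples=80, n_genes=1000, marker_lfc=0.0, stromal_present=False, seed=8
        )
        found = ntpkit.candidate_markers(emat, truth.labels)
        assert sum(len(v) for v in found.values()) <= 0.01 * 1000

    def test_infinite_threshold_empties_all_classes(self):
        emat, truth = ntpkit.simulate_cohort(
            n_samples=40, n_genes=200, markers_per_class=10, seed=9
        )
        found = ntpkit.candidate_markers(emat, truth.labels, lfc_min=np.inf)
        assert all(len(v) == 0 for v in found.values())

    def test_class_below_two_samples_rejected(self):
        emat = emat_from(np.random.default_rng(0).normal(size=(10, 5)))
        labels = pd.Series(["A", "A", "B", "B", "C"], index=emat.columns)
        with pytest.raises(ValidationError, match="C"):
            ntpkit.candidate_markers(emat, labels)


class TestRobustIntrinsicFilter:
    def test_ipr_hand_example(self):
        values = np.array([
            [0.0, 0.0, 10.0, 10.0],
            [5.0, 5.0, 5.0, 5.0],
            [4.0, 4.0, 4.0, 4.0],
            [3.0, 3.0, 3.0, 3.0],
        ])
        # only g0 has nonzero 10-90 IPR; top-25% cutoff keeps it alone
        kept = ntpkit.robust_intrinsic_filter(emat_from(values), min_samples=1)
        assert kept == ["g0"]

    def test_min_samples_criterion(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=(40, 4))
        # g0 in the top quartile of 3 samples, g1 in only 2
        values[0, :3] = 20.0
        values[0, 3] = -20.0
        values[1, :2] = 19.0
        values[1, 2:] = -19.0
        emat = emat_from(values)
        kept = ntpkit.robust_intrinsic_filter(emat, min_samples=3)
        assert "g0" in kept and "g1" not in kept
        kept2 = ntpkit.robust_intrinsic_filter(emat, min_samples=2)
        assert "g1" in kept2

    def test_constant_matrix_empty_with_warning(self):
        with pytest.warns(DegenerateDataWarning):
            kept = ntpkit.robust_intrinsic_filter(emat_from(np.ones((5, 4))))
        assert kept == []

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="min_samples"):
            ntpkit.robust_intrinsic_filter(emat_from(np.ones((5, 2))), min_samples=3)


class TestIntrinsicFilter:
    def test_directional_exclusion(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, size=50)
        tumor = emat_from(base[:, None] + rng.normal(0, 0.2, (50, 6)),
                          samples=[f"t{j}" for j in range(6)])
        xeno = emat_from(base[:, None] + rng.normal(0, 0.2, (50, 6)),
                         samples=[f"x{j}" for j in range(6)])
        tumor.iloc[0] += 4.0  # stromal gene: +4 log2 units in tumors
        kept = ntpkit.intrinsic_filter(tumor, xeno)
        assert "g0" not in kept
        assert "g1" in kept  # identical means, lfc ~ 0

    def test_planted_stromal_simulation(self):
        tumor, xeno, truth = ntpkit.simulate_model_pair(
            n_samples=60, n_genes=1000, markers_per_class=25, n_stromal=50,
            stromal_lfc=3.0, seed=4,
        )
        kept = set(ntpkit.intrinsic_filter(tumor, xeno, lfc_max=2.0))
        stromal = set(truth.stromal_genes)
        excluded_stromal = len(stromal - kept) / len(stromal)
        non_stromal = set(tumor.index) - stromal
        excluded_other = len(non_stromal - kept) / len(non_stromal)
        assert excluded_stromal >= 48 / 50
        assert excluded_other <= 0.05

    def test_no_stromal_signal_retains_nearly_all(self):
        tumor, xeno, _ = ntpkit.simulate_model_pair(
            n_samples=60, n_genes=1000, markers_per_class=25, n_stromal=50,
            stromal_lfc=0.0, seed=5,
        )
        kept = ntpkit.intrinsic_filter(tumor, xeno, lfc_max=2.0)
        assert len(kept) >= 0.95 * 1000

    def test_swapping_cohorts_flips_sign(self):
        tumor, xeno, truth = ntpkit.simulate_model_pair(
            n_samples=40, n_genes=300, markers_per_class=10, n_stromal=30,
            stromal_lfc=3.0, seed=6,
        )
        kept_fwd = set(ntpkit.intrinsic_filter(tumor, xeno, lfc_max=2.0))
        kept_rev = set(ntpkit.intrinsic_filter(xeno, tumor, lfc_max=2.0))
        stromal = set(truth.stromal_genes)
        # stromal genes are high in tumors: excluded forward, retained reversed
        assert len(stromal - kept_fwd) >= 0.9 * len(stromal)
        assert len(stromal & kept_rev) == len(stromal)

    def test_empty_intersection_rejected(self):
        a = emat_from(np.ones((3, 4)), genes=["a1", "a2", "a3"])
        b = emat_from(np.ones((3, 4)), genes=["b1", "b2", "b3"])
        with pytest.raises(ValidationError, match="no genes"):
            ntpkit.intrinsic_filter(a, b)


class TestDeriveTemplate:
    def test_set_algebra(self):
        tpl, report = ntpkit.derive_template(
            {"A": ["g1", "g2"], "B": ["g3"]},
            robust=["g1", "g3"],
            intrinsic=["g1", "g2", "g3"],
        )
        assert tpl.members == {"A": ("g1",), "B": ("g3",)}
        g2 = report.set_index("gene").loc["g2"]
        assert g2["removal_reason"] == "not_robust"
        assert not g2["passed_robust"] and g2["passed_intrinsic"]

    def test_identity_when_filters_pass_everything(self):
        candidates = {"A": ["g1", "g2"], "B": ["g3"]}
        everything = ["g1", "g2", "g3"]
        tpl, report = ntpkit.derive_template(candidates, everything, everything)
        assert tpl.members == {"A": ("g1", "g2"), "B": ("g3",)}
        assert (report["removal_reason"] == "kept").all()

    def test_empty_class_raises(self):
        with pytest.raises(DerivationError, match="B"):
            ntpkit.derive_template({"A": ["g1"], "B": ["g2"]}, ["g1"], ["g1"])


class TestPipelineProperties:
    def test_relaxing_thresholds_never_shrinks_template(self, trio):
        """Monotonicity: looser candidate/intrinsic thresholds give a
        superset template."""
        tumor, truth = trio["tumor"], trio["truth"]
        labels = truth.labels.loc[tumor.columns]
        strict_cand = ntpkit.candidate_markers(tumor, labels, lfc_min=1.5, adjp_max=0.01)
        loose_cand = ntpkit.candidate_markers(tumor, labels, lfc_min=1.0, adjp_max=0.1)
        strict_all = {g for v in strict_cand.values() for g in v}
        loose_all = {g for v in loose_cand.values() for g in v}
        assert strict_all <= loose_all

        strict_intr = set(ntpkit.intrinsic_filter(trio["paired_tumor"], trio["paired_xeno"], lfc_max=1.0))
        loose_intr = set(ntpkit.intrinsic_filter(trio["paired_tumor"], trio["paired_xeno"], lfc_max=2.0))
        assert strict_intr <= loose_intr

        narrow_robust = set(ntpkit.robust_intrinsic_filter(trio["cells"], ipr_top_fraction=0.1,
                                                           expr_top_fraction=0.1))
        wide_robust = set(ntpkit.robust_intrinsic_filter(trio["cells"], ipr_top_fraction=0.25,
                                                         expr_top_fraction=0.25))
        assert narrow_robust <= wide_robust

    def test_selector_estimator_protocol(self, derived_template, trio):
        from sklearn.base import clone

        sel = derived_template
        assert sel.template_set_.classes == tuple(sorted(trio["truth"].marker_map))
        fresh = clone(sel)
        assert fresh.get_params()["lfc_max"] == 2.0
        report = sel.report_
        assert set(report.loc[report["final_class"].notna(), "gene"]) == set(
            sel.template_set_.genes
        )
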