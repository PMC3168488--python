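import math

import numpy as np
import pytest
from scipy import stats

from stratiq import (
    NO_SHRINKAGE,
    ValidationError,
    VariancePrior,
    bh_adjust,
    classify_diet_response,
    estimate_variance_prior,
    moderated_t_test,
    run_all_contrasts,
    quantitative_filter,
)

from conftest import bh_step_up, build_quantitative


def two_group_study(group_a_log2, group_b_log2, extra_null=0):
    """One probe with given log2 values in FC/LC (plus optional null probes)."""
    rows = {
        "p0": {
            "FC": [2.0 ** v for v in group_a_log2],
            "FF": [2.0 ** v for v in group_a_log2],
            "LC": [2.0 ** v for v in group_b_log2],
            "LF": [2.0 ** v for v in group_b_log2],
        }
    }
    rng = np.random.default_rng(0)
    for i in range(extra_null):
        vals = 2.0 ** rng.normal(8, 0.3, 4 * len(group_a_log2))
        chunks = np.split(vals, 4)
        rows[f"n{i}"] = {g: list(c) for g, c in zip(("FC", "FF", "LC", "LF"), chunks)}
    return build_quantitative(rows)


class TestVariancePrior:
    def test_identical_variances_degenerate(self):
        prior = estimate_variance_prior(np.full(50, 0.5), df=6)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.5)

    def test_parameter_recovery_from_scaled_inv_chi2(self):
        """d0=4, s0^2=1 recovered within [3, 5] from 10,000 probes."""
        rng = np.random.default_rng(123)
        d0, s0_sq, df = 4.0, 1.0, 6
        true_var = d0 * s0_sq / rng.chisquare(d0, 10_000)
        s2 = true_var * rng.chisquare(df, 10_000) / df
        prior = estimate_variance_prior(s2, df=df)
        assert 3.0 <= prior.d0 <= 5.0
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.1)

    def test_too_few_probes_fails(self):
        with pytest.raises(ValidationError, match=">=10"):
            estimate_variance_prior(np.array([0.5, 0.7]), df=6)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValidationError):
            VariancePrior(d0=-1.0, s0_sq=1.0)


class TestModeratedT:
    def test_d0_zero_matches_hand_computed_pooled_t(self):
        study = two_group_study([10, 12, 11, 13], [8, 9, 7, 8])
        res = moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)
        assert res.loc["p0", "log2_fold"] == pytest.approx(3.5)
        assert res.loc["p0", "s2"] == pytest.approx(7 / 6)
        assert res.loc["p0", "t"] == pytest.approx(4.583, abs=5e-4)

    def test_d0_zero_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(5)
        a = rng.normal(9, 0.5, 4)
        b = rng.normal(8.5, 0.5, 4)
        study = two_group_study(list(a), list(b))
        res = moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.loc["p0", "t"] == pytest.approx(t_ref)
        assert res.loc["p0", "p"] == pytest.approx(p_ref)

    def test_identical_groups_give_t0_p1(self):
        study = two_group_study([10, 11, 12, 10.5], [10, 11, 12, 10.5])
        res = moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)
        assert res.loc["p0", "t"] == 0.0
        assert res.loc["p0", "p"] == 1.0

    def test_infinite_d0_at_pooled_variance_shrinks_p_only(self):
        study = two_group_study([10, 12, 11, 13], [8, 9, 7, 8])
        plain = moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)
        s2 = float(plain.loc["p0", "s2"])
        inf_prior = VariancePrior(d0=math.inf, s0_sq=s2)
        res = moderated_t_test(study, "FCvsLC", prior=inf_prior)
        assert res.loc["p0", "t"] == pytest.approx(plain.loc["p0", "t"])
        assert res.loc["p0", "p"] <= plain.loc["p0", "p"]

    def test_antisymmetric_under_group_swap(self):
        study = two_group_study([10, 12, 11, 13], [8, 9, 7, 8], extra_null=12)
        fc = moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)
        # swap: build with groups exchanged
        swapped = build_quantitative(
            {
                p: {
                    "FC": list(study.intensities.loc[p, study.sample_ids("L", diet="control")]),
                    "FF": list(study.intensities.loc[p, study.sample_ids("L", diet="highfat")]),
                    "LC": list(study.intensities.loc[p, study.sample_ids("F", diet="control")]),
                    "LF": list(study.intensities.loc[p, study.sample_ids("F", diet="highfat")]),
                }
                for p in study.probe_ids
            }
        )
        fc_sw = moderated_t_test(swapped, "FCvsLC", prior=NO_SHRINKAGE)
        np.testing.assert_allclose(fc_sw["t"], -fc["t"])
        np.testing.assert_allclose(fc_sw["p"], fc["p"])

    def test_shift_invariance_on_log_scale(self):
        study = two_group_study([10, 12, 11, 13], [8, 9, 7, 8], extra_null=12)
        shifted = build_quantitative(
            {
                p: {
                    g: list(
                        study.intensities.loc[p, study.sample_ids(l, diet=d)] * 8.0
                    )
                    for g, (l, d) in {
                        "FC": ("F", "control"),
                        "FF": ("F", "highfat"),
                        "LC": ("L", "control"),
                        "LF": ("L", "highfat"),
                    }.items()
                }
                for p in study.probe_ids
            }
        )
        a = moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)
        b = moderated_t_test(shifted, "FCvsLC", prior=NO_SHRINKAGE)
        np.testing.assert_allclose(a["t"], b["t"], rtol=1e-9)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-9)

    def test_single_replicate_group_fails(self):
        rows = {"p0": {"FC": [512.0], "FF": [512.0, 510.0], "LC": [256.0, 250.0], "LF": [256.0, 250.0]}}
        study = build_quantitative(rows)
        with pytest.raises(ValidationError, match="replicates"):
            moderated_t_test(study, "FCvsLC", prior=NO_SHRINKAGE)


class TestBH:
    def test_hand_computed_example(self):
        adj = bh_adjust([0.005, 0.011, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.022, 0.02667, 0.04], atol=5e-6)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            p = rng.uniform(size=n)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 2)
            np.testing.assert_allclose(bh_adjust(p), bh_step_up(p), atol=1e-12)

    def test_out_of_range_p_fails(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestQuantitativeFilter:
    def test_planted_probe_retained_null_excluded(self):
        rng = np.random.default_rng(9)
        rows = {}
        # strong probe: 4-fold line effect, 500 AU baseline
        rows["hit"] = {
            "FC": list(2.0 ** rng.normal(11, 0.2, 4)),
            "FF": list(2.0 ** rng.normal(11, 0.2, 4)),
            "LC": list(2.0 ** rng.normal(9, 0.2, 4)),
            "LF": list(2.0 ** rng.normal(9, 0.2, 4)),
        }
        # low-AU probe: same fold, 50 AU in the higher group
        rows["dim"] = {
            "FC": list(2.0 ** rng.normal(5.64, 0.2, 4)),
            "FF": list(2.0 ** rng.normal(5.64, 0.2, 4)),
            "LC": list(2.0 ** rng.normal(3.64, 0.2, 4)),
            "LF": list(2.0 ** rng.normal(3.64, 0.2, 4)),
        }
        for i in range(30):
            rows[f"n{i}"] = {
                g: list(2.0 ** rng.normal(9, 0.2, 4)) for g in ("FC", "FF", "LC", "LF")
            }
        study = build_quantitative(rows)
        results = run_all_contrasts(study)
        sel = quantitative_filter(results)
        assert "hit" in sel["FCvsLC"]["up"]
        assert "dim" not in sel["FCvsLC"]["up"]
        assert not any(p.startswith("n") for p in sel["FCvsLC"]["up"])


class TestClassification:
    def test_diet_amplified_pattern(self):
        means = {"FC": 400.0, "FF": 1600.0, "LC": 100.0, "LF": 100.0}
        folds = {"FCvsLC": 2.0, "FFvsLF": 4.0, "FFvsFC": 2.0, "LFvsLC": 0.0}
        sig = {"FCvsLC": True, "FFvsLF": True, "FFvsFC": True, "LFvsLC": False}
        assert classify_diet_response(means, folds, sig) == "diet_amplified"

    def test_flat_probe_is_null(self):
        means = {g: 300.0 for g in ("FC", "FF", "LC", "LF")}
        folds = {c: 0.0 for c in ("FCvsLC", "FFvsLF", "FFvsFC", "LFvsLC")}
        sig = {c: False for c in folds}
        assert classify_diet_response(means, folds, sig) == "null"

    def test_line_only_pattern(self):
        means = {"FC": 400.0, "FF": 400.0, "LC": 100.0, "LF": 100.0}
        folds = {"FCvsLC": 2.0, "FFvsLF": 2.0, "FFvsFC": 0.0, "LFvsLC": 0.0}
        sig = {"FCvsLC": True, "FFvsLF": True, "FFvsFC": False, "LFvsLC": False}
        assert classify_diet_response(means, folds, sig) == "line_only"

    def test_opposing_interaction(self):
        means = {"FC": 400.0, "FF": 100.0, "LC": 100.0, "LF": 400.0}
        folds = {"FCvsLC": 2.0, "FFvsLF": -2.0, "FFvsFC": -2.0, "LFvsLC": 2.0}
        sig = {c: True for c in folds}
        assert classify_diet_response(means, folds, sig) == "interaction_opposing"

    def test_diet_only_pattern(self):
        means = {"FC": 100.0, "FF": 400.0, "LC": 100.0, "LF": 400.0}
        folds = {"FCvsLC": 0.0, "FFvsLF": 0.0, "FFvsFC": 2.0, "LFvsLC": 2.0}
        sig = {"FCvsLC": False, "FFvsLF": False, "FFvsFC": True, "LFvsLC": True}
        assert classify_diet_response(means, folds, sig) == "diet_only"

    def test_missing_group_mean_fails(self):
        with pytest.raises(ValidationError, match="LF"):
            classify_diet_response({"FC": 1.0, "FF": 1.0, "LC": 1.0}, {}, {})
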