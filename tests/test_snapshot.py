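import numpy as np
import pytest

from stratiq import (
    RELAXED,
    STRINGENT,
    FilterConfig,
    ValidationError,
    coordinate_3wat_filter,
    depot_filter,
    mean_3wat_fold,
    sfc_table,
    signed_fold_change,
    stringent_candidates,
)
from stratiq.data import NON_ADIPOSE, WAT_DEPOTS

from conftest import WORKED_EXAMPLE_F, WORKED_EXAMPLE_L, build_snapshot


def from_folds(folds_by_probe, base=400.0):
    """Snapshot study realising given signed folds exactly (L fixed at base)."""
    rows = {}
    for probe, folds in folds_by_probe.items():
        f_vals, l_vals = [], []
        for sfc in folds:
            if sfc >= 1:
                f_vals.append(base * sfc)
                l_vals.append(base)
            else:  # negative convention: -2 means L twice F
                f_vals.append(base)
                l_vals.append(base * (-sfc))
        rows[probe] = (f_vals, l_vals)
    return build_snapshot(rows)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "f,l,expected",
        [
            (947.0, 14.0, 947 / 14),  # printed MES cell, rounds to 68
            (791.0, 18.0, 791 / 18),  # printed liver cell, rounds to 44
            (50.0, 100.0, -2.0),
            (7.0, 7.0, 1.0),
        ],
    )
    def test_definition(self, f, l, expected):
        assert signed_fold_change(f, l) == pytest.approx(expected)

    def test_printed_cells_round_to_integers(self):
        assert round(signed_fold_change(947, 14)) == 68
        assert round(signed_fold_change(791, 18)) == 44

    def test_nonpositive_input_fails(self):
        with pytest.raises(ValidationError):
            signed_fold_change(0.0, 5.0)

    def test_magnitude_never_below_one(self):
        rng = np.random.default_rng(0)
        for f, l in rng.uniform(0.5, 2000, size=(200, 2)):
            assert abs(signed_fold_change(f, l)) >= 1.0


class TestDepotFilter:
    def test_clean_adipose_probe_passes_sc(self):
        study = from_folds({"p": [3.0, 1.0, 1.0, 1.1, -1.05, 1.0]})
        up_f, up_l = depot_filter(study, "SC", RELAXED)
        assert up_f == ["p"] and up_l == []

    def test_bystander_excluded_from_every_depot(self, bystander_example_study):
        # massively divergent in liver/muscle/kidney too -> window rejects it
        for depot in WAT_DEPOTS:
            up_f, up_l = depot_filter(bystander_example_study, depot, RELAXED)
            assert up_f == [] and up_l == []

    def test_bystander_passes_without_window(self, bystander_example_study):
        cfg = FilterConfig(adipose_threshold=1.5, nonadipose_window=None)
        for depot in WAT_DEPOTS:
            up_f, _ = depot_filter(bystander_example_study, depot, cfg)
            assert up_f == ["Depdc6"]

    def test_identical_lines_yield_empty_lists(self):
        study = from_folds({"p": [1.0] * 6})
        for depot in WAT_DEPOTS:
            assert depot_filter(study, depot) == ([], [])

    def test_direction_split(self):
        study = from_folds({"pF": [2.0, 1, 1, 1, 1, 1], "pL": [-2.0, 1, 1, 1, 1, 1]})
        up_f, up_l = depot_filter(study, "SC")
        assert (up_f, up_l) == (["pF"], ["pL"])

    def test_threshold_is_strict_for_relaxed_stage(self):
        study = from_folds({"p": [1.5, 1, 1, 1, 1, 1]})
        assert depot_filter(study, "SC", RELAXED) == ([], [])

    def test_brute_force_equivalence_on_random_studies(self):
        """List membership equals direct evaluation of the printed predicate."""
        rng = np.random.default_rng(42)
        folds = {}
        for i in range(50):
            signs = rng.choice([-1.0, 1.0], 6)
            mags = rng.uniform(1.0, 3.0, 6)
            folds[f"p{i:02d}"] = list(signs * mags)
        study = from_folds(folds)
        sfcs = sfc_table(study)
        for depot in WAT_DEPOTS:
            up_f, up_l = depot_filter(study, depot, RELAXED)
            for probe, fl in folds.items():
                s = dict(zip(("SC", "EPI", "MES", "LIV", "MUS", "KID"), fl))
                windowed = all(abs(s[t]) < 1.5 for t in NON_ADIPOSE)
                assert (probe in up_f) == (s[depot] > 1.5 and windowed)
                assert (probe in up_l) == (s[depot] < -1.5 and windowed)
            # and the sfc table matches the scalar function
            for probe in folds:
                np.testing.assert_allclose(sfcs.loc[probe], folds[probe])


class TestCoordinateFilter:
    def test_coordinate_probe_passes(self):
        study = from_folds({"p": [3.0, 2.8, 2.6, 1.1, -1.1, 1.05]})
        up_f, up_l = coordinate_3wat_filter(study)
        assert up_f == ["p"] and up_l == []

    def test_two_depot_probe_excluded(self):
        study = from_folds({"p": [3.0, 2.8, 1.2, 1.0, 1.0, 1.0]})
        assert coordinate_3wat_filter(study) == ([], [])

    def test_sign_discordant_probe_excluded_from_both(self):
        study = from_folds({"p": [2.0, -2.0, 2.0, 1.0, 1.0, 1.0]})
        assert coordinate_3wat_filter(study) == ([], [])

    def test_antisymmetry_under_line_swap(self):
        rng = np.random.default_rng(7)
        folds = {
            f"p{i}": list(rng.choice([-1, 1], 6) * rng.uniform(1, 4, 6)) for i in range(30)
        }
        study = from_folds(folds)
        swapped = build_snapshot(
            {
                p: (
                    [study.snapshot_column("L", t).loc[p] for t in study.tissues_present()],
                    [study.snapshot_column("F", t).loc[p] for t in study.tissues_present()],
                )
                for p in folds
            }
        )
        # rebuild with canonical tissue order
        order = ("SC", "EPI", "MES", "LIV", "MUS", "KID")
        swapped = build_snapshot(
            {
                p: (
                    [float(study.snapshot_column("L", t).loc[p]) for t in order],
                    [float(study.snapshot_column("F", t).loc[p]) for t in order],
                )
                for p in folds
            }
        )
        up_f, up_l = coordinate_3wat_filter(study)
        sw_f, sw_l = coordinate_3wat_filter(swapped)
        assert up_f == sw_l and up_l == sw_f

    def test_monotone_in_threshold_and_window(self):
        rng = np.random.default_rng(3)
        folds = {
            f"p{i}": list(rng.choice([-1, 1], 6) * rng.uniform(1, 4, 6)) for i in range(40)
        }
        study = from_folds(folds)
        base_f, base_l = coordinate_3wat_filter(study, FilterConfig(1.5, 2.5))
        tight_f, tight_l = coordinate_3wat_filter(study, FilterConfig(2.0, 2.5))
        narrow_f, narrow_l = coordinate_3wat_filter(study, FilterConfig(1.5, 1.5))
        assert set(tight_f) <= set(base_f) and set(tight_l) <= set(base_l)
        assert set(narrow_f) <= set(base_f) and set(narrow_l) <= set(base_l)


class TestStringent:
    def test_strong_candidate_retained_with_mean_fold(self):
        study = from_folds({"p": [4.0, 4.0, 4.0, 1.1, 1.0, -1.1]}, base=125.0)
        table = stringent_candidates(study)
        assert table.up_f["3WAT"] == ["p"]
        assert table.mean_3wat[ "p"] == pytest.approx(4.0)

    def test_low_intensity_candidate_excluded_by_floor(self):
        study = from_folds({"p": [4.0, 4.0, 4.0, 1.0, 1.0, 1.0]}, base=15.0)
        # F-line mean 3-WAT intensity = 60 AU < 100
        assert stringent_candidates(study).up_f["3WAT"] == []

    def test_fold_exactly_two_retained(self):
        study = from_folds({"p": [2.0, 2.0, 2.0, 1.0, 1.0, 1.0]}, base=400.0)
        assert stringent_candidates(study).up_f["3WAT"] == ["p"]

    def test_nested_in_relaxed_at_matched_window(self):
        rng = np.random.default_rng(11)
        folds = {
            f"p{i}": list(rng.choice([-1, 1], 6) * rng.uniform(1, 4, 6)) for i in range(60)
        }
        study = from_folds(folds, base=300.0)
        stringent = stringent_candidates(study)
        relaxed_f, relaxed_l = coordinate_3wat_filter(
            study, FilterConfig(adipose_threshold=1.5, nonadipose_window=2.0)
        )
        assert set(stringent.up_f["3WAT"]) <= set(relaxed_f)
        assert set(stringent.up_l["3WAT"]) <= set(relaxed_l)

    def test_up_l_floor_uses_lean_line_intensity(self):
        # up in L with high L-line AU but tiny F-line AU: floor must look at L
        study = build_snapshot({"p": ([50.0] * 6, [400.0, 420.0, 380.0, 55.0, 52.0, 48.0])})
        table = stringent_candidates(study)
        assert table.up_l["3WAT"] == ["p"]


class TestMean3WatFold:
    def test_arithmetic(self):
        study = from_folds({"p": [6.0, 8.0, 7.0, 1.0, 1.0, 1.0]})
        assert mean_3wat_fold(study, "p") == pytest.approx(7.0)

    def test_constant(self):
        study = from_folds({"p": [3.4, 3.4, 3.4, 1.0, 1.0, 1.0]})
        assert mean_3wat_fold(study, "p") == pytest.approx(3.4)

    def test_sign_discordant_fails(self):
        study = from_folds({"p": [2.0, -2.0, 2.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="sign-discordant"):
            mean_3wat_fold(study, "p")

    def test_planted_high_fold_probe_lands_near_seven(self):
        """A ~2.8 log2 effect with sd 0.1 pooled noise gives mean fold in [6, 8]."""
        from stratiq import GeneratorConfig, generate_snapshot

        cfg = GeneratorConfig(
            n_probes=50,
            class_counts={"adipose_F_up": 10},
            effects={"adipose_F_up": 2.8},
            noise_sd=0.1,
        )
        study, truth = generate_snapshot(cfg, seed=5)
        planted = truth.index[truth["class"] == "adipose_F_up"]
        folds = [mean_3wat_fold(study, p) for p in planted]
        assert all(6.0 <= f <= 8.0 for f in folds)
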