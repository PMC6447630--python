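"""Sensitivity sweeps, optimum selection and method-comparison statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ceusdro as cd
from ceusdro.errors import InputError
from ceusdro.experiments import PARAMETERS, evaluate_settings


class TestRelativeError:
    @pytest.mark.parametrize(
        "measured,truth,expected", [(5.0, 5.0, 0.0), (1.1, 1.0, 10.0), (0.9, 1.0, -10.0)]
    )
    def test_definition(self, measured, truth, expected):
        assert cd.relative_error(measured, truth) == pytest.approx(expected)

    def test_zero_truth_rejected(self):
        with pytest.raises(InputError):
            cd.relative_error(1.0, 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(truth=st.floats(0.5, 100.0), delta=st.floats(1e-6, 1e-3))
    def test_antisymmetric_to_first_order(self, truth, delta):
        up = cd.relative_error(truth * (1 + delta), truth)
        down = cd.relative_error(truth * (1 - delta), truth)
        assert up + down == pytest.approx(0.0, abs=1e-9)


class TestEnumeration:
    def test_experiment_counts_match_parameter_ranges(self):
        assert len(cd.enumerate_settings(cd.SweepSpec(experiment=1))) == 41
        assert len(cd.enumerate_settings(cd.SweepSpec(experiment=2))) == 13
        assert len(cd.enumerate_settings(cd.SweepSpec(experiment=4))) == 5

    def test_experiment_3_is_a_seeded_subset_of_the_grid(self):
        a = cd.enumerate_settings(cd.SweepSpec(experiment=3), seed=5)
        b = cd.enumerate_settings(cd.SweepSpec(experiment=3), seed=5)
        c = cd.enumerate_settings(cd.SweepSpec(experiment=3), seed=6)
        assert len(a) == 50 and a == b and a != c
        assert len({(s.gain_db, s.dynamic_range_db) for s in a}) == 50
        for s in a:
            assert -20 <= s.gain_db <= 20 and 30 <= s.dynamic_range_db <= 90

    def test_default_total_combinations_is_109(self):
        total = sum(
            len(cd.enumerate_settings(cd.SweepSpec(experiment=e))) for e in (1, 2, 3, 4)
        )
        assert total == 109


class TestSweep:
    def test_sweep_is_deterministic(self, small_spec):
        spec = cd.SweepSpec(experiment=4, n_seeds=1, phantom=small_spec)
        a = cd.run_sweep(spec, seed=3)
        b = cd.run_sweep(spec, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["parameter"]) == set(PARAMETERS)
        assert len(a) == 5 * 1 * 4

    def test_narrow_dynamic_range_clips_washout_and_inflates_auc_error(self, small_spec):
        """Clipping at DR 30 dB destroys washout area that DR 60 dB retains."""
        seeds = [1, 2, 3]
        errs = {}
        for dr in (30.0, 60.0):
            table = evaluate_settings(
                [cd.AcquisitionSettings(gain_db=0.0, dynamic_range_db=dr)],
                small_spec,
                seeds,
            )
            auc = table[table["parameter"] == "auc"]
            errs[dr] = auc["relative_error_percent"].abs().mean()
        assert errs[30.0] > errs[60.0]


class TestFindOptimum:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            [
                {
                    "gain_db": g, "dynamic_range_db": d, "frequency_mhz": f,
                    "seed": 0, "parameter": p, "measured": np.nan, "truth": 1.0,
                    "relative_error_percent": e, "flagged": False,
                }
                for (g, d, f, errs) in rows
                for p, e in zip(PARAMETERS, errs)
            ]
        )

    def test_single_row_table_returns_that_setting(self):
        table = self._table([(18.0, 60.0, 1.5, [1, 2, 3, 4])])
        best, residuals = cd.find_optimum(table)
        assert (best.gain_db, best.dynamic_range_db) == (18.0, 60.0)
        assert residuals["mtt"] == pytest.approx(1.0)

    def test_floor_disabled_selects_global_argmin(self):
        table = self._table(
            [(0.0, 60.0, 1.5, [0.1] * 4), (15.0, 60.0, 1.5, [1.0] * 4)]
        )
        best, _ = cd.find_optimum(table, readability_floor_db=0.0)
        assert best.gain_db == 0.0

    def test_floor_excludes_low_gain_even_if_lower_error(self):
        table = self._table(
            [(0.0, 60.0, 1.5, [0.1] * 4), (15.0, 60.0, 1.5, [1.0] * 4)]
        )
        best, _ = cd.find_optimum(table, readability_floor_db=15.0)
        assert best.gain_db == 15.0

    def test_all_flagged_rows_is_an_error(self):
        table = self._table([(15.0, 60.0, 1.5, [1.0] * 4)]).assign(flagged=True)
        with pytest.raises(InputError):
            cd.find_optimum(table)


class TestCompareMethods:
    def _results(self, offsets):
        vals = {"mtt": [30, 35, 40, 45, 50], "auc": [1, 2, 3, 4, 5],
                "mi": [5, 6, 7, 8, 9], "ttp": [20, 22, 24, 26, 28]}
        return {p: np.asarray(v, dtype=float) + offsets.get(p, 0.0) for p, v in vals.items()}

    def test_identical_inputs_give_perfect_agreement(self):
        a = self._results({})
        cmp_res = cd.compare_methods(a, a)
        for p, c in cmp_res.per_parameter.items():
            assert c.pearson_r == pytest.approx(1.0)
            assert c.bias == pytest.approx(0.0)
            assert (c.loa_low, c.loa_high) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_constant_offset_appears_as_bias_with_zero_width_limits(self):
        a = self._results({"mtt": 14.0})
        b = self._results({})
        c = cd.compare_methods(a, b).per_parameter["mtt"]
        assert c.pearson_r == pytest.approx(1.0)
        assert c.bias == pytest.approx(14.0)
        assert c.loa_high - c.loa_low == pytest.approx(0.0, abs=1e-9)

    def test_pearson_matches_hand_worked_five_pair_table(self):
        # x = [1,2,3,4,5], y = [2,1,4,3,7]:
        # sum x=15, y=17, xy=63, x2=55, y2=79
        # r = (5*63-15*17)/sqrt((5*55-225)*(5*79-289)) = 60/sqrt(50*106)
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        c = cd.compare_methods({"mtt": x}, {"mtt": y}, ["mtt"]).per_parameter["mtt"]
        assert c.pearson_r == pytest.approx(60.0 / np.sqrt(50.0 * 106.0), rel=1e-12)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(InputError):
            cd.compare_methods({"mtt": [1.0, 2.0]}, {"mtt": [1.0, 2.0]}, ["mtt"])
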