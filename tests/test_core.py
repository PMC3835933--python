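"""Log-scale transform, prediction, record validation, CSV round trip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allobayes as ab
from allobayes.core import frame_to_trees, trees_to_frame


def tree(D, H, W, component="total", tree_id="t1", age=16):
    return ab.TreeRecord(tree_id=tree_id, age=age, D=D, H=H,
                         biomass={component: W})


class TestToLogData:
    @pytest.mark.parametrize(
        "D,H,W,x,y",
        [
            (10.0, 10.0, 1.0, math.log(1000.0), 0.0),
            (1.0, 1.0, 1.0, 0.0, 0.0),
        ],
    )
    def test_known_points(self, D, H, W, x, y):
        trees = [tree(D, H, W, tree_id="a"), tree(1.0, 1.0, 1.0, tree_id="b"),
                 tree(2.0, 3.0, 4.0, tree_id="c")]
        data = ab.to_log_data(trees, "total")
        assert data.x[0] == pytest.approx(math.log(D**2 * H))
        assert data.y[0] == pytest.approx(math.log(W))
        assert data.n == 3

    def test_predictor_bounded_by_size_range(self, default_trees):
        # cohort envelope: D in [5.6, 28] cm, H in [4.9, 22.7] m
        data = ab.to_log_data(default_trees, "stem")
        lo = math.log(5.6**2 * 4.9)
        hi = math.log(28.0**2 * 22.7)
        assert np.all(data.x >= lo) and np.all(data.x <= hi)

    def test_order_preserved(self, default_trees):
        data = ab.to_log_data(default_trees, "total")
        expect0 = math.log(default_trees[0].D ** 2 * default_trees[0].H)
        assert data.x[0] == pytest.approx(expect0)

    def test_missing_component_names_tree(self):
        trees = [tree(10, 10, 5, "stem", tree_id="tA"),
                 tree(10, 10, 5, "total", tree_id="tB"),
                 tree(10, 10, 5, "stem", tree_id="tC")]
        with pytest.raises(ab.AllometryError, match="tB"):
            ab.to_log_data(trees, "stem")

    def test_too_few_trees_rejected(self):
        with pytest.raises(ab.AllometryError):
            ab.to_log_data([tree(10, 10, 5), tree(11, 11, 6)], "total")


class TestTreeRecord:
    @pytest.mark.parametrize("D,H,W", [(-1, 10, 5), (10, 0, 5), (10, 10, -2)])
    def test_nonpositive_measurements_rejected(self, D, H, W):
        with pytest.raises(ab.AllometryError):
            tree(D, H, W)

    def test_unknown_component_rejected(self):
        with pytest.raises(ab.AllometryError, match="bark"):
            ab.TreeRecord("t1", 16, 10.0, 10.0, {"bark": 1.0})

    def test_inconsistent_total_flagged_not_fixed(self):
        biomass = {"stem": 10.0, "branch": 2.0, "foliage": 1.0,
                   "root": 3.0, "total": 20.0}
        with pytest.warns(UserWarning, match="component sum"):
            t = ab.TreeRecord("t1", 16, 10.0, 10.0, biomass)
        assert t.biomass["total"] == 20.0


class TestPredictBiomass:
    def test_zero_coefficients_give_unit_mass(self):
        p = ab.AllometricParams(0.0, 0.0)
        assert ab.predict_biomass(p, 13.7, 9.1) == pytest.approx(1.0)

    def test_prior_mean_total_allometry(self):
        # alpha=-2.1133, b=0.8197 at D=10 cm, H=10 m -> ~34.78 kg
        p = ab.AllometricParams(-2.1133, 0.8197)
        w = ab.predict_biomass(p, 10.0, 10.0)
        assert w == pytest.approx(
            math.exp(-2.1133 + 0.8197 * math.log(1000.0)), rel=1e-12
        )
        assert w == pytest.approx(34.78, abs=0.01)

    def test_unit_slope_identity(self):
        p = ab.AllometricParams(0.0, 1.0)
        assert ab.predict_biomass(p, 1.0, math.e) == pytest.approx(math.e)

    def test_baskerville_requires_sigma2(self):
        with pytest.raises(ab.AllometryError, match="sigma2"):
            ab.predict_biomass(ab.AllometricParams(-2, 0.8), 10, 10,
                               correction="baskerville")

    def test_baskerville_is_constant_inflation(self):
        p = ab.AllometricParams(-2.0, 0.8, sigma2=0.09)
        D = np.array([6.0, 12.0, 25.0])
        H = np.array([5.0, 11.0, 21.0])
        ratio = (ab.predict_biomass(p, D, H, "baskerville")
                 / ab.predict_biomass(p, D, H, "none"))
        assert np.allclose(ratio, math.exp(0.045))
        assert np.all(ratio > 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(-6, 0), b=st.floats(0.5, 1.2),
        D=st.floats(1.0, 50.0), H=st.floats(1.0, 30.0),
    )
    def test_log_round_trip(self, alpha, b, D, H):
        p = ab.AllometricParams(alpha, b)
        w = ab.predict_biomass(p, D, H)
        assert math.log(w) == pytest.approx(alpha + b * math.log(D**2 * H),
                                            rel=1e-9, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(b=st.floats(0.1, 1.5), D=st.floats(2.0, 40.0), H=st.floats(2.0, 25.0))
    def test_monotone_in_size_for_positive_slope(self, b, D, H):
        p = ab.AllometricParams(-3.0, b)
        w = ab.predict_biomass(p, D, H)
        assert ab.predict_biomass(p, D * 1.1, H) > w
        assert ab.predict_biomass(p, D, H * 1.1) > w


class TestCsvRoundTrip:
    def test_frame_round_trip_preserves_records(self, default_trees):
        back = frame_to_trees(trees_to_frame(default_trees))
        assert back == default_trees

    def test_file_round_trip(self, default_trees, tmp_path):
        path = tmp_path / "trees.csv"
        ab.write_trees_csv(default_trees, path)
        assert ab.read_trees_csv(path)[0].tree_id == default_trees[0].tree_id

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ab.AllometryError, match="missing columns"):
            frame_to_trees(pd.DataFrame({"tree_id": ["a"]}))
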