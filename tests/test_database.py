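import numpy as np
import pytest

from apmoments.cell_models import CellModel, PacingProtocol
from apmoments.database import (
    BiomarkerSpec,
    ParameterBox,
    SimulationDatabase,
    TimeSeriesSpec,
    build_database,
    sobol_sample,
)


class TestParameterBox:
    def test_volume(self):
        box = ParameterBox(["a", "b"], [0.0, 1.0], [2.0, 4.0])
        assert box.volume == pytest.approx(6.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ParameterBox(["a"], [1.0], [1.0])

    def test_index_unknown(self):
        with pytest.raises(KeyError):
            ParameterBox.cube(["a"], 0, 1).index("z")


class TestSobolSample:
    def test_reference_values_1d_skip1(self):
        box = ParameterBox(["x"], [0.0], [1.0])
        cs = sobol_sample(box, 3, skip=1)
        np.testing.assert_allclose(cs.points.ravel(), [0.5, 0.75, 0.25])

    def test_affine_map_preserves_bounds(self):
        box = ParameterBox.cube([f"g{i}" for i in range(6)], 0.5, 2.0)
        cs = sobol_sample(box, 8)
        assert cs.points.shape == (8, 6)
        assert np.all(cs.points >= 0.5) and np.all(cs.points <= 2.0)

    def test_deterministic(self):
        box = ParameterBox.cube(["a", "b"], 0.0, 1.0)
        a = sobol_sample(box, 32).points
        b = sobol_sample(box, 32).points
        np.testing.assert_array_equal(a, b)

    def test_lower_discrepancy_than_pseudorandom(self):
        # star-discrepancy proxy: deviation of empirical box counts over
        # 20 random anchored boxes, 2^10 points in [0,1]^2
        box = ParameterBox.cube(["a", "b"], 0.0, 1.0)
        sob = sobol_sample(box, 2 ** 10).points
        rng = np.random.default_rng(42)
        psr = rng.random((2 ** 10, 2))

        def proxy(pts):
            worst = 0.0
            rng2 = np.random.default_rng(7)
            for _ in range(20):
                corner = rng2.random(2)
                frac = np.mean(np.all(pts <= corner, axis=1))
                worst = max(worst, abs(frac - corner.prod()))
            return worst

        assert proxy(sob) < proxy(psr)

    def test_dimension_cap(self):
        box = ParameterBox.cube([f"g{i}" for i in range(25)], 0.0, 1.0)
        with pytest.raises(ValueError):
            sobol_sample(box, 4)

    def test_n_points_validation(self):
        with pytest.raises(ValueError):
            sobol_sample(ParameterBox.cube(["a"], 0, 1), 0)


class TestBuildDatabase:
    def test_bookkeeping_16_points(self, toy, protocol):
        box = ParameterBox.cube(["g_dep", "g_decay"], 0.5, 2.0)
        coll = sobol_sample(box, 16)
        spec = TimeSeriesSpec(np.arange(0.0, 300.5, 5.0))
        db = build_database(toy, box, coll, protocol, spec)
        assert db.observables.shape == (16, spec.grid.size)
        assert db.valid_mask.all()
        assert db.eval_counter == 16
        assert np.all(np.isfinite(db.valid_observables))

    def test_combined_protocol_biomarker_index(self, toy):
        # 9 + 5 base biomarkers over two protocols -> 14 base, 105 with products
        protos = [PacingProtocol(frequency_hz=1.0, n_prepace=0),
                  PacingProtocol(frequency_hz=2.0, n_prepace=0)]
        box = ParameterBox.cube(["g_dep", "g_decay"], 0.8, 1.5)
        coll = sobol_sample(box, 4)
        base9 = ["APD90", "APD50", "APD30", "APA", "RMP", "V20", "dVdt_max",
                 "V_notch", "AUC"]
        spec = BiomarkerSpec(base9, pairwise=True)
        # both protocols carry all 9 names -> 18 tagged base biomarkers;
        # the 14-name (7 + 7) arithmetic is checked separately below
        db = build_database(toy, box, coll, protos, spec)
        n_base = 18
        assert len(db.observable_index) == n_base + n_base * (n_base - 1) // 2
        assert any(lab.startswith("1Hz_") for lab in db.observable_index)
        assert any(lab.startswith("2Hz_") for lab in db.observable_index)
        assert db.eval_counter == 4 * 2  # one evaluation per point per protocol

    def test_14_base_gives_105_labels(self, toy):
        protos = [PacingProtocol(frequency_hz=1.0, n_prepace=0),
                  PacingProtocol(frequency_hz=2.0, n_prepace=0)]
        box = ParameterBox.cube(["g_dep", "g_decay"], 0.8, 1.5)
        spec = BiomarkerSpec(
            ["APD90", "APD50", "APD30", "APA", "RMP", "V20", "AUC"], pairwise=True
        )
        db = build_database(toy, box, sobol_sample(box, 2), protos, spec)
        assert len(db.observable_index) == 14 + 14 * 13 // 2  # 105

    def test_failures_masked_not_raised(self, toy, protocol):
        # a wrapper model that blows up for g_dep multipliers above 1.2
        def rhs(t, y, g, stim):
            if g[0] > 1.2:  # nominal g_dep is 1.0, so g[0] is the multiplier
                raise FloatingPointError("boom")
            return toy.rhs(t, y, g, stim)

        bad = CellModel(
            name="fragile", state_dim=2,
            nominal_conductances=toy.nominal_conductances,
            fixed_parameters={}, rhs=rhs, initial_state=toy.initial_state,
        )
        box = ParameterBox.cube(["g_dep"], 0.5, 2.0)
        coll = sobol_sample(box, 16)
        spec = TimeSeriesSpec(np.arange(0.0, 100.5, 10.0))
        with pytest.warns(RuntimeWarning, match="failed"):
            db = build_database(bad, box, coll, protocol, spec)
        assert 0 < db.n_valid < 16
        assert db.eval_counter == 16
        assert np.all(np.isnan(db.observables[~db.valid_mask]))

    def test_all_failed_raises(self, toy, protocol):
        def rhs(t, y, g, stim):
            raise FloatingPointError("always")

        broken = CellModel(
            name="broken", state_dim=2,
            nominal_conductances=toy.nominal_conductances,
            fixed_parameters={}, rhs=rhs, initial_state=toy.initial_state,
        )
        box = ParameterBox.cube(["g_dep"], 0.5, 2.0)
        with pytest.raises(RuntimeError, match="all collocation"):
            build_database(broken, box, sobol_sample(box, 4), protocol,
                           TimeSeriesSpec(np.arange(0.0, 50.0, 10.0)))

    def test_rebuild_bit_identical(self, toy, protocol):
        box = ParameterBox.cube(["g_dep", "g_decay"], 0.5, 2.0)
        spec = TimeSeriesSpec(np.arange(0.0, 200.5, 5.0))
        a = build_database(toy, box, sobol_sample(box, 8), protocol, spec)
        b = build_database(toy, box, sobol_sample(box, 8), protocol, spec)
        np.testing.assert_array_equal(a.collocation.points, b.collocation.points)
        np.testing.assert_array_equal(a.observables, b.observables)

    def test_roundtrip_hdf5(self, toy_db_2p, tmp_path):
        path = str(tmp_path / "db.h5")
        toy_db_2p.save(path)
        back = SimulationDatabase.load(path)
        np.testing.assert_array_equal(back.observables, toy_db_2p.observables)
        np.testing.assert_array_equal(back.collocation.points,
                                      toy_db_2p.collocation.points)
        assert back.observable_index == toy_db_2p.observable_index
        assert back.eval_counter == toy_db_2p.eval_counter
        assert back.box.names == toy_db_2p.box.names

    def test_column_lookup(self, toy_db_2p):
        lab = toy_db_2p.observable_index[3]
        np.testing.assert_array_equal(
            toy_db_2p.column(lab), toy_db_2p.valid_observables[:, 3]
        )
        with pytest.raises(KeyError):
            toy_db_2p.column("nope")
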