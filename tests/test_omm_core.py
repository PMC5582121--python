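import numpy as np
import pytest
from scipy.optimize import brentq

from apmoments.database import CollocationSet, ParameterBox, SimulationDatabase
from apmoments.omm_core import (
    ConstraintEntry,
    MeasurementSet,
    MomentConstraintSet,
    ParameterConstraintEntry,
    SolveConfig,
    augment_with_parameter_constraints,
    constraint_residuals,
    count_constraints,
    empirical_moments,
    filter_feasible,
    solve_maxent,
)


class TestEmpiricalMoments:
    def test_single_sample_raw_targets(self):
        ms = MeasurementSet(np.array([[2.0]]), ["u"])
        cs = empirical_moments(ms, 2, standardize=False)
        assert [e.target for e in cs.entries] == [2.0, 4.0]

    def test_three_samples_hand_arithmetic(self):
        ms = MeasurementSet(np.array([[1.0], [2.0], [3.0]]), ["u"])
        cs = empirical_moments(ms, 2, standardize=False)
        assert cs.entries[0].target == pytest.approx(2.0)
        assert cs.entries[1].target == pytest.approx(14.0 / 3.0)

    def test_standardized_targets(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 2.0, size=(500, 1))
        cs = empirical_moments(MeasurementSet(y, ["u"]), 2)
        assert cs.entries[0].target == pytest.approx(0.0, abs=1e-12)
        assert cs.entries[1].target == pytest.approx(1.0, rel=1e-12)

    def test_products_enter_first_order_only(self):
        # 9 base + 36 products, N_m = 2 -> 9*2 + 36 = 54 entries
        labels = [f"b{i}" for i in range(9)]
        labels += [f"b{i}*b{j}" for i in range(9) for j in range(i + 1, 9)]
        ms = MeasurementSet(np.random.default_rng(1).random((20, 45)), labels)
        cs = empirical_moments(ms, 2)
        assert len(cs.entries) == 54

    def test_constant_column_keeps_mean_only(self):
        y = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            cs = empirical_moments(MeasurementSet(y, ["a", "b"]), 2)
        orders_b = [e.order for e in cs.entries if e.label == "b"]
        assert orders_b == [1]

    def test_high_order_warns(self):
        ms = MeasurementSet(np.random.default_rng(2).random((10, 1)), ["u"])
        with pytest.warns(RuntimeWarning, match="instability"):
            empirical_moments(ms, 4)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            empirical_moments(MeasurementSet(np.ones((3, 1)), ["u"]), 0)


class TestCountConstraints:
    @pytest.mark.parametrize(
        "b,nm,pairwise,expected",
        [(9, 2, True, 54), (14, 2, True, 119), (1, 3, False, 3),
         (3, 1, True, 6), (14, 2, False, 28)],
    )
    def test_counts(self, b, nm, pairwise, expected):
        assert count_constraints(b, nm, pairwise) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_constraints(0, 2)


def raw_entry(label, order, target):
    return ConstraintEntry(label, order, target, max(1.0, abs(target)), 0.0, 1.0)


class TestSolveMaxent:
    def test_no_constraints_gives_uniform(self, id_db):
        pdf = solve_maxent(id_db, MomentConstraintSet())
        np.testing.assert_allclose(pdf.values, 1.0 / id_db.box.volume)
        assert pdf.diagnostics["entropy"] == pytest.approx(np.log(id_db.box.volume))
        assert pdf.diagnostics["converged"]

    def test_symmetric_target_keeps_uniform(self, id_db):
        # u = theta on [0,1]; target mean exactly the quadrature mean
        target = float(np.mean(id_db.column("u")))
        cons = MomentConstraintSet(entries=[raw_entry("u", 1, target)], n_m=1)
        pdf = solve_maxent(id_db, cons)
        assert pdf.diagnostics["converged"]
        assert abs(pdf.lagrange_multipliers[1]) < 1e-6
        np.testing.assert_allclose(pdf.values, 1.0, rtol=1e-6)

    def test_oracle_equivalence_exponential_tilt(self, id_db):
        # target 0.6: rho ∝ exp(a u); oracle = scalar root find on the same
        # quadrature, independent of the Newton path
        u = id_db.column("u")
        cons = MomentConstraintSet(entries=[raw_entry("u", 1, 0.6)], n_m=1)
        pdf = solve_maxent(id_db, cons)
        assert pdf.diagnostics["converged"]

        def quad_mean(a):
            w = np.exp(a * u)
            return float(np.sum(u * w) / np.sum(w))

        a_star = brentq(lambda a: quad_mean(a) - 0.6, -50.0, 50.0, xtol=1e-12)
        lam_solver = -pdf.lagrange_multipliers[1]  # rho ∝ exp(-lam * u)
        assert lam_solver == pytest.approx(a_star, abs=1e-4)
        assert pdf.quadrature(u) == pytest.approx(0.6, abs=1e-4)

    def test_normalization_exact(self, id_db):
        cons = MomentConstraintSet(entries=[raw_entry("u", 1, 0.7)], n_m=1)
        pdf = solve_maxent(id_db, cons)
        assert pdf.quadrature(np.ones(pdf.n_valid)) == pytest.approx(1.0, abs=1e-12)
        assert np.all(pdf.values >= 0.0)

    def test_infeasible_target_diagnosed(self, id_db):
        cons = MomentConstraintSet(entries=[raw_entry("u", 1, 1.5)], n_m=1)
        pdf = solve_maxent(id_db, cons, SolveConfig(max_iter=50))
        assert not pdf.diagnostics["converged"]
        assert pdf.diagnostics["infeasible_constraints"]

    def test_entropy_decreases_under_perturbation(self, id_db):
        cons = MomentConstraintSet(
            entries=[raw_entry("u", 1, 0.6), raw_entry("u", 2, 0.45)], n_m=2
        )
        pdf = solve_maxent(id_db, cons)
        assert pdf.diagnostics["converged"]
        u = id_db.column("u")
        w = pdf.quad_weight
        # rows: quadrature-weighted constraint functions + normalization
        basis = np.vstack([np.ones_like(u), u, u ** 2]) * w
        proj = basis.T @ np.linalg.solve(basis @ basis.T, basis)
        rng = np.random.default_rng(3)
        s0 = pdf.entropy()
        n_checked = 0
        for _ in range(100):
            v = rng.standard_normal(pdf.n_valid)
            v = v - proj @ v  # constraint- and norm-preserving direction
            scale = 0.3 * np.min(pdf.values / np.maximum(np.abs(v), 1e-300))
            rho2 = pdf.values + scale * v
            if np.any(rho2 < 0):
                continue
            with np.errstate(all="ignore"):
                s2 = float(-w * np.sum(np.where(rho2 > 0, rho2 * np.log(rho2), 0)))
            assert s2 <= s0 + 1e-10
            n_checked += 1
        assert n_checked > 50

    def test_unidentifiable_parameter_flat_not_failing(self):
        # 2-D box, observable depends on theta_1 only
        box = ParameterBox.cube(["a", "b"], 0.0, 1.0)
        from apmoments.database import sobol_sample

        coll = sobol_sample(box, 2 ** 10)
        db = SimulationDatabase(
            box=box, collocation=coll,
            observables=coll.points[:, :1].copy(), observable_index=["u"],
            valid_mask=np.ones(coll.n_c, bool), eval_counter=0,
        )
        cons = MomentConstraintSet(
            entries=[raw_entry("u", 1, 0.6), raw_entry("u", 2, 0.42)], n_m=2
        )
        pdf = solve_maxent(db, cons)
        assert pdf.diagnostics["converged"]
        from apmoments.postprocess import marginal_density, parameter_mean_std

        md = marginal_density(pdf, "b")
        interior = (md.grid > 0.1) & (md.grid < 0.9)
        assert np.ptp(md.density[interior]) < 0.15 * np.mean(md.density[interior])
        mean_b, sd_b = parameter_mean_std(pdf, "b")
        assert mean_b == pytest.approx(0.5, abs=0.02)
        assert sd_b == pytest.approx(np.sqrt(1.0 / 12.0), rel=0.05)

    def test_zero_forward_evaluations(self, toy_db_2p):
        before = toy_db_2p.eval_counter
        target = float(np.mean(toy_db_2p.valid_observables[:, 10]))
        lab = toy_db_2p.observable_index[10]
        cons = MomentConstraintSet(entries=[raw_entry(lab, 1, target)], n_m=1)
        for _ in range(3):
            solve_maxent(toy_db_2p, cons)
        assert toy_db_2p.eval_counter == before


class TestConstraintResiduals:
    def test_converged_solve_below_tol(self, id_db):
        cons = MomentConstraintSet(
            entries=[raw_entry("u", 1, 0.55), raw_entry("u", 2, 0.38)], n_m=2
        )
        pdf = solve_maxent(id_db, cons)
        res = constraint_residuals(pdf, id_db, cons)
        assert np.max(np.abs(res)) < 1e-6

    def test_uniform_vs_database_self_moments(self, id_db):
        # constraints built from the database itself leave uniform exact
        u = id_db.column("u")
        cons = MomentConstraintSet(
            entries=[raw_entry("u", 1, float(np.mean(u))),
                     raw_entry("u", 2, float(np.mean(u ** 2)))],
            n_m=2,
        )
        from apmoments.omm_core import DiscretePDF

        pdf = DiscretePDF.uniform(id_db.valid_points, id_db.box)
        res = constraint_residuals(pdf, id_db, cons)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_hand_built_three_point_database(self):
        box = ParameterBox(["x"], [0.0], [1.0])
        pts = np.array([[0.0], [0.5], [1.0]])
        db = SimulationDatabase(
            box=box, collocation=CollocationSet(points=pts),
            observables=np.array([[1.0], [2.0], [4.0]]),
            observable_index=["u"],
            valid_mask=np.ones(3, bool), eval_counter=0,
        )
        from apmoments.omm_core import DiscretePDF

        # rho = (0.6, 0.9, 1.5): (1/3) * sum = 1  -> weights (0.2, 0.3, 0.5)
        pdf = DiscretePDF(points=pts, values=np.array([0.6, 0.9, 1.5]), box=box,
                          lagrange_multipliers=np.zeros(1))
        cons = MomentConstraintSet(entries=[raw_entry("u", 1, 2.0)], n_m=1)
        # achieved = 0.2*1 + 0.3*2 + 0.5*4 = 2.8 -> residual (2.8-2)/2 = 0.4
        res = constraint_residuals(pdf, db, cons)
        assert res[0] == pytest.approx(0.4)


class TestFilterFeasible:
    def test_keeps_feasible_drops_infeasible(self, id_db):
        cons = MomentConstraintSet(
            entries=[raw_entry("u", 1, 0.5), raw_entry("u", 1, 2.0)], n_m=1
        )
        with pytest.warns(RuntimeWarning, match="infeasible"):
            out = filter_feasible(id_db, cons)
        assert len(out.entries) == 1
        assert out.entries[0].target == 0.5


class TestAugmentation:
    def test_uniform_prior_standardized_targets(self, id_db):
        from apmoments.omm_core import DiscretePDF

        prior = DiscretePDF.uniform(id_db.valid_points, id_db.box)
        cons = augment_with_parameter_constraints(
            MomentConstraintSet(), prior, ["x"], 2
        )
        assert len(cons.parameter_entries) == 2
        # box [0,1]: z = (x - 0.5)/0.5; uniform gives E[z] = 0, E[z^2] = 1/3
        assert cons.parameter_entries[0].target == pytest.approx(0.0, abs=1e-3)
        assert cons.parameter_entries[1].target == pytest.approx(1.0 / 3.0, rel=1e-2)

    def test_satisfied_constraints_leave_solution_unchanged(self, id_db):
        cons = MomentConstraintSet(
            entries=[raw_entry("u", 1, 0.6)], n_m=1
        )
        pdf1 = solve_maxent(id_db, cons)
        cons2 = augment_with_parameter_constraints(cons, pdf1, ["x"], 2)
        pdf2 = solve_maxent(id_db, cons2)
        assert pdf2.diagnostics["converged"]
        np.testing.assert_allclose(pdf2.values, pdf1.values, rtol=1e-3, atol=1e-6)

    def test_pins_flat_parameter(self):
        # observable sees only "a"; a synthetic prior pins E[b] = 0.8
        box = ParameterBox.cube(["a", "b"], 0.0, 1.0)
        from apmoments.database import sobol_sample
        from apmoments.omm_core import DiscretePDF

        coll = sobol_sample(box, 2 ** 11)
        db = SimulationDatabase(
            box=box, collocation=coll,
            observables=coll.points[:, :1].copy(), observable_index=["u"],
            valid_mask=np.ones(coll.n_c, bool), eval_counter=0,
        )
        cons = MomentConstraintSet(entries=[raw_entry("u", 1, 0.6)], n_m=1)
        # prior concentrated around b = 0.8 on its own 1-D box
        bbox = ParameterBox(["b"], [0.0], [1.0])
        bcoll = sobol_sample(bbox, 2 ** 10)
        x = bcoll.points[:, 0]
        w = np.exp(-0.5 * ((x - 0.8) / 0.05) ** 2)
        rho = w / (bbox.volume / x.size * np.sum(w))
        prior = DiscretePDF(points=bcoll.points, values=rho, box=bbox,
                            lagrange_multipliers=np.zeros(1))
        cons2 = augment_with_parameter_constraints(cons, prior, ["b"], 2, box=box)
        pdf = solve_maxent(db, cons2)
        assert pdf.diagnostics["converged"]
        mean_b = pdf.quadrature(db.valid_points[:, 1])
        assert mean_b == pytest.approx(0.8, abs=1e-2)

    def test_missing_parameter_raises(self, id_db):
        from apmoments.omm_core import DiscretePDF

        prior = DiscretePDF.uniform(id_db.valid_points, id_db.box)
        with pytest.raises(KeyError):
            augment_with_parameter_constraints(MomentConstraintSet(), prior, ["zz"], 1)


class TestMeasurementSet:
    def test_label_alignment_enforced(self):
        with pytest.raises(ValueError):
            MeasurementSet(np.ones((3, 2)), ["only_one"])

    def test_select(self):
        ms = MeasurementSet(np.arange(12.0).reshape(3, 4), ["a", "b", "c", "d"])
        sub = ms.select(["d", "b"])
        np.testing.assert_array_equal(sub.samples[:, 0], ms.samples[:, 3])
        assert sub.labels == ["d", "b"]
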