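"""The empirical dG function: term arithmetic, bounds, solvation oracles
and calibration recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorprobe.fixtures import golden_breakdown_case
from anchorprobe.fragments import make_probe
from anchorprobe.scoring import (ScoringParameters, burial_probability,
                                 calibrate, compose_breakdown,
                                 effective_dielectric, score_pose,
                                 solvation_terms, vdw_corrected)
from anchorprobe.surface import SasaCalculator

P = ScoringParameters()


class TestVdwCorrected:
    @pytest.mark.parametrize("V,n,alpha,expected", [
        (-8.0, 1, 0.7, -8.0),                      # N^alpha = 1
        (-8.0, 4, 1.0, -2.0),                      # direct division
        (-8.0, 7, 0.35, -8.0 / 7 ** 0.35),         # arithmetic oracle
    ])
    def test_matches_independent_arithmetic(self, V, n, alpha, expected):
        assert vdw_corrected(V, n, alpha) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_rejects_empty_probe(self):
        with pytest.raises(ValueError):
            vdw_corrected(-1.0, 0, 0.5)


class TestBurialProbability:
    def test_zero_area_gives_prefactor(self):
        assert burial_probability(0.0, P) == pytest.approx(0.0024,
                                                           abs=1e-15)

    def test_large_area_clamps_to_one(self):
        assert burial_probability(100.0, P) == 1.0

    def test_below_clamp_matches_exponential(self):
        A = 36.0
        assert burial_probability(A, P) == pytest.approx(
            0.0024 * math.exp(0.167 * A), rel=1e-12)

    def test_rejects_negative_area(self):
        with pytest.raises(ValueError):
            burial_probability(-0.1, P)


class TestEffectiveDielectric:
    def test_buried_probe_stays_at_minimization_dielectric(self):
        assert effective_dielectric(0.0, 0.5, P) == 1.5
        assert effective_dielectric(0.7, 0.0, P) == 1.5

    def test_fully_exposed_reaches_eps_max(self):
        assert effective_dielectric(1.0, 1.0, P) == P.eps_max

    def test_midpoint_value(self):
        assert effective_dielectric(0.5, 0.5, P) == pytest.approx(
            1.5 + (20.0 - 1.5) * 0.25, abs=1e-12)


class TestBoundsAndMonotonicity:
    def test_randomized_clamp_and_bound_suite(self):
        """p in [0,1] and eps <= eps_eff <= eps_max over 1000 cases."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            A = rng.uniform(0, 120)
            fa = rng.uniform(0, 1)
            p = burial_probability(A, P)
            assert 0.0 <= p <= 1.0
            ee = effective_dielectric(fa, p, P)
            assert P.eps <= ee <= P.eps_max

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.floats(0, 200), b=st.floats(0, 200))
    def test_burial_probability_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert burial_probability(lo, P) <= burial_probability(hi, P)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(fa=st.floats(0, 1), p1=st.floats(0, 1), p2=st.floats(0, 1))
    def test_effective_dielectric_monotone_in_p(self, fa, p1, p2):
        lo, hi = sorted((p1, p2))
        assert (effective_dielectric(fa, lo, P)
                <= effective_dielectric(fa, hi, P) + 1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(E=st.floats(-50, -0.01), A=st.floats(0, 120),
           fa=st.floats(0, 1))
    def test_shielding_ratio_bounded(self, E, A, fa):
        bd = compose_breakdown(-3.0, E, 5, A, fa, 0.0, 0.0, P)
        ratio = bd.E_corr / bd.E
        assert P.eps / P.eps_max - 1e-12 <= ratio <= 1.0 + 1e-12


class TestCompose:
    def test_pinned_spreadsheet_case(self):
        bd = compose_breakdown(V=-8.0, E=-20.0, n_heavy=7, A=36.0,
                               fA_pol=0.6, S_p=0.5, S_cav=1.2, params=P)
        assert bd.V_corr == pytest.approx(-3.0237157840738176, abs=1e-12)
        assert bd.p == pytest.approx(0.9799178458192147, abs=1e-12)
        assert bd.eps_eff == pytest.approx(12.377088088593283, abs=1e-12)
        assert bd.E_corr == pytest.approx(-2.4238334400841812, abs=1e-12)
        assert bd.dG == pytest.approx(-5.935632504115908, abs=1e-12)

    def test_neutral_probe_pure_normalized_vdw(self):
        bd = compose_breakdown(V=-3.0, E=0.0, n_heavy=3, A=0.0, fA_pol=0.0,
                               S_p=0.0, S_cav=0.0,
                               params=ScoringParameters(alpha=1.0))
        assert bd.dG == pytest.approx(-1.0, abs=1e-12)

    def test_breakdown_recomposes_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            bd = compose_breakdown(
                V=rng.uniform(-15, 0), E=rng.uniform(-40, 10),
                n_heavy=int(rng.integers(1, 10)), A=rng.uniform(0, 80),
                fA_pol=rng.uniform(0, 1), S_p=rng.uniform(-2, 3),
                S_cav=rng.uniform(-2, 3), params=P)
            recomposed = (bd.V_corr + P.lambda_e * bd.E_corr
                          - P.lambda_s * (bd.S_p + bd.S_cav))
            assert bd.dG == recomposed          # exact, same arithmetic


class TestGoldenCase:
    def test_engine_reproduces_independent_recomputation(self):
        structure, pose, params, expected = golden_breakdown_case(
            n_points=96)
        engine = SasaCalculator(n_points=96)
        got = score_pose(structure, pose, expected.V, expected.E, params,
                         engine)
        for field in ("V", "V_corr", "E", "E_corr", "S_p", "S_cav", "A",
                      "fA_pol", "p", "eps_eff", "dG"):
            assert getattr(got, field) == pytest.approx(
                getattr(expected, field), abs=1e-6), field

    def test_negated_charges_flip_electrostatics(self):
        from anchorprobe.fixtures import negate_charges
        structure, pose, params, expected = golden_breakdown_case(
            n_points=96)
        neg = negate_charges(structure)
        engine = SasaCalculator(n_points=96)
        got = score_pose(neg, pose, expected.V, -expected.E, params, engine)
        assert got.E == pytest.approx(-expected.E)
        assert got.E_corr == pytest.approx(-expected.E_corr, rel=1e-9)
        # non-electrostatic terms untouched
        assert got.S_p == pytest.approx(expected.S_p, abs=1e-9)
        assert got.A == pytest.approx(expected.A, abs=1e-9)

    def test_probe_at_infinity_scores_zero(self):
        structure, pose, params, _ = golden_breakdown_case(n_points=96)
        far = pose.with_coords(pose.coords + np.array([500.0, 0, 0]))
        engine = SasaCalculator(n_points=96)
        got = score_pose(structure, far, 0.0, 0.0, params, engine)
        assert got.S_p == pytest.approx(0.0, abs=1e-9)
        assert got.S_cav == pytest.approx(0.0, abs=1e-9)
        assert got.fA_pol == pytest.approx(1.0, abs=1e-9)
        assert got.dG == pytest.approx(0.0, abs=1e-9)


class TestSolvationTerms:
    def test_pose_in_vacuum(self):
        structure, pose, params, _ = golden_breakdown_case(n_points=96)
        far = pose.with_coords(pose.coords + np.array([300.0, 0, 0]))
        engine = SasaCalculator(n_points=96)
        s_p, s_cav, A, fa = solvation_terms(structure, far, engine)
        iso = engine.compute(far.coords, far.radii)
        assert s_cav == 0.0
        assert s_p == pytest.approx(0.0, abs=1e-12)
        assert A == pytest.approx(float(iso.sum()), abs=1e-9)
        assert fa == pytest.approx(1.0, abs=1e-12)

    def test_half_buried_pose_matches_dense_oracle(self, pocket2):
        """Subset/shell bookkeeping agrees with a full-system SASA."""
        structure, truth = pocket2
        pose = make_probe("ARG")
        pose = pose.with_coords(
            pose.coords + np.array(truth["optimal_position"])
            - pose.terminal_pos)
        engine = SasaCalculator(n_points=240)
        s_p, s_cav, A, fa = solvation_terms(structure, pose, engine)
        # oracle: no subset tricks, every atom occluded by every atom
        all_c = np.vstack([pose.coords, structure.coords()])
        all_r = np.concatenate([pose.radii, structure.radii()])
        bound = engine.compute(all_c, all_r)
        iso = engine.compute(pose.coords, pose.radii)
        prot = engine.compute(structure.coords(), structure.radii())
        n = len(pose.coords)
        s_p_o = float(np.sum(pose.asps * (iso - bound[:n])))
        s_cav_o = float(np.sum(structure.asp() * (prot - bound[n:])))
        A_o = float(bound[:n].sum())
        assert A == pytest.approx(A_o, rel=0.02, abs=0.5)
        assert s_p == pytest.approx(s_p_o, rel=0.02, abs=0.02)
        assert s_cav == pytest.approx(s_cav_o, rel=0.02, abs=0.02)
        assert 0.0 <= fa <= 1.0


class TestTranslationInvariance:
    def test_rigid_translation_leaves_score_unchanged(self):
        structure, pose, params, expected = golden_breakdown_case(
            n_points=96)
        engine = SasaCalculator(n_points=96)
        base = score_pose(structure, pose, expected.V, expected.E, params,
                          engine)
        shift = np.array([11.0, -7.0, 3.0])
        from anchorprobe.structure import RigidTransform
        moved = structure.transformed(
            RigidTransform(np.eye(3), shift))
        pose2 = pose.with_coords(pose.coords + shift)
        got = score_pose(moved, pose2, expected.V, expected.E, params,
                         engine)
        assert got.dG == pytest.approx(base.dG, abs=1e-6)


class TestCalibration:
    @staticmethod
    def _context(rng):
        return dict(V=rng.uniform(-12, -1), E=rng.uniform(-30, 5),
                    n_heavy=int(rng.integers(3, 9)), A=rng.uniform(0, 40),
                    fA_pol=rng.uniform(0, 1), S_p=rng.uniform(-1, 2),
                    S_cav=rng.uniform(-1, 2))

    @staticmethod
    def _dg(ctx, params):
        return compose_breakdown(ctx["V"], ctx["E"], ctx["n_heavy"],
                                 ctx["A"], ctx["fA_pol"], ctx["S_p"],
                                 ctx["S_cav"], params).dG

    def test_noiseless_recovery_within_one_percent(self):
        true = ScoringParameters(alpha=0.62, lambda_e=0.31, lambda_s=1.4,
                                 eps_max=14.0)
        rng = np.random.default_rng(0)
        train = []
        for _ in range(60):
            a, b = self._context(rng), self._context(rng)
            train.append((a, b, self._dg(a, true) - self._dg(b, true)))
        res = calibrate(train)
        for f in ("alpha", "lambda_e", "lambda_s", "eps_max"):
            got, want = getattr(res.params, f), getattr(true, f)
            assert abs(got - want) / abs(want) < 0.01, f
        assert res.correlation > 0.999

    def test_noisy_recovery_within_fifteen_percent_over_20_seeds(self):
        true = ScoringParameters(alpha=0.62, lambda_e=0.31, lambda_s=1.4,
                                 eps_max=14.0)
        worst = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            train = []
            for _ in range(60):
                a, b = self._context(rng), self._context(rng)
                t = self._dg(a, true) - self._dg(b, true)
                train.append((a, b, t * (1 + 0.1 * rng.standard_normal())))
            res = calibrate(train)
            worst.append(max(
                abs(getattr(res.params, f) - getattr(true, f))
                / abs(getattr(true, f))
                for f in ("alpha", "lambda_e", "lambda_s", "eps_max")))
        assert float(np.mean(worst)) < 0.15

    def test_underdetermined_training_set_rejected(self):
        rng = np.random.default_rng(1)
        a, b = self._context(rng), self._context(rng)
        with pytest.raises(ValueError):
            calibrate([(a, b, 0.0)],
                      free=("alpha", "lambda_e", "lambda_s", "eps_max"))
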