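"""Assumption-specific mean and covariance construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rbcea as rb
from rbcea.patterns import ParticipantProfile
from rbcea.reference import INTERIM_DROPOUT, INTERIM_MAR
from rbcea.schema import COST, EFFECT

from conftest import random_pd

TWO_TIME_SCHEMA = rb.VariableSchema(
    effect_vars=("y1", "y2"), effect_times=(0.5, 1.0),
    cost_vars=("c1",), cost_times=(1.0,),
)


def _profile(dropout_missing=(), interim_missing=(), dropout_index=None):
    return ParticipantProfile(
        dropout_index or {EFFECT: 0, COST: 0},
        frozenset(dropout_missing), frozenset(interim_missing),
    )


def _draw(mean, cov, arm="a"):
    return rb.PosteriorDraw(arm, np.asarray(mean, float), np.asarray(cov, float), 0)


class TestBuildMean:
    """Post-dropout mean rules on a two-time effectiveness endpoint."""

    # indices 0,1 = effectiveness times; index 2 = cost (observed here)
    prof = _profile(dropout_missing=(1,), dropout_index={EFFECT: 0, COST: 0})

    def test_j2r_switches_to_reference_after_dropout(self):
        mu = rb.build_mean("J2R", np.array([1.0, 2.0, 5.0]), np.array([0.0, 0.5, 5.0]),
                           self.prof, TWO_TIME_SCHEMA)
        np.testing.assert_allclose(mu[:2], [1.0, 0.5])

    def test_cir_copies_reference_increment(self):
        mu = rb.build_mean("CIR", np.array([1.0, 2.0, 5.0]), np.array([0.5, 0.7, 5.0]),
                           self.prof, TWO_TIME_SCHEMA)
        np.testing.assert_allclose(mu[:2], [1.0, 1.0 + (0.7 - 0.5)])

    def test_lmcf_carries_last_randomised_mean(self):
        mu = rb.build_mean("LMCF", np.array([1.0, 2.0, 5.0]), None,
                           self.prof, TWO_TIME_SCHEMA)
        np.testing.assert_allclose(mu[:2], [1.0, 1.0])

    def test_mar_keeps_randomised_means(self):
        mu = rb.build_mean("MAR", np.array([1.0, 2.0, 5.0]), None,
                           self.prof, TWO_TIME_SCHEMA)
        np.testing.assert_allclose(mu, [1.0, 2.0, 5.0])

    def test_bmcf_reverts_to_baseline_mean(self, toy_schema):
        # three-time endpoint with a true baseline at t=0
        prof = _profile(dropout_missing=(1, 2), dropout_index={EFFECT: 0, COST: 0})
        mu = rb.build_mean("BMCF", np.array([0.4, 0.6, 0.7, 100.0]), None,
                           prof, toy_schema)
        np.testing.assert_allclose(mu, [0.4, 0.4, 0.4, 100.0])

    def test_bmcf_cost_without_baseline_falls_back_to_mar(self, toy_schema):
        prof = _profile(dropout_missing=(3,), dropout_index={EFFECT: 2, COST: -1})
        mu = rb.build_mean("BMCF", np.array([0.4, 0.6, 0.7, 100.0]), None,
                           prof, toy_schema)
        np.testing.assert_allclose(mu[3], 100.0)

    def test_reference_equal_to_randomised_reduces_to_mar(self):
        # holds for the options that actually use the reference arm; the
        # carry-forward options (LMCF/BMCF) ignore the reference label and
        # genuinely differ from MAR even within the reference group
        mu_r = np.array([1.0, 2.0, 5.0])
        for a in (rb.Assumption.MAR, rb.Assumption.J2R, rb.Assumption.CIR):
            mu = rb.build_mean(a, mu_r, mu_r, self.prof, TWO_TIME_SCHEMA)
            np.testing.assert_allclose(mu, mu_r, atol=1e-12)

    def test_carry_forward_options_ignore_reference_label(self):
        mu_r = np.array([1.0, 2.0, 5.0])
        for a in (rb.Assumption.LMCF, rb.Assumption.BMCF):
            with_ref = rb.build_mean(a, mu_r, np.array([9.0, 9.0, 9.0]),
                                     self.prof, TWO_TIME_SCHEMA)
            without = rb.build_mean(a, mu_r, None, self.prof, TWO_TIME_SCHEMA)
            np.testing.assert_allclose(with_ref, without)

    def test_j2r_without_reference_draw_raises(self):
        with pytest.raises(ValueError, match="reference"):
            rb.build_mean("J2R", np.zeros(3), None, self.prof, TWO_TIME_SCHEMA)

    def test_interim_policy_controls_mnar_membership(self, toy_schema):
        prof = _profile(interim_missing=(1,), dropout_index={EFFECT: 2, COST: 0})
        mu_rand = np.array([0.4, 0.6, 0.7, 100.0])
        mu_ref = np.array([0.3, 0.2, 0.1, 90.0])
        as_mar = rb.build_mean("J2R", mu_rand, mu_ref, prof, toy_schema,
                               interim_policy=INTERIM_MAR)
        as_drop = rb.build_mean("J2R", mu_rand, mu_ref, prof, toy_schema,
                                interim_policy=INTERIM_DROPOUT)
        np.testing.assert_allclose(as_mar, mu_rand)
        np.testing.assert_allclose(as_drop, [0.4, 0.2, 0.7, 100.0])


class TestBuildCovariance:
    def test_equal_inputs_reduce_to_reference(self):
        rng = np.random.default_rng(0)
        cov = random_pd(rng, 4)
        out = rb.build_covariance_j2r_cir(cov, cov, [0, 1], [2, 3])
        np.testing.assert_allclose(out, (cov + cov.T) / 2, atol=1e-12)

    def test_empty_pre_block_returns_reference(self):
        rng = np.random.default_rng(1)
        a, b = random_pd(rng, 3), random_pd(rng, 3)
        np.testing.assert_allclose(
            rb.build_covariance_j2r_cir(a, b, [], [0, 1, 2]), (b + b.T) / 2
        )

    def test_two_by_two_worked_example(self):
        # randomised arm independent unit variances; reference correlated
        out = rb.build_covariance_j2r_cir(
            np.eye(2), np.array([[2.0, 1.0], [1.0, 2.0]]), [0], [1]
        )
        np.testing.assert_allclose(out, [[1.0, 0.5], [0.5, 1.75]])

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_psd_for_random_pd_inputs(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 6))
        cov_r, cov_f = random_pd(rng, d), random_pd(rng, d)
        k = int(rng.integers(1, d))
        perm = rng.permutation(d)
        P, Q = sorted(perm[:k]), sorted(perm[k:])
        out = rb.build_covariance_j2r_cir(cov_r, cov_f, P, Q)
        np.testing.assert_allclose(out, out.T, atol=1e-10)
        assert np.linalg.eigvalsh(out)[0] > -1e-10 * np.abs(out).max()

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError):
            rb.build_covariance_j2r_cir(np.eye(3), np.eye(3), [0, 1], [1, 2])


class TestBuildJoint:
    def _draws(self, seed=0, d=4):
        rng = np.random.default_rng(seed)
        rand = _draw(rng.normal(size=d), random_pd(rng, d), "active")
        ref = _draw(rng.normal(size=d), random_pd(rng, d), "control")
        return rand, ref

    def test_all_mar_equals_randomised_draw(self, toy_schema):
        rand, ref = self._draws()
        prof = _profile(dropout_missing=(2, 3), dropout_index={EFFECT: 1, COST: -1})
        joint = rb.build_joint(rb.EndpointAssumptions("MAR", "MAR"), rand, ref,
                               prof, toy_schema)
        np.testing.assert_allclose(joint.mean, rand.mean, atol=1e-12)
        np.testing.assert_allclose(joint.cov, rand.cov, atol=1e-12)
        assert joint.mnar_missing == ()

    def test_reduction_identity_when_reference_is_randomised_arm(self, toy_schema):
        rand, _ = self._draws(3)
        prof = _profile(dropout_missing=(1, 2, 3), dropout_index={EFFECT: 0, COST: -1})
        for name in ("MAR", "J2R", "CIR"):
            ea = rb.EndpointAssumptions(name, name)
            joint = rb.build_joint(ea, rand, rand, prof, toy_schema)
            np.testing.assert_allclose(joint.mean, rand.mean, atol=1e-10)
            np.testing.assert_allclose(joint.cov, rand.cov, atol=1e-10)

    def test_carry_forward_joint_keeps_randomised_covariance(self, toy_schema):
        rand, ref = self._draws(4)
        prof = _profile(dropout_missing=(1, 2), dropout_index={EFFECT: 0, COST: 0})
        for name in ("LMCF", "BMCF"):
            ea = rb.EndpointAssumptions(name, "MAR")
            joint = rb.build_joint(ea, rand, ref, prof, toy_schema)
            np.testing.assert_allclose(joint.cov, rand.cov, atol=1e-12)
            # and the reference draw is irrelevant
            other = rb.build_joint(ea, rand, self._draws(99)[1], prof, toy_schema)
            np.testing.assert_allclose(joint.mean, other.mean)

    def test_interim_qol_stays_mar_while_cost_jumps(self, toy_schema):
        # pattern (✓, ✘, ✓, ✘): interim 6-month gap, missing cost
        rand, ref = self._draws(5)
        prof = _profile(dropout_missing=(3,), interim_missing=(1,),
                        dropout_index={EFFECT: 2, COST: -1})
        joint = rb.build_joint(rb.EndpointAssumptions("J2R", "J2R"), rand, ref,
                               prof, toy_schema)
        assert joint.mar_missing == (1,)
        assert joint.mnar_missing == (3,)

    def test_j2r_effect_with_mar_cost_keeps_cost_parameters(self, toy_schema):
        rand, ref = self._draws(7)
        prof = _profile(dropout_missing=(2, 3), dropout_index={EFFECT: 1, COST: -1})
        joint = rb.build_joint(rb.EndpointAssumptions("J2R", "MAR"), rand, ref,
                               prof, toy_schema)
        # cost (index 3) is MAR ⇒ the marginal over everything except the
        # MNAR block (index 2) carries randomised-arm parameters for cost
        P = [0, 1, 3]
        np.testing.assert_allclose(joint.mean[P], rand.mean[P], atol=1e-12)
        np.testing.assert_allclose(joint.cov[np.ix_(P, P)],
                                   rand.cov[np.ix_(P, P)], atol=1e-12)
        assert joint.mnar_missing == (2,)

    def test_observed_and_covariate_parameters_never_switch(self, toy_schema):
        rand, ref = self._draws(11)
        prof = _profile(dropout_missing=(2, 3), dropout_index={EFFECT: 1, COST: -1})
        observed = [0, 1]
        for name in ("J2R", "CIR", "LMCF", "BMCF"):
            ea = rb.EndpointAssumptions(name, name if name in ("J2R", "CIR") else "MAR")
            joint = rb.build_joint(ea, rand, ref, prof, toy_schema)
            np.testing.assert_allclose(joint.mean[observed], rand.mean[observed])
            np.testing.assert_allclose(
                joint.cov[np.ix_(observed, observed)],
                rand.cov[np.ix_(observed, observed)], atol=1e-12,
            )

    def test_j2r_without_reference_raises(self, toy_schema):
        rand, _ = self._draws(13)
        prof = _profile(dropout_missing=(2,), dropout_index={EFFECT: 1, COST: 0})
        with pytest.raises(ValueError, match="reference"):
            rb.build_joint(rb.EndpointAssumptions("J2R", "MAR"), rand, None,
                           prof, toy_schema)


class TestEndpointAssumptions:
    def test_two_distinct_mnar_families_rejected(self):
        with pytest.raises(ValueError, match="MNAR family"):
            rb.EndpointAssumptions("J2R", "LMCF")

    def test_case_insensitive_parsing(self):
        ea = rb.EndpointAssumptions("j2r", "mar")
        assert ea.effect is rb.Assumption.J2R and ea.cost is rb.Assumption.MAR
        with pytest.raises(ValueError, match="unknown assumption"):
            rb.Assumption.parse("JTR")
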