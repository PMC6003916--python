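"""Paradigm predicates, boundary residuals, witnesses, and grid sweeps."""

import numpy as np
import pytest

from tippingmdp import (
    CAUTIOUS,
    POLICIES,
    RISKY,
    TRAP_HH,
    BoundaryKind,
    ParadigmLabel,
    TippingModel,
    boundary_residual,
    classify,
    classify_many,
    find_boundary,
    is_acceptable,
    is_optimal,
    is_safe,
    is_sustainable,
    sweep_classification,
    value_cautious,
    value_risky,
)
from tippingmdp.fixtures import SWEEP_SETTINGS, witness_models
from tippingmdp.mdp import State
from tippingmdp.paradigms import safe_by_reachability, sustainable_by_reachability

from conftest import sample_models


def make(delta=0.2, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.3):
    return TippingModel(delta=delta, rho=rho, gamma=gamma,
                        r_h=1.0, r_l=r_l, r_min=r_min)


# Fig-2-style illustration setting: the optimality boundary along delta is
# the root of 0.14 - 0.73*delta (risky-optimal residual), i.e. 14/73.
FIG2 = dict(rho=0.2, gamma=0.9, r_l=0.5, r_min=0.3)
DELTA_STAR = 14.0 / 73.0


class TestLabel:
    def test_code_round_trip(self):
        for lab in (ParadigmLabel(True, False, True), ParadigmLabel(False, True, False)):
            assert ParadigmLabel.from_code(lab.code) == lab

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            ParadigmLabel.from_code("XYZ")


class TestOptimality:
    def test_risky_wins_without_collapse_risk(self):
        assert is_optimal(RISKY, make(delta=0.0, gamma=0.5))

    def test_cautious_wins_for_myopic_agent_with_high_risk(self):
        # at gamma=0 the risky policy is optimal iff (1-delta) r_h >= r_l
        assert is_optimal(CAUTIOUS, make(delta=0.6, gamma=0.0))
        assert is_optimal(RISKY, make(delta=0.4, gamma=0.0))

    def test_optimality_switches_at_critical_collapse_probability(self):
        eps = 1e-6
        assert is_optimal(RISKY, make(delta=DELTA_STAR - eps, **{k: v for k, v in FIG2.items() if k != "delta"}))
        assert is_optimal(CAUTIOUS, make(delta=DELTA_STAR + eps, rho=0.2, gamma=0.9))
        # exactly on the surface both are optimal (non-strict comparison)
        m = make(delta=DELTA_STAR, rho=0.2, gamma=0.9)
        assert is_optimal(RISKY, m) or is_optimal(CAUTIOUS, m)

    def test_verdict_is_state_independent(self, random_models):
        for m in random_models:
            vr, vc = value_risky(m), value_cautious(m)
            p_verdict = vr.v_p >= vc.v_p
            if m.rho * m.gamma > 1e-12 and abs(vr.v_d - vc.v_d) > 1e-12:
                assert (vr.v_d > vc.v_d) == p_verdict

    def test_trap_policy_rejected(self):
        with pytest.raises(ValueError):
            is_optimal(TRAP_HH, make())


class TestAcceptabilityAndSustainability:
    def test_threshold_boundary_is_acceptable(self):
        m = make(r_l=0.4, r_min=0.4)
        assert is_acceptable(CAUTIOUS, m, State.PROSPEROUS)

    def test_degraded_unacceptable_without_recovery(self):
        m = make(rho=0.0, r_min=0.1)
        assert not is_acceptable(RISKY, m, State.DEGRADED)
        assert is_acceptable(RISKY, make(rho=0.0, r_min=0.0), State.DEGRADED)

    def test_cautious_degraded_acceptability_example(self):
        # v_d = 0.2*0.9/(1-0.8*0.9) * r_l = (0.18/0.28) * 1 ~ 0.6429
        m = TippingModel(delta=0.2, rho=0.2, gamma=0.9, r_h=2.0, r_l=1.0,
                         r_min=0.6)
        assert value_cautious(m).v_d == pytest.approx(0.18 / 0.28)
        assert is_acceptable(CAUTIOUS, m, State.DEGRADED)

    def test_cautious_sustainable_iff_low_reward_meets_threshold(self):
        assert is_sustainable(CAUTIOUS, make(r_l=0.5, r_min=0.5))
        assert not is_sustainable(CAUTIOUS, make(r_l=0.5, r_min=0.7))

    def test_risky_needs_both_states_acceptable(self):
        m = make(delta=0.05, rho=0.2, gamma=0.99, r_min=0.3)
        # farsighted and low-risk: even the degraded state is acceptable
        assert value_risky(m).v_d >= m.r_min
        assert is_sustainable(RISKY, m)
        # a myopic agent discounts the recovery away
        assert not is_sustainable(RISKY, make(delta=0.05, rho=0.2, gamma=0.5,
                                              r_min=0.3))

    def test_risky_trivially_sustainable_with_zero_threshold(self):
        assert is_sustainable(RISKY, make(r_min=0.0))


class TestSafety:
    def test_cautious_always_safe_risky_never(self, random_models):
        for m in random_models[:50]:
            assert is_safe(CAUTIOUS, m)
            assert not is_safe(RISKY, m)

    def test_reachability_cross_check_agrees_off_boundary(self, random_models):
        for m in random_models[:50]:
            if m.delta > 0:
                assert safe_by_reachability(RISKY, m) is False
            assert safe_by_reachability(CAUTIOUS, m) is True

    def test_zero_collapse_probability_convention(self):
        # blanket rule: risky is never safe, even when it never collapses;
        # the reachability variant exposes the boundary discrepancy
        m = make(delta=0.0)
        assert not is_safe(RISKY, m)
        assert safe_by_reachability(RISKY, m)

    def test_sustainability_reachability_cross_check(self, random_models):
        for m in random_models[:100]:
            if m.delta > 0:
                assert sustainable_by_reachability(RISKY, m) == is_sustainable(RISKY, m)
            assert sustainable_by_reachability(CAUTIOUS, m) == is_sustainable(CAUTIOUS, m)


class TestClassify:
    def test_fig2_style_examples(self):
        lab = classify(CAUTIOUS, make(delta=0.3, **{k: FIG2[k] for k in ("rho", "gamma", "r_l", "r_min")}))
        assert (lab.optimal, lab.sustainable, lab.safe) == (True, True, True)
        lab = classify(RISKY, make(delta=0.05, rho=0.2, gamma=0.9))
        assert lab.optimal and not lab.safe

    def test_high_threshold_kills_sustainability_of_cautious(self, random_models):
        for m in random_models[:30]:
            m2 = TippingModel(delta=m.delta, rho=m.rho, gamma=m.gamma,
                              r_h=1.0, r_l=0.5, r_min=0.7)
            lab = classify(CAUTIOUS, m2)
            assert not lab.sustainable and lab.safe

    def test_all_eight_labels_realized_by_witnesses(self):
        for gamma1 in (False, True):
            seen = {}
            for code, policy, model in witness_models(gamma1=gamma1):
                seen[code] = classify(POLICIES[policy], model).code
            assert seen == {c: c for c in seen} and len(seen) == 8

    def test_sajos_exists_iff_low_reward_meets_threshold(self, random_models):
        for m in random_models:
            lab = classify(CAUTIOUS, m)
            assert (lab.sustainable and lab.safe) == (m.r_l >= m.r_min)


RESIDUAL_PREDICATES = {
    BoundaryKind.OPTIMALITY: lambda m: is_optimal(RISKY, m),
    BoundaryKind.RISKY_ACCEPTABLE_P: lambda m: is_acceptable(RISKY, m, State.PROSPEROUS),
    BoundaryKind.RISKY_ACCEPTABLE_D: lambda m: is_acceptable(RISKY, m, State.DEGRADED),
    BoundaryKind.CAUTIOUS_ACCEPTABLE_P: lambda m: is_acceptable(CAUTIOUS, m, State.PROSPEROUS),
    BoundaryKind.CAUTIOUS_ACCEPTABLE_D: lambda m: is_acceptable(CAUTIOUS, m, State.DEGRADED),
}


class TestBoundaryResiduals:
    def test_cautious_prosperous_residual_is_reward_gap(self):
        m = make(r_l=0.45, r_min=0.3)
        assert boundary_residual(BoundaryKind.CAUTIOUS_ACCEPTABLE_P, m) == \
            pytest.approx(0.15)

    def test_optimality_residual_positive_without_risk(self):
        assert boundary_residual(BoundaryKind.OPTIMALITY, make(delta=0.0)) > 0

    @pytest.mark.parametrize("kind", list(BoundaryKind), ids=lambda k: k.value)
    def test_residual_sign_matches_predicate(self, kind, random_models):
        predicate = RESIDUAL_PREDICATES[kind]
        for m in random_models:
            r = boundary_residual(kind, m)
            if abs(r) > 1e-9:
                assert (r > 0) == predicate(m)

    def test_bisection_locates_optimality_boundary(self):
        m = make(**FIG2)
        root = find_boundary(BoundaryKind.OPTIMALITY, m, "delta")
        assert root == pytest.approx(DELTA_STAR, abs=1e-11)
        at_root = make(delta=root, rho=0.2, gamma=0.9)
        assert abs(value_risky(at_root).v_p - value_cautious(at_root).v_p) < 1e-10

    def test_bisection_requires_sign_change(self):
        with pytest.raises(ValueError):
            find_boundary(BoundaryKind.CAUTIOUS_ACCEPTABLE_P, make(), "delta")


class TestVectorizedClassification:
    def test_matches_scalar_classification(self):
        models = sample_models(100, seed=11) + sample_models(50, seed=12, gamma_one=True)
        delta = np.array([m.delta for m in models])
        rho = np.array([m.rho for m in models])
        gamma = np.array([m.gamma for m in models])
        r_l = np.array([m.r_l for m in models])
        r_min = np.array([m.r_min for m in models])
        batch = classify_many(delta, rho, gamma, r_l, r_min)
        for i, m in enumerate(models):
            for name in ("risky", "cautious"):
                opt, sus, safe = (bool(a[i]) for a in batch[name])
                lab = classify(POLICIES[name], m)
                assert (opt, sus, safe) == (lab.optimal, lab.sustainable, lab.safe)

    def test_degenerate_corner_at_gamma_one(self):
        # delta = rho = 0 at gamma = 1: risky never collapses (v_p = r_h,
        # optimal) but the unreachable degraded state carries the limit
        # value 0, so sustainability still requires r_min = 0
        batch = classify_many(0.0, 0.0, 1.0, 0.5, 0.3)
        opt_r, sus_r, _ = batch["risky"]
        assert bool(opt_r) and not bool(sus_r)
        _, sus_r0, _ = classify_many(0.0, 0.0, 1.0, 0.5, 0.0)["risky"]
        assert bool(sus_r0)


class TestSweep:
    def test_fig2_sweep_safety_pattern(self):
        grid = np.linspace(0.0, 1.0, 11)
        df = sweep_classification([RISKY, CAUTIOUS], "delta", grid, "gamma",
                                  grid, fixed=SWEEP_SETTINGS["baseline"])
        assert df.loc[df.policy == "cautious", "safe"].all()
        assert not df.loc[df.policy == "risky", "safe"].any()
        assert set(df.columns) == {"axis1_name", "axis1", "axis2_name", "axis2",
                                   "policy", "optimal", "sustainable", "safe"}

    def test_classification_persists_at_gamma_one(self):
        grid = np.linspace(0.0, 1.0, 21)
        base = sweep_classification([RISKY, CAUTIOUS], "delta", grid, "gamma",
                                    grid, fixed=SWEEP_SETTINGS["baseline"])
        top = base[base.axis2 == 1.0]
        risky_top = top[top.policy == "risky"]
        # sustainable-but-unsafe risky cells survive absolute farsightedness
        assert (risky_top.sustainable & ~risky_top.safe).any()
        high = sweep_classification([RISKY, CAUTIOUS], "delta", grid, "gamma",
                                    grid, fixed=SWEEP_SETTINGS["high_threshold"])
        high_top = high[high.axis2 == 1.0]
        # with r_min > r_l, optimal-but-unsustainable cells occur at gamma=1
        assert (high_top.optimal & ~high_top.sustainable).any()

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            sweep_classification([RISKY], "delta", [0.0, 1.2], "gamma",
                                 [0.0, 1.0], fixed=SWEEP_SETTINGS["baseline"])
        with pytest.raises(ValueError):
            sweep_classification([RISKY], "delta", [0.0, 1.0], "delta",
                                 [0.0, 1.0], fixed=SWEEP_SETTINGS["baseline"])
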