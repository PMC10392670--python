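"""Gaussian-mixture rigid-base-pair sampler: moments, Boltzmann statistics,
umbrella schedules, bias response and analytic ground truth."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

from dnatwist.constants import kbt
from dnatwist.ensembles import (
    EXACT_ENUM_LIMIT,
    SequenceModel,
    StepSubstate,
    _BiasedLabelDist,
    _ModelCache,
    default_model,
    ground_truth_modulus,
    homogeneous_model,
    make_umbrella_schedule,
    metropolis_label_steps,
    restrained_region,
    run_umbrella,
    sample_biased,
    sample_unbiased,
    substate_from_moments,
)
from dnatwist.restraint import TorsionalRestraint

SEQ23 = "GGCGAGTAGCACGTGCTACTCGC"
FRAG = "GTAGCACGTGCTAC"


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

class TestDefaultModel:
    def test_ypr_steps_of_restrained_fragment_are_bimodal(self):
        model = default_model(SEQ23)
        dinucs = [SEQ23[i : i + 2] for i in range(len(SEQ23) - 1)]
        for i, d in enumerate(dinucs):
            expected = 2 if d in ("TA", "TG", "CA", "CG") else 1
            assert len(model.steps[i]) == expected, (i, d)
        # GG step (first) is unimodal; the TA step after GTA... is bimodal
        assert len(model.steps[0]) == 1
        assert dinucs[6] == "TA" and len(model.steps[6]) == 2

    def test_bimodal_twist_separation_is_20_degrees(self):
        model = default_model(SEQ23)
        for step in model.steps:
            if len(step) == 2:
                twists = sorted(s.mean[5] for s in step)
                assert twists[1] - twists[0] == pytest.approx(20.0)
                assert step[0].epsilon == step[1].epsilon

    def test_two_base_sequence_single_step(self):
        model = default_model("GG")
        assert model.n_steps == 1
        assert len(model.steps[0]) == 1

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError, match="ACGT"):
            default_model("GGXN")

    def test_non_pd_stiffness_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            StepSubstate(np.zeros(6), -np.eye(6))


def test_restrained_region_of_printed_sequence():
    assert restrained_region(SEQ23, FRAG) == (6, 18)
    lo, hi = restrained_region(SEQ23, FRAG)
    assert hi - lo + 1 == 13


# --------------------------------------------------------------------------
# unbiased sampling statistics
# --------------------------------------------------------------------------

def test_equipartition_variances_diagonal_model():
    """Sample variances of a single-substate diagonal model must match
    k_B T / (2 F_ii) within 3 standard errors at n = 1e5."""
    model = homogeneous_model(4, twist_sd=3.0)
    n = 100_000
    ens = sample_unbiased(model, n, seed=11)
    F = model.steps[0][0].stiffness
    expected = kbt() / (2.0 * np.diag(F))
    var = ens.params.reshape(-1, 6).var(axis=0, ddof=1)
    se = expected * np.sqrt(2.0 / (4 * n - 1))
    assert np.all(np.abs(var - expected) < 3 * se)


def test_symmetric_substates_split_evenly():
    model = default_model("GTAG")  # TA step bimodal, equal epsilon
    n = 40_000
    ens = sample_unbiased(model, n, seed=3)
    occ = ens.labels[:, 1].mean()
    assert abs(occ - 0.5) < 3 * np.sqrt(0.25 / n)


def test_boltzmann_occupancy_ratio_with_epsilon_offset():
    sds = {"shift": 0.4, "slide": 0.4, "rise": 0.3, "tilt": 2.5, "roll": 4.0,
           "twist": 2.8}
    lo = substate_from_moments(np.array([0, 0, 3.38, 0, 0, 24.6]), sds)
    hi = substate_from_moments(np.array([0, 0, 3.38, 0, 0, 44.6]), sds, epsilon=1.0)
    model = SequenceModel("GTA", ((lo, hi), (lo,)))
    n = 200_000
    ens = sample_unbiased(model, n, seed=5)
    p_hi = ens.labels[:, 0].mean()
    expected = np.exp(-1.0 / kbt()) / (1 + np.exp(-1.0 / kbt()))
    assert abs(p_hi - expected) < 3 * np.sqrt(expected * (1 - expected) / n)


def test_fixed_seed_reproducible():
    model = default_model("GTAGCA")
    a = sample_unbiased(model, 500, seed=42)
    b = sample_unbiased(model, 500, seed=42)
    assert np.array_equal(a.params, b.params)
    assert np.array_equal(a.labels, b.labels)


# --------------------------------------------------------------------------
# umbrella schedule bookkeeping
# --------------------------------------------------------------------------

class TestSchedule:
    def test_default_schedule_refs(self):
        sched = make_umbrella_schedule(450.0)
        assert sched.n_windows == 21
        refs = np.sort(sched.refs)
        assert np.allclose(refs, np.arange(385.0, 515.0 + 1e-9, 6.5))
        assert sched.window_shift_deg == pytest.approx(6.5)

    def test_minimal_schedule(self):
        sched = make_umbrella_schedule(100.0, increment=0.5, max_offset=0.5)
        assert sched.n_windows == 3

    def test_sampling_time_bookkeeping(self):
        sched = make_umbrella_schedule(450.0)
        assert sched.total_sampling_time_us == pytest.approx(21 * 0.5)

    def test_indivisible_increment_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            make_umbrella_schedule(450.0, increment=0.3, max_offset=5.0)


# --------------------------------------------------------------------------
# biased sampling
# --------------------------------------------------------------------------

def test_stiff_spring_limit_pins_cv():
    model = homogeneous_model(13, twist_sd=3.171)
    for ref in (449.8, 475.0, 420.0):
        restraint = TorsionalRestraint(1.0, ref, (1, 13))
        window, _ = sample_biased(model, restraint, 20_000, seed=8)
        assert abs(window.mean_cv - ref) < 0.5


def test_zero_bias_matches_unbiased_distribution():
    """k_tw = 0 windows are statistically identical to unbiased sampling
    (KS test on the CV at alpha = 0.01), including substate occupancies."""
    model = default_model(FRAG)
    restraint = TorsionalRestraint(0.0, 449.8, (1, 13))
    window, _ = sample_biased(model, restraint, 20_000, seed=9)
    unbiased = sample_unbiased(model, 20_000, seed=10)
    p = ks_2samp(window.cv_series, unbiased.cv_series((1, 13))).pvalue
    assert p > 0.01


def test_biased_mean_cv_matches_quadrature_oracle():
    """Single-substate model: the biased mean CV must match 1-D numerical
    quadrature over the Gaussian CV marginal times the bias weight."""
    sd = 3.0
    model = homogeneous_model(13, twist_sd=sd)
    mu0 = 13 * 34.6
    var = 13 * sd**2
    k, ref = 0.06, mu0 + 40.0
    beta = 1.0 / kbt()

    def weight(x):
        return np.exp(-((x - mu0) ** 2) / (2 * var) - beta * k * (x - ref) ** 2)

    lo, hi = mu0 - 80, mu0 + 120
    norm = quad(weight, lo, hi)[0]
    oracle = quad(lambda x: x * weight(x), lo, hi)[0] / norm
    restraint = TorsionalRestraint(k, ref, (1, 13))
    window, _ = sample_biased(model, restraint, 100_000, seed=12)
    se = window.cv_series.std() / np.sqrt(len(window.cv_series))
    assert abs(window.mean_cv - oracle) < 4 * se + 1e-3


def test_cv_series_equals_sum_of_region_twists_exactly():
    model = default_model(SEQ23)
    restraint = TorsionalRestraint(0.06, 449.8, (6, 18))
    window, _ = sample_biased(model, restraint, 2_000, seed=13)
    recomputed = window.ensemble.params[:, 5:18, 5].sum(axis=1)
    assert np.array_equal(window.cv_series, recomputed)


def test_run_umbrella_reproducible_and_ordered():
    model = homogeneous_model(13, twist_sd=3.0)
    sched = make_umbrella_schedule(
        449.8, max_offset=1.0, n_frames_per_window=2_000, sequential_seeding=False
    )
    w1 = run_umbrella(model, sched, seed=21, keep_params=True)
    w2 = run_umbrella(model, sched, seed=21, keep_params=True)
    assert len(w1) == 5
    for a, b in zip(w1, w2):
        assert a.restraint == b.restraint
        assert np.array_equal(a.ensemble.params, b.ensemble.params)
    refs = [w.restraint.twist_ref for w in w1]
    assert refs[0] == pytest.approx(449.8)  # centre first, then the cascades


def test_run_umbrella_region_mismatch_errors():
    model = default_model(SEQ23)
    sched = make_umbrella_schedule(449.8, max_offset=1.0)
    with pytest.raises(ValueError, match="region"):
        run_umbrella(model, sched, seed=1)


# --------------------------------------------------------------------------
# label-chain correctness
# --------------------------------------------------------------------------

def test_exact_mixture_sampler_matches_enumerated_marginal():
    """Label frequencies under the bias equal the exact enumerated marginal."""
    model = default_model(FRAG)
    restraint = TorsionalRestraint(0.06, 449.8 - 3.0 * 13, (1, 13))
    n = 50_000
    window, _ = sample_biased(model, restraint, n, seed=17)
    cache = _ModelCache(model)
    dist = _BiasedLabelDist(cache, restraint)
    cfgs = dist.enumerate_configs()
    lw = dist.logweight(cfgs)
    p = np.exp(lw - lw.max())
    p /= p.sum()
    for i in range(model.n_steps):
        if len(model.steps[i]) == 1:
            continue
        expected = float(p @ (cfgs[:, i] == 1))
        observed = window.ensemble.labels[:, i].mean()
        se = np.sqrt(max(expected * (1 - expected), 1e-6) / len(window.cv_series))
        assert abs(observed - expected) < 4 * se + 5e-3


def test_collapsed_metropolis_detailed_balance():
    """Reversibility of the label Metropolis chain on a toy model with one
    three-substate step: empirical forward/backward flows between every
    state pair balance, and the stationary distribution matches the exact
    Boltzmann marginal."""
    sds = {"shift": 0.4, "slide": 0.4, "rise": 0.3, "tilt": 2.5, "roll": 4.0,
           "twist": 2.8}
    subs = tuple(
        substate_from_moments(
            np.array([0, 0, 3.38, 0, 0, tw]), sds, epsilon=e
        )
        for tw, e in ((24.6, 0.0), (34.6, 0.3), (44.6, 0.8))
    )
    single = substate_from_moments(np.array([0, 0, 3.38, 0, 0, 34.6]), sds)
    model = SequenceModel("GTA", (subs, (single,)))
    restraint = TorsionalRestraint(0.06, 2 * 34.6 + 4.0, (1, 2))
    rng = np.random.default_rng(23)
    n_chains, n_sweeps = 2_000, 500  # one update per sweep -> bare chain
    labels0 = np.zeros((n_chains, 2), dtype=int)
    labels0[:, 0] = rng.integers(0, 3, n_chains)
    _, snaps = metropolis_label_steps(model, restraint, labels0, n_sweeps, rng,
                                      record=True)
    states = np.array(snaps)[:, :, 0]
    a, b = states[n_sweeps // 4 : -1].ravel(), states[n_sweeps // 4 + 1 :].ravel()
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    for i in range(3):
        for j in range(i + 1, 3):
            fwd, bwd = counts[i, j], counts[j, i]
            assert abs(fwd - bwd) < 4 * np.sqrt(fwd + bwd)  # Poisson flow balance
    # stationary distribution vs exact marginal
    dist = _BiasedLabelDist(_ModelCache(model), restraint)
    cfgs = dist.enumerate_configs()
    lw = dist.logweight(cfgs)
    p = np.exp(lw - lw.max())
    p /= p.sum()
    exact = np.array([p[cfgs[:, 0] == s].sum() for s in range(3)])
    tail = states[n_sweeps // 4 :]
    freq = np.bincount(tail.ravel(), minlength=3) / tail.size
    assert np.all(np.abs(freq - exact) < 0.01)


def test_large_label_space_uses_metropolis_fallback():
    # 13 bimodal steps -> 8192 configurations > enumeration limit
    model = default_model("GG" + "TA" * 8, bimodal_steps=set(range(1, 18)))
    assert int(np.prod([len(s) for s in model.steps])) > EXACT_ENUM_LIMIT
    restraint = TorsionalRestraint(0.06, 17 * 34.6, (1, 17))
    window, _ = sample_biased(model, restraint, 300, seed=31)
    assert window.ensemble.acceptance["method"] == "collapsed-metropolis"
    assert window.ensemble.acceptance["rate"] > 0.01


# --------------------------------------------------------------------------
# twist-capacitor emulation and analytic modulus
# --------------------------------------------------------------------------

def test_flank_capacitors_absorb_most_torsional_stress():
    """With bimodal flank steps and a stiff core, over half of the imposed
    twist change concentrates on the two capacitor steps."""
    model = default_model(FRAG, twist_sd=2.0, bimodal_steps={2, 12})
    relaxed, _ = sample_biased(
        model, TorsionalRestraint(0.06, 449.8, (1, 13)), 15_000, seed=41
    )
    for sign in (-1, 1):
        ref = 449.8 + sign * 4.0 * 13
        window, _ = sample_biased(
            model, TorsionalRestraint(0.06, ref, (1, 13)), 15_000, seed=42
        )
        delta = window.step_twist_mean - relaxed.step_twist_mean
        flank_share = (abs(delta[1]) + abs(delta[11])) / abs(delta).sum()
        assert flank_share > 0.5


class TestGroundTruthModulus:
    @pytest.mark.parametrize(
        "sd,expected", [(3.171, 111.0), (2.578, 168.0)]
    )
    def test_analytic_values(self, sd, expected):
        model = homogeneous_model(13, twist_sd=sd)
        assert ground_truth_modulus(model) == pytest.approx(expected, abs=0.5)

    def test_quadratic_scaling(self):
        c1 = ground_truth_modulus(homogeneous_model(13, twist_sd=3.0))
        c2 = ground_truth_modulus(homogeneous_model(13, twist_sd=1.5))
        assert c2 / c1 == pytest.approx(4.0, rel=1e-12)

    def test_long_simulation_cross_check(self):
        """The analytic value agrees with the variance of a long unbiased
        simulation (independent Monte Carlo route)."""
        model = homogeneous_model(13, twist_sd=3.171)
        ens = sample_unbiased(model, 200_000, seed=51)
        var_deg = ens.params[:, :, 5].var(axis=0, ddof=1).mean()
        sim = 0.34 / (var_deg * (np.pi / 180) ** 2)
        assert sim == pytest.approx(ground_truth_modulus(model), rel=0.02)

    def test_mixture_variance_included(self):
        bimodal = default_model(FRAG)
        uni = homogeneous_model(13, twist_sd=3.0)
        assert ground_truth_modulus(bimodal) < ground_truth_modulus(uni) / 3

    def test_refuses_coupled_chain(self):
        model = default_model(FRAG, coupling=0.5)
        with pytest.raises(ValueError, match="J = 0"):
            ground_truth_modulus(model)
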