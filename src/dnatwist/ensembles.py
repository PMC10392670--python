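"""Rigid-base-pair Gaussian-mixture Monte Carlo ensembles.

A DNA duplex is modelled as a chain of bp steps, each carrying one or more
conformational substates.  A substate is a 6-dimensional Gaussian basin over
(shift, slide, rise, tilt, roll, twist) with energy

    E_s(x) = (x - mu_s)^T F_s (x - mu_s) + epsilon_s        [kcal/mol]

(no 1/2 factor, matching the quadratic-restraint convention; the implied
covariance is ``(k_B T / 2) F^-1``).  Adjacent steps' substate labels may be
coupled by a nearest-neighbour mismatch penalty J.  Pyrimidine-purine (YpR)
steps are "twist capacitors": two substates whose mean twists differ by up
to ~20 degrees, so they absorb torsional stress preferentially.

The module samples unbiased ensembles exactly (chain sampling of labels,
conditional Gaussians for the parameters), runs cascade umbrella sampling
under the quadratic end-to-end-twist bias, and provides the analytic
ground-truth torsional modulus used to validate the elasticity pipeline.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .constants import DEG2RAD, L_BP_NM, kbt
from .restraint import TorsionalRestraint, bias_energy

__all__ = [
    "StepSubstate",
    "SequenceModel",
    "EnsembleSample",
    "UmbrellaWindow",
    "UmbrellaSchedule",
    "default_model",
    "homogeneous_model",
    "substate_from_moments",
    "sample_unbiased",
    "sample_biased",
    "make_umbrella_schedule",
    "run_umbrella",
    "ground_truth_modulus",
    "restrained_region",
    "model_energy",
    "metropolis_label_steps",
]

PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
TWIST = 5  # index of twist in the 6-vector

#: Default relaxed per-step twist, degrees (450 deg over 13 steps ~ 34.6).
DEFAULT_TWIST_MEAN = 34.6

#: Default per-parameter fluctuation SDs (A for translations, deg for
#: rotations); synthetic values in the range typical of B-DNA ensembles.
DEFAULT_SDS = {
    "shift": 0.45,
    "slide": 0.40,
    "rise": 0.30,
    "tilt": 2.5,
    "roll": 4.0,
    "twist": 3.0,
}

#: Default cross-parameter correlations of a step basin: twist-roll
#: anti-correlation and twist-slide correlation.
DEFAULT_CORRELATIONS = {("twist", "roll"): -0.4, ("twist", "slide"): 0.3}

#: Mean-twist separation of the two substates at a bimodal (YpR) step, deg.
BIMODAL_SEPARATION = 20.0

#: Per-substate twist SD at bimodal steps, deg.
BIMODAL_TWIST_SD = 2.8

YPR_STEPS = frozenset({"TA", "TG", "CA", "CG"})


# --------------------------------------------------------------------------
# model types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StepSubstate:
    """One Gaussian basin of a bp step: mean 6-vector, stiffness, offset."""

    mean: np.ndarray
    stiffness: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "stiffness", np.asarray(self.stiffness, dtype=float))
        if self.mean.shape != (6,) or self.stiffness.shape != (6, 6):
            raise ValueError("substate needs a 6-vector mean and 6x6 stiffness")
        if np.abs(self.stiffness - self.stiffness.T).max() > 1e-9:
            raise ValueError("stiffness matrix must be symmetric")
        if np.linalg.eigvalsh(self.stiffness).min() <= 0:
            raise ValueError("stiffness matrix must be positive definite")


@dataclass(frozen=True)
class SequenceModel:
    """Gaussian-mixture rigid-base-pair model of a duplex.

    ``steps[i]`` lists the substates of step i (0-based); ``coupling`` is
    the Ising mismatch penalty (kcal/mol) paid when adjacent steps occupy
    substates with different labels.
    """

    sequence: str
    steps: tuple[tuple[StepSubstate, ...], ...]
    coupling: float = 0.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if any(b not in "ACGT" for b in seq):
            raise ValueError(f"sequence must be over ACGT, got {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)
        steps = tuple(tuple(s) for s in self.steps)
        object.__setattr__(self, "steps", steps)
        if len(steps) != len(seq) - 1:
            raise ValueError("need len(sequence)-1 step entries")
        if any(len(s) < 1 for s in steps):
            raise ValueError("every step needs at least one substate")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def beta(self) -> float:
        return 1.0 / kbt(self.temperature)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.sequence.encode())
        h.update(np.float64(self.coupling).tobytes())
        h.update(np.float64(self.temperature).tobytes())
        for step in self.steps:
            for s in step:
                h.update(np.ascontiguousarray(s.mean).tobytes())
                h.update(np.ascontiguousarray(s.stiffness).tobytes())
                h.update(np.float64(s.epsilon).tobytes())
        return h.hexdigest()[:16]


@dataclass
class EnsembleSample:
    """Sampled ensemble: per-frame step parameters and substate labels.

    ``params`` may be None when a run was asked not to retain the full
    parameter trajectory (summary statistics are kept instead).
    """

    params: np.ndarray | None
    labels: np.ndarray
    seed: int | None
    acceptance: dict
    step_twist_mean: np.ndarray
    step_param_mean: np.ndarray
    n_frames: int

    @property
    def twist(self) -> np.ndarray:
        if self.params is None:
            raise ValueError("parameter trajectory was not retained")
        return self.params[:, :, TWIST]

    def cv_series(self, region: tuple[int, int]) -> np.ndarray:
        """End-to-end twist per frame over a 1-based inclusive step range."""
        lo, hi = region
        return self.twist[:, lo - 1 : hi].sum(axis=1)


@dataclass
class UmbrellaWindow:
    """One biased window: its restraint, the CV series and the ensemble."""

    restraint: TorsionalRestraint
    cv_series: np.ndarray
    ensemble: EnsembleSample

    @property
    def mean_cv(self) -> float:
        return float(self.cv_series.mean())

    @property
    def step_twist_mean(self) -> np.ndarray:
        return self.ensemble.step_twist_mean


@dataclass(frozen=True)
class UmbrellaSchedule:
    """Cascade umbrella schedule along the end-to-end twist.

    Windows are ordered outward from the relaxed centre in two one-sided
    cascades; neighbouring references differ by ``increment *
    n_region_steps`` degrees.
    """

    relaxed_ref: float
    increment: float = 0.5
    max_offset: float = 5.0
    n_region_steps: int = 13
    n_frames_per_window: int = 200_000
    window_time_us: float = 0.5
    sequential_seeding: bool = True

    def __post_init__(self) -> None:
        if self.increment <= 0 or self.max_offset <= 0:
            raise ValueError("increment and max_offset must be positive")
        k = self.max_offset / self.increment
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"increment ({self.increment}) must divide max_offset ({self.max_offset})"
            )

    @property
    def n_side(self) -> int:
        return int(round(self.max_offset / self.increment))

    @property
    def n_windows(self) -> int:
        return 2 * self.n_side + 1

    @property
    def window_shift_deg(self) -> float:
        """Total-twist shift between neighbouring windows, degrees."""
        return self.increment * self.n_region_steps

    @property
    def total_sampling_time_us(self) -> float:
        """Bookkeeping: windows x sampling time per window."""
        return self.n_windows * self.window_time_us

    @property
    def offsets_per_bp(self) -> np.ndarray:
        """Window offsets on the per-bp-step axis, in cascade order."""
        side = np.arange(1, self.n_side + 1) * self.increment
        return np.concatenate([[0.0], side, -side])

    @property
    def refs(self) -> np.ndarray:
        """Window reference twists (deg, total), in cascade order:
        centre, then the overwinding branch, then the underwinding branch."""
        return self.relaxed_ref + self.offsets_per_bp * self.n_region_steps


def make_umbrella_schedule(
    relaxed_ref: float,
    increment: float = 0.5,
    max_offset: float = 5.0,
    n_region_steps: int = 13,
    **kwargs,
) -> UmbrellaSchedule:
    """Build the cascade schedule (21 windows with the defaults)."""
    return UmbrellaSchedule(
        relaxed_ref=relaxed_ref,
        increment=increment,
        max_offset=max_offset,
        n_region_steps=n_region_steps,
        **kwargs,
    )


def restrained_region(sequence: str, fragment: str) -> tuple[int, int]:
    """1-based inclusive bp-step range spanned by a subsequence.

    A fragment of m base pairs starting at bp position p covers steps
    p .. p+m-2.
    """
    sequence, fragment = sequence.upper(), fragment.upper()
    pos = sequence.find(fragment)
    if pos < 0:
        raise ValueError(f"fragment {fragment!r} not found in sequence")
    if sequence.find(fragment, pos + 1) >= 0:
        raise ValueError(f"fragment {fragment!r} occurs more than once")
    if len(fragment) < 2:
        raise ValueError("fragment must span at least one step")
    return (pos + 1, pos + len(fragment) - 1)


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def _covariance_from_moments(sds: dict, correlations: dict) -> np.ndarray:
    sd = np.array([float(sds[name]) for name in PARAM_NAMES])
    corr = np.eye(6)
    for (a, b), r in correlations.items():
        ia, ib = PARAM_NAMES.index(a), PARAM_NAMES.index(b)
        corr[ia, ib] = corr[ib, ia] = float(r)
    cov = corr * np.outer(sd, sd)
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("requested SDs/correlations give a non-PD covariance")
    return cov


def substate_from_moments(
    mean: np.ndarray,
    sds: dict,
    correlations: dict | None = None,
    temperature: float = 300.0,
    epsilon: float = 0.0,
) -> StepSubstate:
    """Substate whose Boltzmann distribution has the given moments.

    With the ``E = d^T F d`` convention the stiffness is
    ``F = (k_B T / 2) * Cov^-1`` and the marginal SD of a diagonal basin is
    ``sqrt(k_B T / (2 F_ii))``.
    """
    cov = _covariance_from_moments(sds, correlations or {})
    F = 0.5 * kbt(temperature) * np.linalg.inv(cov)
    F = 0.5 * (F + F.T)
    return StepSubstate(mean=np.asarray(mean, float), stiffness=F, epsilon=epsilon)


def _step_mean(twist_mean: float) -> np.ndarray:
    return np.array([0.0, 0.0, 3.38, 0.0, 0.0, twist_mean])


def default_model(
    sequence: str,
    twist_mean: float = DEFAULT_TWIST_MEAN,
    twist_sd: float = DEFAULT_SDS["twist"],
    bimodal_separation: float = BIMODAL_SEPARATION,
    bimodal_twist_sd: float = BIMODAL_TWIST_SD,
    coupling: float = 0.0,
    temperature: float = 300.0,
    bimodal_steps: set[int] | None = None,
) -> SequenceModel:
    """Sequence-dependent Gaussian-mixture model with YpR twist capacitors.

    Pyrimidine-purine steps (TA, CA, TG, CG) receive two substates whose
    mean twists straddle ``twist_mean`` by ``bimodal_separation`` with equal
    intrinsic energies; all other steps are single Gaussians.  Every basin
    carries the default twist-roll (-0.4) and twist-slide (+0.3) couplings.
    ``bimodal_steps`` (1-based step indices) overrides the sequence rule.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must contain at least one step")
    if any(b not in "ACGT" for b in sequence):
        raise ValueError(f"sequence must be over ACGT, got {sequence!r}")
    steps = []
    for i in range(len(sequence) - 1):
        dinuc = sequence[i : i + 2]
        bimodal = (
            (i + 1) in bimodal_steps if bimodal_steps is not None else dinuc in YPR_STEPS
        )
        if bimodal:
            sds = dict(DEFAULT_SDS, twist=bimodal_twist_sd)
            half = bimodal_separation / 2.0
            subs = tuple(
                substate_from_moments(
                    _step_mean(twist_mean + sign * half),
                    sds,
                    DEFAULT_CORRELATIONS,
                    temperature,
                )
                for sign in (-1.0, +1.0)
            )
        else:
            sds = dict(DEFAULT_SDS, twist=twist_sd)
            subs = (
                substate_from_moments(
                    _step_mean(twist_mean), sds, DEFAULT_CORRELATIONS, temperature
                ),
            )
        steps.append(subs)
    return SequenceModel(sequence, tuple(steps), coupling=coupling, temperature=temperature)


def homogeneous_model(
    n_steps: int,
    twist_sd: float,
    twist_mean: float = DEFAULT_TWIST_MEAN,
    temperature: float = 300.0,
    sds: dict | None = None,
    correlations: dict | None = None,
    sequence: str | None = None,
) -> SequenceModel:
    """Single-substate chain with independent Gaussian per-step twist.

    Every step carries the same diagonal basin (no cross-parameter
    couplings unless given); used for analytic elasticity validation.
    """
    base_sds = dict(DEFAULT_SDS if sds is None else sds, twist=twist_sd)
    sub = substate_from_moments(
        _step_mean(twist_mean), base_sds, correlations or {}, temperature
    )
    if sequence is None:
        sequence = "G" * (n_steps + 1)
    elif len(sequence) != n_steps + 1:
        raise ValueError("sequence length must be n_steps + 1")
    return SequenceModel(sequence, tuple((sub,) for _ in range(n_steps)),
                         coupling=0.0, temperature=temperature)


# --------------------------------------------------------------------------
# cached per-model quantities
# --------------------------------------------------------------------------

class _ModelCache:
    """Per-step substate arrays and factorizations reused by the samplers."""

    def __init__(self, model: SequenceModel):
        self.model = model
        self.beta = model.beta
        self.kT = kbt(model.temperature)
        self.n_steps = model.n_steps
        self.n_sub = [len(s) for s in model.steps]
        self.means = [np.stack([sub.mean for sub in s]) for s in model.steps]
        self.F = [np.stack([sub.stiffness for sub in s]) for s in model.steps]
        self.eps = [np.array([sub.epsilon for sub in s]) for s in model.steps]
        # conditional covariance (kT/2) F^-1 and its Cholesky factor
        self.cov = [0.5 * self.kT * np.linalg.inv(Fs) for Fs in self.F]
        self.cov_chol = [np.stack([cholesky(c, lower=True) for c in cs])
                        for cs in self.cov]
        self.logdetF = [np.array([np.linalg.slogdet(f)[1] for f in Fs])
                        for Fs in self.F]
        self.single_substate = all(n == 1 for n in self.n_sub)

    def marginal_label_logweights(self) -> list[np.ndarray]:
        """log of the Gaussian-integrated substate weights per step:
        -beta*eps - 1/2 log det F (+ const dropped)."""
        return [-self.beta * e - 0.5 * ld
                for e, ld in zip(self.eps, self.logdetF)]


def model_energy(model: SequenceModel, params: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Total model energy per frame (kcal/mol) for given labels."""
    cache = _ModelCache(model)
    params = np.atleast_3d(np.asarray(params, float))
    labels = np.atleast_2d(np.asarray(labels, int))
    n = params.shape[0]
    e = np.zeros(n)
    for i in range(cache.n_steps):
        d = params[:, i, :] - cache.means[i][labels[:, i]]
        F = cache.F[i][labels[:, i]]
        e += np.einsum("nd,nde,ne->n", d, F, d) + cache.eps[i][labels[:, i]]
    if model.coupling != 0.0:
        e += model.coupling * (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
    return e


# --------------------------------------------------------------------------
# unbiased sampling (exact)
# --------------------------------------------------------------------------

def _sample_labels_chain(cache: _ModelCache, n_frames: int, rng) -> np.ndarray:
    """Exact forward-filter / backward-sample of the substate label chain."""
    n_steps = cache.n_steps
    logw = cache.marginal_label_logweights()
    J = cache.model.coupling
    beta = cache.beta
    # backward messages b[i][s] = log sum over chains i+1..end
    b = [np.zeros(n) for n in cache.n_sub]
    for i in range(n_steps - 2, -1, -1):
        si, sj = cache.n_sub[i], cache.n_sub[i + 1]
        trans = np.where(np.eye(si, sj, dtype=bool), 0.0, -beta * J)
        msg = trans + (logw[i + 1] + b[i + 1])[None, :]
        b[i] = np.logaddexp.reduce(msg, axis=1)
    labels = np.empty((n_frames, n_steps), dtype=np.int64)
    # first step from its marginal
    logp = logw[0] + b[0]
    p = np.exp(logp - logp.max())
    p /= p.sum()
    labels[:, 0] = rng.choice(cache.n_sub[0], size=n_frames, p=p)
    for i in range(1, n_steps):
        si, sj = cache.n_sub[i - 1], cache.n_sub[i]
        trans = np.where(np.eye(si, sj, dtype=bool), 0.0, -beta * J)
        logp = trans + (logw[i] + b[i])[None, :]          # (si, sj)
        p = np.exp(logp - logp.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n_frames)
        labels[:, i] = (u[:, None] > cum[labels[:, i - 1]]).sum(axis=1)
    return labels


def _draw_params_given_labels(cache: _ModelCache, labels: np.ndarray, rng) -> np.ndarray:
    """Exact conditional Gaussian draws, grouped by substate label."""
    n_frames, n_steps = labels.shape
    params = np.empty((n_frames, n_steps, 6))
    for i in range(n_steps):
        z = rng.standard_normal((n_frames, 6))
        for s in range(cache.n_sub[i]):
            mask = labels[:, i] == s
            if not np.any(mask):
                continue
            L = cache.cov_chol[i][s]
            params[mask, i, :] = cache.means[i][s] + z[mask] @ L.T
    return params


def _summarize(params, labels, seed, acceptance, keep_params) -> EnsembleSample:
    return EnsembleSample(
        params=params if keep_params else None,
        labels=labels,
        seed=seed,
        acceptance=acceptance,
        step_twist_mean=params[:, :, TWIST].mean(axis=0),
        step_param_mean=params.mean(axis=0),
        n_frames=params.shape[0],
    )


def sample_unbiased(
    model: SequenceModel,
    n_frames: int,
    seed: int | np.random.SeedSequence | None = None,
    keep_params: bool = True,
) -> EnsembleSample:
    """Exact sample from the unbiased model Boltzmann distribution."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    cache = _ModelCache(model)
    rng = np.random.default_rng(seed)
    labels = _sample_labels_chain(cache, n_frames, rng)
    params = _draw_params_given_labels(cache, labels, rng)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return _summarize(params, labels, seed_int, {"method": "exact", "rate": 1.0},
                      keep_params)


# --------------------------------------------------------------------------
# biased sampling
# --------------------------------------------------------------------------

def _biased_precision(cache: _ModelCache, labels_row, restraint: TorsionalRestraint):
    """Joint precision/mean of all step 6-vectors under the twist bias."""
    n = cache.n_steps
    D = 6 * n
    beta = cache.beta
    P = np.zeros((D, D))
    h = np.zeros(D)  # linear term: P @ mean
    for i in range(n):
        F = cache.F[i][labels_row[i]]
        mu = cache.means[i][labels_row[i]]
        blk = 2.0 * beta * F
        P[6 * i : 6 * i + 6, 6 * i : 6 * i + 6] = blk
        h[6 * i : 6 * i + 6] = blk @ mu
    t = np.zeros(D)
    for i in range(restraint.region[0] - 1, restraint.region[1]):
        t[6 * i + TWIST] = 1.0
    P += 2.0 * beta * restraint.k_tw * np.outer(t, t)
    h += 2.0 * beta * restraint.k_tw * restraint.twist_ref * t
    return P, h


def _sample_biased_single(
    cache: _ModelCache, restraint: TorsionalRestraint, n_frames: int, rng
) -> np.ndarray:
    """Vectorized exact draws for a single-substate model under the bias."""
    labels_row = np.zeros(cache.n_steps, dtype=int)
    P, h = _biased_precision(cache, labels_row, restraint)
    L = cholesky(P, lower=True)
    mean = cho_solve((L, True), h)
    z = rng.standard_normal((n_frames, 6 * cache.n_steps))
    x = mean + solve_triangular(L, z.T, trans="T", lower=True).T
    return x.reshape(n_frames, cache.n_steps, 6)


#: Largest substate-configuration count sampled by exact enumeration.
EXACT_ENUM_LIMIT = 4096


class _BiasedLabelDist:
    """Marginal distribution of substate labels under the twist bias.

    Integrating the Gaussian 6-vectors out of ``exp(-beta [E_model +
    k (t.x - r)^2])`` is closed-form because the bias is rank one in the
    twist coordinates: with B = blockdiag(2 beta F_{i,s}) (whose inverse is
    the substate covariance) and u = sqrt(2 beta k) t, the matrix
    determinant lemma gives per-label-configuration log-weights from
    per-step scalars, so single-label flips and full enumeration are cheap.
    """

    def __init__(self, cache: _ModelCache, restraint: TorsionalRestraint):
        self.cache = cache
        self.restraint = restraint
        beta = cache.beta
        k = restraint.k_tw
        r = restraint.twist_ref
        region = set(range(restraint.region[0] - 1, restraint.region[1]))
        self.two_beta_k = 2.0 * beta * k
        # per-step, per-substate scalars
        self.w = []    # label-local part of log-weight
        self.s3 = []   # [Sigma]_{tw,tw} for region steps, else 0
        self.s4 = []   # (Sigma h)_{tw} for region steps, else 0
        for i in range(cache.n_steps):
            S = cache.n_sub[i]
            w_i = np.empty(S)
            s3_i = np.zeros(S)
            s4_i = np.zeros(S)
            for s in range(S):
                F = cache.F[i][s]
                mu = cache.means[i][s]
                Sig = cache.cov[i][s]          # (2 beta F)^-1
                h = 2.0 * beta * (F @ mu)
                if i in region:
                    h = h.copy()
                    h[TWIST] += self.two_beta_k * r
                    s3_i[s] = Sig[TWIST, TWIST]
                    s4_i[s] = (Sig @ h)[TWIST]
                logdet = cache.logdetF[i][s] + 6.0 * np.log(2.0 * beta)
                w_i[s] = (
                    0.5 * float(h @ Sig @ h)
                    - 0.5 * logdet
                    - beta * float(mu @ F @ mu)
                    - beta * cache.eps[i][s]
                )
            self.w.append(w_i)
            self.s3.append(s3_i)
            self.s4.append(s4_i)
        self.n_configs = int(np.prod([float(n) for n in cache.n_sub]))

    def logweight(self, labels: np.ndarray) -> np.ndarray:
        """Log marginal weights of label configurations (n_chains, n_steps)."""
        labels = np.atleast_2d(labels)
        n_chains = labels.shape[0]
        lw = np.zeros(n_chains)
        S3 = np.zeros(n_chains)
        S4 = np.zeros(n_chains)
        for i in range(self.cache.n_steps):
            li = labels[:, i]
            lw += self.w[i][li]
            S3 += self.s3[i][li]
            S4 += self.s4[i][li]
        denom = 1.0 + self.two_beta_k * S3
        lw += -0.5 * np.log(denom) - 0.5 * self.two_beta_k * S4**2 / denom
        J = self.cache.model.coupling
        if J != 0.0:
            lw += -self.cache.beta * J * (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
        return lw

    def enumerate_configs(self) -> np.ndarray:
        """All label configurations, shape (n_configs, n_steps)."""
        grids = np.meshgrid(
            *[np.arange(n) for n in self.cache.n_sub], indexing="ij"
        )
        return np.stack([g.ravel() for g in grids], axis=1)


def _draw_biased_given_labels(cache, restraint, labels, rng, chol_cache):
    """Exact conditional Gaussian draws grouped by label configuration."""
    n_frames = labels.shape[0]
    params = np.empty((n_frames, cache.n_steps, 6))
    uniq, inv = np.unique(labels, axis=0, return_inverse=True)
    for u in range(len(uniq)):
        key = tuple(int(v) for v in uniq[u])
        if key not in chol_cache:
            if len(chol_cache) > 8192:
                chol_cache.clear()
            P, h = _biased_precision(cache, uniq[u], restraint)
            L = cholesky(P, lower=True)
            chol_cache[key] = (L, cho_solve((L, True), h))
        L, mean = chol_cache[key]
        rows = np.where(inv == u)[0]
        z = rng.standard_normal((len(rows), 6 * cache.n_steps))
        x = mean + solve_triangular(L, z.T, trans="T", lower=True).T
        params[rows] = x.reshape(len(rows), cache.n_steps, 6)
    return params


def sample_biased(
    model: SequenceModel,
    restraint: TorsionalRestraint,
    n_frames: int,
    seed: int | np.random.SeedSequence | None = None,
    burn_in_fraction: float = 0.1,
    keep_params: bool = True,
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[UmbrellaWindow, tuple[np.ndarray, np.ndarray]]:
    """Sample one umbrella window under model energy + twist bias.

    Single-substate models are sampled exactly (the biased distribution is
    one joint Gaussian).  For multi-substate models the substate labels are
    sampled from their *marginal* distribution with the 6-vectors
    integrated out analytically (the bias couples only in-region twists,
    quadratically, so the marginal label weights are closed-form): by exact
    enumeration when the configuration space is small, by a collapsed
    Metropolis chain over labels otherwise.  Given labels, all 6-vectors
    are drawn exactly from the conditional Gaussian.

    Returns the window and the final ``(params, labels)`` configuration for
    cascade seeding.  The first ``burn_in_fraction`` of frames is discarded.
    """
    if not (1 <= restraint.region[0] <= restraint.region[1] <= model.n_steps):
        raise ValueError("restraint region outside the model's steps")
    cache = _ModelCache(model)
    rng = np.random.default_rng(seed)
    n_burn = int(burn_in_fraction * n_frames)
    if cache.single_substate:
        params = _sample_biased_single(cache, restraint, n_frames, rng)
        labels = np.zeros((n_frames, cache.n_steps), dtype=np.int64)
        acc = {"method": "exact-gaussian", "rate": 1.0}
    else:
        dist = _BiasedLabelDist(cache, restraint)
        chol_cache: dict[tuple, tuple] = {}
        if dist.n_configs <= EXACT_ENUM_LIMIT:
            configs = dist.enumerate_configs()
            lw = dist.logweight(configs)
            p = np.exp(lw - lw.max())
            p /= p.sum()
            idx = rng.choice(len(configs), size=n_frames, p=p)
            labels = configs[idx]
            acc = {"method": "exact-mixture", "rate": 1.0}
        else:
            labels = np.empty((n_frames, cache.n_steps), dtype=np.int64)
            lab = (
                np.array(start[1], int)
                if start is not None
                else np.zeros(cache.n_steps, dtype=int)
            )
            multi = [i for i in range(cache.n_steps) if cache.n_sub[i] > 1]
            cur_lw = float(dist.logweight(lab[None])[0])
            accepted = proposals = 0
            for f in range(n_frames):
                for i in multi:
                    proposals += 1
                    prop_lab = lab.copy()
                    s = int(rng.integers(cache.n_sub[i] - 1))
                    if s >= lab[i]:
                        s += 1
                    prop_lab[i] = s
                    new_lw = float(dist.logweight(prop_lab[None])[0])
                    if np.log(rng.random()) < new_lw - cur_lw:
                        lab, cur_lw = prop_lab, new_lw
                        accepted += 1
                labels[f] = lab
            rate = accepted / proposals if proposals else 1.0
            acc = {"method": "collapsed-metropolis", "rate": rate}
            if proposals and rate < 0.01:
                warnings.warn(
                    f"label acceptance rate {rate:.3%} below 1%; continuing",
                    RuntimeWarning,
                )
        params = _draw_biased_given_labels(cache, restraint, labels, rng, chol_cache)
    final_state = (params[-1].copy(), labels[-1].copy())
    params, labels = params[n_burn:], labels[n_burn:]
    ens = _summarize(params, labels,
                     seed if isinstance(seed, (int, np.integer)) else None,
                     acc, keep_params)
    cv = params[:, restraint.step_slice, TWIST].sum(axis=1)
    return UmbrellaWindow(restraint=restraint, cv_series=cv, ensemble=ens), final_state


def run_umbrella(
    model: SequenceModel,
    schedule: UmbrellaSchedule,
    k_tw: float = 0.06,
    region: tuple[int, int] | None = None,
    n_frames: int | None = None,
    seed: int | None = None,
    burn_in_fraction: float = 0.1,
    keep_params: bool = False,
) -> list[UmbrellaWindow]:
    """Run the cascade umbrella schedule; one window per reference twist.

    Windows are returned in schedule (cascade) order.  With
    ``schedule.sequential_seeding`` the final configuration of each window
    seeds the next window of the same branch; every window consumes an
    independent RNG stream spawned from the master seed.
    """
    if region is None:
        if model.n_steps != schedule.n_region_steps:
            raise ValueError(
                "model has more steps than the schedule's restrained region; "
                "pass region=(first_step, last_step) explicitly"
            )
        region = (1, model.n_steps)
    if region[1] - region[0] + 1 != schedule.n_region_steps:
        raise ValueError("region length must equal schedule.n_region_steps")
    n_frames = schedule.n_frames_per_window if n_frames is None else n_frames
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(schedule.n_windows)
    refs = schedule.refs
    windows: list[UmbrellaWindow | None] = [None] * schedule.n_windows
    # branch structure: index 0 is the centre; 1..n_side overwinding;
    # n_side+1..2n_side underwinding; cascade seeding follows each branch.
    centre_state: tuple | None = None
    state: tuple | None = None
    for idx in range(schedule.n_windows):
        restraint = TorsionalRestraint(k_tw=k_tw, twist_ref=float(refs[idx]), region=region)
        if schedule.sequential_seeding:
            if idx == 0:
                start = None
            elif idx in (1, schedule.n_side + 1):  # branch roots seed from centre
                start = centre_state
            else:
                start = state
        else:
            start = None
        window, state = sample_biased(
            model,
            restraint,
            n_frames,
            seed=streams[idx],
            burn_in_fraction=burn_in_fraction,
            keep_params=keep_params,
            start=start,
        )
        if idx == 0:
            centre_state = state
        windows[idx] = window
    return windows  # type: ignore[return-value]


# --------------------------------------------------------------------------
# analytic ground truth
# --------------------------------------------------------------------------

def step_twist_moments(model: SequenceModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-step twist mean and variance (deg, deg^2) of the unbiased
    model with independent steps (coupling J = 0)."""
    if model.coupling != 0.0:
        raise ValueError(
            "analytic twist moments require independent steps (J = 0); "
            "estimate from a long unbiased simulation instead"
        )
    cache = _ModelCache(model)
    logw = cache.marginal_label_logweights()
    means = np.empty(model.n_steps)
    variances = np.empty(model.n_steps)
    for i in range(model.n_steps):
        w = np.exp(logw[i] - logw[i].max())
        w /= w.sum()
        mu = cache.means[i][:, TWIST]
        var = cache.cov[i][:, TWIST, TWIST]
        m = float(w @ mu)
        means[i] = m
        variances[i] = float(w @ (var + mu**2) - m**2)
    return means, variances


def ground_truth_modulus(model: SequenceModel, region: tuple[int, int] | None = None) -> float:
    """Analytic torsional modulus (nm) of the model chain.

    For independent steps the fragment twist variance is the sum of per-step
    twist variances and the homogeneous rod model gives

        C = n * L_bp / Var(total twist, rad^2)
          = L_bp / Var(step twist, rad^2)      (homogeneous chain).

    Multimodal steps enter through their exact mixture variance.
    """
    _, variances = step_twist_moments(model)
    if region is not None:
        variances = variances[region[0] - 1 : region[1]]
    n = len(variances)
    var_total_rad = float(variances.sum()) * DEG2RAD**2
    return n * L_BP_NM / var_total_rad


# --------------------------------------------------------------------------
# vectorized collapsed label Metropolis (reversibility checks, fallback chain)
# --------------------------------------------------------------------------

def metropolis_label_steps(
    model: SequenceModel,
    restraint: TorsionalRestraint,
    labels: np.ndarray,
    n_sweeps: int,
    rng,
    record: bool = False,
):
    """Collapsed Metropolis sweeps over substate labels, many chains at once.

    The chain targets the exact marginal label distribution under the
    twist bias (6-vectors integrated out; see :class:`_BiasedLabelDist`).
    ``labels`` has shape (n_chains, n_steps).  With ``record`` the label
    snapshots after every sweep are returned for detailed-balance checks.
    """
    cache = _ModelCache(model)
    dist = _BiasedLabelDist(cache, restraint)
    labels = np.array(labels, dtype=np.int64)
    n_chains, n_steps = labels.shape
    cur_lw = dist.logweight(labels)
    snapshots = []
    for _ in range(n_sweeps):
        for i in range(n_steps):
            S = cache.n_sub[i]
            if S == 1:
                continue
            prop = labels.copy()
            s = rng.integers(S - 1, size=n_chains)
            s = np.where(s >= labels[:, i], s + 1, s)
            prop[:, i] = s
            new_lw = dist.logweight(prop)
            accept = np.log(rng.random(n_chains)) < new_lw - cur_lw
            labels[accept] = prop[accept]
            cur_lw = np.where(accept, new_lw, cur_lw)
        if record:
            snapshots.append(labels.copy())
    return (labels, snapshots) if record else (labels, None)
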