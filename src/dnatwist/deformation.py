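"""Harmonic multi-substate DNA deformation energies with Ising coupling.

A snapshot of the restrained region is scored over the 12 helical
parameters per step (6 inter-bp + 6 intra-bp).  Each step carries one or
more harmonic substates

    E_s(x) = 1/2 (x - mu_s)^T F_s (x - mu_s) + eps_s      [kcal/mol]

and adjacent steps' substate labels are coupled by J(s_i, s_{i+1}).  The
default score Boltzmann-sums over all substate chains with an exact
transfer matrix,

    E(x) = -k_B T ln sum_chains exp(-beta [sum_i E_{s_i}(x_i) + sum_i J]),

and the alternative ``mode="min"`` takes the lowest-energy chain instead.
Energies are referenced so the minimum-energy configuration of the model
scores zero.

The published tetranucleotide parameterization of this model class is not
bundled; parameter sets are pluggable (JSON loader) and the shipped default
is a synthetic dimer-level set derived from the sampling model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kbt
from .ensembles import EnsembleSample, SequenceModel

__all__ = [
    "DeformationModel",
    "DeformationResult",
    "snapshot_energy",
    "window_deformation",
    "deformation_model_from_sequence_model",
    "load_parameter_file",
]

#: Default intra-bp fluctuation SDs used when promoting a 6-parameter
#: sampling model to the 12-parameter deformation model (A / deg).
DEFAULT_INTRA_SDS = np.array([0.3, 0.12, 0.35, 8.0, 8.0, 4.0])
INTRA_MEANS = np.zeros(6)


@dataclass(frozen=True)
class DeformationModel:
    """Per-step multi-substate harmonic model over 12 helical parameters.

    ``means[i]`` is (S_i, 12), ``stiffness[i]`` is (S_i, 12, 12) SPD with
    the 1/2 x^T F x convention, ``epsilon[i]`` is (S_i,); ``coupling[i]``
    is the (S_i, S_{i+1}) Ising table between steps i and i+1.
    """

    means: tuple[np.ndarray, ...]
    stiffness: tuple[np.ndarray, ...]
    epsilon: tuple[np.ndarray, ...]
    coupling: tuple[np.ndarray, ...]
    temperature: float = 300.0
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.provenance not in ("synthetic", "user-supplied"):
            raise ValueError("provenance must be 'synthetic' or 'user-supplied'")
        n = len(self.means)
        if not (len(self.stiffness) == len(self.epsilon) == n):
            raise ValueError("means/stiffness/epsilon length mismatch")
        if len(self.coupling) != max(n - 1, 0):
            raise ValueError("need one coupling table per adjacent step pair")
        for i in range(n):
            S = self.means[i].shape[0]
            if self.means[i].shape != (S, 12):
                raise ValueError(f"step {i}: means must be (S, 12)")
            if self.stiffness[i].shape != (S, 12, 12):
                raise ValueError(f"step {i}: stiffness must be (S, 12, 12)")
            if self.epsilon[i].shape != (S,):
                raise ValueError(f"step {i}: epsilon must be (S,)")
            for F in self.stiffness[i]:
                if np.abs(F - F.T).max() > 1e-8:
                    raise ValueError(f"step {i}: stiffness not symmetric")
                if np.linalg.eigvalsh(F).min() <= 0:
                    raise ValueError(f"step {i}: stiffness not positive definite")
        for i, J in enumerate(self.coupling):
            Si, Sj = self.means[i].shape[0], self.means[i + 1].shape[0]
            if J.shape != (Si, Sj):
                raise ValueError(f"coupling table {i} must be ({Si}, {Sj})")

    @property
    def n_steps(self) -> int:
        return len(self.means)

    @property
    def n_substates(self) -> tuple[int, ...]:
        return tuple(m.shape[0] for m in self.means)

    @property
    def beta(self) -> float:
        return 1.0 / kbt(self.temperature)


@dataclass
class DeformationResult:
    """Per-frame deformation energies and their window statistics."""

    energies: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def _chain_ground_energy(model: DeformationModel) -> tuple[float, np.ndarray]:
    """Minimum over substate chains of sum(eps) + sum(J) (Viterbi, min-plus),
    i.e. the model's global energy minimum (each step's quadratic term can
    reach zero at its own mean).  Returns the energy and the arg-min chain.
    """
    n = model.n_steps
    cost = model.epsilon[0].astype(float).copy()
    back: list[np.ndarray] = []
    for i in range(1, n):
        trial = cost[:, None] + model.coupling[i - 1] + model.epsilon[i][None, :]
        back.append(np.argmin(trial, axis=0))
        cost = np.min(trial, axis=0)
    best_end = int(np.argmin(cost))
    chain = np.empty(n, dtype=int)
    chain[-1] = best_end
    for i in range(n - 2, -1, -1):
        chain[i] = back[i][chain[i + 1]]
    return float(cost[best_end]), chain


def _raw_energies(
    x: np.ndarray, model: DeformationModel, mode: str
) -> np.ndarray:
    """Un-referenced energies for (n_frames, n_steps, 12) configurations."""
    beta = model.beta
    kT = kbt(model.temperature)
    n_frames, n_steps = x.shape[0], x.shape[1]
    # per-step, per-substate basin energies
    h = []
    for i in range(n_steps):
        d = x[:, i, None, :] - model.means[i][None, :, :]
        q = 0.5 * np.einsum("nsd,sde,nse->ns", d, model.stiffness[i], d)
        h.append(q + model.epsilon[i][None, :])
    if mode == "logsum":
        a = -beta * h[0]
        for i in range(1, n_steps):
            a = logsumexp(a[:, :, None] - beta * model.coupling[i - 1][None, :, :], axis=1)
            a = a - beta * h[i]
        return -kT * logsumexp(a, axis=1)
    if mode == "min":
        a = h[0]
        for i in range(1, n_steps):
            a = np.min(a[:, :, None] + model.coupling[i - 1][None, :, :], axis=1) + h[i]
        return np.min(a, axis=1)
    raise ValueError(f"unknown mode {mode!r}; use 'logsum' or 'min'")


def _reference_energy(model: DeformationModel, mode: str) -> float:
    """Energy of the model's minimum-energy configuration (score zero)."""
    e0, chain = _chain_ground_energy(model)
    if mode == "min":
        return e0
    x0 = np.stack([model.means[i][chain[i]] for i in range(model.n_steps)])[None]
    return float(_raw_energies(x0, model, "logsum")[0])


def snapshot_energy(
    params12: np.ndarray, model: DeformationModel, mode: str = "logsum"
) -> float | np.ndarray:
    """Deformation energy of one snapshot (or a batch) in kcal/mol.

    ``params12`` has shape (n_steps, 12) or (n_frames, n_steps, 12); the 12
    components per step are the 6 inter-bp parameters followed by the 6
    intra-bp parameters.  The returned energy is relative to the model's
    minimum-energy configuration.
    """
    x = np.asarray(params12, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1] != model.n_steps or x.shape[2] != 12:
        raise ValueError(
            f"expected (n_frames, {model.n_steps}, 12) parameters, got {x.shape}"
        )
    e = _raw_energies(x, model, mode) - _reference_energy(model, mode)
    return float(e[0]) if single else e


def window_deformation(
    ensemble: EnsembleSample | np.ndarray,
    model: DeformationModel,
    mode: str = "logsum",
) -> DeformationResult:
    """Per-frame deformation energies of a sampled window, with mean/SD.

    Accepts an :class:`~dnatwist.ensembles.EnsembleSample` (6 inter-bp
    parameters per step; the intra-bp block is filled with the model's
    reference intra means) or a raw (n_frames, n_steps, 6 or 12) array.
    Burn-in is assumed already removed by the sampler.
    """
    if isinstance(ensemble, EnsembleSample):
        if ensemble.params is None:
            raise ValueError("ensemble does not retain its parameter trajectory")
        x = ensemble.params
    else:
        x = np.asarray(ensemble, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_frames, n_steps, 6 or 12) parameters")
    if x.shape[2] == 6:
        intra = np.broadcast_to(INTRA_MEANS, x.shape[:2] + (6,))
        x = np.concatenate([x, intra], axis=2)
    energies = snapshot_energy(x, model, mode=mode)
    return DeformationResult(
        energies=energies, mean=float(energies.mean()), sd=float(energies.std())
    )


def deformation_model_from_sequence_model(
    model: SequenceModel,
    region: tuple[int, int] | None = None,
    intra_sds: np.ndarray = DEFAULT_INTRA_SDS,
) -> DeformationModel:
    """Promote a 6-parameter sampling model to a 12-parameter scorer.

    The inter-bp block reuses the sampling model's basins (stiffness
    doubled: the sampler uses ``d^T F d``, the scorer ``1/2 d^T F d``, so
    both describe the same Gaussian).  The intra-bp block is a diagonal
    single basin with the given SDs around zero.  The Ising table applies
    the sampling model's mismatch penalty to unequal labels.
    """
    kT = kbt(model.temperature)
    intra_F = np.diag(kT / np.asarray(intra_sds, float) ** 2)
    lo, hi = region if region is not None else (1, model.n_steps)
    means, stiffs, eps, coup = [], [], [], []
    sizes = []
    for i in range(lo - 1, hi):
        subs = model.steps[i]
        m = np.stack([np.concatenate([s.mean, INTRA_MEANS]) for s in subs])
        F = np.zeros((len(subs), 12, 12))
        for k, s in enumerate(subs):
            F[k, :6, :6] = 2.0 * s.stiffness
            F[k, 6:, 6:] = intra_F
        means.append(m)
        stiffs.append(F)
        eps.append(np.array([s.epsilon for s in subs]))
        sizes.append(len(subs))
    for a, b in zip(sizes[:-1], sizes[1:]):
        J = np.full((a, b), model.coupling)
        np.fill_diagonal(J, 0.0)
        coup.append(J)
    return DeformationModel(
        means=tuple(means),
        stiffness=tuple(stiffs),
        epsilon=tuple(eps),
        coupling=tuple(coup),
        temperature=model.temperature,
        provenance="synthetic",
    )


def load_parameter_file(path, temperature: float = 300.0) -> DeformationModel:
    """Load a user-supplied deformation parameter set from JSON.

    Expected layout::

        {
          "steps": [
            {"substates": [{"mean": [12 floats],
                            "stiffness": [[12 x 12]],
                            "epsilon": 0.0}, ...]},
            ...
          ],
          "coupling": [[[S_i x S_{i+1}]], ...]   # optional, zeros if absent
        }
    """
    with open(path) as fh:
        payload = json.load(fh)
    means, stiffs, eps = [], [], []
    for step in payload["steps"]:
        subs = step["substates"]
        means.append(np.array([s["mean"] for s in subs], dtype=float))
        stiffs.append(np.array([s["stiffness"] for s in subs], dtype=float))
        eps.append(np.array([s.get("epsilon", 0.0) for s in subs], dtype=float))
    n = len(means)
    if "coupling" in payload and payload["coupling"] is not None:
        coup = [np.asarray(J, dtype=float) for J in payload["coupling"]]
    else:
        coup = [np.zeros((means[i].shape[0], means[i + 1].shape[0]))
                for i in range(n - 1)]
    return DeformationModel(
        means=tuple(means),
        stiffness=tuple(stiffs),
        epsilon=tuple(eps),
        coupling=tuple(coup),
        temperature=temperature,
        provenance="user-supplied",
    )
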