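"""Torsional force constants and moduli from twisting PMFs.

The PMF on the per-bp-step axis is fitted with a free-centre quadratic
``F(delta) = K (delta - c)^2 + F0`` over a window of +/- 2 deg/bp around its
minimum; the force constant K (kcal mol^-1 deg^-2) is converted to the
torsional modulus of the homogeneous rod model,

    C = 2 K_rad L_bp / (n k_B T)        [nm]

where ``K_rad = K (180/pi)^2`` and L_bp = 0.34 nm.  For a chain of
independent steps this is equivalent to ``C = L_bp / Var(step twist,
rad^2)``, which serves as the independent validation identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, L_BP_NM, RAD2DEG, kbt
from .wham import PMFProfile

__all__ = [
    "ElasticFit",
    "TorsionalModulus",
    "fit_force_constant",
    "torsional_modulus",
    "supercoiling_density",
]


@dataclass(frozen=True)
class ElasticFit:
    """Quadratic fit of a twisting PMF on the per-bp-step axis."""

    K: float                 # kcal mol^-1 deg^-2 (per-bp axis)
    centre: float            # fitted minimum position, deg/bp
    offset: float            # fitted free-energy offset, kcal/mol
    r_squared: float
    fit_half_range: float    # deg/bp
    n_bins: int

    def to_dict(self) -> dict:
        return {
            "K_kcal_mol_deg2": self.K,
            "centre_deg_per_bp": self.centre,
            "offset_kcal_mol": self.offset,
            "R2": self.r_squared,
            "fit_half_range_deg_per_bp": self.fit_half_range,
            "n_bins": self.n_bins,
        }


@dataclass(frozen=True)
class TorsionalModulus:
    """Rod-model torsional modulus (a length, nm)."""

    C: float
    temperature: float
    L_bp: float
    n_region_steps: int

    def to_dict(self) -> dict:
        return {
            "C_nm": self.C,
            "T_K": self.temperature,
            "L_bp_nm": self.L_bp,
            "n_steps": self.n_region_steps,
        }


def fit_force_constant(pmf: PMFProfile, half_range: float = 2.0) -> ElasticFit:
    """Least-squares quadratic fit around the PMF minimum.

    Only unmasked (sampled) bins with |delta - delta_min| <= half_range on
    the per-bp axis enter the fit; the minimum position is the grid point
    of lowest free energy and the parabola centre is left free.
    """
    good = pmf.mask & np.isfinite(pmf.free_energy)
    if not np.any(good):
        raise ValueError("PMF has no sampled bins")
    grid, free = pmf.grid[good], pmf.free_energy[good]
    delta_min = grid[np.argmin(free)]
    lo, hi = delta_min - half_range, delta_min + half_range
    if grid.min() > lo + 1e-9 or grid.max() < hi - 1e-9:
        raise ValueError(
            f"PMF support [{grid.min():.2f}, {grid.max():.2f}] deg/bp does not "
            f"cover the fit range [{lo:.2f}, {hi:.2f}]"
        )
    sel = (grid >= lo) & (grid <= hi)
    if sel.sum() < 5:
        raise ValueError(f"only {int(sel.sum())} bins in the fit range; need >= 5")
    x, y = grid[sel], free[sel]
    coeff = np.polyfit(x, y, 2)
    a, b, c = coeff
    if a <= 0:
        raise ValueError(f"fitted quadratic is not convex (K = {a:.4g})")
    resid = y - np.polyval(coeff, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    centre = -b / (2 * a)
    return ElasticFit(
        K=float(a),
        centre=float(centre),
        offset=float(c - b**2 / (4 * a)),
        r_squared=r2,
        fit_half_range=float(half_range),
        n_bins=int(sel.sum()),
    )


def torsional_modulus(
    fit: ElasticFit | float,
    n_region_steps: int,
    L_bp: float = L_BP_NM,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> TorsionalModulus:
    """Homogeneous-rod torsional modulus from a per-bp force constant.

    ``fit`` may be an :class:`ElasticFit` or the bare K in
    kcal mol^-1 deg^-2 on the per-bp-step axis.
    """
    K = fit.K if isinstance(fit, ElasticFit) else float(fit)
    if K <= 0:
        raise ValueError(f"force constant must be positive, got {K}")
    if n_region_steps < 1:
        raise ValueError("n_region_steps must be >= 1")
    K_rad = K * RAD2DEG**2
    C = 2.0 * K_rad * L_bp / (n_region_steps * kbt(temperature))
    return TorsionalModulus(
        C=float(C),
        temperature=temperature,
        L_bp=L_bp,
        n_region_steps=int(n_region_steps),
    )


def supercoiling_density(delta_per_bp: float, relaxed_per_bp: float) -> float:
    """Twist-only supercoiling density sigma = delta_twist / relaxed_twist.

    Writhe is neglected, appropriate for short (~10-20 bp) fragments below
    any buckling transition.
    """
    if relaxed_per_bp <= 0:
        raise ValueError("relaxed twist per bp must be positive")
    return float(delta_per_bp) / float(relaxed_per_bp)
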