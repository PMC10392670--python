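"""Quadratic end-to-end-twist restraint.

The collective variable is the sum of helical twists over a contiguous range
of bp steps; the bias is ``E = k_tw * (twist - twist_ref)**2`` with no 1/2
factor (the PLUMED-style convention; a spring constant in the conventional
``1/2 k x^2`` form is ``k = 2 * k_tw``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TorsionalRestraint", "bias_energy", "bias_gradient"]


@dataclass(frozen=True)
class TorsionalRestraint:
    """End-to-end twist restraint.

    Parameters
    ----------
    k_tw : force constant, kcal mol^-1 deg^-2 (>= 0).
    twist_ref : reference end-to-end twist, degrees.
    region : (first_step, last_step), 1-based inclusive bp-step range.
    """

    k_tw: float
    twist_ref: float
    region: tuple[int, int]

    def __post_init__(self) -> None:
        if self.k_tw < 0:
            raise ValueError(f"k_tw must be non-negative, got {self.k_tw}")
        lo, hi = self.region
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise TypeError("region bounds must be integers")
        if lo < 1 or hi < lo:
            raise ValueError(f"region must be a non-empty 1-based step range, got {self.region}")
        object.__setattr__(self, "region", (int(lo), int(hi)))

    @property
    def n_steps(self) -> int:
        return self.region[1] - self.region[0] + 1

    @property
    def step_slice(self) -> slice:
        """0-based slice over step arrays covering the restrained region."""
        return slice(self.region[0] - 1, self.region[1])

    def to_dict(self) -> dict:
        return {
            "k_tw": self.k_tw,
            "twist_ref": self.twist_ref,
            "region_start": self.region[0],
            "region_end": self.region[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TorsionalRestraint":
        return cls(
            k_tw=float(d["k_tw"]),
            twist_ref=float(d["twist_ref"]),
            region=(int(d["region_start"]), int(d["region_end"])),
        )

    def energy(self, twist_total) -> float | np.ndarray:
        """Bias energy at the given end-to-end twist (kcal/mol)."""
        return bias_energy(self, twist_total)


def bias_energy(restraint: TorsionalRestraint, twist_total) -> float | np.ndarray:
    """Bias energy k_tw*(twist - ref)^2 in kcal/mol (vectorized over twist)."""
    twist_total = np.asarray(twist_total, dtype=float)
    e = restraint.k_tw * (twist_total - restraint.twist_ref) ** 2
    return float(e) if e.ndim == 0 else e


def bias_gradient(
    restraint: TorsionalRestraint, twist_total: float, n_steps_total: int | None = None
) -> np.ndarray:
    """Gradient of the bias with respect to each step twist.

    The CV is a plain sum of in-region step twists, so every in-region step
    carries the same derivative ``2*k_tw*(twist - ref)`` and steps outside
    the region carry zero.  Returns an array of length ``n_steps_total``
    (defaults to the last region step).
    """
    if n_steps_total is None:
        n_steps_total = restraint.region[1]
    g = np.zeros(int(n_steps_total))
    g[restraint.step_slice] = 2.0 * restraint.k_tw * (float(twist_total) - restraint.twist_ref)
    return g
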