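"""Weighted histogram analysis of twist-restrained umbrella windows.

Reconstructs the unbiased potential of mean force (PMF) of the end-to-end
twist from the biased windows by the standard self-consistent WHAM
iteration, then reports it on the *average twist change per bp step* axis,

    delta_per_bp = (CV - relaxed mean CV) / n_region_steps,

with the relaxed mean taken from the central (relaxed) window and the
profile min-zeroed over well-sampled bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import kbt
from .ensembles import UmbrellaWindow

__all__ = ["PMFProfile", "wham", "overlap_report"]


@dataclass
class PMFProfile:
    """Free energy vs average twist change per bp step.

    ``grid`` holds bin centres on the per-bp axis (deg), strictly
    increasing and uniform; ``free_energy`` is min-zeroed over unmasked
    bins and NaN where no window contributed samples.
    """

    grid: np.ndarray
    free_energy: np.ndarray
    bin_counts: np.ndarray          # (n_windows, n_bins)
    mask: np.ndarray                # True where the PMF is defined
    relaxed_cv: float               # mean CV of the central window, deg
    n_region_steps: int
    bin_width_total: float          # bin width on the total-twist axis, deg
    iterations: int
    final_delta: float
    temperature: float

    @property
    def n_samples(self) -> np.ndarray:
        return self.bin_counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_twist_per_bp": self.grid,
                "free_energy_kcal_mol": self.free_energy,
                "n_samples": self.n_samples.astype(int),
            }
        )

    def metadata(self) -> dict:
        return {
            "iterations": self.iterations,
            "final_delta": self.final_delta,
            "relaxed_cv": self.relaxed_cv,
            "n_region_steps": self.n_region_steps,
            "bin_width_total_deg": self.bin_width_total,
            "temperature_K": self.temperature,
        }


def _central_window(windows: list[UmbrellaWindow]) -> UmbrellaWindow:
    refs = np.array([w.restraint.twist_ref for w in windows])
    return windows[int(np.argmin(np.abs(refs - np.median(refs))))]


def _check_overlap(windows, edges, counts):
    """Require shared histogram support between ref-adjacent windows."""
    order = np.argsort([w.restraint.twist_ref for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            ra = windows[a].restraint.twist_ref
            rb = windows[b].restraint.twist_ref
            raise ValueError(
                f"no histogram overlap between adjacent windows at "
                f"twist_ref {ra:.2f} and {rb:.2f} deg"
            )


def wham(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.25,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = 300.0,
) -> PMFProfile:
    """Self-consistent 1-D WHAM over the end-to-end twist.

    Parameters
    ----------
    windows : biased umbrella windows (>= 1), sharing a restrained region.
    bin_width : histogram bin width on the total-twist axis, degrees.
    tol : convergence threshold on the window free-energy shifts, kcal/mol.
    max_iter : iteration cap; exceeding it raises with the residual.
    """
    if len(windows) < 1:
        raise ValueError("need at least one umbrella window")
    regions = {w.restraint.region for w in windows}
    if len(regions) != 1:
        raise ValueError(f"windows restrain different regions: {sorted(regions)}")
    n_region = windows[0].restraint.n_steps
    kT = kbt(temperature)

    all_cv = np.concatenate([w.cv_series for w in windows])
    lo = np.floor(all_cv.min() / bin_width) * bin_width
    hi = np.ceil(all_cv.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    centres = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.cv_series, bins=edges)[0] for w in windows])
    if len(windows) > 1:
        _check_overlap(windows, edges, counts)
    n_w = counts.sum(axis=1).astype(float)
    total = counts.sum(axis=0).astype(float)
    sampled = total > 0

    # bias energies on the grid
    bias = np.stack([np.asarray(w.restraint.energy(centres)) for w in windows])
    log_nw = np.log(n_w)[:, None]
    f = np.zeros(len(windows))
    it = 0
    delta = np.inf
    with np.errstate(divide="ignore"):
        log_total = np.log(total)
    for it in range(1, max_iter + 1):
        # log denominator per bin: log sum_w n_w exp(-beta (b_w - f_w))
        a = log_nw + (f[:, None] - bias) / kT
        a_max = a.max(axis=0)
        log_den = a_max + np.log(np.exp(a - a_max).sum(axis=0))
        log_p = np.where(sampled, log_total - log_den, -np.inf)
        # new shifts: f_w = -kT log sum_b exp(-beta b_w) p_b
        b = (-bias / kT) + log_p
        b_max = b.max(axis=1)
        f_new = -kT * (b_max + np.log(np.exp(b - b_max[:, None]).sum(axis=1)))
        f_new -= f_new[0]
        delta = float(np.abs(f_new - f).max())
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta:.3e} kcal/mol)"
        )

    a = log_nw + (f[:, None] - bias) / kT
    a_max = a.max(axis=0)
    log_den = a_max + np.log(np.exp(a - a_max).sum(axis=0))
    free = np.full(len(centres), np.nan)
    free[sampled] = -kT * (log_total[sampled] - log_den[sampled])
    free -= np.nanmin(free)

    relaxed_cv = _central_window(windows).mean_cv
    grid = (centres - relaxed_cv) / n_region
    return PMFProfile(
        grid=grid,
        free_energy=free,
        bin_counts=counts,
        mask=sampled,
        relaxed_cv=relaxed_cv,
        n_region_steps=n_region,
        bin_width_total=bin_width,
        iterations=it,
        final_delta=delta,
        temperature=temperature,
    )


def overlap_report(windows: list[UmbrellaWindow], bin_width: float = 0.25) -> pd.DataFrame:
    """Histogram-overlap fraction between reference-adjacent window pairs.

    The overlap of two normalized histograms p, q is sum(min(p, q)),
    in [0, 1]: 1 for identical windows, 0 for disjoint support.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    order = np.argsort([w.restraint.twist_ref for w in windows])
    rows = []
    for a, b in zip(order[:-1], order[1:]):
        wa, wb = windows[a], windows[b]
        lo = min(wa.cv_series.min(), wb.cv_series.min())
        hi = max(wa.cv_series.max(), wb.cv_series.max())
        edges = np.arange(
            np.floor(lo / bin_width) * bin_width,
            np.ceil(hi / bin_width) * bin_width + bin_width * 0.5,
            bin_width,
        )
        pa = np.histogram(wa.cv_series, bins=edges)[0] / len(wa.cv_series)
        pb = np.histogram(wb.cv_series, bins=edges)[0] / len(wb.cv_series)
        rows.append(
            {
                "ref_lo": wa.restraint.twist_ref,
                "ref_hi": wb.restraint.twist_ref,
                "overlap": float(np.minimum(pa, pb).sum()),
            }
        )
    return pd.DataFrame(rows)
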