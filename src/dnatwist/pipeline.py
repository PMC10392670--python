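"""End-to-end orchestration: simulate -> umbrella -> WHAM -> fit -> modulus
-> deformation -> structural readouts, plus the per-step twist partition.

The run is driven by a validated :class:`RunConfig` (YAML/JSON); every
output embeds the config hash and package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .deformation import deformation_model_from_sequence_model, window_deformation
from .elasticity import fit_force_constant, supercoiling_density, torsional_modulus
from .ensembles import (
    SequenceModel,
    UmbrellaWindow,
    default_model,
    ground_truth_modulus,
    homogeneous_model,
    make_umbrella_schedule,
    restrained_region,
    run_umbrella,
    sample_biased,
)
from .geometry import axis_bending, groove_geometry
from .io import save_windows, write_pmf
from .restraint import TorsionalRestraint
from .structure import build_atom_dicts, frames_from_atom_dicts
from .wham import overlap_report, wham

log = logging.getLogger("dnatwist")

__all__ = ["RunConfig", "TwistPartition", "twist_partition", "run_all", "load_config"]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

class ModelConfig(BaseModel):
    kind: str = Field("default", pattern="^(default|homogeneous)$")
    twist_mean: float = 34.6
    twist_sd: float = 3.0
    bimodal_separation: float = 20.0
    coupling: float = 0.0
    temperature: float = Field(300.0, gt=0)


class ScheduleConfig(BaseModel):
    increment: float = Field(0.5, gt=0)
    max_offset: float = Field(5.0, gt=0)
    window_time_us: float = Field(0.5, gt=0)


class RestraintConfig(BaseModel):
    k_tw: float = Field(0.06, ge=0)


class SamplingConfig(BaseModel):
    n_frames: int = Field(20_000, ge=1)
    burn_in_fraction: float = Field(0.1, ge=0.0, lt=1.0)
    seed: int = 0
    keep_params: bool = False


class WhamConfig(BaseModel):
    bin_width: float = Field(0.25, gt=0)
    tol: float = Field(1e-7, gt=0)
    max_iter: int = Field(100_000, ge=1)


class FitConfig(BaseModel):
    half_range: float = Field(2.0, gt=0)


class DeformationConfig(BaseModel):
    enabled: bool = True
    offsets_per_bp: list[float] = [-4.5, -2.5, 0.0, 2.5, 4.5]
    n_frames: int = Field(5_000, ge=1)


class RunConfig(BaseModel):
    """Validated configuration of a full analysis run."""

    sequence: str = "GGCGAGTAGCACGTGCTACTCGC"
    restrained_fragment: str = "GTAGCACGTGCTAC"
    model: ModelConfig = ModelConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    restraint: RestraintConfig = RestraintConfig()
    sampling: SamplingConfig = SamplingConfig()
    wham: WhamConfig = WhamConfig()
    fit: FitConfig = FitConfig()
    deformation: DeformationConfig = DeformationConfig()
    output_dir: str = "dnatwist_run"

    @field_validator("sequence", "restrained_fragment")
    @classmethod
    def _acgt(cls, v: str) -> str:
        v = v.upper()
        if any(b not in "ACGT" for b in v):
            raise ValueError("sequence must be over ACGT")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw or {})


def build_model(cfg: RunConfig) -> SequenceModel:
    m = cfg.model
    if m.kind == "homogeneous":
        return homogeneous_model(
            len(cfg.sequence) - 1,
            twist_sd=m.twist_sd,
            twist_mean=m.twist_mean,
            temperature=m.temperature,
            sequence=cfg.sequence,
        )
    return default_model(
        cfg.sequence,
        twist_mean=m.twist_mean,
        twist_sd=m.twist_sd,
        bimodal_separation=m.bimodal_separation,
        coupling=m.coupling,
        temperature=m.temperature,
    )


# --------------------------------------------------------------------------
# twist partition (per-step absorption of the imposed torsional stress)
# --------------------------------------------------------------------------

@dataclass
class TwistPartition:
    """Window x step matrix of mean twist changes vs the relaxed window.

    Row sums approximate the imposed total twist change of each window up
    to the soft-restraint gap reported in ``realized_minus_requested``.
    """

    offsets_per_bp: np.ndarray        # requested offset per window, deg/bp
    steps: np.ndarray                 # 1-based step indices (full model)
    matrix: np.ndarray                # (n_windows, n_steps) delta mean twist
    requested_cv: np.ndarray
    realized_cv: np.ndarray

    @property
    def realized_minus_requested(self) -> np.ndarray:
        return self.realized_cv - self.requested_cv

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix,
            index=pd.Index(self.offsets_per_bp, name="offset_per_bp"),
            columns=[f"step_{int(s)}" for s in self.steps],
        )
        df["requested_cv"] = self.requested_cv
        df["realized_cv"] = self.realized_cv
        return df


def twist_partition(windows: list[UmbrellaWindow]) -> TwistPartition:
    """Per-window, per-step mean twist change relative to the relaxed window."""
    if not windows:
        raise ValueError("need at least one window")
    regions = {w.restraint.region for w in windows}
    if len(regions) != 1:
        raise ValueError("windows restrain different regions")
    n_region = windows[0].restraint.n_steps
    refs = np.array([w.restraint.twist_ref for w in windows])
    central = int(np.argmin(np.abs(refs - np.median(refs))))
    base = windows[central].step_twist_mean
    order = np.argsort(refs)
    matrix = np.stack([windows[i].step_twist_mean - base for i in order])
    return TwistPartition(
        offsets_per_bp=(refs[order] - refs[central]) / n_region,
        steps=np.arange(1, len(base) + 1),
        matrix=matrix,
        requested_cv=refs[order] - refs[central],
        realized_cv=np.array([windows[i].mean_cv for i in order])
        - windows[central].mean_cv,
    )


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _window_structural_readouts(windows, sequence, region):
    """Axis bending and groove geometry of each window's mean structure."""
    bend_rows, groove_rows = [], []
    refs = np.array([w.restraint.twist_ref for w in windows])
    central = refs[int(np.argmin(np.abs(refs - np.median(refs))))]
    n_region = windows[0].restraint.n_steps
    for w in windows:
        offset = (w.restraint.twist_ref - central) / n_region
        atoms = build_atom_dicts(sequence, w.ensemble.step_param_mean)
        frames, _ = frames_from_atom_dicts(sequence, atoms)
        bend = axis_bending(frames)
        for i, ang in enumerate(bend.angles, start=1):
            bend_rows.append({"offset_per_bp": offset, "step": i, "bend_deg": ang})
        p_w = np.array([aw["P"] for aw, _ in atoms])
        p_c = np.array([ac["P"] for _, ac in atoms])
        groove = groove_geometry(p_w, p_c, frames)
        for i in range(len(frames)):
            groove_rows.append(
                {
                    "offset_per_bp": offset,
                    "level": i + 1,
                    "minor_width": groove.minor_width[i],
                    "minor_depth": groove.minor_depth[i],
                    "major_width": groove.major_width[i],
                    "major_depth": groove.major_depth[i],
                    "defined": bool(groove.defined[i]),
                }
            )
    return pd.DataFrame(bend_rows), pd.DataFrame(groove_rows)


def run_all(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute every stage of the analysis and write the report bundle.

    Returns a summary dict (also written as ``summary.json``).  Stage
    failures raise; partial outputs written so far are retained.
    """
    t_start = time.time()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "version": __version__}
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))

    stage = "model"
    try:
        model = build_model(config)
        region = restrained_region(config.sequence, config.restrained_fragment)
        n_region = region[1] - region[0] + 1
        relaxed_ref = config.model.twist_mean * n_region
        log.info("model: %d steps, restrained region %s (%d steps)",
                 model.n_steps, region, n_region)

        stage = "umbrella"
        schedule = make_umbrella_schedule(
            relaxed_ref,
            increment=config.schedule.increment,
            max_offset=config.schedule.max_offset,
            n_region_steps=n_region,
            n_frames_per_window=config.sampling.n_frames,
            window_time_us=config.schedule.window_time_us,
        )
        t0 = time.time()
        windows = run_umbrella(
            model,
            schedule,
            k_tw=config.restraint.k_tw,
            region=region,
            seed=config.sampling.seed,
            burn_in_fraction=config.sampling.burn_in_fraction,
            keep_params=config.sampling.keep_params,
        )
        log.info("umbrella: %d windows in %.1f s", len(windows), time.time() - t0)
        save_windows(out / "windows.h5", windows, model_hash=model.content_hash())

        stage = "wham"
        pmf = wham(
            windows,
            bin_width=config.wham.bin_width,
            tol=config.wham.tol,
            max_iter=config.wham.max_iter,
            temperature=config.model.temperature,
        )
        write_pmf(pmf, out / "pmf.csv", out / "pmf.json")
        overlap = overlap_report(windows, bin_width=config.wham.bin_width)
        overlap.to_csv(out / "overlap.csv", index=False)

        stage = "fit"
        fit = fit_force_constant(pmf, half_range=config.fit.half_range)
        stage = "modulus"
        modulus = torsional_modulus(
            fit, n_region, temperature=config.model.temperature
        )
        fit_report = {**fit.to_dict(), **modulus.to_dict(), **provenance}
        (out / "elasticity.json").write_text(json.dumps(fit_report, indent=2))

        stage = "partition"
        partition = twist_partition(windows)
        partition.to_dataframe().to_csv(out / "twist_partition.csv")

        stage = "structural"
        bend_df, groove_df = _window_structural_readouts(
            windows, config.sequence, region
        )
        bend_df.to_csv(out / "bend.csv", index=False)
        groove_df.to_csv(out / "groove.csv", index=False)

        stage = "deformation"
        deform_summary = []
        if config.deformation.enabled:
            dmodel = deformation_model_from_sequence_model(model, region=region)
            streams = np.random.SeedSequence(
                config.sampling.seed + 7_654_321
            ).spawn(len(config.deformation.offsets_per_bp))
            for ss, off in zip(streams, config.deformation.offsets_per_bp):
                restr = TorsionalRestraint(
                    k_tw=config.restraint.k_tw,
                    twist_ref=relaxed_ref + off * n_region,
                    region=region,
                )
                win, _ = sample_biased(
                    model, restr, config.deformation.n_frames, seed=ss,
                    burn_in_fraction=config.sampling.burn_in_fraction,
                )
                res = window_deformation(
                    win.ensemble.params[:, region[0] - 1 : region[1], :], dmodel
                )
                deform_summary.append(
                    {"offset_per_bp": off, "mean": res.mean, "sd": res.sd}
                )
            pd.DataFrame(deform_summary).to_csv(out / "deformation.csv", index=False)

        stage = "report"
        sigma_max = supercoiling_density(
            config.schedule.max_offset, config.model.twist_mean
        )
        summary = {
            **provenance,
            "sequence": config.sequence,
            "region": list(region),
            "n_region_steps": n_region,
            "n_windows": schedule.n_windows,
            "window_shift_deg": schedule.window_shift_deg,
            "total_sampling_time_us": schedule.total_sampling_time_us,
            "sigma_at_max_offset": sigma_max,
            "K_kcal_mol_deg2": fit.K,
            "R2": fit.r_squared,
            "C_nm": modulus.C,
            "wham_iterations": pmf.iterations,
            "elapsed_s": round(time.time() - t_start, 2),
        }
        if model.coupling == 0.0:
            summary["ground_truth_C_nm"] = ground_truth_modulus(model, region=region)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        _write_report(out, config, summary, deform_summary)
        return summary
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, out)
        raise


def _write_report(out: Path, config: RunConfig, summary: dict, deform) -> None:
    lines = [
        "# dnatwist run report",
        "",
        f"- package version: {summary['version']}",
        f"- config hash: {summary['config_hash']}",
        f"- sequence: `{summary['sequence']}` "
        f"(restrained steps {summary['region'][0]}-{summary['region'][1]})",
        f"- umbrella windows: {summary['n_windows']} "
        f"(shift {summary['window_shift_deg']:.1f} deg/window, "
        f"bookkeeping {summary['total_sampling_time_us']:.1f} us)",
        f"- max supercoiling density: +/-{summary['sigma_at_max_offset']:.2f}",
        "",
        "## Torsional elasticity",
        "",
        f"- force constant K = {summary['K_kcal_mol_deg2']:.4f} kcal/mol/deg^2 "
        f"(R^2 = {summary['R2']:.4f})",
        f"- torsional modulus C = {summary['C_nm']:.1f} nm",
    ]
    if "ground_truth_C_nm" in summary:
        lines.append(
            f"- analytic ground truth C = {summary['ground_truth_C_nm']:.1f} nm"
        )
    if deform:
        lines += ["", "## Deformation energy vs imposed twist", ""]
        lines.append("| offset (deg/bp) | mean (kcal/mol) | SD |")
        lines.append("|---|---|---|")
        for row in deform:
            lines.append(
                f"| {row['offset_per_bp']:+.1f} | {row['mean']:.2f} | {row['sd']:.2f} |"
            )
    lines += [
        "",
        "Outputs: pmf.csv/json, elasticity.json, twist_partition.csv, "
        "bend.csv, groove.csv, overlap.csv, windows.h5"
        + (", deformation.csv" if deform else "")
        + ".",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
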