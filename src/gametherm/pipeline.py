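"""Pipeline orchestration: simulate → kinematics → TPC → kinetics → factorial.

A :class:`RunConfig` (round-trippable YAML) drives a deterministic run: every
random stage derives its generator from the single configured seed, outputs are
plain CSV/JSON with units in the column names, and a manifest records the
config hash, seed, package version and per-stage outputs so a run is fully
traceable.  Rerunning the same config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fertkin as fk
from . import io as gio
from . import synthetic, tpc
from .factorial import FactorialDataset, art_anova
from .kinematics import DEFAULT_MOTILITY_THRESHOLD, summarize_sample

__all__ = ["RunConfig", "run_pipeline", "load_config", "demo_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "kinematics", "fit_tpc", "fertkin", "art_anova")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  All randomness flows from ``seed``."""

    seed: int = 0
    output_dir: str = "gametherm_out"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulation design
    species: str = "sand_dollar"  # or "red_urchin"
    # TPC fitting
    tpc_models: tuple = ("quadratic", "gaussian", "modifiedgaussian")
    tpc_n_starts: int = 8
    tpc_n_boot: int = 200
    tpc_ci_level: float = 0.95
    breadth_threshold: float = 0.8
    # kinematics demo stage
    motility_threshold_um_s: float = DEFAULT_MOTILITY_THRESHOLD
    n_tracks: int = 20
    track_speed_um_s: float = 300.0
    track_radius_um: float = 50.0
    frame_rate_hz: float = 60.0
    track_duration_s: float = 10.0
    # fertilization kinetics
    egg_diameter_um: float = 130.0
    s0_per_ul: float = fk.sperm_dilution_concentration()
    e0_per_ul: float = 0.02
    exposure_time_s: float = 900.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
        self.stages = {s: bool(self.stages.get(s, False)) for s in STAGES}
        self.tpc_models = tuple(self.tpc_models)
        for name in self.tpc_models:
            tpc.get_model(name)
        if self.species not in ("sand_dollar", "red_urchin"):
            raise ValueError("species must be 'sand_dollar' or 'red_urchin'")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tpc_models"] = list(self.tpc_models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


def demo_config(seed: int = 0, output_dir: str = "gametherm_demo") -> RunConfig:
    """The packaged demo: full synthetic sand-dollar study, all stages on."""
    return RunConfig(seed=seed, output_dir=output_dir)


def _json_dump(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def _design_for(config: RunConfig) -> synthetic.DesignSpec:
    if config.species == "red_urchin":
        return synthetic.urchin_design(frame_rate=config.frame_rate_hz,
                                       track_duration=config.track_duration_s)
    return synthetic.sand_dollar_design(frame_rate=config.frame_rate_hz,
                                        track_duration=config.track_duration_s)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path) -> list[str]:
    truth = synthetic.default_truth(seed=config.seed)
    design = _design_for(config)
    records, samples = synthetic.generate_single_factor_assay(design, truth)
    f_truth = dataclasses.replace(truth, seed=config.seed + 1)
    f_design = synthetic.factorial_design(frame_rate=config.frame_rate_hz,
                                          track_duration=config.track_duration_s)
    f_records, f_samples = synthetic.generate_factorial_assay(f_design, f_truth)
    files = [
        gio.write_assay_csv(records, out / "assay_single_factor.csv"),
        gio.write_velocity_csv(samples, out / "velocity_single_factor.csv"),
        gio.write_assay_csv(f_records, out / "assay_factorial.csv"),
        gio.write_velocity_csv(f_samples, out / "velocity_factorial.csv"),
    ]
    return [f.name for f in files]


def _stage_kinematics(config: RunConfig, out: Path) -> list[str]:
    tracks = synthetic.generate_tracks(
        n_tracks=config.n_tracks, mean_speed=config.track_speed_um_s,
        radius=config.track_radius_um, frame_rate=config.frame_rate_hz,
        duration=config.track_duration_s, seed=config.seed + 2,
    )
    track_file = gio.write_track_csv(tracks, out / "tracks.csv")
    reread = gio.read_track_csv(track_file)
    sample = summarize_sample(reread, threshold=config.motility_threshold_um_s,
                              sample_id="demo_tracks")
    summary = {
        "n_tracks": len(reread),
        "requested_speed_um_s": config.track_speed_um_s,
        "mean_vcl_um_s": sample.mean_vcl,
        "motile_fraction": sample.motile_fraction,
        "motility_threshold_um_s": config.motility_threshold_um_s,
        "frame_rate_hz": config.frame_rate_hz,
        "track_duration_s": config.track_duration_s,
    }
    _json_dump(summary, out / "kinematics_summary.json")
    return [track_file.name, "kinematics_summary.json"]


def _trait_datasets(out: Path):
    records = gio.read_assay_csv(out / "assay_single_factor.csv")
    samples = gio.read_velocity_csv(out / "velocity_single_factor.csv")
    fert = gio.assay_tpc_dataset(records)
    vel, mot = gio.velocity_tpc_datasets(samples)
    return {"fertilization": fert, "velocity": vel, "motility": mot}


def _stage_fit_tpc(config: RunConfig, out: Path) -> list[str]:
    datasets = _trait_datasets(out)
    fit_rows, derived = [], {}
    for i, (trait, data) in enumerate(sorted(datasets.items())):
        ranked, excluded = tpc.rank_models(
            data, config.tpc_models, seed=config.seed + 10 + i,
            n_starts=config.tpc_n_starts, return_excluded=True)
        for rank, f in enumerate(ranked, start=1):
            fit_rows.append({
                "trait": trait, "rank": rank, "model": f.model.name,
                "n": f.n, "k": f.k, "rss": f.rss, "aicc": f.aicc, "bic": f.bic,
                "estimates": ";".join(f"{p}={v:.8g}" for p, v in
                                      zip(f.model.parameter_names, f.estimates)),
            })
        best = ranked[0]
        design = _design_for(config)
        # proportion traits get the binomial-scaled residual bootstrap
        # (see tpc.bootstrap_cis); counts behind each plotted proportion:
        # eggs per pair for fertilization, tracked sperm for motility
        counts = {"fertilization": design.eggs_per_rep * design.n_technical_reps,
                  "motility": design.n_sperm_per_sample}
        scale = (tpc.binomial_residual_scale(best, counts[trait])
                 if trait in counts else None)
        boot = tpc.bootstrap_cis(
            data, best, n_boot=config.tpc_n_boot, level=config.tpc_ci_level,
            seed=config.seed + 20 + i, threshold=config.breadth_threshold,
            residual_scale=scale)
        derived[trait] = {
            "best_model": best.model.name,
            "excluded": [list(e) for e in excluded],
            **boot.derived.as_dict(),
            "parameter_cis": {k: list(v) for k, v in boot.parameter_cis.items()},
            "bootstrap": {"n_boot": boot.n_boot, "n_failed": boot.n_failed,
                          "level": boot.level, "unreliable": boot.unreliable},
        }
    pd.DataFrame(fit_rows).to_csv(out / "tpc_fits.csv", index=False)
    _json_dump(derived, out / "tpc_derived.json")
    return ["tpc_fits.csv", "tpc_derived.json"]


def _factorial_tables(out: Path):
    records = gio.read_assay_csv(out / "assay_factorial.csv")
    samples = gio.read_velocity_csv(out / "velocity_factorial.csv")
    agg = gio.aggregate_assay(records)
    vel_rows = pd.DataFrame([{
        "temperature_c": s.temperature, "ph": s.ph, "mean_vcl_um_s": s.mean_vcl,
        "motile_fraction": s.motile_fraction,
    } for s in samples])
    return agg, vel_rows


def _stage_fertkin(config: RunConfig, out: Path) -> list[str]:
    agg, vel_rows = _factorial_tables(out)
    sigma0 = fk.egg_cross_section(config.egg_diameter_um)
    measured = (agg.groupby(["temperature_c", "ph"], sort=True)
                ["fertilization_proportion"].mean())
    vel = (vel_rows.groupby(["temperature_c", "ph"], sort=True)
           ["mean_vcl_um_s"].mean())
    obs = []
    for key, phi_obs in measured.items():
        if key in vel.index and 0.0 < phi_obs < 1.0:
            beta0 = fk.beta0_from_swimming(float(vel[key]), sigma0)
            obs.append((float(phi_obs), config.s0_per_ul, config.e0_per_ul,
                        config.exposure_time_s, beta0))
    ratio, se = fk.fit_beta_ratio(obs)
    records, rho, pval = fk.predict_vs_measured(
        assays=dict(measured.items()),
        velocities={k: float(v) for k, v in vel.items()},
        sigma0=sigma0, s0=config.s0_per_ul, e0=config.e0_per_ul,
        t=config.exposure_time_s, ratio=ratio,
    )
    rows = [{
        "temperature_c": r.temperature, "ph": r.ph,
        "measured_phi": r.measured_phi, "modelled_phi": r.modelled_phi,
        "discrepancy": r.discrepancy, "velocity_um_s": r.upsilon_used,
        "sigma0_um2": sigma0, "s0_per_ul": config.s0_per_ul,
        "e0_per_ul": config.e0_per_ul, "exposure_time_s": config.exposure_time_s,
        "beta_over_beta0": ratio,
    } for r in records]
    pd.DataFrame(rows).to_csv(out / "fertkin_predictions.csv", index=False)
    _json_dump({
        "beta_over_beta0": ratio, "beta_over_beta0_se": se,
        "spearman_rho_phi_vs_velocity": rho, "spearman_p": pval,
        "n_conditions": len(records),
    }, out / "fertkin_summary.json")
    return ["fertkin_predictions.csv", "fertkin_summary.json"]


def _stage_art_anova(config: RunConfig, out: Path) -> list[str]:
    agg, _ = _factorial_tables(out)
    data = FactorialDataset(
        response=agg["fertilization_proportion"].to_numpy(),
        a=agg["temperature_c"].to_numpy(), b=agg["ph"].to_numpy(),
        pair_id=agg["pair_id"].to_numpy(),
    )
    result = art_anova(data)
    result.to_frame().to_csv(out / "art_anova.csv", index=False)
    pd.DataFrame([{
        "factor": c.factor, "level_a": c.level_a, "level_b": c.level_b,
        "p_raw": c.p_raw, "p_bonferroni": c.p_adjusted,
        "cohens_d": c.cohens_d, "magnitude": c.magnitude,
    } for c in result.posthoc]).to_csv(out / "art_posthoc.csv", index=False)
    _json_dump({
        "aligned_sums": result.aligned_sums,
        "n": result.n,
        "effects": {k: {"F": e.f, "df": [e.df_num, e.df_den], "p": e.p,
                        "partial_eta_sq": e.partial_eta_squared,
                        "stripped_F": e.stripped_f}
                    for k, e in result.effects.items()},
    }, out / "art_summary.json")
    return ["art_anova.csv", "art_posthoc.csv", "art_summary.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "kinematics": _stage_kinematics,
    "fit_tpc": _stage_fit_tpc,
    "fertkin": _stage_fertkin,
    "art_anova": _stage_art_anova,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order and write a manifest.

    Returns the manifest dict (also written to ``manifest.json``): config
    hash, seed, stage statuses and output filenames.  Stage wall-times go to
    the log only, keeping outputs byte-stable across reruns.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    needs = {"fit_tpc": "simulate", "fertkin": "simulate", "art_anova": "simulate"}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        dep = needs.get(stage)
        if dep and not (config.stages.get(dep) or
                        (out / "assay_single_factor.csv").exists()):
            raise RuntimeError(f"stage {stage!r} needs outputs of {dep!r}")
        t0 = time.perf_counter()
        files = _STAGE_FNS[stage](config, out)
        logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
        manifest["stages"][stage] = {"status": "ok", "outputs": files}
    _json_dump(manifest, out / "manifest.json")
    return manifest
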