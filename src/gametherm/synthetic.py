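"""Seeded synthetic datasets with the structure of the two assay designs.

Two experiment layouts are emulated so that every downstream stage (kinematics,
TPC fitting, kinetics comparison, factorial statistics) can be exercised
without any external data:

* a **single-factor temperature experiment** — many temperature levels, three
  independent male–female pairs (biological replicates) per level, three
  technical replicates of ~50 scored eggs each, plus per-pair sperm velocity
  samples; and
* a **temperature × pH factorial** — three temperatures crossed with three pH
  levels, where each pair is tested under one temperature but across all pH
  levels, giving a balanced 3 × 3 table.

The generating truth is explicit: fertilization success follows a TPC-shaped
probability of temperature, perturbed on the logit scale by an additive pH
offset and by a normal pair-level random shift, and egg counts are binomial.
Sperm velocities are truncated-normal around a TPC-shaped mean with a stated
coefficient of variation, and per-sperm motility is Bernoulli with TPC-shaped
probability.  Circular sperm tracks are laid down at constant angular speed so
the chord-sum (curvilinear) velocity equals a requested speed exactly.

Default truth parameters are **synthetic illustrations**: they copy the
qualitative shape of published echinoderm thermal responses (unimodal with an
optimum near 14–18 °C) but are not fitted to any real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import DEFAULT_MOTILITY_THRESHOLD, SpermTrack
from .tpc import evaluate_model

__all__ = [
    "DesignSpec",
    "TruthSpec",
    "FertAssayRecord",
    "SAND_DOLLAR_TEMPERATURES",
    "URCHIN_TEMPERATURES",
    "FACTORIAL_TEMPERATURES",
    "FACTORIAL_PHS",
    "sand_dollar_design",
    "urchin_design",
    "factorial_design",
    "default_truth",
    "generate_single_factor_assay",
    "generate_factorial_assay",
    "generate_tracks",
]

# single-factor treatment temperatures (degC) for the two study species
SAND_DOLLAR_TEMPERATURES = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 34.0, 38.0)
URCHIN_TEMPERATURES = (8.0, 10.0, 12.0, 14.0, 16.0, 22.0, 28.0)
# factorial design: 3 temperatures x 3 pH (pH ~ 1825/700/425 uatm pCO2)
FACTORIAL_TEMPERATURES = (8.0, 16.0, 24.0)
FACTORIAL_PHS = (7.1, 7.5, 7.9)


@dataclass(frozen=True)
class DesignSpec:
    """Layout of an assay: treatment grid, replication, and track recording."""

    species_label: str
    temperatures: tuple[float, ...]
    phs: tuple[float, ...] = (7.8,)
    n_pairs_per_temperature: int = 3
    n_technical_reps: int = 3
    eggs_per_rep: int = 50
    frame_rate: float = 60.0
    track_duration: float = 10.0
    n_sperm_per_sample: int = 30

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "phs", tuple(float(p) for p in self.phs))
        if any(c < 1 for c in (self.n_pairs_per_temperature, self.n_technical_reps,
                               self.eggs_per_rep, self.n_sperm_per_sample)):
            raise ValueError("all counts must be >= 1")
        if self.frame_rate <= 0 or self.track_duration <= 0:
            raise ValueError("frame_rate and track_duration must be positive")
        if any(b <= a for a, b in zip(temps, temps[1:])) or len(temps) < 1:
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth: TPC shapes plus variance structure and seed.

    ``fert_tpc``/``velocity_tpc``/``motility_tpc`` are ``(model_name, params)``
    pairs evaluated through the TPC model registry; fertilization and motility
    values are clamped to [0, 1] and velocity means to >= 0.
    ``ph_effect_logit`` maps each pH level to an additive shift on the
    fertilization logit; ``pair_sd_logit`` is the SD of the normal pair-level
    shift; ``velocity_cv`` the coefficient of variation of individual sperm
    speeds.
    """

    fert_tpc: tuple[str, tuple[float, ...]]
    velocity_tpc: tuple[str, tuple[float, ...]]
    motility_tpc: tuple[str, tuple[float, ...]]
    ph_effect_logit: dict = field(default_factory=dict)
    pair_sd_logit: float = 0.3
    velocity_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_sd_logit < 0:
            raise ValueError("pair_sd_logit must be >= 0")
        if self.velocity_cv < 0:
            raise ValueError("velocity_cv must be >= 0")
        for label in ("fert_tpc", "velocity_tpc", "motility_tpc"):
            name, params = getattr(self, label)
            arr = np.asarray(params, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{label} parameters must be finite, got {params}")
            evaluate_model(name, arr, 15.0)  # validates name and arity

    def fert_probability(self, temperature) -> np.ndarray:
        name, params = self.fert_tpc
        return np.clip(evaluate_model(name, params, temperature), 0.0, 1.0)

    def velocity_mean(self, temperature) -> np.ndarray:
        name, params = self.velocity_tpc
        return np.maximum(evaluate_model(name, params, temperature), 0.0)

    def motile_probability(self, temperature) -> np.ndarray:
        name, params = self.motility_tpc
        return np.clip(evaluate_model(name, params, temperature), 0.0, 1.0)


@dataclass
class FertAssayRecord:
    """One technical replicate of a fertilization assay."""

    species: str
    temperature: float
    ph: float
    pair_id: str
    tech_rep: int
    n_scored: int
    n_fertilized: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_fertilized <= self.n_scored:
            raise ValueError("need 0 <= n_fertilized <= n_scored")

    @property
    def proportion(self) -> float:
        return self.n_fertilized / self.n_scored


def sand_dollar_design(**overrides) -> DesignSpec:
    """12-temperature single-factor sand dollar design (3 pairs × 3 × 50 eggs)."""
    base = DesignSpec(species_label="sand_dollar", temperatures=SAND_DOLLAR_TEMPERATURES)
    return replace(base, **overrides) if overrides else base


def urchin_design(**overrides) -> DesignSpec:
    """7-temperature single-factor red urchin design."""
    base = DesignSpec(species_label="red_urchin", temperatures=URCHIN_TEMPERATURES)
    return replace(base, **overrides) if overrides else base


def factorial_design(**overrides) -> DesignSpec:
    """3 temperatures × 3 pH factorial design for sand dollars."""
    base = DesignSpec(species_label="sand_dollar",
                      temperatures=FACTORIAL_TEMPERATURES, phs=FACTORIAL_PHS)
    return replace(base, **overrides) if overrides else base


def default_truth(seed: int = 0) -> TruthSpec:
    """Synthetic illustration truth (not fitted to any empirical dataset).

    Fertilization: flat-topped modified gaussian, optimum 17.6 °C, plateau
    0.95, breadth ≈ 18 °C, so the cold tail sits near 0.7 at 8 °C and the hot
    tail collapses by 38 °C.  Velocity: gaussian, optimum 13.9 °C, peak
    350 μm s⁻¹.  Motility: gaussian, optimum 14 °C, peak 0.80.  pH lowers the
    fertilization logit monotonically with acidification.
    """
    return TruthSpec(
        fert_tpc=("modifiedgaussian", (0.95, 17.6, 11.0, 4.0)),
        velocity_tpc=("gaussian", (350.0, 13.9, 10.6)),
        motility_tpc=("gaussian", (0.80, 14.0, 12.0)),
        ph_effect_logit={7.1: -1.5, 7.5: -0.6, 7.9: 0.0},
        pair_sd_logit=0.3,
        velocity_cv=0.2,
        seed=seed,
    )


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _truncated_normal(rng, mean, sd, size):
    """Normal draws truncated at zero by resampling (mean >= 0, moderate CV)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, 0.0)


def _velocity_sample(rng, design: DesignSpec, truth: TruthSpec, temperature: float,
                     ph: float, pair: str):
    """One pair's velocity sample at one condition (deferred import avoids cycle)."""
    from .kinematics import VelocitySample

    mean_v = float(truth.velocity_mean(temperature))
    p_mot = float(truth.motile_probability(temperature))
    n = design.n_sperm_per_sample
    motile = rng.random(n) < p_mot
    speeds = np.zeros(n)
    if mean_v > 0 and motile.any():
        speeds[motile] = _truncated_normal(
            rng, mean_v, truth.velocity_cv * mean_v, int(motile.sum()))
    frac = float(np.mean(speeds > DEFAULT_MOTILITY_THRESHOLD))
    swimming = speeds[speeds > DEFAULT_MOTILITY_THRESHOLD]
    return VelocitySample(
        sample_id=f"{pair}_T{temperature:g}_pH{ph:g}",
        temperature=temperature, ph=ph, velocities=speeds,
        motile_fraction=frac,
        mean_vcl=float(swimming.mean()) if swimming.size else 0.0,
        all_immotile=swimming.size == 0,
    )


def generate_single_factor_assay(design: DesignSpec, truth: TruthSpec):
    """Simulate the single-factor temperature experiment.

    Returns ``(records, samples)``: one :class:`FertAssayRecord` per
    temperature × pair × technical replicate (fertilized counts binomial with
    success probability ``expit(logit(fert_tpc(T)) + pair shift)``), and one
    velocity sample per temperature × pair.  Pair ids are unique across
    temperatures (independent pairs per treatment).  The same truth seed
    reproduces the dataset exactly.
    """
    if len(design.phs) != 1:
        raise ValueError("single-factor design must have exactly one pH level")
    rng = np.random.default_rng(truth.seed)
    ph = design.phs[0]
    ph_shift = float(truth.ph_effect_logit.get(ph, 0.0))
    records: list[FertAssayRecord] = []
    samples = []
    pair_counter = 0
    for temp in design.temperatures:
        base_logit = float(_logit(truth.fert_probability(temp))) + ph_shift
        for _ in range(design.n_pairs_per_temperature):
            pair_counter += 1
            pair = f"{design.species_label}_pair{pair_counter:03d}"
            shift = rng.normal(0.0, truth.pair_sd_logit) if truth.pair_sd_logit > 0 else 0.0
            p = float(_expit(np.asarray(base_logit + shift)))
            for rep in range(1, design.n_technical_reps + 1):
                k = int(rng.binomial(design.eggs_per_rep, p))
                records.append(FertAssayRecord(
                    species=design.species_label, temperature=temp, ph=ph,
                    pair_id=pair, tech_rep=rep,
                    n_scored=design.eggs_per_rep, n_fertilized=k,
                ))
            samples.append(_velocity_sample(rng, design, truth, temp, ph, pair))
    return records, samples


def generate_factorial_assay(design: DesignSpec, truth: TruthSpec):
    """Simulate the temperature × pH factorial.

    Each pair id appears under exactly one temperature but under every pH
    level (the pair-level logit shift is shared across that pair's pH cells),
    producing a balanced table.  Returns ``(records, samples)`` like
    :func:`generate_single_factor_assay`.
    """
    if len(design.temperatures) < 2 or len(design.phs) < 2:
        raise ValueError("factorial design needs >= 2 levels of both factors")
    rng = np.random.default_rng(truth.seed)
    records: list[FertAssayRecord] = []
    samples = []
    pair_counter = 0
    for temp in design.temperatures:
        for _ in range(design.n_pairs_per_temperature):
            pair_counter += 1
            pair = f"{design.species_label}_pair{pair_counter:03d}"
            shift = rng.normal(0.0, truth.pair_sd_logit) if truth.pair_sd_logit > 0 else 0.0
            for ph in design.phs:
                base_logit = float(_logit(truth.fert_probability(temp)))
                base_logit += float(truth.ph_effect_logit.get(ph, 0.0))
                p = float(_expit(np.asarray(base_logit + shift)))
                for rep in range(1, design.n_technical_reps + 1):
                    k = int(rng.binomial(design.eggs_per_rep, p))
                    records.append(FertAssayRecord(
                        species=design.species_label, temperature=temp, ph=ph,
                        pair_id=pair, tech_rep=rep,
                        n_scored=design.eggs_per_rep, n_fertilized=k,
                    ))
                samples.append(_velocity_sample(rng, design, truth, temp, ph, pair))
    return records, samples


def generate_tracks(
    n_tracks: int,
    mean_speed: float,
    radius: float,
    frame_rate: float = 60.0,
    duration: float = 10.0,
    seed: int = 0,
) -> list[SpermTrack]:
    """Synthetic circular sperm tracks traversed at constant angular speed.

    Echinoderm sperm swim in near-circular paths; each track is a circle of
    the given ``radius`` (μm) sampled at ``frame_rate`` Hz for ``duration`` s.
    The per-frame turn angle θ = 2·asin(v/(2·r·f)) makes the chord length per
    frame exactly ``mean_speed / frame_rate``, so the realized chord-sum
    (curvilinear) velocity equals the request to machine precision.  Requests
    implying θ ≥ π per frame (an undersampled circle) are rejected.  Track
    centers, phases and turning directions are randomized from ``seed``.
    """
    if radius <= 0 or frame_rate <= 0 or duration <= 0:
        raise ValueError("radius, frame_rate and duration must be positive")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if mean_speed < 0:
        raise ValueError("mean_speed must be non-negative")
    x = mean_speed / (2.0 * radius * frame_rate)
    if x >= 1.0:
        raise ValueError(
            f"speed {mean_speed} μm/s implies a turn of >= π per frame on a "
            f"{radius} μm circle at {frame_rate} Hz (undersampled); "
            "increase radius or frame rate"
        )
    theta = 2.0 * math.asin(x)
    n_points = round(frame_rate * duration)
    rng = np.random.default_rng(seed)
    tracks = []
    idx = np.arange(n_points)
    for i in range(n_tracks):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        cx, cy = rng.uniform(-500.0, 500.0, size=2)
        ang = phase + direction * theta * idx
        pts = np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
        tracks.append(SpermTrack(track_id=f"track{i:04d}", frame_rate=frame_rate, points=pts))
    return tracks
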