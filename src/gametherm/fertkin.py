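"""Fertilization kinetics: the Vogel collision model linking sperm swimming to
fertilization.

The model treats fertilization of broadcast-spawned eggs as a collision
process.  With sperm concentration S₀ (μl⁻¹), egg concentration E₀ (μl⁻¹),
exposure time t (s), egg–sperm contact rate constant β₀ (mm³ s⁻¹) and
fertilization rate constant β (mm³ s⁻¹), the expected fertilized proportion is

    φ = 1 − exp( −(β·S₀ / (β₀·E₀)) · (1 − e^(−β₀·E₀·t)) )

and the contact rate constant follows from sperm swimming,

    β₀ = υ · σ₀

with υ the sperm curvilinear velocity (μm s⁻¹) and σ₀ the egg cross-sectional
area (μm²).  Units are normalized internally to mm³ and seconds; since
1 μl = 1 mm³, concentrations per μl are numerically per mm³, and the υ·σ₀
product (μm³ s⁻¹) converts to mm³ s⁻¹ by the exact factor 10⁻⁹.

Only the ratio β/β₀ is identifiable from fertilization data alone; it is
estimated by one-dimensional nonlinear least squares, and model predictions
parameterized with measured swimming velocities can then be compared with
measured fertilization condition by condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "UM3_PER_MM3",
    "KineticsParams",
    "PredictionRecord",
    "phi",
    "beta0_from_swimming",
    "egg_cross_section",
    "sperm_dilution_concentration",
    "fit_beta_ratio",
    "predict_vs_measured",
]

#: exact μm³ → mm³ conversion
UM3_PER_MM3 = 1e9


@dataclass
class KineticsParams:
    """All symbols of the kinetics model with units.

    s0, e0: sperm and egg concentrations (count μl⁻¹); t: exposure time (s);
    beta, beta0: fertilization and contact rate constants (mm³ s⁻¹);
    upsilon: sperm velocity (μm s⁻¹); sigma0: egg cross-sectional area (μm²).
    beta may exceed beta0 numerically but a ratio > 1 is physically suspect
    (more fertilizations than contacts) and is flagged.
    """

    s0: float
    e0: float
    t: float
    beta: float
    beta0: float
    upsilon: float = float("nan")
    sigma0: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("s0", "e0", "t", "beta", "beta0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def ratio(self) -> float:
        """β/β₀, the fertilization efficiency per contact."""
        return self.beta / self.beta0 if self.beta0 > 0 else math.nan

    @property
    def ratio_suspect(self) -> bool:
        return self.beta > self.beta0


@dataclass
class PredictionRecord:
    """Paired modelled vs measured fertilization under one condition."""

    temperature: float
    ph: float | None
    measured_phi: float
    modelled_phi: float
    upsilon_used: float

    @property
    def discrepancy(self) -> float:
        """Modelled minus measured proportion; positive = model overestimates."""
        return self.modelled_phi - self.measured_phi


def _phi_core(s0, e0, t, beta, beta0):
    """Vectorized φ with the β₀E₀ → 0 limit handled by series continuation."""
    s0 = np.asarray(s0, dtype=float)
    x = np.asarray(beta0, dtype=float) * np.asarray(e0, dtype=float)
    t = np.asarray(t, dtype=float)
    beta = np.asarray(beta, dtype=float)
    # (1 - exp(-x t)) / x -> t as x -> 0
    with np.errstate(divide="ignore", invalid="ignore"):
        contact = np.where(x * t > 1e-12, -np.expm1(-x * t) / np.where(x > 0, x, 1.0), t)
    return -np.expm1(-beta * s0 * contact)


def phi(params: KineticsParams):
    """Expected fertilized proportion φ ∈ [0, 1] under the kinetics model.

    Limits are exact: t = 0 or S₀ = 0 give 0; as t → ∞,
    φ → 1 − exp(−βS₀/(β₀E₀)); as β₀E₀ → 0, φ → 1 − exp(−βS₀t).
    """
    return float(_phi_core(params.s0, params.e0, params.t, params.beta, params.beta0))


def beta0_from_swimming(upsilon: float, sigma0: float) -> float:
    """Contact rate constant β₀ = υ·σ₀ in mm³ s⁻¹ from velocity (μm s⁻¹) and
    egg cross-sectional area (μm²)."""
    if upsilon < 0 or sigma0 < 0:
        raise ValueError("velocity and cross-section must be non-negative")
    return upsilon * sigma0 / UM3_PER_MM3


def egg_cross_section(diameter: float) -> float:
    """Cross-sectional area (μm²) of a spherical egg of the given diameter (μm)."""
    if diameter <= 0:
        raise ValueError("egg diameter must be positive")
    return math.pi * diameter * diameter / 4.0


def sperm_dilution_concentration(
    stock_per_ml: float = 1e5,
    aliquot_ul: float = 50.0,
    dish_volume_ml: float = 11.0,
) -> float:
    """Final sperm concentration (count μl⁻¹) after diluting an aliquot of
    stock into an assay dish.

    Defaults mirror a typical echinoderm assay protocol: 50 μl of a
    10⁵ sperm ml⁻¹ stock into an 11 ml dish ≈ 0.455 sperm μl⁻¹ (illustrative,
    not an authoritative empirical value).
    """
    if stock_per_ml < 0 or aliquot_ul < 0 or dish_volume_ml <= 0:
        raise ValueError("invalid dilution inputs")
    total_sperm = stock_per_ml * aliquot_ul / 1000.0
    return total_sperm / (dish_volume_ml * 1000.0)


def invert_ratio(measured_phi: float, s0: float, e0: float, t: float, beta0: float) -> float:
    """Closed-form β/β₀ from a single observation:
    ratio = −ln(1−φ)·E₀ / (S₀·(1 − e^(−β₀E₀t)))."""
    if not 0.0 < measured_phi < 1.0:
        raise ValueError("closed-form inversion needs 0 < φ < 1")
    denom = s0 * -math.expm1(-beta0 * e0 * t)
    if denom <= 0:
        raise ValueError("non-identifiable: S₀·(1 − e^(−β₀E₀t)) must be positive")
    return -math.log1p(-measured_phi) * e0 / denom


def fit_beta_ratio(observations) -> tuple[float, float]:
    """Least-squares estimate of the β/β₀ ratio with a standard error.

    ``observations`` is an iterable of ``(measured_phi, s0, e0, t, beta0)``
    rows.  The ratio r minimizes Σ(φ_model(r) − φ_obs)²; since φ is strictly
    increasing in r the objective is well behaved and bounded scalar
    minimization on (0, upper] suffices.  The standard error comes from the
    Gauss–Newton curvature at the optimum.  Rows with φ_obs identically 0 or 1
    carry no information about r alone; if *all* rows are degenerate the ratio
    is non-identifiable and fitting is rejected.
    """
    obs = [tuple(map(float, row)) for row in observations]
    if not obs:
        raise ValueError("need at least one observation")
    informative = [o for o in obs if 0.0 < o[0] < 1.0]
    if not informative:
        raise ValueError(
            "β/β₀ non-identifiable: every observed φ is exactly 0 or 1 "
            "(the model can approach but never attain these at finite ratio)"
        )
    phis = np.array([o[0] for o in obs])
    s0 = np.array([o[1] for o in obs])
    e0 = np.array([o[2] for o in obs])
    t = np.array([o[3] for o in obs])
    beta0 = np.array([o[4] for o in obs])

    def predict(r):
        return _phi_core(s0, e0, t, r * beta0, beta0)

    def sse(r):
        return float(np.sum((predict(r) - phis) ** 2))

    # bracket the optimum: closed-form inversion of each informative row
    inv = [invert_ratio(*o) for o in informative]
    upper = max(10.0, 10.0 * max(inv))
    res = optimize.minimize_scalar(sse, bounds=(1e-12, upper), method="bounded",
                                   options={"xatol": 1e-12})
    r_hat = float(res.x)

    # Gauss-Newton SE: s^2 / sum of squared gradient of φ wrt ratio
    h = max(1e-8, 1e-6 * r_hat)
    grad = (predict(r_hat + h) - predict(max(r_hat - h, 0.0))) / (h + min(h, r_hat))
    g2 = float(np.sum(grad**2))
    n = len(obs)
    dof = max(n - 1, 1)
    s2 = sse(r_hat) / dof
    se = math.sqrt(s2 / g2) if g2 > 0 else math.inf
    return r_hat, se


def predict_vs_measured(
    assays,
    velocities,
    sigma0: float,
    s0: float,
    e0: float,
    t: float,
    ratio: float,
) -> tuple[list[PredictionRecord], float, float]:
    """Model-predicted vs measured fertilization across matched conditions.

    ``assays`` maps condition ``(temperature, ph)`` → measured mean φ;
    ``velocities`` maps the same keys → measured mean sperm velocity
    (μm s⁻¹).  For each condition β₀ is computed from that condition's
    velocity and φ is predicted with the supplied β/β₀ ratio.  A condition
    present in one table but not the other yields a record with a NaN on the
    missing side — an explicit gap, never a silent drop.

    Returns the paired records plus Spearman's ρ and its p-value between
    measured φ and velocity over fully matched conditions.
    """
    from .factorial import spearman_rho

    keys = sorted(set(assays) | set(velocities), key=lambda k: tuple(
        (float("-inf") if v is None else float(v)) for v in k))
    records = []
    for key in keys:
        temp, ph = key
        measured = float(assays.get(key, math.nan))
        ups = float(velocities.get(key, math.nan))
        if math.isnan(ups):
            modelled = math.nan
        else:
            beta0 = beta0_from_swimming(ups, sigma0)
            modelled = float(_phi_core(s0, e0, t, ratio * beta0, beta0))
        records.append(PredictionRecord(
            temperature=temp, ph=ph, measured_phi=measured,
            modelled_phi=modelled, upsilon_used=ups,
        ))
    paired = [(r.measured_phi, r.upsilon_used) for r in records
              if not (math.isnan(r.measured_phi) or math.isnan(r.upsilon_used))]
    if len(paired) >= 3 and len({p[0] for p in paired}) > 1 and len({p[1] for p in paired}) > 1:
        rho, pval = spearman_rho([p[0] for p in paired], [p[1] for p in paired])
    else:
        rho, pval = math.nan, math.nan
    return records, rho, pval
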