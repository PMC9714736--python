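"""Thermal performance curve (TPC) fitting, model selection and derived parameters.

A thermal performance curve describes how a biological rate (here: fertilization
success, sperm curvilinear velocity, or the motile fraction of sperm) varies with
temperature.  Candidate nonlinear models are fitted by bounded multistart least
squares, ranked by small-sample corrected AIC (AICc), and the winning curve is
summarized by three derived parameters:

``r_max``
    the maximum rate over the temperature grid,
``t_opt``
    the temperature at which ``r_max`` occurs,
``t_br``
    the thermal breadth — the total width of the temperature region where the
    rate is at least ``threshold`` (default 80%) of ``r_max``.

Uncertainty in the derived parameters is quantified by a residual bootstrap:
centered residuals are resampled, added back to the fitted values, the model is
refitted, and percentile intervals are taken over the bootstrap replicates.

Information-criterion convention: the parameter count ``k`` used for AICc/BIC is
the number of curve parameters **plus one** for the Gaussian residual variance.
Published AICc values differ between software by exactly this convention, so it
is stated here once and used everywhere.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TPCDataset",
    "TPCModelSpec",
    "TPCFitResult",
    "DerivedTPCParams",
    "BootstrapResult",
    "MODEL_REGISTRY",
    "get_model",
    "evaluate_model",
    "fit_model",
    "aicc",
    "bic",
    "rank_models",
    "derive_params",
    "bootstrap_cis",
]

logger = logging.getLogger(__name__)

BOLTZMANN_EV = 8.617333262e-5  # eV K^-1, for Sharpe-Schoolfield
_SSH_TREF_C = 15.0  # fixed reference temperature (degC) for Sharpe-Schoolfield


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class TPCDataset:
    """(temperature, rate) observations for one trait.

    Parameters
    ----------
    trait_name:
        Label of the measured trait (e.g. ``"fertilization"``).
    temperature:
        Temperatures in degC, one per observation.
    rate:
        Trait values, same length as ``temperature``.
    replicate_id:
        Optional biological-replicate labels, same length.
    """

    trait_name: str
    temperature: np.ndarray
    rate: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.temperature.shape != self.rate.shape:
            raise ValueError("temperature and rate must have equal length")
        if self.temperature.size < 5:
            raise ValueError("a TPC dataset needs at least 5 points")
        if not (np.all(np.isfinite(self.temperature)) and np.all(np.isfinite(self.rate))):
            raise ValueError("temperatures and rates must be finite")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape[0] != self.temperature.shape[0]:
                raise ValueError("replicate_id length mismatch")

    @property
    def n(self) -> int:
        return int(self.temperature.size)


@dataclass(frozen=True)
class TPCModelSpec:
    """A candidate TPC model: formula, parameters, bounds and start heuristics."""

    name: str
    parameter_names: tuple[str, ...]
    formula: Callable[..., np.ndarray]
    bounds_fn: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    guess_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def __call__(self, temperature, params):
        return evaluate_model(self, params, temperature)


@dataclass
class TPCFitResult:
    """Outcome of fitting one candidate model to one dataset."""

    model: TPCModelSpec
    estimates: np.ndarray
    rss: float
    n: int
    k: int  # parameters counted for information criteria (curve params + 1)
    aicc: float
    bic: float
    converged: bool
    message: str = ""
    data: TPCDataset | None = field(default=None, repr=False)

    def predict(self, temperature) -> np.ndarray:
        return evaluate_model(self.model, self.estimates, temperature)


@dataclass
class DerivedTPCParams:
    """Derived summary of a fitted TPC: r_max, T_opt, and thermal breadth."""

    r_max: float
    t_opt: float
    t_br: float
    breadth_threshold: float
    contiguous: bool
    boundary_censored: bool
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "r_max": self.r_max,
            "t_opt": self.t_opt,
            "t_br": self.t_br,
            "breadth_threshold": self.breadth_threshold,
            "contiguous": self.contiguous,
            "boundary_censored": self.boundary_censored,
        }
        for key, (lo, hi) in self.ci.items():
            out[f"{key}_ci_low"] = lo
            out[f"{key}_ci_high"] = hi
        return out


@dataclass
class BootstrapResult:
    """Residual-bootstrap uncertainty for derived and raw parameters."""

    derived: DerivedTPCParams
    parameter_cis: dict[str, tuple[float, float]]
    n_boot: int
    n_failed: int
    level: float
    unreliable: bool
    samples: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.n_boot if self.n_boot else 0.0


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------


def _span(t: np.ndarray) -> float:
    return float(max(t.max() - t.min(), 1.0))


def _guess_peak(t: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """(t_opt, r_max) start values: argmax of rates after light smoothing."""
    order = np.argsort(t)
    ts, rs = t[order], r[order]
    if rs.size >= 5:
        kernel = np.array([0.25, 0.5, 0.25])
        rs = np.convolve(np.pad(rs, 1, mode="edge"), kernel, mode="valid")
    i = int(np.argmax(rs))
    return float(ts[i]), float(r.max())


def _quadratic(t, a, b, c):
    return a + b * t + c * t * t


def _gaussian(t, rmax, topt, a):
    z = (t - topt) / a
    return rmax * np.exp(-0.5 * z * z)


def _modified_gaussian(t, rmax, topt, a, b):
    z = np.abs(t - topt) / a
    return rmax * np.exp(-0.5 * np.power(z, b))


def _briere2(t, a, tmin, tmax, b):
    t = np.asarray(t, dtype=float)
    inside = (t > tmin) & (t < tmax)
    out = np.zeros_like(t)
    tt = t[inside]
    out[inside] = a * tt * (tt - tmin) * np.power(np.maximum(tmax - tt, 0.0), 1.0 / b)
    return out


def _sharpeschoolhigh(t, r_tref, e, eh, th):
    tk = np.asarray(t, dtype=float) + 273.15
    tref = _SSH_TREF_C + 273.15
    thk = th + 273.15
    boltz = r_tref * np.exp(e / BOLTZMANN_EV * (1.0 / tref - 1.0 / tk))
    inact = 1.0 + np.exp(eh / BOLTZMANN_EV * (1.0 / thk - 1.0 / tk))
    return boltz / inact


def _ratkowsky(t, a, b, tmin, tmax):
    t = np.asarray(t, dtype=float)
    core = a * (t - tmin) * (1.0 - np.exp(b * (t - tmax)))
    core = np.where((t > tmin) & (t < tmax), core, 0.0)
    return core * core


def _weibull(t, rmax, topt, b, d):
    # Weibull-shaped TPC; peaks exactly at (topt, rmax) for d > 1.
    c = ((d - 1.0) / d) ** (1.0 / d)
    z = (np.asarray(t, dtype=float) - topt) / b + c
    z = np.maximum(z, 0.0)
    return (
        rmax
        * ((d - 1.0) / d) ** ((1.0 - d) / d)
        * np.power(z, d - 1.0)
        * np.exp(-np.power(z, d) + (d - 1.0) / d)
    )


def _lactin2(t, a, tmax, delta_t, b):
    t = np.asarray(t, dtype=float)
    return np.exp(a * t) - np.exp(a * tmax - (tmax - t) / delta_t) + b


def _rezende(t, a, q10, tth, c):
    # exponential (Q10) rise below the threshold temperature tth,
    # quadratic decline above it
    t = np.asarray(t, dtype=float)
    rise = a * np.power(10.0, np.log10(q10) / 10.0 * t)
    fall = np.where(t > tth, 1.0 - c * (t - tth) ** 2, 1.0)
    return rise * np.maximum(fall, 0.0)


def _flinn(t, a, b, c):
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp(a + b * t + c * t * t))


def _make_registry() -> dict[str, TPCModelSpec]:
    reg: dict[str, TPCModelSpec] = {}

    def add(name, pnames, formula, bounds_fn, guess_fn):
        reg[name] = TPCModelSpec(name, tuple(pnames), formula, bounds_fn, guess_fn)

    add(
        "quadratic",
        ("a", "b", "c"),
        _quadratic,
        lambda t, r: (
            np.array([-1e4, -1e3, -1e3]),
            np.array([1e4, 1e3, 1e3]),
        ),
        lambda t, r: np.polyfit(t, r, 2)[::-1],
    )
    add(
        "gaussian",
        ("rmax", "topt", "a"),
        _gaussian,
        lambda t, r: (
            np.array([1e-8, t.min() - _span(t), 0.1]),
            np.array([max(10 * abs(r).max(), 1.0), t.max() + _span(t), 10 * _span(t)]),
        ),
        lambda t, r: np.array([*reversed(_guess_peak(t, r)), _span(t) / 4.0]),
    )
    add(
        "modifiedgaussian",
        ("rmax", "topt", "a", "b"),
        _modified_gaussian,
        lambda t, r: (
            np.array([1e-8, t.min() - _span(t), 0.1, 0.5]),
            np.array([max(10 * abs(r).max(), 1.0), t.max() + _span(t), 10 * _span(t), 8.0]),
        ),
        lambda t, r: np.array([*reversed(_guess_peak(t, r)), _span(t) / 4.0, 2.0]),
    )
    add(
        "briere2",
        ("a", "tmin", "tmax", "b"),
        _briere2,
        lambda t, r: (
            np.array([1e-10, t.min() - 3 * _span(t), t.max() - 0.5, 0.2]),
            np.array([10.0, t.min() + 0.5, t.max() + 3 * _span(t), 20.0]),
        ),
        lambda t, r: np.array(
            [2e-4 * max(abs(r).max(), 1e-6), t.min() - 2.0, t.max() + 2.0, 3.0]
        ),
    )
    add(
        "sharpeschoolhigh",
        ("r_tref", "e", "eh", "th"),
        _sharpeschoolhigh,
        lambda t, r: (
            np.array([1e-8, 0.01, 0.02, t.min() - _span(t)]),
            np.array([max(10 * abs(r).max(), 1.0), 4.0, 15.0, t.max() + _span(t)]),
        ),
        lambda t, r: np.array([max(np.median(r), 1e-3), 0.6, 3.0, _guess_peak(t, r)[0] + 2.0]),
    )
    add(
        "ratkowsky",
        ("a", "b", "tmin", "tmax"),
        _ratkowsky,
        lambda t, r: (
            np.array([1e-8, 1e-3, t.min() - 5 * _span(t), t.max() - 0.5]),
            np.array([10 * max(abs(r).max(), 1.0), 2.0, t.min() + 0.5, t.max() + 3 * _span(t)]),
        ),
        lambda t, r: np.array(
            [math.sqrt(max(abs(r).max(), 1e-6)) / _span(t), 0.15, t.min() - 5.0, t.max() + 2.0]
        ),
    )
    add(
        "weibull",
        ("rmax", "topt", "b", "d"),
        _weibull,
        lambda t, r: (
            np.array([1e-8, t.min() - _span(t), 0.5, 1.1]),
            np.array([max(10 * abs(r).max(), 1.0), t.max() + _span(t), 20 * _span(t), 30.0]),
        ),
        lambda t, r: np.array([*reversed(_guess_peak(t, r)), _span(t), 3.0]),
    )
    add(
        "lactin2",
        ("a", "tmax", "delta_t", "b"),
        _lactin2,
        lambda t, r: (
            np.array([1e-4, t.max() - 0.5, 0.1, -5.0 * max(abs(r).max(), 1.0)]),
            np.array([0.5, t.max() + 3 * _span(t), 20.0, 5.0 * max(abs(r).max(), 1.0)]),
        ),
        lambda t, r: np.array([0.02, t.max() + 2.0, 4.0, -1.0]),
    )
    add(
        "rezende",
        ("a", "q10", "tth", "c"),
        _rezende,
        lambda t, r: (
            np.array([1e-10, 1.01, t.min(), 1e-6]),
            np.array([10 * max(abs(r).max(), 1.0), 8.0, t.max() + _span(t), 1.0]),
        ),
        lambda t, r: np.array(
            [max(abs(r).max(), 1e-6) / 4.0, 2.0, _guess_peak(t, r)[0], 0.005]
        ),
    )
    add(
        "flinn",
        ("a", "b", "c"),
        _flinn,
        lambda t, r: (np.array([-50.0, -10.0, -1.0]), np.array([50.0, 10.0, 1.0])),
        lambda t, r: np.array([2.0, -0.3, 0.01]),
    )
    return reg


MODEL_REGISTRY: dict[str, TPCModelSpec] = _make_registry()

#: the models named in the empirical figure captions; always part of a default run
CORE_MODELS = ("quadratic", "gaussian", "modifiedgaussian")


def get_model(name: str) -> TPCModelSpec:
    """Look up a model spec by registry name."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(MODEL_REGISTRY))
        raise KeyError(f"unknown TPC model {name!r}; registered models: {known}") from None


def evaluate_model(spec: TPCModelSpec | str, params: Sequence[float], temperature) -> np.ndarray:
    """Evaluate a TPC model at one or many temperatures.

    ``spec`` may be a :class:`TPCModelSpec` or a registry name.  The return
    value broadcasts with ``temperature``.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(f"model {spec.name!r} expects {spec.n_params} parameters, got {params.size}")
    scalar = np.isscalar(temperature) or np.ndim(temperature) == 0
    t = np.atleast_1d(np.asarray(temperature, dtype=float))
    out = np.asarray(spec.formula(t, *params), dtype=float)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC from a Gaussian least-squares fit.

    ``k`` counts every estimated parameter including the residual variance.
    Requires ``n - k - 1 > 0``; at or below that boundary the criterion is
    undefined and the model must be excluded from ranking.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n - k - 1 > 0)")
    if rss <= 0:
        raise ValueError("AICc requires rss > 0 (perfect fits have no defined likelihood scale)")
    aic = -2.0 * _gaussian_loglik(rss, n) + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion under the same Gaussian convention."""
    if rss <= 0 or n <= 0:
        raise ValueError("BIC requires rss > 0 and n > 0")
    return -2.0 * _gaussian_loglik(rss, n) + k * math.log(n)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _clip_to_bounds(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    eps = 1e-10 * (hi - lo)
    return np.clip(x, lo + eps, hi - eps)


def fit_model(
    data: TPCDataset,
    spec: TPCModelSpec | str,
    n_starts: int = 10,
    seed: int | None = None,
    x0: np.ndarray | None = None,
) -> TPCFitResult:
    """Fit one candidate model by bounded multistart nonlinear least squares.

    The first start is a data-driven heuristic (peak location/height); the
    remaining ``n_starts - 1`` are uniform draws within the parameter bounds,
    seeded for reproducibility.  The best (lowest-RSS) converged start wins.
    ``x0`` overrides the start strategy with a single start (used by the
    bootstrap, which restarts refits from the original estimates).
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    t, y = data.temperature, data.rate
    n, kp = data.n, spec.n_params
    if n < kp + 2:
        raise ValueError(f"model {spec.name!r} needs at least {kp + 2} points, got {n}")

    lo, hi = spec.bounds_fn(t, y)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)

    def residuals(p):
        r = spec.formula(t, *p) - y
        return np.where(np.isfinite(r), r, 1e6)

    if x0 is not None:
        starts = [_clip_to_bounds(np.asarray(x0, dtype=float), lo, hi)]
    else:
        rng = np.random.default_rng(seed)
        starts = [_clip_to_bounds(np.asarray(spec.guess_fn(t, y), dtype=float), lo, hi)]
        for _ in range(max(n_starts - 1, 0)):
            starts.append(rng.uniform(lo, hi))

    best = None
    messages = []
    for start in starts:
        try:
            sol = optimize.least_squares(residuals, start, bounds=(lo, hi), method="trf")
        except Exception as exc:  # pragma: no cover - defensive
            messages.append(str(exc))
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            messages.append(sol.message)
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)

    k = kp + 1  # + residual variance, see module docstring
    if best is None:
        return TPCFitResult(
            model=spec, estimates=np.full(kp, np.nan), rss=math.inf, n=n, k=k,
            aicc=math.inf, bic=math.inf, converged=False,
            message="; ".join(messages) or "no start converged", data=data,
        )

    rss, est = best
    if n - k - 1 > 0 and rss > 0:
        a, b = aicc(rss, n, k), bic(rss, n, k)
    else:
        a = b = math.nan
    return TPCFitResult(
        model=spec, estimates=est, rss=rss, n=n, k=k, aicc=a, bic=b,
        converged=True, data=data,
    )


def rank_models(
    data: TPCDataset,
    specs: Sequence[TPCModelSpec | str],
    seed: int = 0,
    n_starts: int = 10,
    return_excluded: bool = False,
):
    """Fit every candidate and rank converged fits by ascending AICc.

    Ties are broken by fewer parameters, then by model name, so the ranking is
    invariant to the order in which candidates are supplied.  Models whose AICc
    is undefined (``n - k - 1 <= 0``, or rss == 0) and models that never
    converge are excluded; with ``return_excluded=True`` the exclusion log
    ``[(model_name, reason), ...]`` is returned alongside the ranking.
    """
    if len(specs) < 1:
        raise ValueError("need at least one candidate model")
    ranked: list[TPCFitResult] = []
    excluded: list[tuple[str, str]] = []
    for i, s in enumerate(specs):
        spec = get_model(s) if isinstance(s, str) else s
        # decouple per-model RNG streams from candidate order (stable hash:
        # built-in str hash is salted per process and would break determinism)
        name_tag = zlib.crc32(spec.name.encode()) % 100003
        fit = fit_model(data, spec, n_starts=n_starts,
                        seed=None if seed is None else seed + name_tag)
        if not fit.converged:
            excluded.append((spec.name, f"no convergence: {fit.message}"))
            logger.warning("TPC model %s excluded: %s", spec.name, fit.message)
        elif not math.isfinite(fit.aicc):
            excluded.append((spec.name, f"AICc undefined (n={fit.n}, k={fit.k}, rss={fit.rss:g})"))
            logger.warning("TPC model %s excluded: AICc undefined", spec.name)
        else:
            ranked.append(fit)
    if not ranked:
        raise RuntimeError("no candidate TPC model converged with a defined AICc")
    ranked.sort(key=lambda f: (f.aicc, f.model.n_params, f.model.name))
    if return_excluded:
        return ranked, excluded
    return ranked


# ---------------------------------------------------------------------------
# derived parameters
# ---------------------------------------------------------------------------


def _clamped_eval(fit: TPCFitResult, t) -> np.ndarray:
    """Model evaluation with negative rates clamped to 0 (derived params only)."""
    return np.maximum(fit.predict(t), 0.0)


def derive_params(
    fit: TPCFitResult,
    grid_low: float,
    grid_high: float,
    grid_step: float = 0.01,
    threshold: float = 0.8,
) -> DerivedTPCParams:
    """Derive r_max, T_opt and thermal breadth from a converged fit.

    The curve is scanned on a dense grid over ``[grid_low, grid_high]``; the
    optimum is refined by bounded scalar maximization around the grid argmax,
    and breadth edges are refined by root bracketing so that T_br is accurate
    well below ``grid_step``.  Negative model values (e.g. quadratic tails)
    are clamped to zero here, never during fitting.  Breadth over several
    disjoint super-threshold regions is reported as their total width, with
    ``contiguous=False``.
    """
    if not fit.converged:
        raise ValueError("derive_params requires a converged fit")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if grid_high <= grid_low or grid_step <= 0:
        raise ValueError("invalid grid")
    grid = np.arange(grid_low, grid_high + grid_step / 2, grid_step)
    vals = _clamped_eval(fit, grid)
    if not np.all(np.isfinite(vals)):
        raise ValueError("model evaluates non-finite on the grid")

    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    boundary = i == 0 or i == grid.size - 1
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x: -float(_clamped_eval(fit, np.array([x]))[0]),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        t_opt, r_max = float(res.x), float(-res.fun)
        grid_best = float(vals[i])
        if grid_best > r_max:
            t_opt, r_max = float(grid[i]), grid_best
    else:  # pragma: no cover - degenerate single-point grid
        t_opt, r_max = float(grid[i]), float(vals[i])

    level = threshold * r_max
    above = vals >= level
    t_br = 0.0
    runs = 0
    if r_max > 0 and above.any():
        f = lambda x: float(_clamped_eval(fit, np.array([x]))[0]) - level
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = [grid_low] if above[0] else []
        ends: list[float] = []
        for j in edges:
            a, b = grid[j], grid[j + 1]
            try:
                x = optimize.brentq(f, a, b, xtol=1e-10)
            except ValueError:
                x = 0.5 * (a + b)
            if above[j + 1] and not above[j]:
                starts.append(x)
            else:
                ends.append(x)
        if above[-1]:
            ends.append(float(grid[-1]))
            boundary = True
        if above[0]:
            boundary = True
        runs = len(starts)
        t_br = float(sum(e - s for s, e in zip(starts, ends)))

    return DerivedTPCParams(
        r_max=r_max, t_opt=t_opt, t_br=t_br, breadth_threshold=threshold,
        contiguous=runs <= 1, boundary_censored=boundary,
    )


# ---------------------------------------------------------------------------
# residual bootstrap
# ---------------------------------------------------------------------------


def binomial_residual_scale(fit: TPCFitResult, n_eggs: int,
                            floor: float = 0.02) -> np.ndarray:
    """Per-point binomial standard errors sqrt(p̂(1−p̂)/n) for proportion traits.

    ``n_eggs`` is the number of eggs behind each plotted proportion (e.g. 150
    for three 50-egg technical replicates averaged into one biological
    replicate).  Fitted proportions are clipped into (0, 1) and the scale is
    floored at ``floor`` times the largest scale so tail points with p̂ ≈ 0
    or 1 do not blow up the standardized residuals.
    """
    if fit.data is None:
        raise ValueError("fit carries no data reference")
    p = np.clip(fit.predict(fit.data.temperature), 1e-6, 1 - 1e-6)
    s = np.sqrt(p * (1 - p) / n_eggs)
    return np.maximum(s, floor * s.max())


def bootstrap_cis(
    data: TPCDataset,
    fit: TPCFitResult,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    grid_low: float | None = None,
    grid_high: float | None = None,
    grid_step: float = 0.05,
    threshold: float = 0.8,
    residual_scale: np.ndarray | None = None,
) -> BootstrapResult:
    """Residual-bootstrap percentile confidence intervals.

    Centered residuals are resampled with replacement, added to the fitted
    values, and the model is refitted starting from the original estimates.
    Percentile intervals at ``level`` are reported for each raw parameter and
    for the derived (r_max, T_opt, T_br).  Refit failures are skipped and
    counted; a failure rate above 50% marks the intervals unreliable.

    ``residual_scale`` makes the resampling heteroscedasticity-consistent:
    residuals are divided by their per-point scale before resampling and
    multiplied by the destination point's scale afterwards.  The plain
    exchangeable scheme (``None``) assumes i.i.d. errors; for binomial
    proportion traits pass :func:`binomial_residual_scale`, since counts near
    0 or 1 have far smaller sampling variance than counts on the curve's
    slopes and exchangeable resampling would misstate the uncertainty there.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    t, y = data.temperature, data.rate
    yhat = fit.predict(t)
    resid = y - yhat
    if residual_scale is not None:
        scale = np.asarray(residual_scale, dtype=float)
        if scale.shape != y.shape or np.any(scale <= 0):
            raise ValueError("residual_scale must be positive, one per point")
        resid = resid / scale
    else:
        scale = None
    # standard df inflation: raw residuals understate the error scale by
    # sqrt((n - k)/n) because k curve parameters were fitted
    resid = resid * math.sqrt(resid.size / max(resid.size - fit.model.n_params, 1))
    resid = resid - resid.mean()

    if grid_low is None:
        grid_low = float(t.min())
    if grid_high is None:
        grid_high = float(t.max())
    point = derive_params(fit, grid_low, grid_high, grid_step, threshold)

    pnames = list(fit.model.parameter_names)
    draws: dict[str, list[float]] = {k: [] for k in [*pnames, "r_max", "t_opt", "t_br"]}
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.choice(resid, size=resid.size, replace=True)
        yb = yhat + (draw if scale is None else draw * scale)
        bdata = TPCDataset(data.trait_name, t, yb)
        bfit = fit_model(bdata, fit.model, x0=fit.estimates)
        if not bfit.converged:
            n_failed += 1
            continue
        try:
            bder = derive_params(bfit, grid_low, grid_high, grid_step, threshold)
        except ValueError:
            n_failed += 1
            continue
        for name, val in zip(pnames, bfit.estimates):
            draws[name].append(float(val))
        draws["r_max"].append(bder.r_max)
        draws["t_opt"].append(bder.t_opt)
        draws["t_br"].append(bder.t_br)

    alpha = 1.0 - level
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    cis: dict[str, tuple[float, float]] = {}
    samples: dict[str, np.ndarray] = {}
    for name, vals in draws.items():
        arr = np.asarray(vals, dtype=float)
        samples[name] = arr
        if arr.size:
            lo_q, hi_q = np.percentile(arr, qs)
            cis[name] = (float(lo_q), float(hi_q))
        else:
            cis[name] = (math.nan, math.nan)

    point.ci = {k: cis[k] for k in ("r_max", "t_opt", "t_br")}
    param_cis = {k: cis[k] for k in pnames}
    unreliable = n_failed > 0.5 * n_boot
    if unreliable:
        logger.warning("bootstrap: %d/%d refits failed; intervals unreliable", n_failed, n_boot)
    return BootstrapResult(
        derived=point, parameter_cis=param_cis, n_boot=n_boot, n_failed=n_failed,
        level=level, unreliable=unreliable, samples=samples,
    )
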