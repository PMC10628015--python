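"""Forward models mapping (power, velocity) to ablation width.

Two models are exposed:

- a physical reference model ``width = (1/sqrt(beta_device*beta_tissue)) *
  sqrt(P/v)`` whose coefficients encode device efficiency and how much
  ablation width the tissue produces per unit energy; and
- the calibrated log-linear model used for planning,
  ``mu = alpha + beta_power*ln(P) + beta_velocity*ln(v)`` with
  heteroscedastic observation noise ``sigma = eps + eps_power*P +
  eps_velocity*v``.

Widths are full transverse diameters of the coagulated zone in mm
(radius = width/2 when rasterizing).  Logarithms are natural throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PhysicalCoefficients",
    "CalibrationCoefficients",
    "PosteriorCoefficients",
    "DEFAULT_COEFFS",
    "width_eq1",
    "width_mean",
    "width_sd",
    "predictive_interval",
    "save_coefficients",
    "load_coefficients",
]

_COEF_NAMES = ("alpha", "beta_power", "beta_velocity", "eps", "eps_power", "eps_velocity")
_FILE_VERSION = "1"


@dataclass(frozen=True)
class PhysicalCoefficients:
    """Coefficients of the physical square-root width model."""

    beta_device: float
    beta_tissue: float

    def __post_init__(self) -> None:
        if self.beta_device <= 0 or self.beta_tissue <= 0:
            raise ValueError("physical coefficients must be strictly positive")


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Point coefficients of the calibrated log-linear width model.

    ``alpha`` [mm], ``beta_power`` [mm per ln W], ``beta_velocity``
    [mm per ln(mm/s)] parameterize the mean; ``eps`` [mm],
    ``eps_power`` [mm/W], ``eps_velocity`` [mm/(mm/s)] the noise sd.
    """

    alpha: float
    beta_power: float
    beta_velocity: float
    eps: float = 0.0
    eps_power: float = 0.0
    eps_velocity: float = 0.0

    def __post_init__(self) -> None:
        if self.eps < 0 or self.eps_power < 0 or self.eps_velocity < 0:
            raise ValueError("noise coefficients eps* must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _COEF_NAMES])


#: Default planning coefficients for a 60-140 W water-cooled microwave probe
#: in a tissue-mimicking phantom: 20 mm width at 100 W / 0.1 mm/s, widths of
#: roughly 8-26 mm across the calibration design, with noise slopes of
#: 0.03 mm per watt and 0.85 mm per mm/s.
DEFAULT_COEFFS = CalibrationCoefficients(
    alpha=-30.657,
    beta_power=9.0,
    beta_velocity=-4.0,
    eps=0.5,
    eps_power=0.03,
    eps_velocity=0.85,
)


class PosteriorCoefficients:
    """Posterior draws of :class:`CalibrationCoefficients` from MCMC.

    Stores one row per retained draw, with chain/draw indices, in the
    column order ``(alpha, beta_power, beta_velocity, eps, eps_power,
    eps_velocity)``.
    """

    coef_names = _COEF_NAMES

    def __init__(self, draws: np.ndarray, chain: np.ndarray | None = None,
                 draw: np.ndarray | None = None):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim != 2 or draws.shape[1] != 6:
            raise ValueError("draws must be an (n, 6) array")
        if draws.shape[0] < 1:
            raise ValueError("posterior needs at least one draw")
        if np.any(draws[:, 3:] < 0):
            raise ValueError("noise-coefficient draws must be non-negative")
        self.draws = draws
        n = draws.shape[0]
        self.chain = np.zeros(n, dtype=int) if chain is None else np.asarray(chain, dtype=int)
        self.draw = np.arange(n) if draw is None else np.asarray(draw, dtype=int)

    def __len__(self) -> int:
        return self.draws.shape[0]

    def __iter__(self) -> Iterator[CalibrationCoefficients]:
        for row in self.draws:
            yield CalibrationCoefficients(*row)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, _COEF_NAMES.index(name)]

    def mean_coefficients(self) -> CalibrationCoefficients:
        return CalibrationCoefficients(*self.draws.mean(axis=0))

    @classmethod
    def from_point(cls, coeffs: CalibrationCoefficients) -> "PosteriorCoefficients":
        return cls(coeffs.as_array()[None, :])


def width_eq1(power, velocity, phys: PhysicalCoefficients):
    """Physical width model: ``(1/sqrt(beta_device*beta_tissue))*sqrt(P/v)``.

    Undefined for a stationary probe (``velocity == 0``); dwells are
    handled by the planner's equivalent-velocity model instead.
    """
    power = np.asarray(power, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if np.any(velocity == 0):
        raise ZeroDivisionError("width_eq1 is singular at velocity = 0")
    if np.any(power <= 0) or np.any(velocity < 0):
        raise ValueError("power must be > 0 and velocity > 0")
    out = np.sqrt(power / velocity) / math.sqrt(phys.beta_device * phys.beta_tissue)
    return float(out) if out.ndim == 0 else out


def width_mean(coeffs: CalibrationCoefficients, power, velocity):
    """Mean ablation width [mm]: ``alpha + b_P*ln(P) + b_v*ln(v)``."""
    power = np.asarray(power, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if np.any(power <= 0) or np.any(velocity <= 0):
        raise ValueError("power and velocity must be strictly positive")
    out = coeffs.alpha + coeffs.beta_power * np.log(power) + coeffs.beta_velocity * np.log(velocity)
    return float(out) if out.ndim == 0 else out


def width_sd(coeffs: CalibrationCoefficients, power, velocity):
    """Width observation sd [mm]: ``eps + eps_P*P + eps_v*v`` (heteroscedastic)."""
    power = np.asarray(power, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if np.any(power < 0) or np.any(velocity < 0):
        raise ValueError("power and velocity must be non-negative")
    out = coeffs.eps + coeffs.eps_power * power + coeffs.eps_velocity * velocity
    return float(out) if out.ndim == 0 else out


def predictive_interval(
    post: PosteriorCoefficients,
    power: float,
    velocity: float,
    level: float = 0.95,
    method: str = "mixture",
    n_grid: int = 4097,
    seed: int | None = None,
    n_samples: int = 20000,
) -> tuple[float, float]:
    """Central posterior-predictive interval for the width at (P, v).

    The predictive distribution is the equal-weight Gaussian mixture
    ``Normal(width_mean(d), width_sd(d))`` over posterior draws ``d``.
    ``method='mixture'`` inverts the mixture CDF on an ``n_grid``-point
    grid; ``method='mc'`` draws Monte-Carlo samples (seeded).
    """
    if len(post) == 0:
        raise ValueError("empty posterior")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    mus = np.array([width_mean(c, power, velocity) for c in post])
    sds = np.array([width_sd(c, power, velocity) for c in post])
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    if np.max(sds) < 1e-12:
        # degenerate predictive: point masses at the per-draw means
        return float(np.quantile(mus, lo_q)), float(np.quantile(mus, hi_q))
    if method == "mc":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(mus), size=n_samples)
        samples = rng.normal(mus[idx], sds[idx])
        return float(np.quantile(samples, lo_q)), float(np.quantile(samples, hi_q))
    if method != "mixture":
        raise ValueError(f"unknown method {method!r}")
    sds_f = np.maximum(sds, 1e-9)
    lo_grid = np.min(mus - 8.5 * sds_f)
    hi_grid = np.max(mus + 8.5 * sds_f)
    grid = np.linspace(lo_grid, hi_grid, n_grid)
    cdf = stats.norm.cdf((grid[:, None] - mus[None, :]) / sds_f[None, :]).mean(axis=1)

    def mix_cdf(w):
        return stats.norm.cdf((w - mus) / sds_f).mean()

    def quantile(q):
        # grid bracket, then root-polish the mixture CDF
        w0 = float(np.interp(q, cdf, grid))
        a, b = w0 - (grid[1] - grid[0]), w0 + (grid[1] - grid[0])
        fa, fb = mix_cdf(a) - q, mix_cdf(b) - q
        if fa * fb > 0:
            return w0
        return float(optimize.brentq(lambda w: mix_cdf(w) - q, a, b, xtol=1e-12))

    return quantile(lo_q), quantile(hi_q)


def save_coefficients(
    coeffs: CalibrationCoefficients | PosteriorCoefficients, path: str | Path
) -> None:
    """Write coefficients to the versioned JSON interchange format.

    Point coefficients are stored as scalars; posteriors additionally carry
    an array of draws (and their point summary, the posterior mean).
    """
    if isinstance(coeffs, PosteriorCoefficients):
        point = coeffs.mean_coefficients()
        payload = {n: getattr(point, n) for n in _COEF_NAMES}
        payload["draws"] = coeffs.draws.tolist()
        payload["chain"] = coeffs.chain.tolist()
        payload["draw"] = coeffs.draw.tolist()
    else:
        payload = {n: getattr(coeffs, n) for n in _COEF_NAMES}
    payload["version"] = _FILE_VERSION
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_coefficients(path: str | Path) -> CalibrationCoefficients | PosteriorCoefficients:
    d = json.loads(Path(path).read_text())
    if "version" not in d:
        raise ValueError("coefficients file is missing the mandatory version field")
    if "draws" in d:
        return PosteriorCoefficients(
            np.asarray(d["draws"]),
            chain=np.asarray(d["chain"]) if "chain" in d else None,
            draw=np.asarray(d["draw"]) if "draw" in d else None,
        )
    return CalibrationCoefficients(**{n: d[n] for n in _COEF_NAMES})
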