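"""Piecewise-linear calibration of hysteretic thin-film pressure sensors.

A force-sensitive resistor read through a Wheatstone bridge and a
microcontroller ADC yields a dimensionless AD count whose relation to the
applied force (in gram-force, gf) is nonlinear and path dependent: the
loading sweep and the unloading sweep trace different curves.  The model
here fits each sweep with a continuous piecewise-linear function of the AD
count (breakpoint positions chosen by numerical optimization of the
residual sum of squares) and predicts force as the arithmetic mean of the
loading and unloading fits, which splits the hysteresis band.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .errors import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

LOADING = "loading"
UNLOADING = "unloading"


@dataclass
class CalibrationSweep:
    """One monotone-trend calibration sweep: paired (AD count, force gf) samples."""

    ad: np.ndarray
    force: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        self.ad = np.asarray(self.ad, dtype=float).ravel()
        self.force = np.asarray(self.force, dtype=float).ravel()
        if self.direction not in (LOADING, UNLOADING):
            raise InputError(f"direction must be {LOADING!r} or {UNLOADING!r}, got {self.direction!r}")
        if self.ad.size != self.force.size:
            raise InputError("ad and force must have equal length")
        if self.ad.size < 2:
            raise InputError("sweep needs at least 2 points")
        if np.any(self.force < 0):
            raise InputError("forces must be non-negative")
        if not (np.all(np.isfinite(self.ad)) and np.all(np.isfinite(self.force))):
            raise InputError("sweep contains non-finite values")

    def __len__(self) -> int:
        return int(self.ad.size)


@dataclass
class PiecewiseCurve:
    """Continuous piecewise-linear force(AD) fit.

    Stored as knot positions (the ``n_segments + 1`` breakpoints, outer ones
    at the data extremes) and the fitted force at each knot; slopes and
    intercepts per segment follow from those.  Evaluation outside the fitted
    AD range extrapolates the terminal segments linearly.
    """

    breakpoints: np.ndarray
    knot_values: np.ndarray
    ssr: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.knot_values = np.asarray(self.knot_values, dtype=float)
        if self.breakpoints.size != self.knot_values.size:
            raise InputError("breakpoints and knot_values must have equal length")
        if self.breakpoints.size < 2 or np.any(np.diff(self.breakpoints) <= 0):
            raise InputError("breakpoints must be strictly increasing with >= 2 entries")

    @property
    def n_segments(self) -> int:
        return self.breakpoints.size - 1

    @property
    def slopes(self) -> np.ndarray:
        """Per-segment slope in gf per AD count."""
        return np.diff(self.knot_values) / np.diff(self.breakpoints)

    @property
    def intercepts(self) -> np.ndarray:
        """Per-segment intercept in gf (force at AD = 0 on the segment's line)."""
        return self.knot_values[:-1] - self.slopes * self.breakpoints[:-1]

    def predict(self, ad) -> np.ndarray | float:
        ad_arr = np.asarray(ad, dtype=float)
        scalar = ad_arr.ndim == 0
        ad_arr = np.atleast_1d(ad_arr)
        out = np.interp(ad_arr, self.breakpoints, self.knot_values)
        slopes = self.slopes
        lo, hi = self.breakpoints[0], self.breakpoints[-1]
        below = ad_arr < lo
        above = ad_arr > hi
        if np.any(below) or np.any(above):
            logger.warning("predicting outside the calibrated AD range; extrapolating terminal segments")
        out[below] = self.knot_values[0] + slopes[0] * (ad_arr[below] - lo)
        out[above] = self.knot_values[-1] + slopes[-1] * (ad_arr[above] - hi)
        return float(out[0]) if scalar else out

    def to_dict(self) -> dict:
        return {
            "breakpoints": self.breakpoints.tolist(),
            "knot_values": self.knot_values.tolist(),
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
            "n_segments": self.n_segments,
            "ssr": self.ssr,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseCurve":
        return cls(
            breakpoints=np.asarray(d["breakpoints"], dtype=float),
            knot_values=np.asarray(d["knot_values"], dtype=float),
            ssr=float(d["ssr"]),
            seed=d.get("seed"),
        )


@dataclass
class CalibrationCurve:
    """Hysteresis-aware AD -> force map: loading and unloading fits kept separately."""

    up: PiecewiseCurve
    down: PiecewiseCurve

    def predict(self, ad):
        return predict_pressure(self, ad)

    def to_dict(self) -> dict:
        return {"up": self.up.to_dict(), "down": self.down.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(up=PiecewiseCurve.from_dict(d["up"]), down=PiecewiseCurve.from_dict(d["down"]))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationCurve":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CalibrationReport:
    """Signed prediction error for one (predicted, true) force pair, in gf."""

    f_predict: float
    f_true: float
    f_error: float = field(init=False)
    percent_error: float = field(init=False)
    percent_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.f_true < 0:
            raise InputError("true force must be non-negative")
        self.f_error = self.f_predict - self.f_true
        if self.f_true > 0:
            self.percent_error = self.f_error / self.f_true
            self.percent_defined = True
        else:
            self.percent_error = float("nan")
            self.percent_defined = False


def _hinge_design(x: np.ndarray, interior: np.ndarray) -> np.ndarray:
    # force = b0 + b1*x + sum_m c_m * max(0, x - t_m): continuous by construction
    cols = [np.ones_like(x), x]
    for t in interior:
        cols.append(np.maximum(0.0, x - t))
    return np.column_stack(cols)


def _solve_given_breaks(x: np.ndarray, y: np.ndarray, interior: np.ndarray):
    A = _hinge_design(x, np.sort(interior))
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ beta - y
    return float(resid @ resid), beta


def fit_piecewise(sweep: CalibrationSweep, n_segments: int = 9, seed: int = 0) -> PiecewiseCurve:
    """Fit a continuous piecewise-linear force(AD) curve with ``n_segments`` segments.

    Given interior breakpoints the fit is an ordinary least-squares problem in
    a hinge basis; the breakpoints themselves are chosen by minimizing the
    residual sum of squares, starting from data quantiles and refined by a
    seeded stochastic global search plus a local polish.  A candidate set of
    breakpoints only replaces the incumbent when it strictly lowers the RSS,
    so exactly representable data keeps the deterministic quantile solution.
    """
    if n_segments < 1:
        raise InputError("n_segments must be positive")
    x, y = sweep.ad, sweep.force
    n = x.size
    if n < 2 * (n_segments + 1):
        raise InputError(f"need at least {2 * (n_segments + 1)} points for {n_segments} segments, got {n}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise DegenerateInputError("AD values span a zero range")

    if n_segments == 1:
        ssr, _ = _solve_given_breaks(x, y, np.empty(0))
        return _build_curve(x, y, np.empty(0), lo, hi, ssr, seed)

    # deterministic start: interior breakpoints at data quantiles
    qs = np.quantile(x, np.linspace(0, 1, n_segments + 1)[1:-1])
    best_interior = np.sort(qs)
    best_ssr, _ = _solve_given_breaks(x, y, best_interior)

    def objective(theta):
        ssr, _ = _solve_given_breaks(x, y, theta)
        return ssr

    if best_ssr > 1e-12:
        bounds = [(lo, hi)] * (n_segments - 1)
        de = differential_evolution(
            objective, bounds, seed=seed, maxiter=250, popsize=20, tol=1e-12,
            init="sobol", polish=True,
        )
        if de.fun < best_ssr * (1 - 1e-12):
            best_interior = np.sort(np.asarray(de.x))
            best_ssr = float(de.fun)
        nm = minimize(
            objective, best_interior, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-18, "maxiter": 4000},
        )
        if nm.fun < best_ssr:
            best_interior = np.sort(np.asarray(nm.x))
            best_ssr = float(nm.fun)

    return _build_curve(x, y, best_interior, lo, hi, best_ssr, seed)


def _build_curve(x, y, interior, lo, hi, ssr, seed) -> PiecewiseCurve:
    interior = np.sort(np.clip(np.asarray(interior, dtype=float), lo, hi))
    # guard against collapsed segments from the optimizer
    eps = max((hi - lo) * 1e-9, 1e-12)
    for i in range(interior.size):
        floor = lo + eps * (i + 1) if i == 0 else interior[i - 1] + eps
        interior[i] = max(interior[i], floor)
    interior = interior[(interior > lo) & (interior < hi)]
    ssr, beta = _solve_given_breaks(x, y, interior)
    breaks = np.concatenate(([lo], interior, [hi]))
    A = _hinge_design(breaks, interior)
    knots = A @ beta
    return PiecewiseCurve(breakpoints=breaks, knot_values=knots, ssr=ssr, seed=seed)


def fit_hysteresis_pair(
    up: CalibrationSweep, down: CalibrationSweep, n_segments: int = 9, seed: int = 0
) -> CalibrationCurve:
    """Fit the loading and unloading sweeps independently and pair the curves."""
    if up.direction != LOADING:
        raise InputError(f"'up' sweep must have direction {LOADING!r}, got {up.direction!r}")
    if down.direction != UNLOADING:
        raise InputError(f"'down' sweep must have direction {UNLOADING!r}, got {down.direction!r}")
    return CalibrationCurve(
        up=fit_piecewise(up, n_segments=n_segments, seed=seed),
        down=fit_piecewise(down, n_segments=n_segments, seed=seed),
    )


def predict_pressure(curve: CalibrationCurve, ad):
    """Predict force (gf) as the mean of the loading and unloading fits."""
    up = curve.up.predict(ad)
    down = curve.down.predict(ad)
    return (up + down) / 2.0


def calibration_error(pred: float, true: float) -> CalibrationReport:
    """Signed error report ``f_error = f_predict - f_true`` (percent flagged undefined at 0 gf)."""
    return CalibrationReport(f_predict=float(pred), f_true=float(true))


def read_sweeps_csv(path) -> dict[str, CalibrationSweep]:
    """Read calibration sweeps from a CSV with header ``ad,force_gf,direction``."""
    df = pd.read_csv(path)
    required = {"ad", "force_gf", "direction"}
    if not required.issubset(df.columns):
        raise InputError(f"calibration CSV needs columns {sorted(required)}")
    out = {}
    for direction, grp in df.groupby("direction"):
        out[str(direction)] = CalibrationSweep(
            ad=grp["ad"].to_numpy(), force=grp["force_gf"].to_numpy(), direction=str(direction)
        )
    return out


def write_sweeps_csv(path, sweeps: list[CalibrationSweep]) -> None:
    frames = [
        pd.DataFrame({"ad": s.ad, "force_gf": s.force, "direction": s.direction}) for s in sweeps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
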