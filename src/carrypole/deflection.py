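"""Static stiffness from load-deflection testing.

Each pole end is a cantilever fixed at the functional centre.  Under a tip
load of mass ``m`` at lever arm ``x_L``, classical beam theory gives the
deflection at distance ``x`` from the fixed centre as

    delta = a * (3 m g x_L x**2 - m g x**3),      a = 1 / (6 E I),

linear in load and cubic in position.  Fitting the measured deflection
surface over (load, position) yields the coefficient ``a``, hence the
flexural rigidity ``E I`` and, given the section's second moment ``I``, the
Young's modulus ``E`` of the bamboo.

Loading/unloading loops at the attachment point quantify hysteresis: the
fraction of strain energy lost over a full cycle,

    hys = (int F+ ddelta - int F- ddelta) / int F+ ddelta,

with resilience ``res = 1 - hys``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .config import GRAVITY

__all__ = [
    "DeflectionRecord",
    "DeflectionFit",
    "HysteresisResult",
    "DeflectionSurfaceRegressor",
    "records_to_frame",
    "fit_deflection_surface",
    "young_modulus",
    "hysteresis",
    "build_loop_curves",
]


@dataclass(frozen=True)
class DeflectionRecord:
    """One marker observation: load, position along the pole, deflection.

    ``load_mass`` is the per-end applied mass in kg (basket included),
    ``marker_distance`` the distance x from the fixed functional centre in m,
    ``deflection`` the downward deflection in m, ``phase`` either
    ``"loading"`` or ``"unloading"``.
    """

    load_mass: float
    marker_distance: float
    deflection: float
    phase: str = "loading"
    end_label: str = ""

    def __post_init__(self) -> None:
        if self.load_mass < 0:
            raise ValueError("load_mass must be nonnegative")
        if self.marker_distance < 0:
            raise ValueError("marker_distance must be nonnegative")
        if self.phase not in ("loading", "unloading"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class DeflectionFit:
    """Fitted deflection-surface coefficient and derived stiffness.

    ``a`` has units s^2 kg^-1 m^-3; ``flexural_rigidity`` is E*I in N m^2;
    ``E`` (Pa) is populated when a second moment of area is supplied.
    """

    a: float
    a_ci95: tuple[float, float]
    flexural_rigidity: float
    x_L: float
    residual_sd: float
    n_obs: int
    E: float | None = None


@dataclass(frozen=True)
class HysteresisResult:
    """Energy lost/returned over a full loading-unloading cycle (fractions)."""

    hysteresis: float
    resilience: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.hysteresis <= 1.0):
            raise ValueError("hysteresis must lie in [0, 1]")


class DeflectionSurfaceRegressor(BaseEstimator, RegressorMixin):
    """Least-squares fit of the cantilever deflection surface.

    The model ``delta = a * (3 m g x_L x**2 - m g x**3)`` is linear in the
    single coefficient ``a``, so the least-squares optimum is closed-form:
    regression through the origin on the beam-theory regressor
    ``u = m g (3 x_L x**2 - x**3)``.

    Parameters
    ----------
    x_L : float
        Lever arm from the fixed functional centre to the load attachment, m.
    g : float
        Gravitational acceleration, m s^-2.

    Attributes
    ----------
    a_ : float
        Fitted surface coefficient, s^2 kg^-1 m^-3.
    a_se_ : float
        Standard error of ``a_``.
    a_ci95_ : tuple of float
        95% confidence interval for ``a_`` (t-distribution).
    flexural_rigidity_ : float
        E*I = 1 / (6 a_), N m^2.
    residual_sd_ : float
        Residual standard deviation of the fit, m.
    n_obs_ : int
        Number of observations used.
    """

    def __init__(self, x_L: float = 1.0, g: float = GRAVITY):
        self.x_L = x_L
        self.g = g

    def _regressor(self, X: np.ndarray) -> np.ndarray:
        m, x = X[:, 0], X[:, 1]
        return m * self.g * (3.0 * self.x_L * x**2 - x**3)

    def fit(self, X, y) -> "DeflectionSurfaceRegressor":
        """Fit the coefficient ``a``.

        ``X`` has columns (load_mass kg, marker_distance m); ``y`` is the
        measured deflection in m.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (load_mass, marker_distance)")
        if self.x_L <= 0:
            raise ValueError("x_L must be positive")
        if np.any(X[:, 1] > self.x_L * (1 + 1e-9)):
            raise ValueError("marker distance beyond the load attachment x_L")
        if len(np.unique(X[:, 0])) < 2 or len(np.unique(X[:, 1])) < 2:
            raise ValueError(
                "rank-deficient design: need >=2 distinct loads and marker distances"
            )
        u = self._regressor(X)
        denom = float(u @ u)
        if denom <= 0:
            raise ValueError("degenerate design: all regressor values are zero")
        a = float(u @ y) / denom
        resid = y - a * u
        dof = max(len(y) - 1, 1)
        s2 = float(resid @ resid) / dof
        se = np.sqrt(s2 / denom)
        tcrit = stats.t.ppf(0.975, dof)
        self.a_ = a
        self.a_se_ = float(se)
        self.a_ci95_ = (a - tcrit * se, a + tcrit * se)
        self.flexural_rigidity_ = 1.0 / (6.0 * a) if a > 0 else np.inf
        self.residual_sd_ = float(np.sqrt(s2))
        self.n_obs_ = int(len(y))
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted deflection (m) at the given (load, position) points."""
        check_is_fitted(self, "a_")
        X = np.asarray(X, dtype=float)
        return self.a_ * self._regressor(X)


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of a collection of :class:`DeflectionRecord`."""
    return pd.DataFrame(
        {
            "load_mass_kg": [r.load_mass for r in records],
            "marker_distance_m": [r.marker_distance for r in records],
            "deflection_m": [r.deflection for r in records],
            "phase": [r.phase for r in records],
            "end_label": [r.end_label for r in records],
        }
    )


def fit_deflection_surface(
    records, x_L: float, g: float = GRAVITY, phase: str = "loading", I: float | None = None
) -> DeflectionFit:
    """Fit the beam-theory deflection surface to a set of records.

    Only records of the requested ``phase`` enter the fit (static stiffness
    is read from the loading branch).  When a second moment of area ``I``
    (m^4) is given, Young's modulus ``E = 1/(6 a I)`` is attached.
    """
    sel = [r for r in records if r.phase == phase]
    if not sel:
        raise ValueError(f"no records in phase {phase!r}")
    X = np.array([[r.load_mass, r.marker_distance] for r in sel])
    y = np.array([r.deflection for r in sel])
    reg = DeflectionSurfaceRegressor(x_L=x_L, g=g).fit(X, y)
    return DeflectionFit(
        a=reg.a_,
        a_ci95=reg.a_ci95_,
        flexural_rigidity=reg.flexural_rigidity_,
        x_L=x_L,
        residual_sd=reg.residual_sd_,
        n_obs=reg.n_obs_,
        E=young_modulus(reg.a_, I) if I is not None else None,
    )


def young_modulus(a: float, I: float) -> float:
    """Young's modulus (Pa) from the surface coefficient and second moment.

    ``E = 1 / (6 a I)`` with ``a`` in s^2 kg^-1 m^-3 and ``I`` in m^4.
    """
    if a <= 0 or I <= 0:
        raise ValueError("a and I must be positive")
    return 1.0 / (6.0 * a * I)


def hysteresis(loading_curve, unloading_curve, n_grid: int = 512) -> HysteresisResult:
    """Strain-energy fraction lost between loading and unloading curves.

    Both curves are (deflection m, force N) pairs over a shared deflection
    range; they are interpolated onto a common grid and integrated by the
    trapezoidal rule.  Points where the unloading force exceeds the loading
    force (measurement noise) are clipped with a warning.
    """
    dl, fl = _as_curve(loading_curve)
    du, fu = _as_curve(unloading_curve)
    lo = max(dl.min(), du.min())
    hi = min(dl.max(), du.max())
    if hi <= lo:
        raise ValueError("loading and unloading curves share no deflection range")
    grid = np.linspace(lo, hi, n_grid)
    f_plus = np.interp(grid, dl, fl)
    f_minus = np.interp(grid, du, fu)
    if np.any(f_minus > f_plus + 1e-12):
        warnings.warn(
            "unloading force exceeds loading force at some deflections; clipping",
            stacklevel=2,
        )
        f_minus = np.minimum(f_minus, f_plus)
    e_plus = np.trapezoid(f_plus, grid)
    e_minus = np.trapezoid(f_minus, grid)
    if e_plus <= 0:
        raise ValueError("loading curve encloses no strain energy")
    hys = float((e_plus - e_minus) / e_plus)
    hys = min(max(hys, 0.0), 1.0)
    return HysteresisResult(hysteresis=hys, resilience=1.0 - hys)


def build_loop_curves(
    records, x_L: float, g: float = GRAVITY, rtol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Loading and unloading (deflection, force) curves at the attachment point.

    Records at ``x = x_L`` are converted to force ``F = m g``, deflections
    averaged over repeats of the same load, and each branch ordered by
    deflection.  Returns ``(loading, unloading)`` as (n, 2) arrays.
    """
    at_tip = [r for r in records if abs(r.marker_distance - x_L) <= rtol * max(x_L, 1.0)]
    curves = {}
    for phase in ("loading", "unloading"):
        sel = [r for r in at_tip if r.phase == phase]
        if not sel:
            raise ValueError(f"no records at x = x_L in phase {phase!r}")
        df = records_to_frame(sel)
        mean = df.groupby("load_mass_kg", as_index=False)["deflection_m"].mean()
        delta = mean["deflection_m"].to_numpy()
        force = mean["load_mass_kg"].to_numpy() * g
        order = np.argsort(delta)
        curves[phase] = np.column_stack([delta[order], force[order]])
    return curves["loading"], curves["unloading"]


def _as_curve(curve) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("curve must be an (n>=2, 2) array of (deflection, force)")
    order = np.argsort(arr[:, 0])
    return arr[order, 0], arr[order, 1]
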