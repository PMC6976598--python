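"""Death-closure landscape fit and the migration/death score decomposition.

Plotting death change DC on the horizontal axis and wound-closure change WC
on the vertical axis, a dose series traces a curve from the origin.  A drug
that delays closure without killing (Sorafenib-like) climbs straight up the
vertical axis; a drug whose delay is driven by death bends toward the
horizontal.  The dose-parameterized relationship is captured by a
first-order saturation model

    WC = wc_max * (1 - exp(-k * DC))

fitted by least squares through the origin; when the fit is inadequate
(r^2 below threshold, a vertical degenerate series, or non-convergence) a
straight line DC = slope * WC through the origin is used instead.

At each dose the tangent angle theta, measured from the vertical
(wound-closure) axis, apportions the closure delay between phenotypes:

    Death_xi     = WC_xi * (theta_xi / (pi/2))
    Migration_xi = WC_xi - Death_xi

so a vertical tangent (theta = 0) means pure migration inhibition and a
horizontal one (theta = pi/2) pure death.  Per-dose scores are summarized
over the two-fold dose series as normalized AUCs on the log2-concentration
axis ("lumped" scores), i.e. mean scores over the log-dose range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError
from .kinetics import ClosureDeathMetrics

FIRST_ORDER = "first_order"
LINEAR = "linear"

# below this DC variance the series is treated as a vertical line
_VERTICAL_VARIANCE = 1e-12
_WC_MAX_BOUND = 1.5
_K_BOUNDS = (1e-9, 1e4)


@dataclass
class LandscapeFit:
    """Fitted wound-closure-vs-death relationship for one dose series."""

    model: str  # FIRST_ORDER or LINEAR
    params: dict[str, float]
    r2: float
    points: list[tuple[float, float]]  # (wc, dc) ordered by concentration, origin first
    diagnostics: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.diagnostics is None:
            self.diagnostics = {}


@dataclass
class DoseScores:
    """Migration/death decomposition of the closure change at one dose."""

    concentration: float
    theta: float
    migration: float
    death: float
    flag: str | None = None


@dataclass
class LumpedScores:
    """Per-series mean scores over the log2-dose axis."""

    migration_lumped: float
    death_lumped: float

    @property
    def bias(self) -> float:
        return self.death_lumped - self.migration_lumped


def _first_order(dc: np.ndarray, wc_max: float, k: float) -> np.ndarray:
    return wc_max * -np.expm1(-k * dc)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-24 else -np.inf
    return 1.0 - ss_res / ss_tot


def _linear_fit(wc: np.ndarray, dc: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of DC = slope * WC through the origin, plus its r^2."""
    denom = float(np.sum(wc * wc))
    slope = float(np.sum(wc * dc) / denom) if denom > 0 else 0.0
    return slope, _r_squared(dc, slope * wc)


def fit_landscape(
    metrics: Sequence[ClosureDeathMetrics],
    r2_threshold: float = 0.6,
) -> LandscapeFit:
    """Fit the (DC, WC) relationship of one ordered dose series.

    ``metrics`` holds the treated conditions of one series in ascending
    concentration; the control origin (0, 0) is prepended internally.
    """
    if len(metrics) < 3:
        raise InsufficientDataError(
            f"need >= 3 dose points to fit a landscape, got {len(metrics)}"
        )
    concs = [m.condition.concentration for m in metrics]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise InsufficientDataError("dose points must be ordered by ascending concentration")

    wc = np.array([0.0] + [m.wc for m in metrics])
    dc = np.array([0.0] + [m.dc for m in metrics])
    points = list(zip(wc.tolist(), dc.tolist()))
    diagnostics: dict = {}

    first_order_ok = float(np.var(dc)) >= _VERTICAL_VARIANCE
    if first_order_ok:
        wc_max0 = float(np.clip(np.max(wc), 1e-3, _WC_MAX_BOUND))
        nonzero = np.flatnonzero(dc > _VERTICAL_VARIANCE)
        if nonzero.size == 0:
            first_order_ok = False
        else:
            i = int(nonzero[0])
            secant = wc[i] / dc[i]
            k0 = float(np.clip(secant / wc_max0, 1e-3, _K_BOUNDS[1]))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _first_order,
                        dc,
                        wc,
                        p0=[wc_max0, k0],
                        bounds=([1e-9, _K_BOUNDS[0]], [_WC_MAX_BOUND, _K_BOUNDS[1]]),
                        maxfev=20000,
                    )
                wc_max, k = float(popt[0]), float(popt[1])
                r2 = _r_squared(wc, _first_order(dc, wc_max, k))
                diagnostics["first_order_r2"] = r2
                if r2 >= r2_threshold:
                    return LandscapeFit(
                        model=FIRST_ORDER,
                        params={"wc_max": wc_max, "k": k},
                        r2=r2,
                        points=points,
                        diagnostics=diagnostics,
                    )
            except (RuntimeError, ValueError) as exc:
                diagnostics["first_order_error"] = str(exc)

    slope, r2_lin = _linear_fit(wc, dc)
    diagnostics.setdefault("fallback_reason", "vertical" if not first_order_ok else "low_r2")
    return LandscapeFit(
        model=LINEAR,
        params={"slope_dc_per_wc": slope},
        r2=r2_lin,
        points=points,
        diagnostics=diagnostics,
    )


def theta_at(fit: LandscapeFit, wc: float, dc: float) -> float:
    """Tangent angle (radians from the vertical axis) at an observed point.

    The angle is arctan(dDC/dWC) along the fitted curve, evaluated at the
    point's projection onto the curve (the fitted abscissa at the observed
    WC), and clamped to [0, pi/2].
    """
    if fit.model == LINEAR:
        return math.atan(max(fit.params["slope_dc_per_wc"], 0.0))
    wc_max, k = fit.params["wc_max"], fit.params["k"]
    wc_eff = max(wc, 0.0)
    if wc_eff >= wc_max * (1.0 - 1e-12):
        warnings.warn(
            f"observed wc {wc:.4g} at or beyond fitted plateau wc_max {wc_max:.4g}; "
            "tangent clamped to pi/2"
        )
        return math.pi / 2
    # project onto the curve: dc_fit = -ln(1 - wc/wc_max)/k, where the
    # tangent slope dWC/dDC is wc_max*k*exp(-k*dc_fit) = k*(wc_max - wc)
    return min(max(math.atan(1.0 / (k * (wc_max - wc_eff))), 0.0), math.pi / 2)


def phenotype_scores(
    fit: LandscapeFit,
    metrics: Sequence[ClosureDeathMetrics],
) -> list[DoseScores]:
    """Decompose each dose's closure change into migration and death scores.

    Conditions whose closure is enhanced (wc < 0) receive zero scores and a
    "closure_enhancement" flag: the theta apportioning is only meaningful
    for delays.
    """
    out: list[DoseScores] = []
    for m in metrics:
        theta = theta_at(fit, max(m.wc, 0.0), m.dc)
        if m.wc < 0:
            out.append(
                DoseScores(
                    concentration=m.condition.concentration,
                    theta=theta,
                    migration=0.0,
                    death=0.0,
                    flag="closure_enhancement",
                )
            )
            continue
        death = m.wc * (theta / (math.pi / 2))
        out.append(
            DoseScores(
                concentration=m.condition.concentration,
                theta=theta,
                migration=m.wc - death,
                death=death,
            )
        )
    return out


def lumped_scores(scores: Sequence[DoseScores]) -> LumpedScores:
    """Normalized AUC of the per-dose scores over the log2-concentration axis.

    With a two-fold serial dose design the log2 axis is uniform, so the
    lumped score is the mean score over the log-dose range; a constant
    score c lumps to c for any grid.
    """
    if len(scores) < 2:
        raise InsufficientDataError("lumped scores need >= 2 concentrations")
    conc = np.array([s.concentration for s in scores], dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise InsufficientDataError("concentrations must be positive and strictly increasing")
    x = np.log2(conc)
    span = x[-1] - x[0]
    mig = np.array([s.migration for s in scores])
    death = np.array([s.death for s in scores])
    return LumpedScores(
        migration_lumped=float(np.trapezoid(mig, x) / span),
        death_lumped=float(np.trapezoid(death, x) / span),
    )
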