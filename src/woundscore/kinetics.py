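"""Analysis windows and AUC-based closure/death change metrics.

Scores are computed per stratum (one cell line at one seeding density and
MMC state, sharing one vehicle control).  For each condition an analysis
window is chosen by one of three endpoint criteria:

  A  the fixed experiment endpoint (default 72 h);
  B  the time at which the vehicle control's closure rate has declined to
     the slope threshold (default 0.02 RWD-fraction/h), one window for the
     whole stratum;
  C  the per-condition time at which RWD first reaches the target
     (default 50%), falling back to the last observed time.

Within the window, the wound-closure change of condition xi is

    WC_xi  = (AUC(RWD)_ctrl - AUC(RWD)_xi) / AUC(RWD)_ctrl
    WC_ind =  AUC(RWD)_xi / AUC(RWD)_ctrl          (so WC_xi + WC_ind = 1)

and the death change, from the integrated caspase-3/7 signal D, is

    DC_xi = (AUC(D)_xi - AUC(D)_ctrl) / AUC(D)_max

with AUC(D)_max the stratum-wide maximum (control included).  Negative DC
is clamped to zero (a drug cannot contribute negative death to the delay);
the raw value is kept alongside.  Under method C the AUCs are divided by
the window length first, so windows of unequal length remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assay_io import AnalysisConfig, Condition, WellTimeSeries
from .errors import (
    DegenerateControlError,
    EmptyInputError,
    StratumError,
    WindowError,
)


@dataclass
class ClosureDeathMetrics:
    """Per-condition AUC-derived quantities over the analysis window."""

    condition: Condition
    window_end: float
    auc_rwd: float
    wc: float
    wc_ind: float
    auc_death: float
    dc: float
    dc_raw: float


def trapezoid_auc(times: np.ndarray, values: np.ndarray, t_end: float) -> float:
    """Trapezoidal integral of a sampled trace over [times[0], t_end].

    If ``t_end`` falls between samples the trace is linearly interpolated
    there, so the result is exact for piecewise-linear traces.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise WindowError("trace contains non-finite values")
    if not (times[0] < t_end <= times[-1]):
        raise WindowError(
            f"t_end {t_end} outside ({times[0]}, {times[-1]}]"
        )
    head = times < t_end
    v_end = float(np.interp(t_end, times, values))
    tt = np.concatenate([times[head], [t_end]])
    vv = np.concatenate([values[head], [v_end]])
    return float(np.trapezoid(vv, tt))


def time_to_rwd(series: WellTimeSeries, target: float) -> float | None:
    """Earliest time at which linearly interpolated RWD first reaches target.

    Returns None if the target is never reached within the trace.
    """
    if not (0 < target < 1):
        raise WindowError(f"target must lie in (0, 1), got {target}")
    r, t = series.rwd, series.times
    if r[0] >= target:
        return float(t[0])
    hits = np.flatnonzero(r >= target)
    if hits.size == 0:
        return None
    i = int(hits[0])
    # first crossing: r[i-1] < target <= r[i], so the segment is rising
    return float(t[i - 1] + (target - r[i - 1]) * (t[i] - t[i - 1]) / (r[i] - r[i - 1]))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average over the available window."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def control_trace(stratum: Sequence[WellTimeSeries]) -> WellTimeSeries:
    """Pointwise-mean vehicle-control trace of a stratum."""
    controls = [w for w in stratum if w.condition.is_control]
    if not controls:
        raise StratumError("stratum has no vehicle-control well")
    if len(controls) == 1:
        return controls[0]
    ref = controls[0]
    rwd = np.mean([w.rwd for w in controls], axis=0)
    casp = np.mean([w.caspase for w in controls], axis=0)
    return WellTimeSeries(ref.condition, ref.times.copy(), rwd, casp)


def endpoint_time(
    stratum: Sequence[WellTimeSeries],
    config: AnalysisConfig,
    condition: Condition,
) -> float:
    """Analysis-window end for ``condition`` under the configured criterion."""
    if not stratum:
        raise EmptyInputError("endpoint_time: empty stratum")
    times = stratum[0].times
    method = config.endpoint_method
    if method == "A":
        if not (times[0] < config.fixed_endpoint <= times[-1]):
            raise WindowError(
                f"fixed endpoint {config.fixed_endpoint} h outside observed "
                f"range ({times[0]}, {times[-1]}] h"
            )
        return float(config.fixed_endpoint)
    if method == "B":
        ctrl = control_trace(stratum)
        slope = np.gradient(ctrl.rwd, ctrl.times)
        smooth = _moving_average(slope, config.slope_smooth_window)
        # the guard skips the initial lag plateau, where the slope is also
        # below threshold but closure has not yet begun
        eligible = (ctrl.rwd > config.slope_guard) & (smooth <= config.slope_threshold)
        hits = np.flatnonzero(eligible)
        if hits.size == 0:
            return float(ctrl.times[-1])
        return float(ctrl.times[int(hits[0])])
    # method C
    matches = [w for w in stratum if w.condition == condition]
    if not matches:
        raise StratumError(f"condition {condition} not found in stratum")
    t50 = time_to_rwd(matches[0], config.rwd_target)
    return float(matches[0].times[-1]) if t50 is None or t50 <= times[0] else t50


def closure_death_metrics(
    stratum: Sequence[WellTimeSeries],
    config: AnalysisConfig,
) -> list[ClosureDeathMetrics]:
    """Closure/death change metrics for every well of one stratum.

    The control's metrics are 0 by construction.  Raises
    DegenerateControlError when the control closure AUC is zero; when the
    death-AUC normalizer is zero (no caspase signal anywhere) all DC values
    are set to 0 with a warning.
    """
    if not stratum:
        raise EmptyInputError("closure_death_metrics: empty stratum")
    ctrl = control_trace(stratum)
    method = config.endpoint_method

    def window_for(w: WellTimeSeries) -> float:
        return endpoint_time(stratum, config, w.condition)

    if method in ("A", "B"):
        shared = endpoint_time(stratum, config, stratum[0].condition)
        wins = {id(w): shared for w in stratum}
        ctrl_win = shared
    else:
        wins = {id(w): window_for(w) for w in stratum}
        t50 = time_to_rwd(ctrl, config.rwd_target)
        ctrl_win = float(ctrl.times[-1]) if t50 is None or t50 <= ctrl.times[0] else t50

    def aucs(w: WellTimeSeries, t_end: float) -> tuple[float, float, float, float]:
        a_r = trapezoid_auc(w.times, w.rwd, t_end)
        a_d = trapezoid_auc(w.times, w.caspase, t_end)
        if method == "C":
            span = t_end - w.times[0]
            return a_r, a_d, a_r / span, a_d / span
        return a_r, a_d, a_r, a_d

    _, _, ctrl_r_eff, ctrl_d_eff = aucs(ctrl, ctrl_win)
    if ctrl_r_eff == 0:
        raise DegenerateControlError("control closure AUC is zero; WC undefined")

    raw: list[tuple[WellTimeSeries, float, float, float, float, float]] = []
    for w in stratum:
        t_end = wins[id(w)]
        a_r, a_d, r_eff, d_eff = aucs(w, t_end)
        raw.append((w, t_end, a_r, a_d, r_eff, d_eff))

    d_max = max(d_eff for *_, d_eff in raw)
    if d_max == 0:
        warnings.warn("stratum death-AUC normalizer is zero; all DC set to 0")

    out: list[ClosureDeathMetrics] = []
    for w, t_end, a_r, a_d, r_eff, d_eff in raw:
        if w.condition.is_control:
            wc, wc_ind, dc_raw = 0.0, 1.0, 0.0
        else:
            wc = (ctrl_r_eff - r_eff) / ctrl_r_eff
            wc_ind = r_eff / ctrl_r_eff
            dc_raw = (d_eff - ctrl_d_eff) / d_max if d_max > 0 else 0.0
        out.append(
            ClosureDeathMetrics(
                condition=w.condition,
                window_end=t_end,
                auc_rwd=a_r,
                wc=wc,
                wc_ind=wc_ind,
                auc_death=a_d,
                dc=max(dc_raw, 0.0),
                dc_raw=dc_raw,
            )
        )
    return out
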