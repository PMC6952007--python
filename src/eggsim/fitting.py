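"""Estimate internal-cycle-length curve parameters from oviposition records.

The observable signature of the ICL curve is the lag between successive
ovipositions within a clutch: the interval between two eggs' absolute lay
times minus the external cycle length.  Pooling those (days-since-first-egg,
lag) pairs across hens and fitting the exponential-decay-plus-linear-
senescence form by nonlinear least squares recovers the population-mean curve
parameters, provided lags are not floored at zero (curves that dip below the
external cycle censor the observable lag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ovulation import ICLCurve, OvipositionRecord

__all__ = ["ICLCurveModel", "ICLCurveResults", "lag_observations"]

_PARAM_NAMES = ("baseline_h", "initial_excess_h", "decay_rate", "senescence_slope_h_per_d")


def lag_observations(
    records: Sequence[OvipositionRecord], external_cycle_h: float = 24.0
) -> pd.DataFrame:
    """Extract (t, lag) pairs from successive within-clutch ovipositions.

    ``t`` is days since the hen's first recorded egg; ``lag`` is the interval
    between consecutive eggs of the same clutch minus the external cycle
    length.  Returns a DataFrame with columns hen_id, t_d, lag_h.
    """
    by_hen: dict[int, list[OvipositionRecord]] = {}
    for r in records:
        by_hen.setdefault(r.hen_id, []).append(r)
    rows = []
    for hen_id, recs in by_hen.items():
        recs = sorted(recs, key=lambda r: (r.day, r.time_of_lay_h))
        first_day = recs[0].day
        for a, b in zip(recs, recs[1:]):
            if b.clutch_index != a.clutch_index or b.position_in_clutch != a.position_in_clutch + 1:
                continue
            abs_a = 24.0 * a.day + a.time_of_lay_h
            abs_b = 24.0 * b.day + b.time_of_lay_h
            rows.append(
                {
                    "hen_id": hen_id,
                    "t_d": b.day - first_day,
                    "lag_h": abs_b - abs_a - external_cycle_h,
                }
            )
    return pd.DataFrame(rows, columns=["hen_id", "t_d", "lag_h"])


def _lag_model(t, base_lag, amplitude, decay, slope):
    return base_lag + amplitude * np.exp(-decay * t) + slope * t


@dataclass
class ICLCurveResults:
    """Fitted ICL curve with standard errors and fit diagnostics."""

    params: ICLCurve
    bse: dict[str, float]
    nobs: int
    resid_sd_h: float

    def summary(self) -> str:
        lines = [
            "ICL curve fit (nonlinear least squares on within-clutch lags)",
            f"observations: {self.nobs}    residual SD: {self.resid_sd_h:.3f} h",
            f"{'parameter':<28}{'estimate':>12}{'std err':>12}",
        ]
        for name in _PARAM_NAMES:
            lines.append(
                f"{name:<28}{getattr(self.params, name):>12.5f}{self.bse.get(name, float('nan')):>12.5f}"
            )
        return "\n".join(lines)


class ICLCurveModel:
    """Nonlinear least-squares model for the ICL curve.

    Parameters
    ----------
    observations : DataFrame with columns t_d, lag_h (see ``lag_observations``).
    """

    def __init__(self, observations: pd.DataFrame):
        if observations.empty:
            raise ValueError("no lag observations to fit")
        self.observations = observations

    @classmethod
    def from_records(
        cls, records: Sequence[OvipositionRecord], external_cycle_h: float = 24.0
    ) -> "ICLCurveModel":
        return cls(lag_observations(records, external_cycle_h))

    def fit(self, p0: tuple[float, float, float, float] | None = None) -> ICLCurveResults:
        t = self.observations["t_d"].to_numpy(float)
        lag = self.observations["lag_h"].to_numpy(float)
        if p0 is None:
            late = lag[t > np.quantile(t, 0.5)]
            early = lag[t <= np.quantile(t, 0.1)]
            base0 = float(np.median(late)) if late.size else float(np.median(lag))
            amp0 = max(float(np.median(early)) - base0, 0.1) if early.size else 1.0
            p0 = (base0, amp0, 0.1, 1e-3)
        popt, pcov = curve_fit(
            _lag_model,
            t,
            lag,
            p0=p0,
            bounds=([-24.0, 1e-6, 1e-6, 0.0], [24.0, 48.0, 5.0, 1.0]),
            maxfev=20000,
        )
        base_lag, amplitude, decay, slope = popt
        se = np.sqrt(np.diag(pcov))
        params = ICLCurve(
            baseline_h=24.0 + base_lag,
            initial_excess_h=base_lag + amplitude,
            decay_rate=decay,
            senescence_slope_h_per_d=slope,
        )
        bse = {
            "baseline_h": se[0],
            "initial_excess_h": float(np.hypot(se[0], se[1])),
            "decay_rate": se[2],
            "senescence_slope_h_per_d": se[3],
        }
        resid = lag - _lag_model(t, *popt)
        return ICLCurveResults(
            params=params, bse=bse, nobs=len(t), resid_sd_h=float(np.std(resid))
        )
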