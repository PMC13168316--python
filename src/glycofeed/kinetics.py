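"""Cell-specific rates and cumulative growth quantities from fed-batch time courses.

All quantities follow the standard bioprocess conventions:

* specific growth rate ``mu_i = Δln(VCD) / Δt`` per day,
* integral of viable cell density (IVCD) as the trapezoidal area under the
  VCD curve, incrementally and cumulatively,
* cell-specific lactate rate ``q_LAC = ΔLAC / ΔIVCD`` over 48-h intervals
  (pmol/cell/d; production positive, consumption negative),
* cell-specific productivity ``q_P = ΔP / ΔIVCD`` over 24-h intervals
  (pg/cell/d; negatives tolerated — feed addition dilutes the titer),
* cell-specific glucose consumption ``q_GLC`` as minus the slope of an
  ordinary least-squares fit of glucose concentration against cumulative
  IVCD within each feeding window.

Units work out so that numbers can be used directly: with VCD in
10^6 cells/mL, titer in mg/L and lactate in mM, the ratios above are already
pg/cell/d and pmol/cell/d respectively.

Missing or undefined intervals (non-positive VCD, zero ΔIVCD) are flagged as
NaN and carried through, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeedEvent",
    "CultureTimeCourse",
    "specific_growth_rate",
    "incremental_ivcd",
    "cumulative_ivcd",
    "specific_lactate_rate",
    "specific_productivity",
    "specific_glucose_rate",
    "rate_summary_table",
]


@dataclass(frozen=True)
class FeedEvent:
    """One feeding event: day, feed volume fraction, glucose added, Gal+ flag."""

    day: float
    feed_pct_vv: float
    glucose_added_g_l: float
    gal_plus: bool = False


@dataclass
class CultureTimeCourse:
    """Daily process measurements of one fed-batch replicate (sampled pre-feed).

    Arrays are aligned on ``t`` (days since inoculation, strictly increasing).
    ``vcd`` is viable cell density in 10^6 cells/mL, ``glucose`` g/L,
    ``lactate`` mM, ``titer`` mg/L.
    """

    t: np.ndarray
    vcd: np.ndarray
    viability: np.ndarray | None = None
    diameter: np.ndarray | None = None
    glucose: np.ndarray | None = None
    lactate: np.ndarray | None = None
    titer: np.ndarray | None = None
    ph: np.ndarray | None = None
    feed_events: list[FeedEvent] = field(default_factory=list)
    replicate: str = "r1"
    strategy: str = "STD"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vcd = np.asarray(self.vcd, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if len(self.t) != len(self.vcd):
            raise ValueError("t and vcd length mismatch")
        for name in ("viability", "diameter", "glucose", "lactate", "titer", "ph"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.t):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        data = {"replicate": self.replicate, "strategy": self.strategy, "day": self.t,
                "vcd_1e6_per_ml": self.vcd}
        for name, col in [("viability", "viability_pct"), ("diameter", "diameter_um"),
                          ("glucose", "glucose_g_l"), ("lactate", "lactate_mm"),
                          ("titer", "titer_mg_l"), ("ph", "ph")]:
            v = getattr(self, name)
            if v is not None:
                data[col] = v
        return pd.DataFrame(data)


def specific_growth_rate(course: CultureTimeCourse) -> pd.DataFrame:
    """Per-interval specific growth rate ``mu = Δln(VCD)/Δt`` in 1/d.

    Intervals with a non-positive VCD endpoint are flagged NaN rather than
    raising, so a culture collapse does not abort the analysis.
    """
    t, vcd = course.t, course.vcd
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.where(vcd > 0, np.log(np.where(vcd > 0, vcd, 1.0)), np.nan)
    mu = np.diff(ln) / dt
    return pd.DataFrame({
        "t_start": t[:-1], "t_end": t[1:], "mu_per_d": mu,
        "flag_missing": ~np.isfinite(mu),
    })


def incremental_ivcd(course: CultureTimeCourse) -> pd.DataFrame:
    """Trapezoidal IVCD per interval, 10^6 cells·d/mL."""
    t, vcd = course.t, course.vcd
    if len(t) < 2:
        raise ValueError("need at least 2 time points for IVCD")
    ivcd = 0.5 * (vcd[:-1] + vcd[1:]) * np.diff(t)
    return pd.DataFrame({"t_start": t[:-1], "t_end": t[1:], "ivcd": ivcd})


def cumulative_ivcd(course: CultureTimeCourse) -> pd.DataFrame:
    """Cumulative IVCD at each time point (0 at the first sample)."""
    inc = incremental_ivcd(course)
    sums = np.concatenate([[0.0], np.cumsum(inc["ivcd"].to_numpy())])
    return pd.DataFrame({"t": course.t, "ivcd_sum": sums})


def _interval_rate(
    course: CultureTimeCourse, values: np.ndarray, spacing_days: float
) -> pd.DataFrame:
    """Δvalue / ΔIVCD over intervals of the requested nominal spacing.

    Endpoints are matched to the nearest available sampling days; when a day
    is missing the interval is widened to the nearest points and flagged.
    Intervals with ΔIVCD = 0 or a missing measurement are NaN-flagged.
    """
    t = course.t
    cum = cumulative_ivcd(course)["ivcd_sum"].to_numpy()
    # pick endpoint indices stepping ~spacing_days through the sampled days
    idx = [0]
    while True:
        target = t[idx[-1]] + spacing_days
        later = np.where(t > t[idx[-1]])[0]
        if len(later) == 0:
            break
        j = later[np.argmin(np.abs(t[later] - target))]
        idx.append(int(j))
        if j == len(t) - 1:
            break
    rows = []
    for a, b in zip(idx[:-1], idx[1:]):
        dv = values[b] - values[a]
        divcd = cum[b] - cum[a]
        rate = dv / divcd if (np.isfinite(dv) and divcd > 0) else np.nan
        rows.append({
            "t_start": t[a], "t_end": t[b], "delta_ivcd": divcd, "rate": rate,
            "flag_missing": not np.isfinite(rate),
            "flag_widened": bool(abs((t[b] - t[a]) - spacing_days) > 1e-9),
        })
    return pd.DataFrame(rows)


def specific_lactate_rate(course: CultureTimeCourse) -> pd.DataFrame:
    """Cell-specific lactate rate over 48-h intervals, pmol/cell/d.

    Positive values are net production, negative net consumption. The mM to
    pmol/mL conversion (1 mM = 10^6 pmol/mL) cancels against VCD's 10^6
    factor, so the plain ratio is already in pmol/cell/d.
    """
    if course.lactate is None:
        raise ValueError("course has no lactate measurements")
    out = _interval_rate(course, course.lactate, 2.0)
    return out.rename(columns={"rate": "q_lac_pmol_per_cell_d"})


def specific_productivity(
    course: CultureTimeCourse, *, process_window: tuple[float, float] = (3.0, 11.0)
) -> tuple[pd.DataFrame, float]:
    """Cell-specific productivity q_P over 24-h intervals plus a process average.

    Returns the per-interval table (pg/cell/d; negative values are kept —
    they arise from titer dilution after feed addition) and the single
    process-average q_P computed from the total titer change over the
    ``process_window`` days divided by the IVCD accumulated in that window.
    """
    if course.titer is None:
        raise ValueError("course has no titer measurements")
    out = _interval_rate(course, course.titer, 1.0)
    out = out.rename(columns={"rate": "q_p_pg_per_cell_d"})
    t = course.t
    cum = cumulative_ivcd(course)["ivcd_sum"].to_numpy()
    lo = int(np.argmin(np.abs(t - process_window[0])))
    hi = int(np.argmin(np.abs(t - process_window[1])))
    divcd = cum[hi] - cum[lo]
    avg = (course.titer[hi] - course.titer[lo]) / divcd if divcd > 0 else np.nan
    return out, float(avg)


def feeding_windows(course: CultureTimeCourse) -> list[tuple[float, float]]:
    """Half-open [feed_k, feed_{k+1}) windows between consecutive feed events.

    The window sequence starts at the first feed event; the pre-feed sample
    taken on the day of feed_{k+1} belongs to window k. The tail after the
    last feed runs to the final sampling day.
    """
    days = sorted({e.day for e in course.feed_events})
    if not days:
        return [(float(course.t[0]), float(course.t[-1]))]
    bounds = days + [float(course.t[-1])]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def specific_glucose_rate(
    course: CultureTimeCourse, windows: Sequence[tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Cell-specific glucose consumption per feeding window via OLS.

    Within each window bounded by consecutive feed events, glucose
    concentration is regressed on cumulative IVCD::

        c_GLC = slope * IVCD_sum + d + eps

    and the consumption rate is reported as ``q_GLC = -slope`` (consumption
    positive), in g/L per 10^6 cells·d/mL (numerically equal to ng/cell/d).
    Windows with fewer than two samples are skipped. Residuals are retained
    for diagnostics.
    """
    if course.glucose is None:
        raise ValueError("course has no glucose measurements")
    if windows is None:
        windows = feeding_windows(course)
    t = course.t
    cum = cumulative_ivcd(course)["ivcd_sum"].to_numpy()
    rows = []
    for (a, b) in windows:
        # window start is exclusive (the sample on the feed day is pre-feed and
        # belongs to the previous window); the pre-feed sample at the window
        # end belongs to this window
        mask = (t > a + 1e-9) & (t <= b + 1e-9) & np.isfinite(course.glucose)
        x = cum[mask]
        y = course.glucose[mask]
        if len(x) < 2 or np.ptp(x) == 0:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        rows.append({
            "t_start": a, "t_end": b, "n_points": int(len(x)),
            "q_glc": -slope, "slope": slope, "intercept": intercept,
            "rss": float(resid @ resid),
            "max_abs_residual": float(np.max(np.abs(resid))),
        })
    return pd.DataFrame(rows)


def rate_summary_table(course: CultureTimeCourse) -> pd.DataFrame:
    """Tidy long table with one row per (replicate, interval, quantity)."""
    frames = []
    mu = specific_growth_rate(course)
    frames.append(mu.assign(quantity="mu_per_d", value=mu["mu_per_d"]))
    ivcd = incremental_ivcd(course)
    frames.append(ivcd.assign(quantity="ivcd", value=ivcd["ivcd"]))
    if course.lactate is not None:
        q = specific_lactate_rate(course)
        frames.append(q.assign(quantity="q_lac_pmol_per_cell_d",
                               value=q["q_lac_pmol_per_cell_d"]))
    if course.titer is not None:
        q, avg = specific_productivity(course)
        frames.append(q.assign(quantity="q_p_pg_per_cell_d",
                               value=q["q_p_pg_per_cell_d"]))
        frames.append(pd.DataFrame([{"t_start": 3.0, "t_end": 11.0,
                                     "quantity": "q_p_process_avg", "value": avg}]))
    if course.glucose is not None:
        q = specific_glucose_rate(course)
        if len(q):
            frames.append(q.assign(quantity="q_glc", value=q["q_glc"]))
    out = pd.concat(frames, ignore_index=True)[
        ["t_start", "t_end", "quantity", "value"]
    ]
    out.insert(0, "strategy", course.strategy)
    out.insert(0, "replicate", course.replicate)
    return out
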