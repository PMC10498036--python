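"""Open-flow respirometry: from raw gas traces to resting metabolic rate.

A respirometry session records O2 and CO2 fractions of air leaving an
animal chamber, bracketed by two ambient-air baseline segments.  Rates of
oxygen consumption and carbon dioxide production follow from the
steady-state mass-balance equations

    VO2  = (FiO2 - FeO2)  / (1 - FiO2)  * FR
    VCO2 = (FeCO2 - FiCO2) / (1 - FiCO2) * FR

where Fi/Fe are incurrent (ambient) and excurrent gas fractions and FR is
the flow rate in ml min^-1.  Analyser drift is removed by interpolating the
ambient reference linearly in time between the two baseline segments, and
rates are averaged over a 5-min window of the animal trace (by default
minutes 13-18, shifted to the nearest stable window when the trace is
noisy there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RespirometrySession",
    "RMREstimate",
    "correct_baseline_drift",
    "select_window",
    "compute_vo2",
    "compute_vco2",
    "mass_correct",
    "estimate_rmr",
    "read_sessions_csv",
]

#: canonical segment labels, in required temporal order
SEGMENT_ORDER = ("baseline1", "animal", "baseline2")

#: default analysis window, minutes from the start of the animal segment
DEFAULT_WINDOW_MIN = (13.0, 18.0)

#: window length in seconds (5 min)
WINDOW_LENGTH_S = 300.0


class RespirometryError(ValueError):
    """Invalid session structure or parameters."""


@dataclass
class RespirometrySession:
    """One animal's trace plus its two bracketing ambient baselines.

    Parameters
    ----------
    data
        Tidy frame with columns ``time_s`` (strictly increasing),
        ``segment`` (one of ``baseline1``, ``animal``, ``baseline2``),
        ``o2_frac`` and ``co2_frac`` (fractions in (0, 1)).  After
        :func:`correct_baseline_drift` the frame additionally carries
        ``o2_incurrent`` / ``co2_incurrent`` reference columns.
    flow_rate_ml_min
        Pump flow through the chamber.
    truth
        Optional ground-truth metadata attached by the synthetic generator
        (true rates, drift slope, ...); never consulted by the analysis.
    """

    data: pd.DataFrame
    flow_rate_ml_min: float
    session_id: str = "session"
    chick_id: str = "chick"
    truth: Optional[dict] = None
    drift_corrected: bool = field(default=False)

    def __post_init__(self) -> None:
        required = {"time_s", "segment", "o2_frac", "co2_frac"}
        missing = required - set(self.data.columns)
        if missing:
            raise RespirometryError(f"session data missing columns {sorted(missing)}")
        if self.flow_rate_ml_min <= 0:
            raise RespirometryError("flow rate must be positive")
        t = self.data["time_s"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise RespirometryError("time_s must be strictly increasing")
        for col in ("o2_frac", "co2_frac"):
            v = self.data[col].to_numpy(float)
            if len(v) and (np.any(v <= 0) or np.any(v >= 1)):
                raise RespirometryError(f"{col} values must lie in (0, 1)")
        # baseline1 must precede animal must precede baseline2
        seg = self.data["segment"]
        firsts = {
            s: int(np.argmax((seg == s).to_numpy()))
            for s in SEGMENT_ORDER
            if (seg == s).any()
        }
        present = [s for s in SEGMENT_ORDER if s in firsts]
        if [s for _, s in sorted((firsts[s], s) for s in present)] != present:
            raise RespirometryError(
                "segments must appear in order baseline1, animal, baseline2"
            )

    def segment(self, label: str) -> pd.DataFrame:
        part = self.data[self.data["segment"] == label]
        if part.empty:
            raise RespirometryError(f"session has no '{label}' segment")
        return part

    @property
    def animal_start_s(self) -> float:
        return float(self.segment("animal")["time_s"].iloc[0])


@dataclass
class RMREstimate:
    """Per-trace metabolic-rate estimate, raw and mass-corrected."""

    chick_id: str
    vo2_ml_min: float
    vco2_ml_min: float
    window: tuple[float, float]
    body_mass_g: Optional[float] = None
    vo2_mass_corrected: Optional[float] = None
    quality_flag: str = "default_window"

    def __post_init__(self) -> None:
        if abs((self.window[1] - self.window[0]) - WINDOW_LENGTH_S) > 1e-6:
            raise RespirometryError("analysis window must span 300 s")


# ---------------------------------------------------------------------------
# baseline drift correction


def correct_baseline_drift(session: RespirometrySession) -> RespirometrySession:
    """Attach a time-varying ambient reference to every reading.

    The incurrent fraction at time *t* is the linear interpolation between
    the mean of the first baseline segment (anchored at its mid-time) and
    the mean of the second.  For a linear analyser drift this removes the
    drift from the incurrent-excurrent difference exactly, because both
    the reference and the animal readings share the same additive shift.
    """
    b1 = session.segment("baseline1")
    b2 = session.segment("baseline2")
    data = session.data.copy()
    t = data["time_s"].to_numpy(float)
    for gas in ("o2", "co2"):
        col = f"{gas}_frac"
        t1, m1 = float(b1["time_s"].mean()), float(b1[col].mean())
        t2, m2 = float(b2["time_s"].mean()), float(b2[col].mean())
        slope = (m2 - m1) / (t2 - t1) if t2 > t1 else 0.0
        data[f"{gas}_incurrent"] = m1 + slope * (t - t1)
    return replace(session, data=data, drift_corrected=True)


# ---------------------------------------------------------------------------
# stable-window selection


def _rolling_sd(values: np.ndarray, width: int) -> np.ndarray:
    """Centred rolling standard deviation, edges padded by the nearest value."""
    s = (
        pd.Series(values)
        .rolling(width, center=True, min_periods=max(2, width // 2))
        .std()
    )
    return s.bfill().ffill().to_numpy()


def select_window(
    session: RespirometrySession,
    default_start_min: float = DEFAULT_WINDOW_MIN[0],
    default_end_min: float = DEFAULT_WINDOW_MIN[1],
    stability_sd_threshold: Optional[float] = None,
    rolling_width_s: float = 30.0,
) -> tuple[float, float, str]:
    """Choose the 5-min averaging window within the animal segment.

    Returns ``(start_s, end_s, quality_flag)`` in absolute session time.
    The default window (minutes 13-18 of the animal trace) is kept when
    the rolling standard deviation of both gas traces stays at or below
    the stability threshold throughout it; otherwise the sub-threshold
    5-min window nearest the default start (on a 1-s grid) is taken and
    flagged ``shifted_window``; if no window qualifies, the window with
    the globally smallest peak rolling SD is returned, also flagged.

    The default threshold is 3x the median rolling SD of the animal trace
    (the larger of the two gases), a scale-free notion of "stable for this
    session".
    """
    animal = session.segment("animal")
    t = animal["time_s"].to_numpy(float)
    if t[-1] - t[0] + 1e-9 < WINDOW_LENGTH_S:
        raise RespirometryError("animal segment shorter than the 300 s window")

    dt = float(np.median(np.diff(t)))
    width = max(3, int(round(rolling_width_s / dt)))
    sd_o2 = _rolling_sd(animal["o2_frac"].to_numpy(float), width)
    sd_co2 = _rolling_sd(animal["co2_frac"].to_numpy(float), width)
    # stability score per sample: the noisier gas decides
    score = np.maximum(sd_o2 / max(np.median(sd_o2), 1e-15),
                       sd_co2 / max(np.median(sd_co2), 1e-15))
    if stability_sd_threshold is None:
        threshold = 3.0
    else:
        # absolute threshold applies to the raw per-gas rolling SDs
        score = np.maximum(sd_o2, sd_co2)
        threshold = float(stability_sd_threshold)

    t0 = t[0]
    default_start = t0 + default_start_min * 60.0
    # candidate starts on a 1-s grid
    starts = np.arange(t0, t[-1] - WINDOW_LENGTH_S + 1e-9, 1.0)
    if len(starts) == 0:
        starts = np.array([t0])
    peak = np.empty(len(starts))
    for i, s in enumerate(starts):
        m = (t >= s) & (t <= s + WINDOW_LENGTH_S)
        peak[i] = score[m].max()

    def _window(s: float, flag: str) -> tuple[float, float, str]:
        return float(s), float(s + WINDOW_LENGTH_S), flag

    # default window first
    i_default = int(np.argmin(np.abs(starts - default_start)))
    if peak[i_default] <= threshold and abs(starts[i_default] - default_start) <= 1.0:
        return _window(starts[i_default], "default_window")
    ok = peak <= threshold
    if ok.any():
        cand = np.flatnonzero(ok)
        best = cand[np.argmin(np.abs(starts[cand] - default_start))]
        return _window(starts[best], "shifted_window")
    return _window(starts[int(np.argmin(peak))], "shifted_window")


# ---------------------------------------------------------------------------
# rate equations


def _window_means(
    session: RespirometrySession, window: tuple[float, float], gas: str
) -> tuple[float, float]:
    if not session.drift_corrected:
        raise RespirometryError(
            "session must be drift-corrected before computing rates"
        )
    animal = session.segment("animal")
    start_s, end_s = window
    m = (animal["time_s"] >= start_s) & (animal["time_s"] <= end_s)
    if not m.any():
        raise RespirometryError("window lies outside the animal segment")
    sel = animal[m]
    return float(sel[f"{gas}_incurrent"].mean()), float(sel[f"{gas}_frac"].mean())


def compute_vo2(
    session: RespirometrySession, window: tuple[float, float]
) -> float:
    """Oxygen consumption rate (ml min^-1) averaged over *window*.

    Negative results within noise tolerance (|VO2| < 1% of the oxygen
    delivered) are clipped to zero with a warning; larger negatives raise.
    """
    fi, fe = _window_means(session, window, "o2")
    if fi >= 1.0:
        raise RespirometryError("incurrent O2 fraction must be < 1")
    vo2 = (fi - fe) / (1.0 - fi) * session.flow_rate_ml_min
    return _clip_negative(vo2, session, "VO2")


def compute_vco2(
    session: RespirometrySession, window: tuple[float, float]
) -> float:
    """Carbon dioxide production rate (ml min^-1) averaged over *window*."""
    fi, fe = _window_means(session, window, "co2")
    if fi >= 1.0:
        raise RespirometryError("incurrent CO2 fraction must be < 1")
    vco2 = (fe - fi) / (1.0 - fi) * session.flow_rate_ml_min
    return _clip_negative(vco2, session, "VCO2")


def _clip_negative(rate: float, session: RespirometrySession, label: str) -> float:
    tolerance = 0.01 * session.flow_rate_ml_min * 0.2095
    if rate < -tolerance:
        raise RespirometryError(f"{label} strongly negative ({rate:.3f} ml/min)")
    if rate < 0:
        warnings.warn(f"{label} slightly negative ({rate:.4f}); clipped to 0")
        return 0.0
    return rate


def mass_correct(vo2_ml_min: float, mass_g: float) -> float:
    """Mass-specific rate: ml min^-1 g^-1."""
    if mass_g <= 0:
        raise RespirometryError("body mass must be positive")
    return vo2_ml_min / mass_g


def estimate_rmr(
    session: RespirometrySession,
    body_mass_g: Optional[float] = None,
    stability_sd_threshold: Optional[float] = None,
) -> RMREstimate:
    """Full per-trace chain: drift correction, window selection, rates."""
    corrected = (
        session if session.drift_corrected else correct_baseline_drift(session)
    )
    start_s, end_s, flag = select_window(
        corrected, stability_sd_threshold=stability_sd_threshold
    )
    vo2 = compute_vo2(corrected, (start_s, end_s))
    vco2 = compute_vco2(corrected, (start_s, end_s))
    mc = mass_correct(vo2, body_mass_g) if body_mass_g is not None else None
    return RMREstimate(
        chick_id=session.chick_id,
        vo2_ml_min=vo2,
        vco2_ml_min=vco2,
        window=(start_s, end_s),
        body_mass_g=body_mass_g,
        vo2_mass_corrected=mc,
        quality_flag=flag,
    )


# ---------------------------------------------------------------------------
# I/O


def read_sessions_csv(path) -> list[RespirometrySession]:
    """Load sessions from the tidy CSV schema written by the generator.

    Expected columns: session_id, chick_id, time_s, segment, o2_frac,
    co2_frac, flow_ml_min.  Percent-scale gas columns (values > 1) are
    accepted and divided by 100.
    """
    frame = pd.read_csv(path)
    sessions = []
    for sid, part in frame.groupby("session_id", sort=True):
        part = part.sort_values("time_s").reset_index(drop=True)
        for col in ("o2_frac", "co2_frac"):
            if (part[col] > 1.0).any():
                part[col] = part[col] / 100.0
        chick = str(part["chick_id"].iloc[0]) if "chick_id" in part else "chick"
        sessions.append(
            RespirometrySession(
                data=part[["time_s", "segment", "o2_frac", "co2_frac"]],
                flow_rate_ml_min=float(part["flow_ml_min"].iloc[0]),
                session_id=str(sid),
                chick_id=chick,
            )
        )
    return sessions
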