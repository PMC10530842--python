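"""Freezing-window and onset detection in thermocouple-style traces.

A freezing trace of the gel shows a characteristic morphology: an initial
cooling ramp, a supercooling dip below the equilibrium freezing point, a
sharp recalescence jump back up when nucleation releases latent heat, a
near-isothermal plateau while the latent heat is extracted, and a final
decay toward the bath temperature once the sample is fully solid.  This
module locates the plateau (the freezing window ``[t_ci, t_cf]``, whose
length is the freezing time ``t_c = t_cf - t_ci``) and the supercooling
nadir that defines the crystallization onset temperature.

Detection runs on a lightly smoothed copy (centered 3-point median) to
reject single-sample spikes; reported temperatures come from the raw
samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .solver import ProbeTrace

__all__ = [
    "ProbeTrace",
    "FreezingWindow",
    "DetectionError",
    "detect_freezing_window",
    "freezing_time",
    "onset_temperature",
    "read_trace_csv",
    "write_trace_csv",
]


class DetectionError(ValueError):
    """The trace does not exhibit the feature being searched for."""


@dataclass(frozen=True)
class FreezingWindow:
    """Start/end of the freezing plateau and its duration."""

    t_ci: float
    t_cf: float
    plateau_T: float = float("nan")

    def __post_init__(self) -> None:
        if self.t_cf < self.t_ci:
            raise ValueError(f"t_cf ({self.t_cf}) must not precede t_ci ({self.t_ci})")

    @property
    def t_c(self) -> float:
        return self.t_cf - self.t_ci


def freezing_time(window: FreezingWindow) -> float:
    """Freezing time ``t_c = t_cf - t_ci`` in seconds (non-negative)."""
    return window.t_c


def _median3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.copy()
    out = x.copy()
    stack = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stack, axis=0)
    return out


def _nadir_index(T_smooth: np.ndarray, below: float, jump: float,
                 horizon: int = 3) -> int | None:
    """First local minimum below ``below`` followed by a rise >= jump."""
    n = T_smooth.size
    for i in range(1, n - 1):
        if T_smooth[i] >= below:
            continue
        if T_smooth[i] > T_smooth[i - 1] or T_smooth[i] > T_smooth[i + 1]:
            continue  # not a local minimum
        ahead = T_smooth[i + 1: i + 1 + horizon]
        if ahead.size and np.max(ahead) >= T_smooth[i] + jump:
            return i
    return None


def detect_freezing_window(
    trace: ProbeTrace,
    T_f: float = 0.0,
    band: float = 0.5,
    min_dwell: int = 3,
    exit_drop: float = 2.0,
    exit_horizon: float = 30.0,
) -> FreezingWindow:
    """Locate the freezing plateau of a trace.

    ``t_ci`` is the first time the temperature jumps up into the band
    ``[T_f - band, T_f + band]`` after the supercooling nadir
    (recalescence); ``t_cf`` is the first subsequent time it falls below
    ``T_f - band`` for good, i.e. never re-enters the band and keeps
    decreasing (a sustained drop of at least ``exit_drop`` kelvin within
    ``exit_horizon`` seconds, which separates the plateau collapse from
    slow within-plateau drift).  Temperatures are degC.

    Raises :class:`DetectionError` when the trace shows no recalescence or
    no plateau exit.
    """
    t = trace.times
    T_raw = trace.temperatures_C
    T = _median3(T_raw)

    lo, hi = T_f - band, T_f + band
    m = _nadir_index(T, below=lo, jump=band)
    if m is None:
        raise DetectionError(
            "no supercooling nadir followed by recalescence found "
            f"(trace range {T_raw.min():.2f}..{T_raw.max():.2f} degC)"
        )

    below = T < lo
    in_band = (T >= lo) & (T <= hi)

    # permanent exit: first below-band sample never followed by a re-entry
    ever_band_after = np.zeros(T.size, dtype=bool)
    seen = False
    for j in range(T.size - 1, -1, -1):
        ever_band_after[j] = seen
        seen = seen or T[j] >= lo
    permanent = below & ~ever_band_after

    i_ci = None
    k_exit = None
    for i in np.flatnonzero(in_band[m:]) + m:
        after = np.flatnonzero(permanent[i:])
        k = int(after[0] + i) if after.size else None
        dwell_ok = (i + min_dwell <= T.size
                    and np.all(T[i: i + min_dwell] >= lo - 1e-12))
        resident = k is not None and np.all(T[i:k] >= lo - 1e-12)
        if dwell_ok or resident:
            i_ci, k_exit = int(i), k
            break
    if i_ci is None:
        raise DetectionError("recalescence found but no plateau dwell in the band")
    if k_exit is None:
        raise DetectionError("plateau never ends within the trace")

    # plateau collapse: the first permanent-exit sample followed by a
    # sustained drop; a very slow collapse falls back to the band exit
    i_cf = k_exit
    for j in np.flatnonzero(permanent) :
        if j < k_exit:
            continue
        seg = T[j:][t[j:] <= t[j] + exit_horizon]
        if seg.size and seg.min() <= T[j] - exit_drop:
            i_cf = int(j)
            break

    plateau_T = float(np.median(T_raw[i_ci:i_cf]))
    return FreezingWindow(t_ci=float(t[i_ci]), t_cf=float(t[i_cf]), plateau_T=plateau_T)


def onset_temperature(trace: ProbeTrace, jump: float = 1.0, horizon: int = 3) -> float:
    """Crystallization onset: temperature at the supercooling nadir (degC).

    The nadir is the first local minimum below 0 degC followed by a rise
    of at least ``jump`` kelvin within ``horizon`` samples (the
    recalescence signature).  The raw (unsmoothed) sample value at the
    nadir is returned.
    """
    T = _median3(trace.temperatures_C)
    m = _nadir_index(T, below=0.0, jump=jump, horizon=horizon)
    if m is None:
        raise DetectionError(
            "no supercooling minimum followed by recalescence "
            f"(trace range {trace.temperatures_C.min():.2f}.."
            f"{trace.temperatures_C.max():.2f} degC)"
        )
    # report the raw nadir in a small neighbourhood of the smoothed minimum
    lo = max(m - 1, 0)
    seg = trace.temperatures_C[lo: m + 2]
    return float(seg.min())


def read_trace_csv(path: str | Path, source: str = "experimental") -> ProbeTrace:
    """Read a time/temperature trace from CSV.

    Requires a header with ``time_s`` and ``T_degC`` columns; comma and
    semicolon dialects are auto-detected.
    """
    path = Path(path)
    text = path.read_text()
    delim = ";" if text.splitlines()[0].count(";") > text.splitlines()[0].count(",") else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    header = [h.strip() for h in rows[0]]
    if "time_s" not in header or "T_degC" not in header:
        raise ValueError(f"{path}: expected 'time_s' and 'T_degC' columns, got {header}")
    it, iT = header.index("time_s"), header.index("T_degC")
    data = np.array([[float(r[it]), float(r[iT])] for r in rows[1:] if r])
    return ProbeTrace(data[:, 0], data[:, 1], position=(np.nan, np.nan), source=source)


def write_trace_csv(trace: ProbeTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,T_degC`` CSV."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_s", "T_degC"])
        for ti, Ti in zip(trace.times, trace.temperatures_C):
            w.writerow([f"{ti:.6g}", f"{Ti:.6g}"])
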