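"""Freezing-rate to pore-size estimation.

The mean diameter of the solvent (ice) crystals that template the cryogel
pores is estimated from the local freezing rate through the empirical
correlation

    d_p [um] = 50 * v_c^(-0.25),   v_c in degC/s,

where ``v_c`` is the magnitude of the cooling rate during late-stage
solidification — the time window in which the local solid fraction
``theta_ph1`` passes from 0.96 to 0.99.  Slowly frozen regions grow large
crystals (large pores); rapidly frozen regions near the cooled walls stay
fine-pored.  Sample-level summaries use the axisymmetric volume average
(2*pi*r weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import T_ZERO_C, default_registry, phase_fraction
from .solver import AxiGrid, SimulationResult, _EnthalpyCurves

__all__ = [
    "PoreField",
    "pore_diameter",
    "freezing_rate_field",
    "volume_average",
    "pore_map",
]

#: Late-freezing solid-fraction window over which v_c is averaged.
RATE_WINDOW = (0.96, 0.99)


def pore_diameter(v_c):
    """Estimated solvent-crystal (pore) diameter in micrometers.

    ``d_p = 50 * v_c**-0.25`` with ``v_c`` the freezing rate in degC/s.
    Strictly decreasing in ``v_c``; quadrupling the rate twice (x16)
    halves the diameter.
    """
    v = np.asarray(v_c, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("freezing rate v_c must be positive and finite")
    out = 50.0 * v ** -0.25
    return float(out) if out.ndim == 0 else out


def _window_capacity(config, window: tuple[float, float]):
    """Window temperature bounds (K) and mean apparent capacity within.

    Inverts the solid-fraction profile to the window's temperature span
    and reads the enthalpy drop across it off the gel's nucleated-branch
    curve; their ratio is the mean volumetric apparent heat capacity a
    freezing cell presents while its solid fraction crosses the window.
    """
    lo, hi = window
    cur = _EnthalpyCurves(config, default_registry())
    xs = np.linspace(0.0, 1.0, 4001)
    th = phase_fraction(config.T_f - 2.0 * config.dT_trans_K * xs,
                        config.T_f, config.dT_trans_K, True, config.theta_profile)
    x_lo, x_hi = np.interp([lo, hi], th, xs)
    T_enter = config.T_f - 2.0 * config.dT_trans_K * x_lo  # theta = lo
    T_exit = config.T_f - 2.0 * config.dT_trans_K * x_hi  # theta = hi
    dH = np.interp(T_enter, cur.Tg, cur.H_nuc) - np.interp(T_exit, cur.Tg, cur.H_nuc)
    C_win = dH / (T_enter - T_exit)
    return cur, T_enter, T_exit, C_win


def freezing_rate_field(
    result: SimulationResult,
    window: tuple[float, float] = RATE_WINDOW,
    method: str = "window_mean",
) -> np.ndarray:
    """Per-gel-cell freezing rate v_c (degC/s) from the stored history.

    For each gel cell the cooling rate dT/dt (centered finite differences)
    is averaged with trapezoidal weighting over the time window in which
    the cell's solid fraction lies in ``window``; cells that never
    complete freezing are returned as NaN.

    Fast-frozen cells (near the cooled walls) cross the whole window
    within one time step, where a raw finite difference would conflate
    the in-window rate with the much faster post-plateau crash.  For
    those degenerate windows the rate is recovered from the energy
    balance instead: the volumetric heat-extraction rate across the
    crossing step (enthalpy drop per unit time, read off the gel's
    enthalpy curve) divided by the window's mean apparent heat capacity —
    i.e. the same |dT/dt| the window would show if it were resolved.

    ``method="endpoint_slope"`` uses the secant slope between the first
    and last window samples for resolved windows.
    """
    lo, hi = window
    times = result.times
    T = result.T_history
    theta = result.theta_history
    n_cells = T.shape[1]
    vc = np.full(n_cells, np.nan)

    completed = theta[-1] >= hi
    if not completed.any():
        raise ValueError("no gel cell completed freezing; cannot form a rate field")

    cur, _, _, C_win = _window_capacity(result.config, window)
    T_K = T + T_ZERO_C
    H_nuc = np.interp(T_K, cur.Tg, cur.H_nuc)
    H_liq = np.interp(T_K, cur.Tg, cur.H_liq)
    H = np.where(theta > 0, H_nuc, H_liq)

    dTdt = np.gradient(T, times, axis=0)
    for i in range(n_cells):
        if not completed[i]:
            continue
        th = theta[:, i]
        mask = (th >= lo) & (th < hi)
        idx = np.flatnonzero(mask)
        if idx.size >= 2 and times[idx[-1]] > times[idx[0]]:
            ti = times[idx]
            if method == "endpoint_slope":
                vc[i] = abs(T[idx[-1], i] - T[idx[0], i]) / (ti[-1] - ti[0])
            else:
                rate = np.abs(dTdt[idx, i])
                vc[i] = np.trapezoid(rate, ti) / (ti[-1] - ti[0])
        else:
            # degenerate window: energy-based rate across the crossing step
            j = max(int(np.argmax(th >= hi)), 1)
            q = (H[j - 1, i] - H[j, i]) / (times[j] - times[j - 1])
            vc[i] = max(q, 0.0) / C_win
            if vc[i] <= 0:  # no extraction recorded: fall back to the slope
                vc[i] = abs(T[j, i] - T[j - 1, i]) / (times[j] - times[j - 1])
    return vc


def volume_average(field: np.ndarray, grid: AxiGrid, region: str = "cryogel",
                   cells: np.ndarray | None = None) -> float:
    """2*pi*r-weighted (cell-volume-weighted) average over one region.

    ``field`` may be given either on the grid's full active-cell numbering
    or on the region's cells directly (pass their flat indices via
    ``cells`` — e.g. ``result.cryogel_cells``).  Missing (NaN) cells raise
    an error listing them.
    """
    field = np.asarray(field, dtype=float)
    vol = grid.cell_volume_flat
    mask = grid.region_mask_flat(region)
    if field.size == grid.n_active:
        vals = field[mask]
        weights = vol[mask]
    else:
        if cells is None:
            cells = np.flatnonzero(mask)
        if field.size != cells.size:
            raise ValueError(
                f"field has {field.size} values but region {region!r} has {cells.size} cells"
            )
        vals = field
        weights = vol[cells]
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise ValueError(f"field undefined on {bad.size} cells of {region!r}: {bad[:10].tolist()}")
    return float(np.sum(vals * weights) / np.sum(weights))


@dataclass
class PoreField:
    """Per-cell freezing rate and estimated crystal diameter on the gel."""

    grid: AxiGrid
    cells: np.ndarray  # flat active-cell indices of the gel cells
    v_c: np.ndarray  # degC/s
    d_p: np.ndarray  # micrometers
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def mean_diameter(self) -> float:
        """Volume-averaged pore diameter over the gel, micrometers."""
        return volume_average(self.d_p, self.grid, "cryogel", cells=self.cells)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular r-z field (radius on x, height on y convention)."""
        r, z = self.grid.cell_coords()
        return pd.DataFrame({
            "r_mm": r[self.cells] * 1e3,
            "z_mm": z[self.cells] * 1e3,
            "vc_degC_per_s": self.v_c,
            "dp_um": self.d_p,
        })

    def plot(self, path=None, vmin: float = 30.0, vmax: float = 170.0):
        """Render the pore-size field as an r-z heat map.

        Radius on the x axis, height above the sample base on the y axis,
        diameter on a color scale (default range 30-170 um).  Saves to
        ``path`` when given, otherwise returns the matplotlib figure.
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        rs = np.unique(df.r_mm)
        zs = np.unique(df.z_mm)
        img = np.full((zs.size, rs.size), np.nan)
        ir = np.searchsorted(rs, df.r_mm)
        iz = np.searchsorted(zs, df.z_mm)
        img[iz, ir] = df.dp_um
        fig, ax = plt.subplots(figsize=(4, 4))
        m = ax.pcolormesh(rs, zs - zs.min(), img, cmap="turbo",
                          vmin=vmin, vmax=vmax, shading="nearest")
        fig.colorbar(m, ax=ax, label="pore diameter (um)")
        ax.set_xlabel("radius (mm)")
        ax.set_ylabel("height (mm)")
        ax.set_aspect("equal")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig


def pore_map(result: SimulationResult, window: tuple[float, float] = RATE_WINDOW,
             method: str = "window_mean") -> PoreField:
    """Compose the freezing-rate field and the diameter correlation.

    Requires the simulation to have frozen the whole gel; raises if any
    gel cell never completed freezing.
    """
    vc = freezing_rate_field(result, window, method)
    missing = ~np.isfinite(vc)
    if missing.any():
        raise ValueError(
            f"{missing.sum()} gel cells never completed freezing; "
            "extend total_time or lower the bath set point"
        )
    dp = pore_diameter(vc)
    # flag degenerate-window cells (single-step fallback)
    theta = result.theta_history
    lo, hi = window
    flags = np.array([
        np.count_nonzero((theta[:, i] >= lo) & (theta[:, i] < hi)) < 2
        for i in range(theta.shape[1])
    ])
    return PoreField(result.grid, result.cryogel_cells, vc, dp, flags)
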