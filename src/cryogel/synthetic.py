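"""Synthetic data generators and analytic oracles.

No public dataset accompanies the freezing/compression experiments this
package models, so every analysis stage is exercised on synthetic inputs
with known ground truth:

* :func:`stefan_oracle` — the classical two-phase Stefan (Neumann)
  similarity solution for a freezing half-space, used to verify the
  phase-change solver in 1-D slab mode;
* :func:`synth_probe_trace` — thermocouple-style traces with the full
  freezing morphology (cooling ramp, supercooling dip, recalescence jump,
  plateau, post-freeze decay) and exactly known window/onset parameters;
* :func:`render_cylinder_sequence` — silhouette image sequences of a
  compressed cylinder under the same pinhole projection the metrology
  pipeline corrects for, with exact per-frame geometry.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfc

from .imaging import CameraModel, FrameMeasurement, depth_offset, scale_at
from .materials import MaterialRegistry, PropertyTable
from .solver import ProbeTrace

__all__ = [
    "StefanParams",
    "TrajectorySpec",
    "constant_property_registry",
    "neumann_lambda",
    "stefan_oracle",
    "synth_probe_trace",
    "render_cylinder_sequence",
    "compression_trajectory",
    "relaxation_force",
]

T_F_C = 0.0  # freezing front for the water oracle, degC


def constant_property_registry() -> MaterialRegistry:
    """Synthetic constant-property water/ice registry for verification.

    The Neumann similarity solution assumes temperature-independent
    properties and equal solid/liquid density (no volume change), so the
    solver comparison uses this idealized registry rather than the shipped
    handbook tables.
    """
    reg = MaterialRegistry()
    consts = {
        ("water", "density"): 1000.0,
        ("water", "conductivity"): 0.561,
        ("water", "specific_heat"): 4200.0,
        ("water", "latent_heat"): 334000.0,
        ("ice", "density"): 1000.0,  # equal-density idealization
        ("ice", "conductivity"): 2.22,
        ("ice", "specific_heat"): 2050.0,
    }
    for (mat, prop), v in consts.items():
        reg.register(PropertyTable(mat, prop, np.array([273.15]), np.array([v])))
    return reg


@dataclass(frozen=True)
class StefanParams:
    """Conditions of the 1-D freezing half-space benchmark (degC, m)."""

    T_initial_C: float = 5.0
    T_boundary_C: float = -19.0
    slab_length: float = 0.05
    material: str = "water"

    def __post_init__(self) -> None:
        if not (self.T_boundary_C < T_F_C < self.T_initial_C):
            raise ValueError("need T_boundary < T_f < T_initial")
        if self.slab_length <= 0:
            raise ValueError("slab_length must be positive")


def _oracle_props(registry: MaterialRegistry | None = None):
    reg = registry or constant_property_registry()
    T0 = 273.15
    k_s = reg.property_at("ice", "conductivity", T0)
    k_l = reg.property_at("water", "conductivity", T0)
    c_s = reg.property_at("ice", "specific_heat", T0)
    c_l = reg.property_at("water", "specific_heat", T0)
    rho = reg.property_at("water", "density", T0)
    lam = reg.property_at("water", "latent_heat", T0)
    return k_s, k_l, c_s, c_l, rho, lam


def neumann_lambda(params: StefanParams,
                   registry: MaterialRegistry | None = None,
                   xtol: float = 1e-12) -> float:
    """Similarity constant of the two-phase Neumann solution.

    Root of the interface energy balance

        k_s dT_s/dx - k_l dT_l/dx = rho * lambda * ds/dt

    evaluated on the similarity profiles, solved by bracketed root
    finding to ``xtol``.
    """
    k_s, k_l, c_s, c_l, rho, lam = _oracle_props(registry)
    a_s = k_s / (rho * c_s)
    a_l = k_l / (rho * c_l)
    nu = math.sqrt(a_s / a_l)
    dTs = T_F_C - params.T_boundary_C
    dTl = params.T_initial_C - T_F_C

    def f(L: float) -> float:
        solid = k_s * dTs * math.exp(-L * L) / (erf(L) * math.sqrt(math.pi * a_s))
        liq = (k_l * dTl * math.exp(-(L * nu) ** 2)
               / (erfc(L * nu) * math.sqrt(math.pi * a_l)))
        return solid - liq - rho * lam * L * math.sqrt(a_s)

    return float(brentq(f, 1e-9, 5.0, xtol=xtol))


def stefan_oracle(params: StefanParams, t: float,
                  registry: MaterialRegistry | None = None):
    """Analytic frozen-front position and temperature profile at time t.

    Returns ``(s, profile)`` where ``s = 2 * Lambda * sqrt(alpha_s * t)``
    is the front depth in meters and ``profile(x)`` gives the temperature
    in degC at depth ``x`` (vectorized).  At ``t = 0`` the front is at the
    cooled surface and the profile is uniform at the initial temperature.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    k_s, k_l, c_s, c_l, rho, lam = _oracle_props(registry)
    a_s = k_s / (rho * c_s)
    a_l = k_l / (rho * c_l)
    nu = math.sqrt(a_s / a_l)
    L = neumann_lambda(params, registry)
    s = 2.0 * L * math.sqrt(a_s * t)

    Tb, Ti = params.T_boundary_C, params.T_initial_C

    def profile(x):
        x = np.asarray(x, dtype=float)
        if t == 0:
            out = np.full_like(x, Ti)
            return float(out) if out.ndim == 0 else out
        us = x / (2.0 * math.sqrt(a_s * t))
        ul = x / (2.0 * math.sqrt(a_l * t))
        T_solid = Tb + (T_F_C - Tb) * erf(us) / erf(L)
        T_liq = Ti - (Ti - T_F_C) * erfc(ul) / erfc(L * nu)
        out = np.where(x <= s, T_solid, T_liq)
        return float(out) if out.ndim == 0 else out

    return s, profile


# ---------------------------------------------------------------------------
# thermocouple-style traces
# ---------------------------------------------------------------------------

def synth_probe_trace(
    t_ci: float,
    t_cf: float,
    nadir_C: float = -8.0,
    T_start_C: float = 85.0,
    T_end_C: float = -19.0,
    T_f_C: float = 0.0,
    sampling: float = 1.5,
    tau_cool: float | None = None,
    tau_post: float = 25.0,
    post_duration: float = 120.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ProbeTrace:
    """Piecewise freezing trace with exactly known window and onset.

    The trace cools exponentially from ``T_start_C`` to the supercooling
    nadir one sample before ``t_ci``, jumps to the freezing plateau held
    exactly at ``T_f_C`` on ``[t_ci, t_cf]``, then decays toward
    ``T_end_C``.  Optional Gaussian noise (``noise_sigma`` kelvin) is
    seeded and reproducible.
    """
    if not t_ci < t_cf:
        raise ValueError("need t_ci < t_cf")
    if nadir_C >= T_f_C:
        raise ValueError("nadir must lie below the freezing temperature")
    if t_ci < 2 * sampling:
        raise ValueError("t_ci too early to fit a cooling ramp and nadir")

    # snap the window to the sampling grid so the nadir and the plateau
    # edges are actually sampled (shift <= half a sampling interval)
    t_ci = round(t_ci / sampling) * sampling
    t_cf = max(round(t_cf / sampling) * sampling, t_ci + sampling)
    t_nadir = t_ci - sampling
    if tau_cool is None:
        tau_cool = max(t_nadir / 4.0, sampling)
    times = np.arange(0.0, t_cf + post_duration + 0.5 * sampling, sampling)
    T = np.empty_like(times)

    ramp = times <= t_nadir + 1e-9
    g = (np.exp(-times[ramp] / tau_cool) - math.exp(-t_nadir / tau_cool)) / (
        1.0 - math.exp(-t_nadir / tau_cool)
    )
    T[ramp] = nadir_C + (T_start_C - nadir_C) * g

    jump = (~ramp) & (times < t_ci)
    T[jump] = nadir_C + (T_f_C - nadir_C) * (times[jump] - t_nadir) / (t_ci - t_nadir)

    plateau = (times >= t_ci - 1e-9) & (times <= t_cf + 1e-9)
    T[plateau] = T_f_C

    tail = times > t_cf + 1e-9
    T[tail] = T_end_C + (T_f_C - T_end_C) * np.exp(-(times[tail] - t_cf) / tau_post)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        T = T + rng.normal(0.0, noise_sigma, size=T.shape)

    return ProbeTrace(times, T, position=(np.nan, np.nan), source="synthetic",
                      sampling_interval=sampling)


# ---------------------------------------------------------------------------
# rendered compression sequences
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Ground-truth geometry trajectory and capture setup for rendering.

    ``height_fn`` / ``diameter_fn`` give the cylinder geometry in mm as a
    function of time in seconds.  Frames are captured every
    ``frame_interval`` seconds (109 ms by default, the burst rate of the
    reference capture setup).
    """

    height_fn: Callable[[float], float]
    diameter_fn: Callable[[float], float]
    duration: float
    camera: CameraModel
    frame_interval: float = 0.109
    image_size: tuple[int, int] = (960, 1280)  # rows, cols
    noise_sigma: float = 0.0
    background: int = 230
    foreground: int = 20

    def frame_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5 * self.frame_interval,
                         self.frame_interval)


def _render_frame(spec: TrajectorySpec, h_mm: float, d_mm: float,
                  rng: np.random.Generator | None) -> np.ndarray:
    """Rasterize one silhouette under the pinhole projection.

    Every surface point at lateral offset ``x`` sits ``sqrt(R^2-x^2)``
    nearer the lens and is scaled by the local conversion factor; the
    silhouette column at that offset therefore shows the cylinder's full
    height at the magnified scale — exactly the geometry the metrology
    pipeline inverts.
    """
    cam = spec.camera
    R = d_mm / 2.0
    H = h_mm
    rows, cols = spec.image_size
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    if R >= cam.working_distance:
        raise ValueError("cylinder radius reaches the lens")

    n = max(2048, int(16 * R * cam.base_scale))
    xs = np.linspace(-R, R, n)
    d_near = depth_offset(R, np.abs(xs))
    scale = scale_at(cam, d_near)
    u = xs * scale  # px from center (lateral position magnified at its depth)
    v_half = (H / 2.0) * scale

    if np.max(np.abs(u)) >= cx or np.max(v_half) >= cy:
        raise ValueError("cylinder silhouette exceeds the image frame")

    col = np.rint(cx + u).astype(int)
    vmax = np.zeros(cols)
    np.maximum.at(vmax, col, v_half)
    covered = vmax > 0
    row_idx = np.arange(rows)[:, None]
    mask = covered[None, :] & (np.abs(row_idx - cy) <= vmax[None, :])

    img = np.full((rows, cols), float(spec.background))
    img[mask] = float(spec.foreground)
    if spec.noise_sigma > 0 and rng is not None:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_cylinder_sequence(spec: TrajectorySpec, seed: int = 0):
    """Render a compression sequence and its exact ground truth.

    Returns ``(images, truth, times)`` where ``truth`` is a list of
    :class:`~cryogel.imaging.FrameMeasurement` with the exact per-frame
    geometry the renderer used.
    """
    rng = np.random.default_rng(seed)
    times = spec.frame_times()
    images, truth = [], []
    for t in times:
        h = float(spec.height_fn(t))
        d = float(spec.diameter_fn(t))
        if h <= 0 or d <= 0:
            raise ValueError("trajectory produced non-positive geometry")
        images.append(_render_frame(spec, h, d, rng))
        truth.append(FrameMeasurement(t=float(t), height_mm=h, diameter_mm=d))
    return images, truth, times


def compression_trajectory(
    h0_mm: float = 10.0,
    d0_mm: float = 20.0,
    strain: float = 0.10,
    delta_V_mL: float = 0.4,
    ramp_time: float = 5.0,
):
    """Height/diameter trajectory of a compression with water release.

    The height ramps linearly to ``(1 - strain) * h0`` over ``ramp_time``
    while the total volume decreases linearly by ``delta_V_mL`` (the water
    expelled from the pores); the diameter follows from the cylinder
    model.  Returns ``(height_fn, diameter_fn)`` in mm.
    """
    V0 = math.pi * (d0_mm / 2.0) ** 2 * h0_mm / 1000.0
    if delta_V_mL >= V0:
        raise ValueError("cannot expel more volume than the sample holds")

    def progress(t: float) -> float:
        return min(max(t / ramp_time, 0.0), 1.0)

    def height_fn(t: float) -> float:
        return h0_mm * (1.0 - strain * progress(t))

    def diameter_fn(t: float) -> float:
        V = V0 - delta_V_mL * progress(t)
        return 2.0 * math.sqrt(V * 1000.0 / (math.pi * height_fn(t)))

    return height_fn, diameter_fn


def relaxation_force(
    times,
    t_contact: float = 3.0,
    ramp_time: float = 5.0,
    peak_N: float = 0.848,
    residual_N: float = 0.3,
    tau: float = 60.0,
):
    """Simple exponential-relaxation force fixture (no constitutive model).

    Zero before probe contact, linear ramp to the peak during compression,
    then exponential decay toward a residual — the qualitative shape of an
    unconfined stress-relaxation test, for exercising the stress pipeline.
    """
    t = np.asarray(times, dtype=float)
    F = np.zeros_like(t)
    ramp = (t >= t_contact) & (t < t_contact + ramp_time)
    F[ramp] = peak_N * (t[ramp] - t_contact) / ramp_time
    relax = t >= t_contact + ramp_time
    F[relax] = residual_N + (peak_N - residual_N) * np.exp(
        -(t[relax] - t_contact - ramp_time) / tau
    )
    return F
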