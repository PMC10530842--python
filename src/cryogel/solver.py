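"""Axisymmetric transient freezing solver for cryogel production.

Models the solid domains of the production setup — the gel sample inside
an aluminum mold closed by a PLA cap, optionally resting on a Pyrex
beaker — as a 2-D axisymmetric (r-z) transient heat-conduction problem.
The surrounding glycol bath and air are represented by Robin (convective)
boundary conditions instead of a conjugate CFD model: bath-wetted surfaces
exchange heat with an ambient equal to the chiller set point plus a fixed
contact offset, air-exposed surfaces with the cooler's air temperature.

Phase change in the gel uses a conservative enthalpy formulation: each
cell carries a volumetric enthalpy ``H`` and its temperature is read off a
precomputed monotone H(T) curve.  The gel has two branches:

* a *liquid* branch (supercooled liquid below the freezing point — the gel
  retains its full latent heat until it nucleates), and
* a *nucleated* branch whose heat capacity is the apparent-heat-capacity
  mixture of :func:`cryogel.materials.mix_properties`, i.e. sensible heat
  plus the latent pulse spread over the transition interval.

A cell switches branch the first time its temperature reaches the
crystallization onset ``Tc`` (about -8 degC experimentally).  At that
moment its enthalpy corresponds to a point well up the nucleated branch,
so the cell temperature relaxes upward (recalescence) at the rate set by
the nucleation source ``Qn = lambda * k_i * (T_f - T*)`` until it lands on
the equilibrium curve; freezing then proceeds on the plateau governed by
conduction.  Because sensible and latent heat live in the single enthalpy
variable, the latent budget is shared between the nucleation burst and the
plateau and can never be released twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import (
    MaterialRegistry,
    T_ZERO_C,
    default_registry,
    latent_pulse,
    phase_fraction,
)

__all__ = [
    "ProcessConfig",
    "ConfigurationError",
    "AxiGrid",
    "ThermalState",
    "ProbeTrace",
    "SimulationResult",
    "build_grid",
    "build_slab_grid",
    "nucleation_source",
    "advance",
    "run_simulation",
    "extract_probe",
]

# Region codes for the grid's region map.
EXCLUDED, CRYOGEL, CAP, MOLD, BEAKER = 0, 1, 2, 3, 4
REGION_NAMES = {EXCLUDED: "excluded", CRYOGEL: "cryogel", CAP: "cap", MOLD: "mold", BEAKER: "beaker"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}
REGION_MATERIAL = {CAP: "pla", MOLD: "aluminum", BEAKER: "pyrex"}


class ConfigurationError(ValueError):
    """Invalid process configuration or grid resolution."""


@dataclass
class ProcessConfig:
    """Operating conditions, geometry and numerics of a production run.

    Temperatures are in degC (converted internally), geometry in meters,
    times in seconds.  Defaults reproduce the reference production setup:
    gel poured at 85 degC into a 95 degC mold, PLA cap at 25 degC, bath
    contact temperature 2 K above the chiller set point, cooler air at
    10 degC.
    """

    bath_setpoint_C: float = -19.0
    bath_contact_offset_K: float = 2.0
    T_air_C: float = 10.0
    T_wall_C: float = 15.0  # cooler top wall; unused without the fluid domains
    T_init_cryogel_C: float = 85.0
    T_init_cap_C: float = 25.0
    T_init_mold_C: float = 95.0
    Tc_C: float = -8.0
    T_f_C: float = 0.0
    dT_trans_K: float = 0.5
    k_i: float = 430.0  # nucleation-rate constant, kg/(m^3 s K)
    h_bath: float = 150.0  # W/(m^2 K), free convection in the glycol bath
    # (calibrated once against the measured freezing-time scale; see docs)
    h_air: float = 10.0  # W/(m^2 K), natural convection in air
    # effective conductivity multiplier of the *liquid* gel, representing
    # natural convection in the solution before it gels/freezes; 1 = pure
    # conduction (use 1 for Stefan-limit verification)
    kappa_liquid_factor: float = 8.0
    # geometry (m)
    sample_radius: float = 0.010
    sample_height: float = 0.010
    mold_outer_radius: float = 0.015
    mold_base_thickness: float = 0.005
    cap_radius: float = 0.015
    cap_thickness: float = 0.005
    beaker_thickness: float = 0.0033
    beaker_radius: float = 0.054
    include_beaker: bool = False
    immersion_depth: float = 0.015  # bath level above the mold base bottom
    # numerics
    grid_size: float = 0.001
    dt: float = 0.5
    total_time: float = 1200.0
    trace_interval: float = 1.5
    probe_points: tuple = ((0.0, 0.0015), (0.0067, 0.0015), (0.0096, 0.0015))
    theta_profile: str = "smooth"

    def __post_init__(self) -> None:
        # Tc == T_f disables supercooling (used for Stefan-limit verification)
        if not (self.bath_setpoint_C < self.Tc_C <= self.T_f_C):
            raise ConfigurationError(
                f"need bath_setpoint < Tc <= T_f, got {self.bath_setpoint_C} / "
                f"{self.Tc_C} / {self.T_f_C}"
            )
        if self.h_bath <= 0 or self.h_air <= 0:
            raise ConfigurationError("convection coefficients must be positive")
        if self.kappa_liquid_factor < 1.0:
            raise ConfigurationError("kappa_liquid_factor must be >= 1")
        for name in ("sample_radius", "sample_height", "mold_outer_radius",
                     "mold_base_thickness", "cap_radius", "cap_thickness",
                     "grid_size", "dt", "total_time", "trace_interval", "dT_trans_K"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.mold_outer_radius <= self.sample_radius:
            raise ConfigurationError("mold outer radius must exceed sample radius")

    # convenience: kelvin values
    @property
    def T_f(self) -> float:
        return self.T_f_C + T_ZERO_C

    @property
    def Tc(self) -> float:
        return self.Tc_C + T_ZERO_C

    @property
    def bath_contact_T(self) -> float:
        return self.bath_setpoint_C + self.bath_contact_offset_K + T_ZERO_C


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass
class AxiGrid:
    """Structured axisymmetric (or 1-D slab) cell grid with region labels.

    ``region`` is an (nz, nr) integer map using the module-level region
    codes.  Cells labelled ``excluded`` do not participate in the solve.
    Boundary faces carry an environment tag (``bath``, ``air`` or
    ``adiabatic``) assigned by the grid builder.
    """

    r_faces: np.ndarray
    z_faces: np.ndarray
    region: np.ndarray
    cell_volume: np.ndarray
    axisymmetric: bool = True
    # flattened connectivity for the active cells, filled by _finalize
    index: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    n_active: int = 0
    face_a: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    face_b: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    face_area: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    face_da: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    face_db: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    bface_cell: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    bface_area: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    bface_d: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    bface_env: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    def region_volume(self, name: str) -> float:
        return float(self.cell_volume[self.region == REGION_CODES[name]].sum())

    def region_mask_flat(self, name: str) -> np.ndarray:
        """Boolean mask over active-cell numbering for one region."""
        code = REGION_CODES[name]
        mask = np.zeros(self.n_active, dtype=bool)
        sel = (self.region == code) & (self.index >= 0)
        mask[self.index[sel]] = True
        return mask

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, z) centers of the active cells in flat numbering."""
        nz, nr = self.region.shape
        rr, zz = np.meshgrid(self.r_centers, self.z_centers)
        act = self.index >= 0
        r = np.empty(self.n_active)
        z = np.empty(self.n_active)
        r[self.index[act]] = rr[act]
        z[self.index[act]] = zz[act]
        return r, z


def _subdivide(edges: Sequence[float], h: float) -> np.ndarray:
    """Face coordinates covering ``edges`` with spacing <= h, faces on edges."""
    faces = [float(edges[0])]
    for a, b in zip(edges[:-1], edges[1:]):
        n = max(2, int(np.ceil((b - a) / h)))
        faces.extend(np.linspace(a, b, n + 1)[1:])
    return np.array(faces)


def _finalize(grid: AxiGrid, env_of_bface) -> AxiGrid:
    """Fill connectivity arrays: interior faces, boundary faces, volumes."""
    region = grid.region
    nz, nr = region.shape
    active = region != EXCLUDED
    index = np.full(region.shape, -1, dtype=int)
    index[active] = np.arange(active.sum())
    grid.index = index
    grid.n_active = int(active.sum())

    r_f, z_f = grid.r_faces, grid.z_faces
    dr = np.diff(r_f)
    dz = np.diff(z_f)

    fa, fb, farea, fda, fdb = [], [], [], [], []
    bcell, barea, bd, benv = [], [], [], []

    def radial_area(i_face: int, j: int) -> float:
        if grid.axisymmetric:
            return 2.0 * np.pi * r_f[i_face] * dz[j]
        return 1.0

    def axial_area(i: int) -> float:
        if grid.axisymmetric:
            return np.pi * (r_f[i + 1] ** 2 - r_f[i] ** 2)
        return 1.0

    for j in range(nz):
        for i in range(nr):
            if not active[j, i]:
                continue
            me = index[j, i]
            # east neighbour (i+1)
            if i + 1 < nr and active[j, i + 1]:
                fa.append(me)
                fb.append(index[j, i + 1])
                farea.append(radial_area(i + 1, j))
                fda.append(0.5 * dr[i])
                fdb.append(0.5 * dr[i + 1])
            # north neighbour (j+1)
            if j + 1 < nz and active[j + 1, i]:
                fa.append(me)
                fb.append(index[j + 1, i])
                farea.append(axial_area(i))
                fda.append(0.5 * dz[j])
                fdb.append(0.5 * dz[j + 1])
            # boundary faces (domain edge or excluded neighbour)
            rc = 0.5 * (r_f[i] + r_f[i + 1])
            zc = 0.5 * (z_f[j] + z_f[j + 1])
            sides = []
            if i + 1 == nr or not active[j, i + 1]:
                sides.append((radial_area(i + 1, j), 0.5 * dr[i], r_f[i + 1], zc))
            if i == 0:
                pass  # symmetry axis (axisym) / handled by env for slab below
            elif not active[j, i - 1]:
                sides.append((radial_area(i, j), 0.5 * dr[i], r_f[i], zc))
            if not grid.axisymmetric and i == 0:
                sides.append((radial_area(0, j), 0.5 * dr[i], r_f[0], zc))
            if j + 1 == nz or not active[j + 1, i]:
                sides.append((axial_area(i), 0.5 * dz[j], rc, z_f[j + 1]))
            if j == 0 or not active[j - 1, i]:
                sides.append((axial_area(i), 0.5 * dz[j], rc, z_f[j]))
            for area, d, rf, zf in sides:
                env = env_of_bface(rf, zf)
                if env == "adiabatic" or area == 0.0:
                    continue
                bcell.append(me)
                barea.append(area)
                bd.append(d)
                benv.append(env)

    grid.face_a = np.array(fa, dtype=int)
    grid.face_b = np.array(fb, dtype=int)
    grid.face_area = np.array(farea)
    grid.face_da = np.array(fda)
    grid.face_db = np.array(fdb)
    grid.bface_cell = np.array(bcell, dtype=int)
    grid.bface_area = np.array(barea)
    grid.bface_d = np.array(bd)
    grid.bface_env = np.array(benv)
    return grid


def build_grid(config: ProcessConfig) -> AxiGrid:
    """Build the axisymmetric production grid from the configuration.

    The region map reproduces the solid domains of the setup: gel sample
    (``sample_radius`` x ``sample_height``) sitting on the mold base,
    surrounded by the mold wall out to ``mold_outer_radius``, closed from
    above by the PLA cap plate, optionally resting on the beaker bottom.
    Cell faces are aligned with every material interface.
    """
    c = config
    base = c.mold_base_thickness
    z_sample_top = base + c.sample_height
    z_top = z_sample_top + c.cap_thickness
    r_edges = sorted({0.0, c.sample_radius, c.mold_outer_radius, c.cap_radius})
    z_edges = [0.0, base, z_sample_top, z_top]
    z0 = 0.0
    if c.include_beaker:
        z0 = -c.beaker_thickness
        z_edges = [z0] + z_edges
        r_edges = sorted(set(r_edges) | {c.beaker_radius})

    r_faces = _subdivide(r_edges, c.grid_size)
    z_faces = _subdivide(z_edges, c.grid_size)
    rc = 0.5 * (r_faces[:-1] + r_faces[1:])
    zc = 0.5 * (z_faces[:-1] + z_faces[1:])
    rr, zz = np.meshgrid(rc, zc)

    region = np.full(rr.shape, EXCLUDED, dtype=int)
    region[(zz > z0) & (zz < base) & (rr < c.mold_outer_radius)] = MOLD
    region[(zz > base) & (zz < z_sample_top) & (rr < c.mold_outer_radius)] = MOLD
    region[(zz > base) & (zz < z_sample_top) & (rr < c.sample_radius)] = CRYOGEL
    region[(zz > z_sample_top) & (zz < z_top) & (rr < c.cap_radius)] = CAP
    if c.include_beaker:
        region[(zz > z0) & (zz < 0.0) & (rr < c.beaker_radius)] = BEAKER

    for code, name in REGION_NAMES.items():
        if code == EXCLUDED:
            continue
        if code == BEAKER and not c.include_beaker:
            continue
        if not (region == code).any():
            raise ConfigurationError(f"grid resolution too coarse to resolve region {name!r}")

    dzs = np.diff(z_faces)
    vol = (np.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2))[None, :] * dzs[:, None]
    grid = AxiGrid(r_faces, z_faces, region, vol, axisymmetric=True)

    immersion = c.immersion_depth

    def env(rf: float, zf: float) -> str:
        # exterior faces: bath below the immersion level, air above
        return "bath" if zf <= immersion + 1e-12 else "air"

    return _finalize(grid, env)


def build_slab_grid(length: float, n_cells: int, cold_side: str = "bath") -> AxiGrid:
    """1-D Cartesian slab of gel/water for solver verification.

    The slab spans ``[0, length]`` along z; the ``z = 0`` face is the
    cooled (Robin) boundary and the far face is adiabatic.  Used with
    nucleation disabled to compare against the analytic two-phase Stefan
    (Neumann) solution.
    """
    if length <= 0 or n_cells < 2:
        raise ConfigurationError("slab needs positive length and >= 2 cells")
    z_faces = np.linspace(0.0, length, n_cells + 1)
    r_faces = np.array([0.0, 1.0])  # unit cross-section
    region = np.full((n_cells, 1), CRYOGEL, dtype=int)
    vol = np.diff(z_faces)[:, None] * 1.0
    grid = AxiGrid(r_faces, z_faces, region, vol, axisymmetric=False)

    def env(rf: float, zf: float) -> str:
        if abs(zf) < 1e-15:
            return cold_side
        if abs(zf - length) < 1e-15:
            return "adiabatic"
        return "adiabatic"  # lateral faces of the 1-D column

    return _finalize(grid, env)


# ---------------------------------------------------------------------------
# enthalpy curves
# ---------------------------------------------------------------------------

class _EnthalpyCurves:
    """Precomputed monotone volumetric-enthalpy curves H(T) per material.

    The gel gets two branches (liquid incl. supercooled, and nucleated
    with the latent pulse); other materials get a single sensible curve.
    All curves share the same temperature grid and a common additive
    reference so enthalpy is continuous when a gel cell nucleates.
    """

    def __init__(self, config: ProcessConfig, registry: MaterialRegistry,
                 region_codes=()):
        c = config
        Tmin = min(c.bath_setpoint_C, -45.0) + T_ZERO_C
        Tmax = max(c.T_init_mold_C, c.T_init_cryogel_C, 25.0) + 20.0 + T_ZERO_C
        self.Tg = np.linspace(Tmin, Tmax, 6000)
        dT = self.Tg[1] - self.Tg[0]
        reg = registry

        # nucleated gel branch: apparent-heat-capacity mixture
        theta = phase_fraction(self.Tg, c.T_f, c.dT_trans_K, True, c.theta_profile)
        rho1 = reg.property_at("ice", "density", self.Tg)
        rho2 = reg.property_at("water", "density", self.Tg)
        cp1 = reg.property_at("ice", "specific_heat", self.Tg)
        cp2 = reg.property_at("water", "specific_heat", self.Tg)
        lam = reg.property_at("water", "latent_heat", c.T_f)
        rho_mix = theta * rho1 + (1 - theta) * rho2
        C_sens = theta * rho1 * cp1 + (1 - theta) * rho2 * cp2
        C_nuc = C_sens + rho_mix * lam * latent_pulse(self.Tg, c.T_f, c.dT_trans_K)
        self.C_nuc = C_nuc
        self.H_nuc = np.concatenate([[0.0], np.cumsum(0.5 * (C_nuc[1:] + C_nuc[:-1]) * dT)])

        # liquid branch: pure liquid sensible heat, anchored to the
        # nucleated branch at/above T_f (same energy reference)
        C_liq = rho2 * cp2
        H_liq = np.concatenate([[0.0], np.cumsum(0.5 * (C_liq[1:] + C_liq[:-1]) * dT)])
        iTf = int(np.searchsorted(self.Tg, c.T_f))
        H_liq += np.interp(c.T_f, self.Tg, self.H_nuc) - np.interp(c.T_f, self.Tg, H_liq)
        self.C_liq = C_liq
        self.H_liq = H_liq

        # total latent budget per unit volume (J/m^3); cum(T) integrates the
        # latent pulse from the cold end, so a cell sitting at T on the
        # nucleated branch still has cum(T) of its budget left to release
        lat = rho_mix * lam * latent_pulse(self.Tg, c.T_f, c.dT_trans_K)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (lat[1:] + lat[:-1]) * dT)])
        self.B0 = float(cum[-1])
        self.lat_remaining_of_T = cum

        # other materials (only those present in the grid)
        self.C_mat: dict[int, np.ndarray] = {}
        self.H_mat: dict[int, np.ndarray] = {}
        for code, mat in REGION_MATERIAL.items():
            if code not in region_codes:
                continue
            rho = reg.property_at(mat, "density", self.Tg)
            cp = reg.property_at(mat, "specific_heat", self.Tg)
            C = rho * cp
            self.C_mat[code] = C
            self.H_mat[code] = np.concatenate(
                [[0.0], np.cumsum(0.5 * (C[1:] + C[:-1]) * dT)]
            )

    def T_from_H(self, H: np.ndarray, Hcurve: np.ndarray) -> np.ndarray:
        return np.interp(H, Hcurve, self.Tg)

    def H_from_T(self, T: np.ndarray, Hcurve: np.ndarray) -> np.ndarray:
        return np.interp(T, self.Tg, Hcurve)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class ThermalState:
    """Per-cell thermal state in the grid's flat active-cell numbering."""

    t: float
    T: np.ndarray
    H: np.ndarray
    theta_ph1: np.ndarray
    nucleated: np.ndarray
    on_curve: np.ndarray
    latent_remaining: np.ndarray
    energy_out: float = 0.0  # cumulative boundary heat leaving the system, J

    def copy(self) -> "ThermalState":
        return ThermalState(
            self.t, self.T.copy(), self.H.copy(), self.theta_ph1.copy(),
            self.nucleated.copy(), self.on_curve.copy(),
            self.latent_remaining.copy(), self.energy_out,
        )


@dataclass
class ProbeTrace:
    """Time/temperature series at a fixed (r, z) location."""

    times: np.ndarray
    temperatures_C: np.ndarray
    position: tuple[float, float]
    source: str = "simulated"
    sampling_interval: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        if self.times.shape != self.temperatures_C.shape:
            raise ValueError("times and temperatures must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.sampling_interval is None and self.times.size > 1:
            self.sampling_interval = float(np.median(np.diff(self.times)))


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`.

    ``T_history``/``theta_history`` hold the per-step temperature (degC)
    and solid fraction of every gel cell (columns follow
    ``cryogel_cells``, indices into the grid's flat numbering), which is
    what the pore-size estimator consumes.
    """

    config: ProcessConfig
    grid: AxiGrid
    times: np.ndarray
    cryogel_cells: np.ndarray
    T_history: np.ndarray
    theta_history: np.ndarray
    probe_traces: list[ProbeTrace]
    snapshot_times: np.ndarray
    energy_residual: float
    fully_frozen: bool
    final_state: ThermalState

    @property
    def freeze_rate_field(self) -> np.ndarray:
        """Per-gel-cell mean |dT/dt| over the late-freezing window (degC/s)."""
        from .pores import freezing_rate_field

        return freezing_rate_field(self)


# ---------------------------------------------------------------------------
# physics operations
# ---------------------------------------------------------------------------

def nucleation_source(
    T_star: float,
    T_f: float,
    lambda_: float,
    k_i: float,
    gate: bool,
    latent_remaining: float,
    dt: float | None = None,
) -> float:
    """Nucleation heat release rate Qn [W/m^3].

    ``Qn = lambda * k_i * (T_f - T*)`` while the gate is open (the cell has
    nucleated and sits in the supercooled band between the onset and the
    freezing front) and latent heat remains; zero otherwise.  When ``dt``
    is given the rate is clamped so the energy released in one step cannot
    exceed the remaining latent budget.
    """
    if lambda_ <= 0 or k_i <= 0:
        raise ValueError("lambda_ and k_i must be positive")
    if not gate or latent_remaining <= 0:
        return 0.0
    q = lambda_ * k_i * max(T_f - T_star, 0.0)
    if dt is not None and q * dt > latent_remaining:
        q = latent_remaining / dt
    return q


class _Solver:
    """Reusable assembly buffers for one (grid, config) pair."""

    def __init__(self, grid: AxiGrid, config: ProcessConfig,
                 registry: MaterialRegistry | None = None):
        self.grid = grid
        self.config = config
        self.reg = registry or default_registry()
        n = grid.n_active
        # material code per active cell
        codes = np.zeros(n, dtype=int)
        act = grid.index >= 0
        codes[grid.index[act]] = grid.region[act]
        self.codes = codes
        self.curves = _EnthalpyCurves(config, self.reg, set(np.unique(codes)))
        self.is_gel = codes == CRYOGEL
        # sparse pattern: diagonal + off-diagonal pairs
        self.rows = np.concatenate([np.arange(n), grid.face_a, grid.face_b])
        self.cols = np.concatenate([np.arange(n), grid.face_b, grid.face_a])
        self.amb = {
            "bath": config.bath_contact_T,
            "air": config.T_air_C + T_ZERO_C,
        }
        self.h_of_env = {"bath": config.h_bath, "air": config.h_air}
        self.bface_h = np.array([self.h_of_env[e] for e in grid.bface_env])
        self.bface_amb = np.array([self.amb[e] for e in grid.bface_env])
        self.lam = float(self.reg.property_at("water", "latent_heat", config.T_f))
        # gel-gel adjacency, used to propagate nucleation by ice contact
        gg = self.is_gel[grid.face_a] & self.is_gel[grid.face_b]
        self.gel_pairs = (grid.face_a[gg], grid.face_b[gg])

    def initial_state(self) -> ThermalState:
        c, g = self.config, self.grid
        T = np.empty(g.n_active)
        T[self.codes == CRYOGEL] = c.T_init_cryogel_C + T_ZERO_C
        T[self.codes == MOLD] = c.T_init_mold_C + T_ZERO_C
        T[self.codes == CAP] = c.T_init_cap_C + T_ZERO_C
        T[self.codes == BEAKER] = c.bath_contact_T
        H = np.empty(g.n_active)
        for code in np.unique(self.codes):
            m = self.codes == code
            curve = self.curves.H_liq if code == CRYOGEL else self.curves.H_mat[code]
            H[m] = self.curves.H_from_T(T[m], curve)
        n = g.n_active
        return ThermalState(
            t=0.0, T=T, H=H,
            theta_ph1=np.zeros(n),
            nucleated=np.zeros(n, dtype=bool),
            on_curve=np.zeros(n, dtype=bool),
            latent_remaining=np.where(self.is_gel, self.curves.B0, 0.0),
        )

    # -- per-cell property evaluation -------------------------------------
    def _capacity_conductivity(self, state: ThermalState):
        cur = self.curves
        T = state.T
        C = np.empty_like(T)
        kappa = np.empty_like(T)
        for code in np.unique(self.codes):
            m = self.codes == code
            if code == CRYOGEL:
                continue
            C[m] = np.interp(T[m], cur.Tg, cur.C_mat[code])
            kappa[m] = self.reg.property_at(REGION_MATERIAL[code], "conductivity", T[m])
        gel = self.is_gel
        frozen_branch = gel & state.nucleated & state.on_curve
        liquid_branch = gel & ~frozen_branch
        if liquid_branch.any():
            C[liquid_branch] = np.interp(T[liquid_branch], cur.Tg, cur.C_liq)
            kappa[liquid_branch] = (
                self.config.kappa_liquid_factor
                * self.reg.property_at("water", "conductivity", T[liquid_branch])
            )
        if frozen_branch.any():
            Tn = T[frozen_branch]
            C[frozen_branch] = np.interp(Tn, cur.Tg, cur.C_nuc)
            th = phase_fraction(Tn, self.config.T_f, self.config.dT_trans_K,
                                True, self.config.theta_profile)
            k1 = self.reg.property_at("ice", "conductivity", Tn)
            k2 = self.reg.property_at("water", "conductivity", Tn)
            kappa[frozen_branch] = th * k1 + (1 - th) * k2
        return C, kappa

    def step(self, state: ThermalState, dt: float) -> ThermalState:
        g, c, cur = self.grid, self.config, self.curves
        n = g.n_active
        C, kappa = self._capacity_conductivity(state)

        # harmonic-mean interior face conductance
        ka, kb = kappa[g.face_a], kappa[g.face_b]
        gf = g.face_area / (g.face_da / ka + g.face_db / kb)
        # Robin boundary conductance (half-cell conduction in series with h)
        gb = g.bface_area / (g.bface_d / kappa[g.bface_cell] + 1.0 / self.bface_h)

        diag = g.cell_volume_flat * C / dt
        diag_full = diag.copy()
        np.add.at(diag_full, g.face_a, gf)
        np.add.at(diag_full, g.face_b, gf)
        np.add.at(diag_full, g.bface_cell, gb)
        rhs = diag * state.T
        np.add.at(rhs, g.bface_cell, gb * self.bface_amb)

        data = np.concatenate([diag_full, -gf, -gf])
        A = sp.csr_matrix((data, (self.rows, self.cols)), shape=(n, n))
        T_star = spla.spsolve(A, rhs)

        new = state.copy()
        new.t = state.t + dt
        dH = C * (T_star - state.T)
        new.H = state.H + dH
        new.energy_out = state.energy_out + float(
            np.sum(gb * (T_star[g.bface_cell] - self.bface_amb)) * dt
        )

        # nucleation: a gel cell switches branch when it reaches the
        # crystallization onset Tc, or — once ice exists anywhere in
        # contact with it — as soon as it is subcooled below T_f (ice
        # propagates into subcooled liquid without further supercooling;
        # only the first event needs the deep supercool to Tc)
        nuc = new.nucleated | (self.is_gel & (T_star <= c.Tc))
        fa, fb = self.gel_pairs
        cold = T_star < c.T_f
        while True:
            nxt = nuc.copy()
            np.logical_or.at(nxt, fa, nuc[fb] & cold[fa])
            np.logical_or.at(nxt, fb, nuc[fa] & cold[fb])
            if (nxt == nuc).all():
                break
            nuc = nxt
        new.nucleated = nuc

        T_new = T_star.copy()
        # non-gel and liquid-branch cells: temperature from their curve
        for code in np.unique(self.codes):
            if code == CRYOGEL:
                continue
            m = self.codes == code
            T_new[m] = cur.T_from_H(new.H[m], cur.H_mat[code])
        liq = self.is_gel & ~new.nucleated
        T_new[liq] = cur.T_from_H(new.H[liq], cur.H_liq)

        nuc = self.is_gel & new.nucleated
        if nuc.any():
            T_eq = cur.T_from_H(new.H[nuc], cur.H_nuc)
            T_here = T_star[nuc]
            below = T_here < T_eq - 1e-9
            # recalescence: relax toward the equilibrium curve at the
            # nucleation-source rate (internal latent -> sensible transfer,
            # enthalpy unchanged)
            C_liq_here = np.interp(T_here, cur.Tg, cur.C_liq)
            lat_rem = new.latent_remaining[nuc]
            q = self.lam * c.k_i * np.maximum(c.T_f - T_here, 0.0)
            q = np.where(lat_rem > 0, q, 0.0)
            dT_max = q * dt / C_liq_here
            T_rel = np.where(below, np.minimum(T_eq, T_here + dT_max), T_eq)
            # off-curve cells that have not yet reached T_eq stay transient
            arrived = T_rel >= T_eq - 1e-9
            on = new.on_curve[nuc] | arrived
            new.on_curve[nuc] = on
            T_new[nuc] = np.where(on, T_eq, T_rel)
            # remaining latent from the equilibrium curve position
            rem = np.interp(np.minimum(T_new[nuc], c.T_f),
                            cur.Tg, cur.lat_remaining_of_T)
            new.latent_remaining[nuc] = np.where(on, rem, lat_rem)

        new.T = T_new
        theta = phase_fraction(T_new, c.T_f, c.dT_trans_K, True, c.theta_profile)
        theta = np.where(self.is_gel & new.nucleated & new.on_curve, theta, 0.0)
        # monotone freezing: no thaw is modelled, so theta never decreases
        new.theta_ph1 = np.maximum(state.theta_ph1, theta)
        return new


def _flat_volumes(grid: AxiGrid) -> np.ndarray:
    v = np.empty(grid.n_active)
    act = grid.index >= 0
    v[grid.index[act]] = grid.cell_volume[act]
    return v


# attach flat volumes lazily so AxiGrid stays a plain dataclass
def _cell_volume_flat(self: AxiGrid) -> np.ndarray:
    if not hasattr(self, "_vol_flat"):
        self._vol_flat = _flat_volumes(self)
    return self._vol_flat


AxiGrid.cell_volume_flat = property(_cell_volume_flat)  # type: ignore[attr-defined]


def advance(state: ThermalState, grid: AxiGrid, config: ProcessConfig,
            dt: float, _solver: _Solver | None = None) -> ThermalState:
    """Advance the thermal state by one implicit step of length ``dt``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    solver = _solver or _Solver(grid, config)
    return solver.step(state, dt)


def run_simulation(config: ProcessConfig,
                   registry: MaterialRegistry | None = None,
                   n_snapshots: int = 9) -> SimulationResult:
    """Integrate the freezing process from t=0 to ``config.total_time``.

    Records probe traces at ``config.probe_points`` (r, z above the sample
    base) every ``config.trace_interval`` seconds and the full per-step
    temperature / solid-fraction history of the gel cells.
    """
    grid = build_grid(config)
    solver = _Solver(grid, config, registry)
    state = solver.initial_state()

    gel_cells = np.flatnonzero(solver.is_gel)
    probe_w = [_probe_weights(grid, config, r, z, gel_cells)
               for (r, z) in config.probe_points]

    n_steps = int(round(config.total_time / config.dt))
    stride = max(1, int(round(config.trace_interval / config.dt)))

    times = np.empty(n_steps + 1)
    T_hist = np.empty((n_steps + 1, gel_cells.size))
    th_hist = np.empty((n_steps + 1, gel_cells.size))
    times[0] = 0.0
    T_hist[0] = state.T[gel_cells] - T_ZERO_C
    th_hist[0] = state.theta_ph1[gel_cells]

    def probe_T(s: ThermalState) -> np.ndarray:
        return np.array([
            float(np.dot(w, s.T[cells])) - T_ZERO_C for cells, w in probe_w
        ])

    trace_t = [0.0]
    trace_T = [probe_T(state)]

    E0 = float(np.sum(state.H * grid.cell_volume_flat))
    for k in range(1, n_steps + 1):
        state = solver.step(state, config.dt)
        times[k] = state.t
        T_hist[k] = state.T[gel_cells] - T_ZERO_C
        th_hist[k] = state.theta_ph1[gel_cells]
        if k % stride == 0:
            trace_t.append(state.t)
            trace_T.append(probe_T(state))

    E1 = float(np.sum(state.H * grid.cell_volume_flat))
    residual = abs((E1 - E0) + state.energy_out) / max(abs(E1 - E0), 1.0)

    trace_T = np.array(trace_T)
    traces = [
        ProbeTrace(np.array(trace_t), trace_T[:, i],
                   position=tuple(config.probe_points[i]),
                   source="simulated", sampling_interval=config.trace_interval)
        for i in range(len(probe_w))
    ]

    fully = bool(np.all(state.theta_ph1[gel_cells] >= 0.999))
    if not fully:
        warnings.warn("simulation ended before the gel froze completely", stacklevel=2)

    snap = np.linspace(0.0, config.total_time, n_snapshots)
    return SimulationResult(
        config=config, grid=grid, times=times, cryogel_cells=gel_cells,
        T_history=T_hist, theta_history=th_hist, probe_traces=traces,
        snapshot_times=snap, energy_residual=residual, fully_frozen=fully,
        final_state=state,
    )


def _probe_weights(grid: AxiGrid, config: ProcessConfig, r: float, z: float,
                   gel_cells: np.ndarray):
    """Bilinear interpolation stencil for a probe at (r, z-above-base).

    Probes are interpolated between the four surrounding gel cell centers
    (clamped to the nearest center at the region edges), so the reported
    temperature refers to the exact probe location and refines smoothly
    with the grid.
    """
    if not (0.0 <= r < config.sample_radius) or not (0.0 <= z < config.sample_height):
        raise ValueError(
            f"probe (r={r * 1e3:.2f} mm, z={z * 1e3:.2f} mm) outside the gel region"
        )
    z_abs = config.mold_base_thickness + z
    r_all, z_all = grid.cell_coords()
    rg = np.unique(np.round(r_all[gel_cells], 12))
    zg = np.unique(np.round(z_all[gel_cells], 12))
    # gel cells are stored row-major (z outer, r inner) in flat numbering
    assert gel_cells.size == rg.size * zg.size

    def axis_weights(x: float, centers: np.ndarray):
        if x <= centers[0]:
            return [(0, 1.0)]
        if x >= centers[-1]:
            return [(centers.size - 1, 1.0)]
        i = int(np.searchsorted(centers, x)) - 1
        f = (x - centers[i]) / (centers[i + 1] - centers[i])
        return [(i, 1.0 - f), (i + 1, f)]

    cols, weights = [], []
    for iz, wz in axis_weights(z_abs, zg):
        for ir, wr in axis_weights(r, rg):
            cols.append(gel_cells[iz * rg.size + ir])
            weights.append(wz * wr)
    return np.array(cols), np.array(weights)


def extract_probe(result: SimulationResult, r: float, z: float) -> ProbeTrace:
    """Temperature trace at probe point (r, z above the sample base).

    Reconstructed from the stored per-step gel history by bilinear
    interpolation between the surrounding cell centers, resampled at the
    configured trace interval.
    """
    grid, config = result.grid, result.config
    cells, w = _probe_weights(grid, config, r, z, result.cryogel_cells)
    cols = np.array([int(np.flatnonzero(result.cryogel_cells == c)[0]) for c in cells])
    stride = max(1, int(round(config.trace_interval / config.dt)))
    sel = slice(None, None, stride)
    T = result.T_history[sel][:, cols] @ w
    return ProbeTrace(result.times[sel], T, position=(r, z), source="simulated",
                      sampling_interval=config.trace_interval)


# ---------------------------------------------------------------------------
# 1-D slab mode (solver verification against the analytic Stefan solution)
# ---------------------------------------------------------------------------

@dataclass
class SlabResult:
    """History of a 1-D freezing-slab run (temperatures in degC)."""

    config: ProcessConfig
    z_centers: np.ndarray
    times: np.ndarray
    T_history: np.ndarray
    theta_history: np.ndarray
    energy_residual: float

    def front_position(self) -> np.ndarray:
        """Frozen-front trajectory: depth of the mid-transition isotherm."""
        T_mid = self.config.T_f_C - self.config.dT_trans_K
        out = np.zeros(self.times.size)
        z = self.z_centers
        for k, prof in enumerate(self.T_history):
            if prof[0] >= T_mid:
                out[k] = 0.0
            elif prof[-1] <= T_mid:
                out[k] = z[-1]
            else:
                i = int(np.searchsorted(prof, T_mid))  # profile increases with z
                z0, z1 = z[i - 1], z[i]
                f = (T_mid - prof[i - 1]) / (prof[i] - prof[i - 1])
                out[k] = z0 + f * (z1 - z0)
        return out


def run_slab_simulation(config: ProcessConfig, length: float, n_cells: int,
                        registry: MaterialRegistry | None = None) -> SlabResult:
    """Freeze a 1-D water slab cooled from z = 0 with a Robin condition.

    With ``Tc_C == T_f_C`` (nucleation disabled) and a large ``h_bath``
    this approaches the classical two-phase Stefan problem with a fixed
    cold-wall temperature of ``bath_setpoint + bath_contact_offset``.
    """
    grid = build_slab_grid(length, n_cells)
    solver = _Solver(grid, config, registry)
    state = solver.initial_state()
    n_steps = int(round(config.total_time / config.dt))
    times = np.empty(n_steps + 1)
    T_hist = np.empty((n_steps + 1, grid.n_active))
    th_hist = np.empty_like(T_hist)
    times[0], T_hist[0], th_hist[0] = 0.0, state.T - T_ZERO_C, state.theta_ph1
    E0 = float(np.sum(state.H * grid.cell_volume_flat))
    for k in range(1, n_steps + 1):
        state = solver.step(state, config.dt)
        times[k], T_hist[k], th_hist[k] = state.t, state.T - T_ZERO_C, state.theta_ph1
    E1 = float(np.sum(state.H * grid.cell_volume_flat))
    residual = abs((E1 - E0) + state.energy_out) / max(abs(E1 - E0), 1.0)
    return SlabResult(config, grid.z_centers, times, T_hist, th_hist, residual)
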