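"""Temperature-dependent material properties and solid/liquid phase mixing.

The freezing simulation treats the gel as water that solidifies over a
narrow transition interval below the equilibrium freezing point ``T_f``.
Within that interval the local state is described by the solid volume
fraction ``theta_ph1`` (``theta_ph2 = 1 - theta_ph1`` is the liquid
fraction).  Mixture density and conductivity are volume-fraction weighted,
while the apparent specific heat carries the latent heat of fusion as a
normalized Gaussian pulse spread over the transition interval — the
standard apparent-heat-capacity treatment of phase change.

Property tables are shipped as plain CSV files (columns ``T_K,value``)
under :mod:`cryogel.data`, one file per material/property pair, and are
evaluated by piecewise-linear interpolation with constant extrapolation
outside the sampled range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PropertyTable",
    "MaterialRegistry",
    "PhaseMix",
    "default_registry",
    "property_at",
    "mix_properties",
    "phase_fraction",
    "latent_pulse",
    "T_ZERO_C",
]

#: 0 degC in kelvin; the default freezing-front temperature.
T_ZERO_C = 273.15

_DATA_DIR = Path(__file__).parent / "data"

#: Properties a table may describe, with their SI units.
PROPERTIES = {
    "density": "kg/m^3",
    "conductivity": "W/(m K)",
    "specific_heat": "J/(kg K)",
    "latent_heat": "J/kg",
}


@dataclass(frozen=True)
class PropertyTable:
    """Sampled property of one material, linearly interpolated in T.

    Temperatures must be strictly increasing and values finite and
    positive.  Outside the sampled range the nearest endpoint value is
    used (constant extrapolation), which matches the convention of the
    shipped handbook tables where low-temperature data are assumed
    constant below the last sampled point.
    """

    material_id: str
    prop: str
    temperatures_K: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures_K, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if T.ndim != 1 or T.shape != v.shape or T.size == 0:
            raise ValueError("table needs matching 1-D temperature/value arrays")
        if T.size > 1 and not np.all(np.diff(T) > 0):
            raise ValueError(f"{self.material_id}/{self.prop}: temperatures not strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError(f"{self.material_id}/{self.prop}: values must be finite and positive")
        object.__setattr__(self, "temperatures_K", T)
        object.__setattr__(self, "values", v)

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        if not np.all(np.isfinite(T)):
            raise ValueError("temperature must be finite")
        out = np.interp(T, self.temperatures_K, self.values)
        return float(out) if out.ndim == 0 else out


class MaterialRegistry:
    """Collection of :class:`PropertyTable` keyed by (material, property)."""

    def __init__(self) -> None:
        self._tables: dict[tuple[str, str], PropertyTable] = {}

    def register(self, table: PropertyTable) -> None:
        self._tables[(table.material_id, table.prop)] = table

    def table(self, material_id: str, prop: str) -> PropertyTable:
        try:
            return self._tables[(material_id, prop)]
        except KeyError:
            raise LookupError(
                f"no table for material={material_id!r} property={prop!r}; "
                f"registered: {sorted(self._tables)}"
            ) from None

    def property_at(self, material_id: str, prop: str, T):
        """Evaluate a property at temperature ``T`` (kelvin)."""
        return self.table(material_id, prop)(T)

    def materials(self) -> set[str]:
        return {m for m, _ in self._tables}

    @classmethod
    def from_directory(cls, path: Path | str) -> "MaterialRegistry":
        """Load every ``<material>_<property>.csv`` file in ``path``.

        Lines starting with ``#`` are comments; the first non-comment
        line must be the ``T_K,value`` header.
        """
        reg = cls()
        path = Path(path)
        for f in sorted(path.glob("*.csv")):
            stem = f.stem
            for prop in PROPERTIES:
                if stem.endswith("_" + prop):
                    material = stem[: -len(prop) - 1]
                    break
            else:
                continue
            rows = []
            with open(f) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#") or line.lower().startswith("t_k"):
                        continue
                    t, v = line.split(",")
                    rows.append((float(t), float(v)))
            T, v = (np.array(c) for c in zip(*rows))
            reg.register(PropertyTable(material, prop, T, v))
        return reg


_default: MaterialRegistry | None = None


def default_registry() -> MaterialRegistry:
    """The registry built from the CSV tables shipped with the package."""
    global _default
    if _default is None:
        _default = MaterialRegistry.from_directory(_DATA_DIR)
    return _default


def property_at(material_id: str, prop: str, T, registry: MaterialRegistry | None = None):
    """Module-level convenience wrapper around the default registry."""
    return (registry or default_registry()).property_at(material_id, prop, T)


@dataclass(frozen=True)
class PhaseMix:
    """Solid/liquid volume fractions during the freezing transition."""

    theta_ph1: float
    theta_ph2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.theta_ph2 is None:
            object.__setattr__(self, "theta_ph2", 1.0 - self.theta_ph1)
        if not (0.0 <= self.theta_ph1 <= 1.0 and 0.0 <= self.theta_ph2 <= 1.0):
            raise ValueError(f"phase fractions out of [0, 1]: {self}")
        if abs(self.theta_ph1 + self.theta_ph2 - 1.0) > 1e-9:
            raise ValueError("theta_ph1 + theta_ph2 must equal 1")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def phase_fraction(
    T,
    T_f: float = T_ZERO_C,
    dT_trans: float = 0.5,
    nucleated=True,
    profile: str = "smooth",
):
    """Solid volume fraction ``theta_ph1`` as a function of temperature.

    The transition spans ``[T_f - 2*dT_trans, T_f]``: zero at or above the
    freezing front, one at or below the cold edge, and a monotone ramp in
    between (cubic smoothstep by default, or a linear ramp with
    ``profile="linear"``).  Cells that have never reached the nucleation
    temperature remain liquid regardless of ``T`` (``nucleated=False``).
    """
    if dT_trans <= 0:
        raise ValueError("dT_trans must be positive")
    if profile not in ("smooth", "linear"):
        raise ValueError(f"unknown profile {profile!r}")
    T = np.asarray(T, dtype=float)
    x = (T_f - T) / (2.0 * dT_trans)
    theta = _smoothstep(x) if profile == "smooth" else np.clip(x, 0.0, 1.0)
    theta = np.where(np.asarray(nucleated, dtype=bool), theta, 0.0)
    return float(theta) if theta.ndim == 0 else theta


# Truncated-Gaussian latent pulse, following the usual apparent-heat-capacity
# convention: characteristic width a = (transition interval)/4, support
# limited to the interval and renormalized to unit integral.
_PULSE_NORM = math.erf(2.0)  # integral of exp(-u^2)/sqrt(pi) over [-2a, 2a]


def latent_pulse(T, T_f: float = T_ZERO_C, dT_trans: float = 0.5):
    """Normalized latent-heat distribution D(T) over the transition [1/K].

    Gaussian centered mid-interval at ``T_f - dT_trans`` with width
    parameter ``a = dT_trans/2``, truncated to ``[T_f - 2*dT_trans, T_f]``
    and renormalized so that the integral over the interval is exactly 1.
    Multiplying by ``rho*lambda`` gives the volumetric latent contribution
    to the apparent heat capacity.
    """
    if dT_trans <= 0:
        raise ValueError("dT_trans must be positive")
    T = np.asarray(T, dtype=float)
    a = dT_trans / 2.0
    u = (T - (T_f - dT_trans)) / a
    D = np.exp(-np.clip(u * u, 0.0, 700.0)) / (a * math.sqrt(math.pi) * _PULSE_NORM)
    D = np.where((T <= T_f) & (T >= T_f - 2.0 * dT_trans), D, 0.0)
    return float(D) if D.ndim == 0 else D


def mix_properties(
    theta: PhaseMix | float,
    T,
    T_f: float = T_ZERO_C,
    dT_trans: float = 0.5,
    registry: MaterialRegistry | None = None,
    solid: str = "ice",
    liquid: str = "water",
):
    """Mixture (rho, kappa, Cp_apparent) of the freezing gel at (theta, T).

    Density and conductivity are volume-fraction weighted means of the
    solid and liquid phase tables.  The apparent specific heat is the
    mass-weighted sensible mixture plus the latent heat of fusion
    distributed over the transition interval::

        Cp_app = (th1*rho1*Cp1 + th2*rho2*Cp2) / rho + lambda * D(T)

    with D the normalized pulse from :func:`latent_pulse`, so that the
    integral of ``rho * Cp_app`` across the transition recovers the
    sensible heat plus ``rho * lambda``.
    """
    reg = registry or default_registry()
    if not isinstance(theta, PhaseMix):
        theta = PhaseMix(float(theta))
    th1, th2 = theta.theta_ph1, theta.theta_ph2
    rho1 = reg.property_at(solid, "density", T)
    rho2 = reg.property_at(liquid, "density", T)
    k1 = reg.property_at(solid, "conductivity", T)
    k2 = reg.property_at(liquid, "conductivity", T)
    cp1 = reg.property_at(solid, "specific_heat", T)
    cp2 = reg.property_at(liquid, "specific_heat", T)
    lam = reg.property_at(liquid, "latent_heat", T)

    rho = th1 * rho1 + th2 * rho2
    kappa = th1 * k1 + th2 * k2
    cp_sens = (th1 * rho1 * cp1 + th2 * rho2 * cp2) / rho
    cp_app = cp_sens + lam * latent_pulse(T, T_f, dT_trans)
    return rho, kappa, cp_app
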