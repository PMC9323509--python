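"""Two-domain finite-volume solver for the well-plate cell-solute model.

The culture well is reduced to a 1D axial column: a thin cell-seeded collagen
gel at the base with culture medium above (radial gradients are negligible for
a 96-well geometry).  Oxygen, glucose and VEGF diffuse through both layers
with layer-specific diffusivities; the viable cell density lives on the gel
cells only and follows death-only kinetics.

Boundary conditions: oxygen is held at the ambient set-point at the
medium-air interface (Dirichlet) and is no-flux at the well base; glucose and
VEGF are no-flux at every outer boundary; at the gel-medium interface all
solutes satisfy continuity of concentration and flux (harmonic-mean face
diffusivity).

Time integration is semi-implicit: diffusion and all terms linear in the
solute (VEGF decay, the linearised Michaelis–Menten sinks) are advanced with
backward Euler — unconditionally stable and positivity-preserving — while
the VEGF source is evaluated at the current state and the cell-density ODE is
integrated exactly over the step with frozen rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .model_core import (
    O2_KG_M3_PER_PERCENT,
    CELLS_M3_PER_ML,
    GLUCOSE_KG_M3_PER_MM,
    ParameterSet,
    specific_death_rate,
    vegf_source,
)

__all__ = [
    "WellGeometry",
    "Mesh",
    "FieldState",
    "SimulationResult",
    "BoundaryConfig",
    "Stepper",
    "DEFAULT_WELL_RADIUS_M",
    "DEFAULT_GEL_PRESTAB_UL",
    "DEFAULT_MEDIUM_UL",
    "DEFAULT_COMPRESSION_FACTOR",
    "build_geometry",
    "default_geometry",
    "stabilized_density",
    "build_mesh",
    "initial_state",
    "step",
    "simulate",
    "gel_average",
    "medium_average",
]

logger = logging.getLogger(__name__)

# 96-well plate geometry defaults.  The protocol states the pre-compression
# gel volume (240 uL); plastic compression concentrates cells ~40-fold
# (seeding 0.5e6 -> 20e6 cells/mL), fixing the post-compression volume at
# 6 uL (~0.19 mm).  The medium volume is taken as 200 uL, the handling volume
# used throughout the staining/assay protocol.
DEFAULT_WELL_RADIUS_M = 3.175e-3
DEFAULT_GEL_PRESTAB_UL = 240.0
DEFAULT_MEDIUM_UL = 200.0
DEFAULT_COMPRESSION_FACTOR = 40.0

#: Initial gel oxygen from medium preconditioning, % ambient equivalent.
INITIAL_GEL_O2_PERCENT = 12.0
#: Initial glucose, mM.
INITIAL_GLUCOSE_MEDIUM_MM = 25.0
INITIAL_GLUCOSE_GEL_MM = 1.25

_SPECIES = ("oxygen", "glucose", "vegf", "cells")

#: Undershoot below this (absolute, modeling units) is a solver failure.
_NEGATIVE_TOL = 1e-12


# ---------------------------------------------------------------------------
# Geometry & mesh
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellGeometry:
    """Axisymmetric well reduced to axial heights; gel below medium."""

    radius: float         # m
    gel_height: float     # m
    medium_height: float  # m

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.gel_height <= 0 or self.medium_height <= 0:
            raise ValueError("radius and heights must be strictly positive")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def gel_volume(self) -> float:
        return self.area * self.gel_height

    @property
    def medium_volume(self) -> float:
        return self.area * self.medium_height

    @property
    def total_height(self) -> float:
        return self.gel_height + self.medium_height


def stabilized_density(seeded_density_per_ml: float, compression_factor: float) -> float:
    """Post-compression cell density (cells/mL): seeding density x factor."""
    if compression_factor < 1:
        raise ValueError("compression_factor must be >= 1")
    return seeded_density_per_ml * compression_factor


def build_geometry(
    gel_volume_prestab_ul: float = DEFAULT_GEL_PRESTAB_UL,
    medium_volume_ul: float = DEFAULT_MEDIUM_UL,
    compression_factor: float = DEFAULT_COMPRESSION_FACTOR,
    radius_m: float = DEFAULT_WELL_RADIUS_M,
) -> WellGeometry:
    """Well geometry after plastic compression of the seeded gel.

    Compression removes interstitial fluid: the post-compression gel volume is
    the cast volume divided by ``compression_factor`` (cell density scales up
    by the same factor, see :func:`stabilized_density`).
    """
    if gel_volume_prestab_ul <= 0 or medium_volume_ul <= 0 or radius_m <= 0:
        raise ValueError("volumes and radius must be strictly positive")
    if compression_factor < 1:
        raise ValueError("compression_factor must be >= 1")
    area = math.pi * radius_m**2
    gel_volume = gel_volume_prestab_ul * 1e-9 / compression_factor  # uL -> m^3
    medium_volume = medium_volume_ul * 1e-9
    return WellGeometry(
        radius=radius_m,
        gel_height=gel_volume / area,
        medium_height=medium_volume / area,
    )


def default_geometry() -> WellGeometry:
    return build_geometry()


@dataclass(frozen=True)
class Mesh:
    """Two-part axial finite-volume grid; the gel-medium interface is a face.

    Cell centres ascend from the well base (z=0).  Cells are uniform within
    each domain but the two domains have different widths, giving finer
    resolution in the thin gel where gradients are steepest.
    """

    cell_centres: np.ndarray  # m, ascending
    cell_widths: np.ndarray   # m
    n_gel: int                # gel cells are indices [0, n_gel)

    @property
    def n_cells(self) -> int:
        return self.cell_centres.size

    @property
    def interface_index(self) -> int:
        """Face index of the gel-medium interface (face i sits above cell i-1)."""
        return self.n_gel

    @property
    def gel(self) -> slice:
        return slice(0, self.n_gel)

    @property
    def medium(self) -> slice:
        return slice(self.n_gel, self.n_cells)

    def domain_labels(self) -> np.ndarray:
        labels = np.full(self.n_cells, "medium", dtype=object)
        labels[: self.n_gel] = "gel"
        return labels


def build_mesh(geom: WellGeometry, n_cells: int = 100, gel_fraction: float = 0.2) -> Mesh:
    """Partition the column into ``round(gel_fraction * n_cells)`` uniform gel
    cells and the remainder uniform medium cells."""
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if not 0 < gel_fraction < 1:
        raise ValueError("gel_fraction must lie in (0, 1)")
    n_gel = round(gel_fraction * n_cells)
    if n_gel < 2:
        raise ValueError("gel_fraction * n_cells must be >= 2")
    n_med = n_cells - n_gel
    if n_med < 2:
        raise ValueError("medium must contain at least 2 cells")
    w_gel = geom.gel_height / n_gel
    w_med = geom.medium_height / n_med
    widths = np.concatenate([np.full(n_gel, w_gel), np.full(n_med, w_med)])
    centres = np.cumsum(widths) - widths / 2
    return Mesh(cell_centres=centres, cell_widths=widths, n_gel=n_gel)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class FieldState:
    """Concentrations (kg/m^3) on all cells; viable density on gel cells."""

    t: float
    c: np.ndarray  # oxygen
    s: np.ndarray  # glucose
    v: np.ndarray  # VEGF
    n: np.ndarray  # cells (zero outside the gel)

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.c.copy(), self.s.copy(), self.v.copy(), self.n.copy())


@dataclass(frozen=True)
class BoundaryConfig:
    """Outer boundary conditions.

    ``oxygen_top='dirichlet'`` holds oxygen at the ambient set-point at the
    medium-air interface; ``'zero_flux'`` seals the column (used for
    conservation checks).  Glucose and VEGF are always no-flux outside.
    """

    ambient_percent: float
    oxygen_top: str = "dirichlet"

    def __post_init__(self) -> None:
        if self.oxygen_top not in ("dirichlet", "zero_flux"):
            raise ValueError("oxygen_top must be 'dirichlet' or 'zero_flux'")

    @property
    def ambient_concentration(self) -> float:
        return self.ambient_percent * O2_KG_M3_PER_PERCENT


def initial_state(
    mesh: Mesh,
    ambient_percent: float,
    n0_per_ml: float,
    gel_o2_percent: float = INITIAL_GEL_O2_PERCENT,
    glucose_medium_mM: float = INITIAL_GLUCOSE_MEDIUM_MM,
    glucose_gel_mM: float = INITIAL_GLUCOSE_GEL_MM,
) -> FieldState:
    """Pre-incubation initial condition.

    The gel starts at the preconditioned-medium oxygen level (12 % equivalent)
    while the medium starts at ambient; glucose starts at 25 mM in the medium
    and 1.25 mM in the gel; VEGF at zero; cells uniformly in the gel.
    """
    c = np.full(mesh.n_cells, ambient_percent * O2_KG_M3_PER_PERCENT)
    c[mesh.gel] = gel_o2_percent * O2_KG_M3_PER_PERCENT
    s = np.full(mesh.n_cells, glucose_medium_mM * GLUCOSE_KG_M3_PER_MM)
    s[mesh.gel] = glucose_gel_mM * GLUCOSE_KG_M3_PER_MM
    v = np.zeros(mesh.n_cells)
    n = np.zeros(mesh.n_cells)
    n[mesh.gel] = n0_per_ml * CELLS_M3_PER_ML
    return FieldState(t=0.0, c=c, s=s, v=v, n=n)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------


class Stepper:
    """Semi-implicit integrator with precomputed face conductances.

    Face conductance ``g = 1 / (w_L/(2 D_L) + w_R/(2 D_R))`` (harmonic mean)
    makes the diffusive flux continuous across the gel-medium interface.
    """

    def __init__(self, mesh: Mesh, params: ParameterSet, bc: BoundaryConfig) -> None:
        self.mesh = mesh
        self.params = params
        self.bc = bc
        w = mesh.cell_widths
        self._inv_w = 1.0 / w
        self._species = {}
        for species, d_gel, d_med in (
            ("oxygen", params.D_c_gel, params.D_c_med),
            ("glucose", params.D_s_gel, params.D_s_med),
            ("vegf", params.D_v_gel, params.D_v_med),
        ):
            D = np.full(mesh.n_cells, d_med)
            D[mesh.gel] = d_gel
            g = 1.0 / (w[:-1] / (2 * D[:-1]) + w[1:] / (2 * D[1:]))
            # static banded structure: only the diagonal changes per step
            ab = np.zeros((3, mesh.n_cells))
            ab[0, 1:] = -g * self._inv_w[:-1]   # coefficient of x[i+1] in row i
            ab[2, :-1] = -g * self._inv_w[1:]   # coefficient of x[i-1] in row i
            diag_base = np.zeros(mesh.n_cells)
            diag_base[:-1] += g * self._inv_w[:-1]
            diag_base[1:] += g * self._inv_w[1:]
            self._species[species] = (ab, diag_base)
        # Dirichlet "half-cell" conductance at the top face for oxygen
        self._g_top = params.D_c_med / (w[-1] / 2.0)

    def _solve_species(self, species, x, dt, extra_diag, rhs_extra, dirichlet_top):
        ab, diag_base = self._species[species]
        ab[1] = 1.0 / dt + diag_base + extra_diag
        rhs = x / dt + rhs_extra
        if dirichlet_top:
            g_eff = self._g_top * self._inv_w[-1]
            ab[1, -1] += g_eff
            rhs[-1] += g_eff * self.bc.ambient_concentration
        return solve_banded((1, 1), ab, rhs, check_finite=False)

    def step(self, state: FieldState, dt: float, with_vegf: bool = True) -> FieldState:
        """Advance the coupled system by one step of length ``dt``.

        ``with_vegf=False`` skips the VEGF solve (its dynamics feed back on
        nothing), which speeds up calibration passes that only need the
        oxygen/glucose/cell observables.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        mesh = self.mesh
        c, s, v, n = state.c, state.s, state.v, state.n

        # Michaelis-Menten sinks linearised about the current state enter the
        # implicit diagonal, which keeps concentrations nonnegative for any dt.
        sink_c = p.M_c * n / (c + p.c_half)
        sink_s = p.M_s * n / (s + p.s_half) * (1.0 + p.A * p.c_half / (c + p.c_half))
        gel = mesh.gel

        dirichlet = self.bc.oxygen_top == "dirichlet"
        c_new = self._solve_species("oxygen", c, dt, sink_c, 0.0, dirichlet)
        s_new = self._solve_species("glucose", s, dt, sink_s, 0.0, False)
        if with_vegf:
            src_v = np.zeros(mesh.n_cells)
            src_v[gel] = vegf_source(np.maximum(c[gel], 0.0), n[gel], p)
            v_new = self._solve_species("vegf", v, dt, p.K_v, src_v, False)
        else:
            v_new = v.copy()

        # death-only cell kinetics: exact decay with rates frozen over the step
        n_new = n.copy()
        delta = specific_death_rate(np.maximum(c[gel], 0.0), np.maximum(s[gel], 0.0), p)
        n_new[gel] = n[gel] * np.exp(-delta * dt)

        out = FieldState(t=state.t + dt, c=c_new, s=s_new, v=v_new, n=n_new)
        for name, arr in (("oxygen", out.c), ("glucose", out.s), ("vegf", out.v)):
            lo = arr.min()
            if lo < -_NEGATIVE_TOL:
                raise RuntimeError(
                    f"{name} undershot to {lo:.3e} at t={out.t:.1f} s; "
                    "reduce dt or check parameters"
                )
            np.clip(arr, 0.0, None, out=arr)
        return out


def step(state: FieldState, dt: float, params: ParameterSet, bc: BoundaryConfig,
         mesh: Mesh) -> FieldState:
    """One-off convenience wrapper around :class:`Stepper`."""
    return Stepper(mesh, params, bc).step(state, dt)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

_FIELD_OF = {"oxygen": "c", "glucose": "s", "vegf": "v", "cells": "n"}


def _weighted_mean(values: np.ndarray, widths: np.ndarray) -> float:
    return float(np.sum(values * widths) / np.sum(widths))


def gel_average(state: FieldState, species: str, mesh: Mesh) -> float:
    """Volume-weighted mean of a field over the gel domain (the model's
    principal observable)."""
    if species not in _FIELD_OF:
        raise ValueError(f"unknown species {species!r}; expected one of {sorted(_FIELD_OF)}")
    sl = mesh.gel
    return _weighted_mean(getattr(state, _FIELD_OF[species])[sl], mesh.cell_widths[sl])


def medium_average(state: FieldState, species: str, mesh: Mesh) -> float:
    """Volume-weighted mean of a solute over the medium domain."""
    if species not in _FIELD_OF or species == "cells":
        raise ValueError(f"unknown medium species {species!r}")
    sl = mesh.medium
    return _weighted_mean(getattr(state, _FIELD_OF[species])[sl], mesh.cell_widths[sl])


def _gel_centre_index(mesh: Mesh, geom: WellGeometry) -> int:
    centres = mesh.cell_centres[mesh.gel]
    return int(np.argmin(np.abs(centres - geom.gel_height / 2.0)))


def _zone_viability(state: FieldState, mesh: Mesh) -> dict[str, float]:
    """Volume-weighted viable density in the bottom/middle/top thirds of the gel."""
    idx = np.arange(mesh.n_gel)
    zones = np.array_split(idx, 3)
    out = {}
    for name, zone in zip(("bottom", "middle", "top"), zones):
        out[name] = _weighted_mean(state.n[zone], mesh.cell_widths[zone])
    return out


@dataclass
class SimulationResult:
    """Observable traces at the requested output cadence."""

    times: np.ndarray                          # s
    centre_oxygen_trace: np.ndarray            # kg/m^3 at the gel axial midpoint
    gel_averages: dict[str, np.ndarray]        # per species, kg/m^3 (cells: cell/m^3)
    medium_averages: dict[str, np.ndarray]     # oxygen/glucose/vegf
    viable_fraction: np.ndarray                # <n>_gel / n0 per output time
    zone_viability: dict[str, float]           # bottom/middle/top thirds, final time
    final_state: FieldState = field(repr=False, default=None)
    mesh: Mesh = field(repr=False, default=None)
    geometry: WellGeometry = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def simulate(
    params: ParameterSet,
    ambient_O2: float,
    n0_per_ml: float,
    geom: WellGeometry | None = None,
    mesh: Mesh | None = None,
    t_end: float = 86400.0,
    output_every: float = 1800.0,
    dt: float = 100.0,
    bc: BoundaryConfig | None = None,
    initial_kwargs: dict | None = None,
    with_vegf: bool = True,
) -> SimulationResult:
    """Integrate the well model from the standard initial condition.

    Parameters
    ----------
    ambient_O2 : ambient oxygen set-point in % (0 < ambient <= 21).
    n0_per_ml : post-stabilization viable density, cells/mL (0 for acellular).
    t_end, output_every, dt : seconds.  When an output time is not a multiple
        of ``dt`` the final step of the interval is shortened to land exactly.
    """
    if not 0 < ambient_O2 <= 21:
        raise ValueError("ambient_O2 must lie in (0, 21] percent")
    if n0_per_ml < 0:
        raise ValueError("n0_per_ml must be nonnegative")
    geom = default_geometry() if geom is None else geom
    mesh = build_mesh(geom) if mesh is None else mesh
    bc = BoundaryConfig(ambient_percent=ambient_O2) if bc is None else bc
    init_kw = initial_kwargs or {}
    state = initial_state(mesh, ambient_O2, n0_per_ml, **init_kw)
    stepper = Stepper(mesh, params, bc)

    n_out = int(round(t_end / output_every))
    out_times = output_every * np.arange(1, n_out + 1)
    centre = _gel_centre_index(mesh, geom)
    n0_density = n0_per_ml * CELLS_M3_PER_ML

    times = [0.0]
    centre_trace = [state.c[centre]]
    gel_avgs = {sp: [gel_average(state, sp, mesh)] for sp in _SPECIES}
    med_avgs = {sp: [medium_average(state, sp, mesh)] for sp in ("oxygen", "glucose", "vegf")}
    viable = [1.0 if n0_density == 0 else gel_average(state, "cells", mesh) / n0_density]

    for t_target in out_times:
        while state.t < t_target - 1e-9:
            dt_eff = min(dt, t_target - state.t)
            if dt_eff < dt - 1e-9:
                logger.debug("shortened step to %.3f s to land on t=%.1f s", dt_eff, t_target)
            state = stepper.step(state, dt_eff, with_vegf=with_vegf)
        times.append(t_target)
        centre_trace.append(state.c[centre])
        for sp in _SPECIES:
            gel_avgs[sp].append(gel_average(state, sp, mesh))
        for sp in ("oxygen", "glucose", "vegf"):
            med_avgs[sp].append(medium_average(state, sp, mesh))
        viable.append(1.0 if n0_density == 0 else gel_avgs["cells"][-1] / n0_density)

    return SimulationResult(
        times=np.asarray(times),
        centre_oxygen_trace=np.asarray(centre_trace),
        gel_averages={sp: np.asarray(tr) for sp, tr in gel_avgs.items()},
        medium_averages={sp: np.asarray(tr) for sp, tr in med_avgs.items()},
        viable_fraction=np.asarray(viable),
        zone_viability=_zone_viability(state, mesh),
        final_state=state,
        mesh=mesh,
        geometry=geom,
    )
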