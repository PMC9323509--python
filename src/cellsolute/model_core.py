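"""Model constants, unit conversions and pointwise reaction kinetics.

The cell-solute model couples three solutes — oxygen ``c``, glucose ``s`` and
VEGF ``v`` — to the viable cell density ``n`` of neural stem cells seeded in a
plastic-compressed collagen gel under culture medium.  This module houses the
19 free rate/transport constants of the governing equations, the unit system,
and the local (per-point) reaction terms:

* oxygen consumption: Michaelis–Menten, ``M_c n c/(c + c_half)``;
* glucose consumption: Michaelis–Menten times an anaerobic enhancement
  ``1 + A c_half/(c + c_half)`` that doubles down on glycolysis as oxygen
  falls below its half-saturation scale;
* VEGF secretion: an oxygen-proportional baseline plus a hypoxia-gated term
  ``beta exp(-c/c_tau)``, saturated in cell density by a crowding factor
  ``n_tau``;
* cell death: baseline plus oxygen- and glucose-deprivation terms, each with
  the same half-saturation gating as the consumption kinetics.

Internal ("modeling") units are SI mass concentrations: kg/m^3 for solutes,
cell/m^3 for cells, m and s for space and time.  Practical assay units
(%O2, mmHg, mol/mL, mM, pg/mL, cells/mL) exist only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass
from typing import Iterator

import yaml

__all__ = [
    "ParameterSet",
    "FREE_PARAMETER_NAMES",
    "PARAMETER_BOUNDS",
    "LOG_SCALE_PARAMETERS",
    "MMHG_PER_PERCENT",
    "O2_KG_M3_PER_PERCENT",
    "O2_MOL_ML_PER_PERCENT",
    "GLUCOSE_KG_M3_PER_MM",
    "VEGF_PG_ML_PER_KG_M3",
    "convert_oxygen",
    "oxygen_sink",
    "glucose_sink",
    "vegf_source",
    "death_rate",
    "load_parameters",
    "save_parameters",
    "final_fit_parameters",
    "check_bounds",
]

# ---------------------------------------------------------------------------
# Unit system
# ---------------------------------------------------------------------------

#: 1 % ambient O2 corresponds to 7.6 mmHg partial pressure at the probe.
MMHG_PER_PERCENT = 7.6

#: Dissolved-oxygen solubility: 1 % ambient O2 <-> 1.33e-8 mol/mL in medium.
#: Chosen to reproduce the dual listing of the oxygen half-saturation
#: constant (1.65e-8 mol/mL <-> 1.24 % O2); the small residual mismatch with
#: the kg/m^3 column is documented in docs/methods.md, not absorbed here.
O2_MOL_ML_PER_PERCENT = 1.33e-8

#: O2 molar mass, kg/mol.
O2_MOLAR_MASS = 0.032

#: kg/m^3 of dissolved O2 per % ambient O2 (1 mol/mL = 1e6 mol/m^3).
O2_KG_M3_PER_PERCENT = O2_MOL_ML_PER_PERCENT * 1e6 * O2_MOLAR_MASS

#: Glucose: 1 mM = 0.18016 kg/m^3 (molar mass 180.16 g/mol).
GLUCOSE_KG_M3_PER_MM = 0.18016

#: VEGF: 1 kg/m^3 = 1e9 pg/mL.
VEGF_PG_ML_PER_KG_M3 = 1e9

#: cells/mL -> cells/m^3
CELLS_M3_PER_ML = 1e6

_O2_UNIT_TO_PERCENT = {
    "percent": 1.0,
    "mmHg": 1.0 / MMHG_PER_PERCENT,
    "kg/m^3": 1.0 / O2_KG_M3_PER_PERCENT,
    "mol/mL": 1.0 / O2_MOL_ML_PER_PERCENT,
}


def convert_oxygen(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a dissolved/ambient oxygen value between unit systems.

    Supported units: ``percent`` (ambient O2 fraction), ``mmHg`` (partial
    pressure), ``kg/m^3`` and ``mol/mL`` (dissolved mass / molar
    concentration).  All conversions are linear through a single module-level
    solubility constant, so round trips are identities to machine precision.
    """
    for u in (from_unit, to_unit):
        if u not in _O2_UNIT_TO_PERCENT:
            raise ValueError(
                f"unknown oxygen unit {u!r}; expected one of {sorted(_O2_UNIT_TO_PERCENT)}"
            )
    if value < 0:
        raise ValueError(f"oxygen value must be nonnegative, got {value}")
    percent = value * _O2_UNIT_TO_PERCENT[from_unit]
    return percent / _O2_UNIT_TO_PERCENT[to_unit]


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """The 19 free constants of the cell-solute model, in modeling units.

    ``n_max`` is carried as metadata only: with the proliferation rate fixed
    at zero the maximal packing density enters no governing equation.
    """

    # oxygen transport & consumption
    D_c_gel: float  # O2 diffusivity in gel, m^2/s
    D_c_med: float  # O2 diffusivity in medium, m^2/s
    M_c: float      # maximal O2 consumption, kg/cell/s
    c_half: float   # O2 half-saturation, kg/m^3
    # glucose transport & consumption
    D_s_gel: float  # glucose diffusivity in gel, m^2/s
    D_s_med: float  # glucose diffusivity in medium, m^2/s
    M_s: float      # maximal glucose consumption, kg/cell/s
    s_half: float   # glucose half-saturation, kg/m^3
    A: float        # anaerobic enhancement factor, dimensionless
    # VEGF transport, turnover & secretion
    D_v_gel: float  # VEGF diffusivity in gel, m^2/s
    D_v_med: float  # VEGF diffusivity in medium, m^2/s
    K_v: float      # VEGF degradation rate, 1/s
    alpha: float    # O2-proportional secretion, kg/cell/s per (kg O2/m^3)
    beta: float     # hypoxia-gated secretion, kg/cell/s
    c_tau: float    # hypoxic threshold for secretion, kg/m^3
    n_tau: float    # crowding factor, cell/m^3
    # death kinetics
    delta_0: float  # baseline death rate, 1/s
    delta_c: float  # hypoxic death rate, 1/s
    delta_s: float  # glucose-deprivation death rate, 1/s
    # metadata (not a free model constant)
    n_max: float = 6.0e13  # maximal cell density, cell/m^3

    def __post_init__(self) -> None:
        for name in FREE_PARAMETER_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")

    def free_values(self) -> dict[str, float]:
        """The 19 free constants as an ordered name -> value mapping."""
        return {name: getattr(self, name) for name in FREE_PARAMETER_NAMES}

    def replace(self, **kwargs: float) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.free_values().items())


#: Canonical ordering of the 19 free model constants.
FREE_PARAMETER_NAMES: tuple[str, ...] = (
    "D_c_gel", "D_c_med", "M_c", "c_half",
    "D_s_gel", "D_s_med", "M_s", "s_half", "A",
    "D_v_gel", "D_v_med", "K_v", "alpha", "beta", "c_tau", "n_tau",
    "delta_0", "delta_c", "delta_s",
)

_STRICTLY_POSITIVE = (
    "D_c_gel", "D_c_med", "c_half",
    "D_s_gel", "D_s_med", "s_half",
    "D_v_gel", "D_v_med", "c_tau", "n_tau",
)

#: Literature-informed search intervals per parameter, modeling units.
#: Diffusivities quoted in cm^2/s are converted (x 1e-4), molar consumption
#: rates via the species molar mass, %O2 thresholds via the solubility
#: constant, mM via the glucose molar mass and cells/mL via x 1e6.
#: A, alpha and beta had no literature interval; the packaged choices bracket
#: the final-fit values by about an order of magnitude either side.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "D_c_gel": (1e-10, 4e-10),
    "D_c_med": (1e-9, 4e-9),
    "M_c": (1e-18 * O2_MOLAR_MASS, 7.7e-16 * O2_MOLAR_MASS),
    "c_half": (6.66e-9 * 1e6 * O2_MOLAR_MASS, 4e-8 * 1e6 * O2_MOLAR_MASS),
    "D_s_gel": (0.23e-6 * 1e-4, 1.51e-6 * 1e-4),
    "D_s_med": (5.65e-6 * 1e-4, 1.09e-5 * 1e-4),
    "M_s": (5e-17 * 0.18016, 2.2e-16 * 0.18016),
    "s_half": (2 * GLUCOSE_KG_M3_PER_MM, 10 * GLUCOSE_KG_M3_PER_MM),
    "A": (0.5, 10.0),
    "D_v_gel": (2.9e-7 * 1e-4, 1.13e-6 * 1e-4),
    "D_v_med": (1.3e-6 * 1e-4, 2e-6 * 1e-4),
    "K_v": (2.67e-6, 1.28e-4),
    "alpha": (1e-22, 1e-19),
    "beta": (1e-23, 1e-20),
    "c_tau": (0.1 * O2_KG_M3_PER_PERCENT, 2 * O2_KG_M3_PER_PERCENT),
    "n_tau": (1e6 * CELLS_M3_PER_ML, 60e6 * CELLS_M3_PER_ML),
    "delta_0": (3.3e-7, 1.1334e-5),
    "delta_c": (1.7e-8, 4e-6),
    "delta_s": (1.7e-8, 4e-6),
}

#: Parameters whose interval spans >= 2 decades are explored in log10 space
#: by the screening and calibration machinery (uniform linear sampling over
#: e.g. [3.2e-20, 2.5e-17] would almost never visit the lower decades).
LOG_SCALE_PARAMETERS: frozenset[str] = frozenset(
    name for name, (lo, hi) in PARAMETER_BOUNDS.items() if hi / lo >= 100.0
)


def calibration_bounds(nominal: ParameterSet | None = None,
                       margin: float = 3.0) -> dict[str, tuple[float, float]]:
    """Search intervals for calibration: the literature intervals, widened
    where necessary to contain the nominal values.

    Screening alone cannot fix intervals — several published final values sit
    outside the literature ranges — so the fitting intervals are the union of
    each literature interval with ``[nominal/margin, nominal*margin]``.  This
    guarantees the nominal (or synthetic ground-truth) vector is
    representable while keeping the literature width elsewhere.
    """
    nominal = final_fit_parameters() if nominal is None else nominal
    out = {}
    for name, (lo, hi) in PARAMETER_BOUNDS.items():
        v = getattr(nominal, name)
        if v > 0:
            lo, hi = min(lo, v / margin), max(hi, v * margin)
        out[name] = (lo, hi)
    return out


def check_bounds(p: ParameterSet, bounds: dict[str, tuple[float, float]] | None = None) -> list[str]:
    """Names of free parameters lying outside their search interval.

    The packaged final-fit set violates four intervals (``D_c_gel``,
    ``D_s_med``, ``D_s_gel``, ``M_s``); the anomaly is documented in
    docs/methods.md and preserved verbatim rather than silently corrected.
    """
    bounds = PARAMETER_BOUNDS if bounds is None else bounds
    out = []
    for name, value in p.free_values().items():
        lo, hi = bounds[name]
        if not (lo <= value <= hi):
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# Reaction kinetics (pointwise, modeling units)
# ---------------------------------------------------------------------------


def _check_nonnegative(**values: object) -> None:
    import numpy as _np

    for name, v in values.items():
        if _np.any(_np.asarray(v) < 0):
            raise ValueError(f"{name} must be nonnegative")


def oxygen_sink(c, n, p: ParameterSet):
    """Volumetric oxygen consumption rate, kg m^-3 s^-1 (returned >= 0).

    Michaelis–Menten in the local oxygen concentration, proportional to the
    viable cell density: ``M_c n c/(c + c_half)``.
    """
    _check_nonnegative(c=c, n=n)
    return p.M_c * n * c / (c + p.c_half)


def glucose_sink(c, s, n, p: ParameterSet):
    """Volumetric glucose consumption rate, kg m^-3 s^-1 (returned >= 0).

    Michaelis–Menten in glucose with an anaerobic enhancement factor
    ``1 + A c_half/(c + c_half)`` — glycolytic compensation turns on over the
    same oxygen scale at which aerobic consumption weakens, approaching
    ``1 + A`` in anoxia and 1 in abundant oxygen.
    """
    _check_nonnegative(c=c, s=s, n=n)
    return p.M_s * n * s / (s + p.s_half) * (1.0 + p.A * p.c_half / (c + p.c_half))


def vegf_source(c, n, p: ParameterSet):
    """Volumetric VEGF secretion rate, kg m^-3 s^-1.

    Per-cell output ``alpha c + beta exp(-c/c_tau)`` — an oxygen-proportional
    baseline plus a hypoxia-gated surge — saturated in density by the
    crowding factor: the whole source is divided by ``1 + n/n_tau``, so the
    per-cell rate halves at ``n = n_tau``.
    """
    _check_nonnegative(c=c, n=n)
    import numpy as np

    per_cell = p.alpha * c + p.beta * np.exp(-np.asarray(c, dtype=float) / p.c_tau)
    return n * per_cell / (1.0 + n / p.n_tau)


def death_rate(c, s, n, p: ParameterSet):
    """Rate of change of viable cell density, cell m^-3 s^-1 (always <= 0).

    Death-only kinetics: a baseline rate ``delta_0`` plus oxygen- and
    glucose-deprivation terms gated by the same half-saturation scales as the
    consumption kinetics.  Magnitude lies in ``[n delta_0,
    n (delta_0 + delta_c + delta_s)]`` for all nonnegative concentrations.
    """
    _check_nonnegative(c=c, s=s, n=n)
    return -n * specific_death_rate(c, s, p)


def specific_death_rate(c, s, p: ParameterSet):
    """Per-cell death rate delta(c, s) in 1/s (positive)."""
    return (
        p.delta_0
        + p.delta_c * p.c_half / (c + p.c_half)
        + p.delta_s * p.s_half / (s + p.s_half)
    )


# ---------------------------------------------------------------------------
# Serialization & packaged final-fit values
# ---------------------------------------------------------------------------

_FIXTURE_RESOURCE = "final_params.yaml"


def save_parameters(p: ParameterSet, path) -> None:
    """Write a flat key-value YAML file, one key per model constant (SI units)."""
    payload = {name: float(v) for name, v in p.free_values().items()}
    payload["n_max"] = float(p.n_max)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_parameters(path) -> ParameterSet:
    """Read a ParameterSet from a flat key-value YAML file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _params_from_mapping(payload, source=str(path))


def _params_from_mapping(payload: dict, source: str = "<mapping>") -> ParameterSet:
    if not isinstance(payload, dict):
        raise ValueError(f"{source}: expected a flat key-value mapping")
    known = set(FREE_PARAMETER_NAMES) | {"n_max"}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"{source}: unknown parameter keys {sorted(unknown)}")
    missing = set(FREE_PARAMETER_NAMES) - set(payload)
    if missing:
        raise ValueError(f"{source}: missing parameter keys {sorted(missing)}")
    return ParameterSet(**{k: float(v) for k, v in payload.items()})


def practical_units(p: ParameterSet) -> dict[str, str]:
    """Render the parameter set in bench/assay units for reports."""
    return {
        "D_c_gel": f"{p.D_c_gel * 1e4:.3g} cm^2/s",
        "D_c_med": f"{p.D_c_med * 1e4:.3g} cm^2/s",
        "M_c": f"{p.M_c / O2_MOLAR_MASS:.3g} mol/cell/s",
        "c_half": f"{convert_oxygen(p.c_half, 'kg/m^3', 'mol/mL'):.3g} mol/mL "
                  f"({convert_oxygen(p.c_half, 'kg/m^3', 'percent'):.3g}% O2)",
        "D_s_gel": f"{p.D_s_gel * 1e4:.3g} cm^2/s",
        "D_s_med": f"{p.D_s_med * 1e4:.3g} cm^2/s",
        "M_s": f"{p.M_s / 0.18016:.3g} mol/cell/s",
        "s_half": f"{p.s_half / GLUCOSE_KG_M3_PER_MM:.3g} mM",
        "A": f"{p.A:.3g}",
        "D_v_gel": f"{p.D_v_gel * 1e4:.3g} cm^2/s",
        "D_v_med": f"{p.D_v_med * 1e4:.3g} cm^2/s",
        "K_v": f"{p.K_v:.3g} 1/s",
        "alpha": f"{p.alpha * 1e15:.3g} pg/cell/s per (kg O2/m^3)",
        "beta": f"{p.beta * 1e15:.3g} pg/cell/s",
        "c_tau": f"{convert_oxygen(p.c_tau, 'kg/m^3', 'percent'):.3g}% O2",
        "n_tau": f"{p.n_tau / CELLS_M3_PER_ML:.3g} cells/mL",
        "delta_0": f"{p.delta_0:.3g} 1/s",
        "delta_c": f"{p.delta_c:.3g} 1/s",
        "delta_s": f"{p.delta_s:.3g} 1/s",
    }


def final_fit_parameters() -> ParameterSet:
    """The packaged final-fit (calibrated) parameter values, modeling units."""
    ref = importlib.resources.files("cellsolute.data").joinpath(_FIXTURE_RESOURCE)
    payload = yaml.safe_load(ref.read_text())
    return _params_from_mapping(payload, source=_FIXTURE_RESOURCE)
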