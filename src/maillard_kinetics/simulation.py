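"""Forward simulation of the reaction network and the observation model.

Integrates the mass-action ODE system over the heating protocol (0-21 min)
and provides the unit conversions of the observation model: mass
concentration (ug/mL) to molar (mmol/L) via molar mass, and melanoidin
absorbance at 470 nm to mmol/L via Lambert-Beer with epsilon = 282
L/(mol·cm).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint, solve_ivp

from .reaction_model import (
    IDX,
    MOLAR_MASS_G_PER_MOL,
    N_SPECIES,
    SPECIES,
    ModelSystemSpec,
    RateConstants,
    make_odesys,
)

__all__ = [
    "DESIGN_TIMES",
    "MELANOIDIN_EXTINCTION_L_PER_MOL_CM",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "melanoidin_concentration",
    "melanoidin_absorbance",
    "mass_to_molar",
    "molar_to_mass",
]

logger = logging.getLogger(__name__)

#: Sampling design: vials pulled from the oil bath every 3 min up to 21 min,
#: plus the unheated t = 0 anchor.
DESIGN_TIMES: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)

#: Extinction coefficient of glucose/asparagine melanoidins at 470 nm.
MELANOIDIN_EXTINCTION_L_PER_MOL_CM: float = 282.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a trajectory."""


@dataclass
class Trajectory:
    """A solved concentration time course (time x species, mmol/L)."""

    spec: ModelSystemSpec
    k: RateConstants
    times: np.ndarray
    values: np.ndarray
    rel_tol: float
    abs_tol: float
    method: str
    clip_magnitude: float = 0.0

    def species(self, name: str) -> np.ndarray:
        """Concentration time course of one species."""
        if name not in IDX:
            raise KeyError(f"unknown species {name!r}")
        return self.values[:, IDX[name]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: time_min, species, value (mmol/L)."""
        nt = len(self.times)
        return pd.DataFrame(
            {
                "time_min": np.repeat(self.times, N_SPECIES),
                "species": np.tile(np.array(SPECIES, dtype=object), nt),
                "value": self.values.ravel(),
            }
        )


def integrate(
    spec: ModelSystemSpec,
    k: RateConstants,
    times: Sequence[float] = DESIGN_TIMES,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Solve the reaction ODEs and report concentrations at ``times``.

    ``times`` must start at 0 and increase strictly.  A stiff-capable
    solver is the default: the active constants span roughly four orders
    of magnitude and amino-acid depletion creates a fast initial layer.
    Tiny negative excursions (solver tolerance artefacts) are clipped to
    zero on output; the clip magnitude is recorded on the trajectory.
    """
    times = np.asarray(list(times), dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if times[0] != 0.0:
        raise ValueError(f"times must start at 0, got {times[0]}")
    if len(times) > 1 and not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    if not (rel_tol > 0 and abs_tol > 0):
        raise ValueError("tolerances must be > 0")

    y0 = spec.initial_state()
    if len(times) == 1:
        return Trajectory(spec, k, times, y0[None, :].copy(), rel_tol, abs_tol, method)

    rhs, jac = make_odesys(spec, k)
    if method == "LSODA":
        # the light odeint wrapper around LSODA; noticeably faster than
        # solve_ivp's stepping loop for this small system
        with warnings.catch_warnings():
            # failures are detected from the info dict and reported below
            warnings.simplefilter("ignore", ODEintWarning)
            raw, info = odeint(
                rhs,
                y0,
                times,
                Dfun=jac,
                tfirst=True,
                rtol=rel_tol,
                atol=abs_tol,
                full_output=True,
                printmessg=False,
                mxstep=20000,
            )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE solver LSODA failed for {spec.condition_id} "
                f"(rel_tol={rel_tol}, abs_tol={abs_tol}): {info['message']}"
            )
    else:
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            y0,
            method=method,
            t_eval=times,
            rtol=rel_tol,
            atol=abs_tol,
            jac=jac if method in ("BDF", "Radau") else None,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver {method} failed for {spec.condition_id} "
                f"(rel_tol={rel_tol}, abs_tol={abs_tol}): {sol.message}"
            )
        raw = sol.y.T
    clip = max(0.0, float(-raw.min()))
    return Trajectory(
        spec=spec,
        k=k,
        times=times,
        values=np.clip(raw, 0.0, None),
        rel_tol=rel_tol,
        abs_tol=abs_tol,
        method=method,
        clip_magnitude=clip,
    )


# --------------------------------------------------------------------------
# Observation-model unit conversions
# --------------------------------------------------------------------------


def melanoidin_concentration(
    absorbance_470: float,
    path_cm: float = 1.0,
    extinction: float = MELANOIDIN_EXTINCTION_L_PER_MOL_CM,
) -> float:
    """Melanoidin concentration (mmol/L) from absorbance at 470 nm.

    Lambert-Beer: A = epsilon * c * l, so c = A/(epsilon*l) mol/L, times
    1000 for mmol/L.
    """
    if not math.isfinite(absorbance_470):
        raise ValueError(f"absorbance must be finite, got {absorbance_470}")
    if absorbance_470 < 0:
        raise ValueError(f"absorbance must be >= 0, got {absorbance_470}")
    if not (path_cm > 0 and extinction > 0):
        raise ValueError("path length and extinction coefficient must be > 0")
    return 1000.0 * absorbance_470 / (extinction * path_cm)


def melanoidin_absorbance(
    concentration_mmolL: float,
    path_cm: float = 1.0,
    extinction: float = MELANOIDIN_EXTINCTION_L_PER_MOL_CM,
) -> float:
    """Inverse of :func:`melanoidin_concentration` (simulated A470)."""
    if not math.isfinite(concentration_mmolL) or concentration_mmolL < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {concentration_mmolL}")
    if not (path_cm > 0 and extinction > 0):
        raise ValueError("path length and extinction coefficient must be > 0")
    return concentration_mmolL * extinction * path_cm / 1000.0


def mass_to_molar(
    value_ug_per_ml: float,
    species: str,
    molar_mass: dict[str, float | None] | None = None,
) -> float:
    """Convert ug/mL to mmol/L for a species with a defined molar mass.

    ug/mL equals mg/L, and mg/L divided by g/mol is mmol/L.  Melanoidins
    have no molar mass; use :func:`melanoidin_concentration` instead.
    """
    masses = MOLAR_MASS_G_PER_MOL if molar_mass is None else molar_mass
    if species not in masses:
        raise KeyError(f"unknown species {species!r}")
    m = masses[species]
    if m is None:
        raise ValueError(
            "melanoidins have no molar mass; convert via melanoidin_concentration"
        )
    if not math.isfinite(value_ug_per_ml) or value_ug_per_ml < 0:
        raise ValueError(f"mass concentration must be finite and >= 0, got {value_ug_per_ml}")
    return value_ug_per_ml / m


def molar_to_mass(
    value_mmolL: float,
    species: str,
    molar_mass: dict[str, float | None] | None = None,
) -> float:
    """Inverse of :func:`mass_to_molar`."""
    masses = MOLAR_MASS_G_PER_MOL if molar_mass is None else molar_mass
    if species not in masses:
        raise KeyError(f"unknown species {species!r}")
    m = masses[species]
    if m is None:
        raise ValueError("melanoidins have no molar mass; convert via melanoidin_absorbance")
    if not math.isfinite(value_mmolL) or value_mmolL < 0:
        raise ValueError(f"molar concentration must be finite and >= 0, got {value_mmolL}")
    return value_mmolL * m
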