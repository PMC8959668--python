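"""Synthetic concentration datasets emulating the experimental design.

The sampling design being emulated: four amino-acid/glucose model systems,
two oil-bath temperatures (170 and 200 C), vials sampled at 3-21 min in
3-min steps (plus the unheated t = 0 anchor), triplicate measurements, and
measurement scatter that grows with concentration — modelled as
multiplicative Gaussian noise, value = truth * (1 + eps), eps ~ N(0, cv),
truncated at zero.

``table1_scenarios`` exposes the eight tabulated estimation conditions
(system x temperature) as ready-to-simulate truth parameter sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .reaction_model import (
    IDX,
    N_SPECIES,
    SPECIES,
    ModelSystemSpec,
    RateConstants,
    build_model_system,
)
from .simulation import DESIGN_TIMES, Trajectory, integrate

__all__ = [
    "NoiseModel",
    "Dataset",
    "generate_dataset",
    "Scenario",
    "TABLE1_PRINTED",
    "SCENARIO_IDS",
    "table1_scenarios",
    "table1_scenario",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement-noise specification.

    cv
        Relative standard deviation of the multiplicative noise; the
        default 0.05 reflects triplicate scatter of roughly 5-10%.
    floor_mmolL
        Additive detection floor: generated values below it are censored
        to zero (off by default).
    seed
        Seed of the generator; identical seed and inputs give identical
        datasets.
    """

    cv: float = 0.05
    floor_mmolL: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cv) and self.cv >= 0):
            raise ValueError(f"cv must be finite and >= 0, got {self.cv}")
        if not (math.isfinite(self.floor_mmolL) and self.floor_mmolL >= 0):
            raise ValueError(f"floor_mmolL must be finite and >= 0, got {self.floor_mmolL}")


@dataclass
class Dataset:
    """Tidy replicated concentration observations for one condition.

    ``observations`` has columns time_min, replicate, species, value with
    values already in mmol/L.  ``provenance`` records the truth parameters
    and noise model when the dataset is synthetic, so it can be regenerated
    exactly.  ``header_lines`` preserves the comment header of a file the
    dataset was read from (for byte-identical round trips).
    """

    spec: ModelSystemSpec
    observations: pd.DataFrame
    provenance: dict | None = None
    header_lines: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"time_min", "replicate", "species", "value"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.observations["time_min"].to_numpy(dtype=float))

    @property
    def n_replicates(self) -> int:
        return int(self.observations["replicate"].nunique())

    def species_observed(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.observations["species"]))

    def averaged(self) -> "Dataset":
        """Replicates collapsed to their mean (single pseudo-replicate)."""
        mean = (
            self.observations.groupby(["time_min", "species"], sort=False, as_index=False)[
                "value"
            ]
            .mean()
            .assign(replicate=1)
        )[["time_min", "replicate", "species", "value"]]
        return Dataset(
            spec=self.spec,
            observations=mean,
            provenance=self.provenance,
            header_lines=self.header_lines,
        )


def generate_dataset(
    spec: ModelSystemSpec,
    k: RateConstants,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    times: Sequence[float] = DESIGN_TIMES,
    include_t0: bool = True,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> Dataset:
    """Simulate the truth trajectory and draw noisy replicate observations.

    Every tracked species is reported at every design time for every
    replicate; species the system cannot produce simply carry zeros (the
    estimator excludes them).  Full provenance is recorded.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    traj = integrate(spec, k, times=times, rel_tol=rel_tol, abs_tol=abs_tol)
    truth = traj.values  # (nt, n_species)
    nt = len(traj.times)

    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.cv, size=(n_replicates, nt, N_SPECIES)) if noise.cv > 0 else np.zeros(
        (n_replicates, nt, N_SPECIES)
    )
    values = np.clip(truth[None, :, :] * (1.0 + eps), 0.0, None)
    if noise.floor_mmolL > 0:
        values = np.where(values < noise.floor_mmolL, 0.0, values)

    frames = []
    for rep in range(n_replicates):
        frames.append(
            pd.DataFrame(
                {
                    "time_min": np.repeat(traj.times, N_SPECIES),
                    "replicate": rep + 1,
                    "species": np.tile(np.array(SPECIES, dtype=object), nt),
                    "value": values[rep].ravel(),
                }
            )
        )
    obs = pd.concat(frames, ignore_index=True)
    if not include_t0:
        obs = obs[obs["time_min"] > 0].reset_index(drop=True)

    provenance = {
        "system": spec.name,
        "temperature_C": spec.temperature_C,
        "initial_mmolL": {s: v for s, v in spec.initial_mmolL.items() if v > 0},
        "k_natural": list(k.k),
        "e_natural": list(k.e),
        "cv": noise.cv,
        "floor_mmolL": noise.floor_mmolL,
        "seed": noise.seed,
        "n_replicates": n_replicates,
        "times": [float(t) for t in traj.times],
        "include_t0": include_t0,
    }
    return Dataset(spec=spec, observations=obs, provenance=provenance)


def regenerate_from_provenance(provenance: dict) -> Dataset:
    """Rebuild a synthetic dataset exactly from its recorded provenance."""
    spec = build_model_system(
        provenance["system"],
        provenance["temperature_C"],
        initial_mmolL=provenance.get("initial_mmolL"),
    )
    k = RateConstants(k=tuple(provenance["k_natural"]), e=tuple(provenance["e_natural"]))
    noise = NoiseModel(
        cv=provenance["cv"],
        floor_mmolL=provenance.get("floor_mmolL", 0.0),
        seed=provenance["seed"],
    )
    times = provenance["times"]
    if provenance.get("include_t0", True) is False:
        times = [0.0] + [t for t in times if t > 0]
    return generate_dataset(
        spec,
        k,
        noise,
        n_replicates=provenance["n_replicates"],
        times=times,
        include_t0=provenance.get("include_t0", True),
    )


# --------------------------------------------------------------------------
# Tabulated estimation conditions (truth sets for recovery studies)
# --------------------------------------------------------------------------


class Scenario(NamedTuple):
    id: str
    spec: ModelSystemSpec
    k: RateConstants


#: Printed-scale rate constants of the eight tabulated conditions.
#: Scales: k3, k4 in 1e-2 min^-1; k9, k10 in 1e-3 min^-1; others min^-1.
#: Absent keys are the tabulated dashes (constant inactive in that system).
TABLE1_PRINTED: dict[str, dict[int, float]] = {
    "Lys-Glu-170": {1: 0.135, 2: 0.030, 3: 0.042, 4: 0.721, 6: 0.041, 7: 0.012, 11: 2.198},
    "Trp-Glu-170": {1: 0.172, 2: 0.029, 6: 0.049, 7: 0.006, 9: 0.006, 10: 0.019, 11: 1.833},
    "Asn-Glu-170": {1: 0.257, 2: 0.015, 5: 0.062, 6: 0.197, 7: 0.105, 8: 0.103, 11: 1.579},
    "Com-Glu-170": {
        1: 0.199, 2: 0.023, 3: 0.015, 4: 0.523, 5: 0.050, 6: 0.114,
        7: 0.072, 8: 0.071, 9: 0.012, 10: 0.015, 11: 1.420,
    },
    "Lys-Glu-200": {1: 0.178, 2: 0.029, 3: 0.072, 4: 0.441, 6: 0.027, 7: 0.014, 11: 2.369},
    "Trp-Glu-200": {1: 0.199, 2: 0.029, 6: 0.045, 7: 0.005, 9: 0.007, 10: 0.063, 11: 2.480},
    "Asn-Glu-200": {1: 0.143, 2: 0.037, 5: 0.095, 6: 0.237, 7: 0.114, 8: 0.112, 11: 1.864},
    "Com-Glu-200": {
        1: 0.160, 2: 0.026, 3: 0.022, 4: 0.211, 5: 0.089, 6: 0.155,
        7: 0.101, 8: 0.099, 9: 0.028, 10: 0.052, 11: 1.882,
    },
}

SCENARIO_IDS: tuple[str, ...] = tuple(TABLE1_PRINTED)

_ID_TO_SYSTEM = {
    "Lys-Glu": "Lys/Glu",
    "Trp-Glu": "Trp/Glu",
    "Asn-Glu": "Asn/Glu",
    "Com-Glu": "Com/Glu",
}


def table1_scenario(scenario_id: str) -> Scenario:
    """One tabulated condition as a ready-to-simulate truth set."""
    if scenario_id not in TABLE1_PRINTED:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; valid: {', '.join(SCENARIO_IDS)}"
        )
    prefix, temp = scenario_id.rsplit("-", 1)
    spec = build_model_system(_ID_TO_SYSTEM[prefix], int(temp))
    k = RateConstants.from_printed(TABLE1_PRINTED[scenario_id])
    return Scenario(id=scenario_id, spec=spec, k=k)


def table1_scenarios() -> list[Scenario]:
    """All eight tabulated conditions (system x temperature)."""
    return [table1_scenario(sid) for sid in SCENARIO_IDS]
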