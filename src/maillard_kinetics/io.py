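"""Tidy CSV dataset format, fit reports, and configuration files.

Dataset files are plain UTF-8 CSV (comma separator, ``.`` decimal point)
with optional leading comment lines beginning ``#`` (provenance) and the
exact header::

    model_system,temperature_C,time_min,replicate,species,value,unit

``unit`` is ``mmol/L``, ``ug/mL`` (converted on load via molar mass; not
valid for melanoidins) or ``A470`` (absorbance at 470 nm; melanoidins
only, converted via Lambert-Beer).  All values are stored as mmol/L in
memory.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .reaction_model import (
    MOLAR_MASS_G_PER_MOL,
    SPECIES,
    ModelSystemSpec,
    RateConstants,
    build_model_system,
    natural_to_printed,
)
from .simulation import (
    MELANOIDIN_EXTINCTION_L_PER_MOL_CM,
    mass_to_molar,
    melanoidin_concentration,
)
from .synthetic_data import Dataset

__all__ = [
    "CSV_COLUMNS",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "write_fit_report",
    "load_config",
    "build_system_from_config",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS: tuple[str, ...] = (
    "model_system",
    "temperature_C",
    "time_min",
    "replicate",
    "species",
    "value",
    "unit",
)
VALID_UNITS = ("mmol/L", "ug/mL", "A470")


class DatasetFormatError(ValueError):
    """A dataset file violates the tidy CSV contract."""


def _fmt(v: float) -> str:
    return format(float(v), ".12g")


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    *,
    extra_header: Iterable[str] = (),
) -> None:
    """Write a dataset as tidy CSV (values in mmol/L).

    The comment header embeds provenance: either the header preserved
    from the file the dataset was read from (verbatim, so write-read-write
    round trips are byte-identical) or a generated one including the
    synthetic-truth record.
    """
    path = Path(path)
    lines: list[str] = []
    if dataset.header_lines:
        lines.extend(dataset.header_lines)
    else:
        lines.append(f"# maillard-kinetics v{__version__} dataset")
        for extra in extra_header:
            lines.append(f"# {extra}" if not extra.startswith("#") else extra)
        if dataset.provenance is not None:
            lines.append(
                "# provenance: " + json.dumps(dataset.provenance, sort_keys=True)
            )
    rows = [",".join(CSV_COLUMNS)]
    sysname = dataset.spec.name
    temp = dataset.spec.temperature_C
    for rec in dataset.observations.itertuples(index=False):
        rows.append(
            f"{sysname},{temp},{_fmt(rec.time_min)},{int(rec.replicate)},"
            f"{rec.species},{_fmt(rec.value)},mmol/L"
        )
    path.write_text("\n".join(lines + rows) + "\n", encoding="utf-8")
    logger.info("wrote %d observations to %s", len(dataset.observations), path)


def read_dataset(path: str | Path, config: Mapping | None = None) -> Dataset:
    """Read and validate a tidy CSV dataset, converting all units to mmol/L.

    Violations (unknown species, negative value, unit rules, inconsistent
    condition) are rejected naming the offending 1-based file row.
    """
    path = Path(path)
    cfg = config or {}
    masses = dict(MOLAR_MASS_G_PER_MOL)
    masses.update(cfg.get("molar_mass", {}))
    extinction = float(cfg.get("extinction_L_per_mol_cm", MELANOIDIN_EXTINCTION_L_PER_MOL_CM))
    path_cm = float(cfg.get("path_cm", 1.0))

    header_lines: list[str] = []
    provenance = None
    data_rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if stripped.startswith("#"):
                if header is not None:
                    raise DatasetFormatError(f"{path}:{lineno}: comment after header")
                header_lines.append(stripped)
                if stripped.startswith("# provenance: "):
                    provenance = json.loads(stripped[len("# provenance: "):])
                continue
            if not stripped.strip():
                continue
            fields = next(csv.reader([stripped]))
            if header is None:
                header = fields
                if tuple(header) != CSV_COLUMNS:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: header must be exactly "
                        f"{','.join(CSV_COLUMNS)}, got {','.join(header)}"
                    )
                continue
            data_rows.append((lineno, fields))
    if header is None or not data_rows:
        raise DatasetFormatError(f"{path}: no data rows found")

    records = []
    condition: tuple[str, int] | None = None
    for lineno, fields in data_rows:
        if len(fields) != len(CSV_COLUMNS):
            raise DatasetFormatError(
                f"{path}:{lineno}: expected {len(CSV_COLUMNS)} fields, got {len(fields)}"
            )
        sysname, temp_s, time_s, rep_s, species, value_s, unit = fields
        try:
            temp = int(temp_s)
            time_min = float(time_s)
            replicate = int(rep_s)
            value = float(value_s)
        except ValueError as exc:
            raise DatasetFormatError(f"{path}:{lineno}: {exc}") from exc
        if condition is None:
            condition = (sysname, temp)
        elif (sysname, temp) != condition:
            raise DatasetFormatError(
                f"{path}:{lineno}: condition ({sysname}, {temp}) differs from "
                f"{condition}; one file holds one condition"
            )
        if species not in SPECIES:
            raise DatasetFormatError(f"{path}:{lineno}: unknown species {species!r}")
        if not value >= 0:
            raise DatasetFormatError(f"{path}:{lineno}: negative value {value}")
        if replicate < 1:
            raise DatasetFormatError(f"{path}:{lineno}: replicate must be >= 1")
        if unit not in VALID_UNITS:
            raise DatasetFormatError(
                f"{path}:{lineno}: unknown unit {unit!r}; valid: {', '.join(VALID_UNITS)}"
            )
        if unit == "A470" and species != "MEL":
            raise DatasetFormatError(
                f"{path}:{lineno}: unit A470 is only valid for MEL, not {species}"
            )
        if unit == "ug/mL" and species == "MEL":
            raise DatasetFormatError(
                f"{path}:{lineno}: melanoidins have no molar mass; use A470 or mmol/L"
            )
        if unit == "ug/mL":
            value = mass_to_molar(value, species, masses)
        elif unit == "A470":
            value = melanoidin_concentration(value, path_cm, extinction)
        records.append((time_min, replicate, species, value))

    assert condition is not None
    spec = build_system_from_config(cfg, condition[0], condition[1])
    obs = pd.DataFrame(records, columns=["time_min", "replicate", "species", "value"])
    return Dataset(
        spec=spec,
        observations=obs,
        provenance=provenance,
        header_lines=tuple(header_lines),
    )


# --------------------------------------------------------------------------
# Fit reports
# --------------------------------------------------------------------------


def write_fit_report(
    result,
    spec: ModelSystemSpec,
    out_prefix: str | Path,
    extra_header: Iterable[str] = (),
) -> tuple[Path, Path]:
    """Write ``<prefix>.txt`` (key-value summary) and ``<prefix>.csv``
    (estimates in natural and printed scales).  Returns both paths.
    """
    out_prefix = Path(out_prefix)
    txt = out_prefix.with_suffix(".txt")
    csvp = out_prefix.with_suffix(".csv")

    lines = [
        f"# maillard-kinetics v{__version__} fit report",
        *(f"# {h}" if not h.startswith("#") else h for h in extra_header),
        f"condition: {spec.condition_id}",
        f"converged: {result.converged}",
        f"iterations: {result.iterations}",
        f"n_obs: {result.n_obs}",
        f"ssr: {_fmt(result.ssr)}",
        f"multimodal_warning: {result.multimodal}",
        f"excluded_species: {','.join(result.excluded_species) or 'none'}",
        f"free_constants: {','.join('k%d' % i for i in result.free_indices)}",
    ]
    for s, r2 in result.per_response_r2.items():
        lines.append(f"R2[{s}]: {_fmt(r2)}")
    txt.write_text("\n".join(lines) + "\n", encoding="utf-8")

    rows = ["index,natural_min_inv,printed_value,printed_unit"]
    unit_label = {1e-2: "1e-2 min^-1", 1e-3: "1e-3 min^-1", 1.0: "min^-1"}
    from .reaction_model import PRINTED_SCALE

    for i in result.free_indices:
        nat = result.estimates[i]
        rows.append(
            f"k{i},{_fmt(nat)},{_fmt(natural_to_printed(nat, i))},"
            f"{unit_label[PRINTED_SCALE[i]]}"
        )
    csvp.write_text("\n".join(rows) + "\n", encoding="utf-8")
    logger.info("wrote fit report %s / %s", txt, csvp)
    return txt, csvp


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration overriding paper-gap constants.

    Recognised keys: ``molar_mass`` (species -> g/mol),
    ``initial_mmolL`` (system name -> species -> mmol/L),
    ``extinction_L_per_mol_cm``, ``path_cm``, ``dicarbonyl_ref_mmolL``
    (``null`` for raw second-order fluxes), ``aa_sat_mmolL``.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def build_system_from_config(
    config: Mapping,
    name: str,
    temperature_C: int,
    lys_variant: bool = False,
) -> ModelSystemSpec:
    """``build_model_system`` with configuration overrides applied."""
    kwargs: dict = {}
    initials = (config or {}).get("initial_mmolL", {})
    if name in initials:
        kwargs["initial_mmolL"] = initials[name]
    if "dicarbonyl_ref_mmolL" in (config or {}):
        kwargs["dicarbonyl_ref_mmolL"] = config["dicarbonyl_ref_mmolL"]
    if "aa_sat_mmolL" in (config or {}):
        kwargs["aa_sat_mmolL"] = config["aa_sat_mmolL"]
    return build_model_system(name, temperature_C, lys_variant, **kwargs)
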