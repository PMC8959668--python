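"""Mass-action reaction network for Maillard reaction harmful products.

The network lumps the early/advanced Maillard chemistry of an aqueous
amino-acid/glucose model system into eleven reactions:

======  ===========================  =====================================
symbol  reaction                     role
======  ===========================  =====================================
k1      GLU -> GO                    glucose fragmentation to glyoxal
k2      GLU -> MGO                   glucose fragmentation to methylglyoxal
k3      LYS + GO  -> CML             carboxymethyl-lysine formation
k4      LYS + MGO -> CEL             carboxyethyl-lysine formation
k5      ASN + GO  -> AA              asparagine-route acrylamide
k6      GLU -> ACH                   glucose degradation to acetaldehyde
k7      ACH -> ACR                   acetaldehyde oxidation to acrolein
k8      ASN + ACR -> AA              acrolein-route acrylamide
k9      TRP + ACH -> HAR             Pictet-Spengler + oxidation to harmane
k10     TRP -> NOR                   lumped norharmane formation
k11     GLU -> MEL                   melanoidin (browning) formation
======  ===========================  =====================================

Melanoidin formation additionally co-consumes free amino acids (they are
incorporated into the polymer) 1:1 with the k11 flux, distributed across
Lys/Asn/Trp in proportion to their current concentrations and saturating
smoothly as the amino-acid pool empties (see ``ModelSystemSpec.aa_sat_mmolL``).

Seven optional first-order elimination constants e12..e18 remove GO, MGO,
ACH, ACR, AA, HAR and NOR respectively (degradation/polymerisation sinks);
they default to zero.

Concentrations are mmol/L throughout; time is minutes.  Bimolecular fluxes
are written k*[A]*[B]/ref with ref = 100 mmol/L (the initial glucose
concentration), which keeps every rate constant on the min^-1 scale the
tabulated estimates use while preserving mass-action structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "IDX",
    "N_SPECIES",
    "MOLAR_MASS_G_PER_MOL",
    "AMINO_ACIDS",
    "SUBSTRATES",
    "REACTIONS",
    "ELIMINATION_SPECIES",
    "SYSTEM_NAMES",
    "ACTIVE_SETS",
    "DEFAULT_INITIALS",
    "PRINTED_SCALE",
    "printed_to_natural",
    "natural_to_printed",
    "RateConstants",
    "ModelSystemSpec",
    "build_model_system",
    "make_odesys",
    "ode_rhs",
    "reachable_species",
]

# --------------------------------------------------------------------------
# Species registry
# --------------------------------------------------------------------------

#: Tracked chemical species, in state-vector order.
SPECIES: tuple[str, ...] = (
    "GLU", "LYS", "ASN", "TRP",          # substrates
    "GO", "MGO", "ACH", "ACR",           # intermediates
    "AA", "CML", "CEL", "HAR", "NOR",    # harmful end products
    "MEL",                               # melanoidins (Lambert-Beer units)
)
IDX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}
N_SPECIES: int = len(SPECIES)

#: Molar masses in g/mol, used for ug/mL <-> mmol/L conversion.  Melanoidins
#: are heterogeneous polymers without a molar mass; they are quantified
#: directly in mmol/L via absorbance at 470 nm (Lambert-Beer).
MOLAR_MASS_G_PER_MOL: dict[str, float | None] = {
    "GLU": 180.16,
    "LYS": 146.19,
    "ASN": 132.12,
    "TRP": 204.23,
    "GO": 58.04,
    "MGO": 72.06,
    "ACH": 44.05,
    "ACR": 56.06,
    "AA": 71.08,
    "CML": 204.22,
    "CEL": 218.25,
    "HAR": 182.22,
    "NOR": 168.19,
    "MEL": None,
}

AMINO_ACIDS: tuple[str, ...] = ("LYS", "ASN", "TRP")
SUBSTRATES: tuple[str, ...] = ("GLU", "LYS", "ASN", "TRP")

#: Reaction list (index, reactants, products).  One-reactant entries are
#: first order, two-reactant entries second order (normalised, see module
#: docstring).  R11 carries the amino-acid co-consumption side channel,
#: which is handled separately in :func:`ode_rhs`.
REACTIONS: tuple[tuple[int, tuple[str, ...], tuple[str, ...]], ...] = (
    (1, ("GLU",), ("GO",)),
    (2, ("GLU",), ("MGO",)),
    (3, ("LYS", "GO"), ("CML",)),
    (4, ("LYS", "MGO"), ("CEL",)),
    (5, ("ASN", "GO"), ("AA",)),
    (6, ("GLU",), ("ACH",)),
    (7, ("ACH",), ("ACR",)),
    (8, ("ASN", "ACR"), ("AA",)),
    (9, ("TRP", "ACH"), ("HAR",)),
    (10, ("TRP",), ("NOR",)),
    (11, ("GLU",), ("MEL",)),
)

#: Species removed by the optional elimination constants e12..e18, in order.
ELIMINATION_SPECIES: tuple[str, ...] = ("GO", "MGO", "ACH", "ACR", "AA", "HAR", "NOR")

# --------------------------------------------------------------------------
# Model systems
# --------------------------------------------------------------------------

SYSTEM_NAMES: tuple[str, ...] = ("Lys/Glu", "Asn/Glu", "Trp/Glu", "Com/Glu")
VALID_TEMPERATURES: tuple[int, ...] = (170, 200)

#: Rate constants with a defined (non-dash) estimate per system.
ACTIVE_SETS: dict[str, frozenset[int]] = {
    "Lys/Glu": frozenset({1, 2, 3, 4, 6, 7, 11}),
    "Trp/Glu": frozenset({1, 2, 6, 7, 9, 10, 11}),
    "Asn/Glu": frozenset({1, 2, 5, 6, 7, 8, 11}),
    "Com/Glu": frozenset(range(1, 12)),
}

#: Design concentrations, mmol/L.  The combined system uses Lys 30 by
#: default (the food-proportion design); ``lys_variant`` selects Lys 100.
DEFAULT_INITIALS: dict[str, dict[str, float]] = {
    "Lys/Glu": {"LYS": 30.0, "GLU": 100.0},
    "Asn/Glu": {"ASN": 200.0, "GLU": 100.0},
    "Trp/Glu": {"TRP": 5.0, "GLU": 100.0},
    "Com/Glu": {"LYS": 30.0, "ASN": 200.0, "TRP": 5.0, "GLU": 100.0},
}
COM_LYS_VARIANT_MMOLL: float = 100.0

# --------------------------------------------------------------------------
# Printed-scale conventions
# --------------------------------------------------------------------------

#: Multiplier taking a printed (tabulated) value to natural min^-1 units.
#: k3, k4 are tabulated in 1e-2 min^-1; k9, k10 in 1e-3 min^-1; the rest
#: (including the elimination constants) in min^-1.
PRINTED_SCALE: dict[int, float] = {i: 1.0 for i in range(1, 19)}
PRINTED_SCALE[3] = PRINTED_SCALE[4] = 1e-2
PRINTED_SCALE[9] = PRINTED_SCALE[10] = 1e-3


def _check_index(index: int) -> None:
    if not (isinstance(index, (int, np.integer)) and 1 <= index <= 18):
        raise ValueError(f"rate-constant index must be an integer in 1..18, got {index!r}")


def printed_to_natural(value: float, index: int) -> float:
    """Convert a tabulated rate constant to natural min^-1 units."""
    _check_index(index)
    return value * PRINTED_SCALE[index]


def natural_to_printed(value: float, index: int) -> float:
    """Convert a natural min^-1 rate constant to its tabulated scale."""
    _check_index(index)
    return value / PRINTED_SCALE[index]


# --------------------------------------------------------------------------
# Rate constants
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """The k1..k11 vector plus optional elimination constants e12..e18.

    All values are in natural units (min^-1; bimolecular constants act on
    a normalised partner concentration, so they share the min^-1 scale).
    """

    k: tuple[float, ...]
    e: tuple[float, ...] = (0.0,) * 7

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", tuple(float(v) for v in self.k))
        object.__setattr__(self, "e", tuple(float(v) for v in self.e))
        if len(self.k) != 11:
            raise ValueError(f"expected 11 reaction constants k1..k11, got {len(self.k)}")
        if len(self.e) != 7:
            raise ValueError(f"expected 7 elimination constants e12..e18, got {len(self.e)}")
        for i, v in enumerate(self.k + self.e, start=1):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate constant #{i} must be finite and >= 0, got {v}")

    # -- indexed access ----------------------------------------------------

    def __getitem__(self, index: int) -> float:
        _check_index(index)
        return self.k[index - 1] if index <= 11 else self.e[index - 12]

    def as_dict(self) -> dict[int, float]:
        return {i: self[i] for i in range(1, 19)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def zeros(cls) -> "RateConstants":
        return cls(k=(0.0,) * 11)

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "RateConstants":
        """Build from a sparse {index: natural value} mapping; missing -> 0."""
        k = [float(mapping.get(i, 0.0)) for i in range(1, 12)]
        e = [float(mapping.get(i, 0.0)) for i in range(12, 19)]
        return cls(k=tuple(k), e=tuple(e))

    @classmethod
    def from_printed(cls, mapping: Mapping[int, float]) -> "RateConstants":
        """Build from a sparse {index: printed value} mapping (table scales)."""
        return cls.from_mapping(
            {i: printed_to_natural(v, i) for i, v in mapping.items()}
        )

    # -- views / derivations ----------------------------------------------

    def to_printed(self) -> dict[int, float]:
        """All 18 constants on their printed (tabulated) scales."""
        return {i: natural_to_printed(self[i], i) for i in range(1, 19)}

    def scaled(self, factor: float) -> "RateConstants":
        """Every constant multiplied by ``factor`` (e.g. a 2x fit start)."""
        return RateConstants(
            k=tuple(v * factor for v in self.k),
            e=tuple(v * factor for v in self.e),
        )

    def with_values(self, mapping: Mapping[int, float]) -> "RateConstants":
        d = self.as_dict()
        d.update({i: float(v) for i, v in mapping.items()})
        return RateConstants.from_mapping(d)


# --------------------------------------------------------------------------
# Model system specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSystemSpec:
    """One experimental condition: composition, temperature, active constants.

    Parameters
    ----------
    name
        One of ``SYSTEM_NAMES``.
    temperature_C
        Heating temperature, 170 or 200 (categorical; no Arrhenius link).
    initial_mmolL
        Initial concentration of every species, mmol/L (products 0).
    active_k
        Indices of the rate constants defined for this system; constants
        outside the set contribute zero flux.
    dicarbonyl_ref_mmolL
        Normalising concentration for bimolecular fluxes (min^-1 scale
        convention); ``None`` switches to raw second-order L/(mmol·min).
    aa_sat_mmolL
        Saturation constant of the melanoidin amino-acid co-consumption;
        small relative to any initial amino-acid pool.
    """

    name: str
    temperature_C: int
    initial_mmolL: Mapping[str, float]
    active_k: frozenset[int]
    dicarbonyl_ref_mmolL: float | None = 100.0
    aa_sat_mmolL: float = 0.1

    def __post_init__(self) -> None:
        initial = {s: float(self.initial_mmolL.get(s, 0.0)) for s in SPECIES}
        unknown = set(self.initial_mmolL) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species in initial concentrations: {sorted(unknown)}")
        for s, v in initial.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"initial concentration of {s} must be finite and >= 0, got {v}")
            if s not in SUBSTRATES and v != 0.0:
                raise ValueError(f"non-substrate species {s} must start at 0, got {v}")
        object.__setattr__(self, "initial_mmolL", initial)
        object.__setattr__(self, "active_k", frozenset(int(i) for i in self.active_k))
        if not self.active_k <= set(range(1, 12)):
            raise ValueError("active_k must be a subset of {1..11}")

    def initial_state(self) -> np.ndarray:
        return np.array([self.initial_mmolL[s] for s in SPECIES], dtype=float)

    @property
    def condition_id(self) -> str:
        """Stable identifier, e.g. ``Lys-Glu-170``."""
        return f"{self.name.replace('/', '-')}-{self.temperature_C}"


def build_model_system(
    name: str,
    temperature_C: int,
    lys_variant: bool = False,
    *,
    initial_mmolL: Mapping[str, float] | None = None,
    dicarbonyl_ref_mmolL: float | None = 100.0,
    aa_sat_mmolL: float = 0.1,
) -> ModelSystemSpec:
    """Construct one of the four amino-acid/glucose model systems.

    ``lys_variant`` selects the 100 mmol/L lysine variant of the combined
    system (the design tabulates both 30 and 100).  ``initial_mmolL``
    overrides individual design concentrations.
    """
    if name not in SYSTEM_NAMES:
        raise ValueError(f"unknown model system {name!r}; valid systems: {', '.join(SYSTEM_NAMES)}")
    temperature_C = int(temperature_C)
    if temperature_C not in VALID_TEMPERATURES:
        raise ValueError(
            f"unknown temperature {temperature_C}; valid temperatures: "
            f"{', '.join(str(t) for t in VALID_TEMPERATURES)}"
        )
    initial = dict(DEFAULT_INITIALS[name])
    if lys_variant:
        if name != "Com/Glu":
            raise ValueError("lys_variant applies only to the Com/Glu system")
        initial["LYS"] = COM_LYS_VARIANT_MMOLL
    if initial_mmolL:
        initial.update({s: float(v) for s, v in initial_mmolL.items()})
    return ModelSystemSpec(
        name=name,
        temperature_C=temperature_C,
        initial_mmolL=initial,
        active_k=ACTIVE_SETS[name],
        dicarbonyl_ref_mmolL=dicarbonyl_ref_mmolL,
        aa_sat_mmolL=aa_sat_mmolL,
    )


def reachable_species(spec: ModelSystemSpec) -> frozenset[str]:
    """Species that can attain nonzero concentration in ``spec``.

    Propagates from the nonzero initial pool through the active reactions
    until a fixed point; used to decide which responses carry information
    (and which elimination constants are structurally identifiable).
    """
    present = {s for s in SPECIES if spec.initial_mmolL[s] > 0}
    changed = True
    while changed:
        changed = False
        for idx, reactants, products in REACTIONS:
            if idx in spec.active_k and all(r in present for r in reactants):
                for p in products:
                    if p not in present:
                        present.add(p)
                        changed = True
    return frozenset(present)


# --------------------------------------------------------------------------
# ODE right-hand side
# --------------------------------------------------------------------------


def make_odesys(spec: ModelSystemSpec, k: RateConstants):
    """Compiled-down (closure) right-hand side and analytic Jacobian.

    Returns ``(rhs, jac)`` callables with the ``f(t, y)`` signature the
    integrator expects.  Both clip tiny negative trial states to zero.
    The analytic Jacobian makes the stiff solver cheap: the melanoidin
    co-consumption creates a fast initial depletion layer whose Newton
    iterations otherwise rely on finite differences.
    """
    active = spec.active_k
    c = 1.0 if spec.dicarbonyl_ref_mmolL is None else 1.0 / spec.dicarbonyl_ref_mmolL
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, k11 = (
        (k[i] if i in active else 0.0) for i in range(1, 12)
    )
    e12, e13, e14, e15, e16, e17, e18 = (k[i] for i in range(12, 19))
    ks = spec.aa_sat_mmolL

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        # .tolist() yields Python floats: scalar arithmetic is several times
        # faster than on numpy scalars, and this is the integrator hot path
        glu, lys, asn, trp, go, mgo, ach, acr, aa, _cml, _cel, har, nor, _mel = [
            v if v > 0.0 else 0.0 for v in y.tolist()
        ]
        r1 = k1 * glu
        r2 = k2 * glu
        r3 = k3 * lys * go * c
        r4 = k4 * lys * mgo * c
        r5 = k5 * asn * go * c
        r6 = k6 * glu
        r7 = k7 * ach
        r8 = k8 * asn * acr * c
        r9 = k9 * trp * ach * c
        r10 = k10 * trp
        r11 = k11 * glu
        # melanoidin amino-acid co-consumption, 1:1 with the r11 flux while
        # the pool lasts, split in proportion to current concentrations
        pool = r11 / (lys + asn + trp + ks)
        return np.array(
            [
                -r1 - r2 - r6 - r11,
                -r3 - r4 - pool * lys,
                -r5 - r8 - pool * asn,
                -r9 - r10 - pool * trp,
                r1 - r3 - r5 - e12 * go,
                r2 - r4 - e13 * mgo,
                r6 - r7 - r9 - e14 * ach,
                r7 - r8 - e15 * acr,
                r5 + r8 - e16 * aa,
                r3,
                r4,
                r9 - e17 * har,
                r10 - e18 * nor,
                r11,
            ]
        )

    def jac(_t: float, y: np.ndarray) -> np.ndarray:
        glu, lys, asn, trp, go, mgo, ach, acr, _aa, _cml, _cel, _har, _nor, _mel = [
            v if v > 0.0 else 0.0 for v in y.tolist()
        ]
        r11 = k11 * glu
        t_tot = lys + asn + trp + ks
        pool = r11 / t_tot
        q = r11 / (t_tot * t_tot)  # d(pool)/d(amino acid), sign handled below
        J = np.zeros((N_SPECIES, N_SPECIES))
        # GLU
        J[0, 0] = -(k1 + k2 + k6 + k11)
        # LYS
        J[1, 0] = -k11 * lys / t_tot
        J[1, 1] = -k3 * go * c - k4 * mgo * c - pool + q * lys
        J[1, 2] = q * lys
        J[1, 3] = q * lys
        J[1, 4] = -k3 * lys * c
        J[1, 5] = -k4 * lys * c
        # ASN
        J[2, 0] = -k11 * asn / t_tot
        J[2, 1] = q * asn
        J[2, 2] = -k5 * go * c - k8 * acr * c - pool + q * asn
        J[2, 3] = q * asn
        J[2, 4] = -k5 * asn * c
        J[2, 7] = -k8 * asn * c
        # TRP
        J[3, 0] = -k11 * trp / t_tot
        J[3, 1] = q * trp
        J[3, 2] = q * trp
        J[3, 3] = -k9 * ach * c - k10 - pool + q * trp
        J[3, 6] = -k9 * trp * c
        # GO
        J[4, 0] = k1
        J[4, 1] = -k3 * go * c
        J[4, 2] = -k5 * go * c
        J[4, 4] = -k3 * lys * c - k5 * asn * c - e12
        # MGO
        J[5, 0] = k2
        J[5, 1] = -k4 * mgo * c
        J[5, 5] = -k4 * lys * c - e13
        # ACH
        J[6, 0] = k6
        J[6, 3] = -k9 * ach * c
        J[6, 6] = -k7 - k9 * trp * c - e14
        # ACR
        J[7, 2] = -k8 * acr * c
        J[7, 6] = k7
        J[7, 7] = -k8 * asn * c - e15
        # AA
        J[8, 2] = k5 * go * c + k8 * acr * c
        J[8, 4] = k5 * asn * c
        J[8, 7] = k8 * asn * c
        J[8, 8] = -e16
        # CML / CEL
        J[9, 1] = k3 * go * c
        J[9, 4] = k3 * lys * c
        J[10, 1] = k4 * mgo * c
        J[10, 5] = k4 * lys * c
        # HAR
        J[11, 3] = k9 * ach * c
        J[11, 6] = k9 * trp * c
        J[11, 11] = -e17
        # NOR
        J[12, 3] = k10
        J[12, 12] = -e18
        # MEL
        J[13, 0] = k11
        return J

    return rhs, jac


def ode_rhs(
    state: np.ndarray,
    k: RateConstants,
    spec: ModelSystemSpec,
    *,
    check: bool = True,
) -> np.ndarray:
    """Time derivative d[state]/dt in mmol/(L·min).

    ``state`` follows the ``SPECIES`` order.  Constants outside
    ``spec.active_k`` contribute no flux.  Negative concentrations are
    rejected (they signal integrator misuse); the integrator wrapper clips
    its trial states before calling.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},), got {state.shape}")
    if check and (state < 0).any():
        bad = [SPECIES[i] for i in np.where(state < 0)[0]]
        raise ValueError(f"negative concentrations for {bad}; states must be >= 0")
    rhs, _ = make_odesys(spec, k)
    return rhs(0.0, state)
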