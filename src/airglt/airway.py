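"""Per-generation airflow velocities and Reynolds numbers in a Weibel tree.

The conducting airways are modelled as a symmetric dichotomously branching
tree of 24 generations (trachea = generation 0), each generation ``z``
holding ``2**z`` parallel branches of identical diameter ``d(z)``.  Given a
tracheal volumetric flow rate ``Q`` the mean axial airflow velocity in
generation ``z`` is

    v(z) = Q / A(z),    A(z) = 2**z * pi * d(z)**2 / 4

assuming incompressible flow, conservation of volume flow across
generations and a uniform velocity profile within each generation.

Airway calibre is smaller during exhalation than inhalation (airway
hysteresis).  Exhalation diameters are derived from the inhalation (TLC)
diameters by bracketed percentage decreases taken from bronchographic
measurements: 13% for airways < 1.7 mm, 16% for 1.7-3.5 mm, 10% for
3.5-7 mm and 7% for airways >= 7 mm.  At equal volume flow this makes the
expiratory velocity exceed the inspiratory velocity in every generation —
the asymmetry that drives cilia-independent gas-liquid transport of mucus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

__all__ = [
    "AirwayGeneration",
    "AirwayTree",
    "GasProperties",
    "FlowCondition",
    "GenerationFlowResult",
    "BODY_AIR",
    "LAMINAR_REYNOLDS_LIMIT",
    "exhale_diameter",
    "liters_per_min_to_m3_per_s",
    "build_weibel_tree",
    "load_default_diameters",
    "generation_velocity",
    "reynolds",
    "flow_table",
    "flow_table_frame",
    "deepest_generation_with_asymmetry",
]

#: Conventional upper bound of the laminar regime for pipe flow.
LAMINAR_REYNOLDS_LIMIT = 2000.0

#: (lower diameter bound mm inclusive, fractional decrease on exhalation)
_NARROWING_BRACKETS = (
    (7.0, 0.07),
    (3.5, 0.10),
    (1.7, 0.16),
    (0.0, 0.13),
)

_MAX_GENERATIONS = 24


class ValidationError(ValueError):
    """Raised when an input violates a model invariant."""


def exhale_diameter(d_tlc: float) -> float:
    """Exhalation diameter (mm) for an airway of TLC diameter ``d_tlc`` mm.

    Applies the bracketed fractional narrowing (13% below 1.7 mm, 16% for
    [1.7, 3.5) mm, 10% for [3.5, 7) mm, 7% at or above 7 mm).  Brackets are
    half-open so every positive diameter maps to exactly one fraction.
    """
    if not d_tlc > 0:
        raise ValidationError(f"diameter must be positive, got {d_tlc}")
    for lower, fraction in _NARROWING_BRACKETS:
        if d_tlc >= lower:
            return d_tlc * (1.0 - fraction)
    raise AssertionError("unreachable: brackets cover (0, inf)")


def liters_per_min_to_m3_per_s(q: float) -> float:
    """Convert a volumetric flow from L/min to m^3/s (q / 60000)."""
    if q < 0:
        raise ValidationError(f"flow rate must be nonnegative, got {q}")
    return q / 60_000.0


@dataclass(frozen=True)
class AirwayGeneration:
    """One generation of the symmetric dichotomous tree.

    ``branch_count`` is always ``2**index``; diameters are in millimetres,
    with ``diameter_exhale`` strictly below ``diameter_tlc``.
    """

    index: int
    diameter_tlc: float
    diameter_exhale: float
    branch_count: int = field(default=0)

    def __post_init__(self) -> None:
        if not 0 <= self.index < _MAX_GENERATIONS:
            raise ValidationError(
                f"generation index must be in [0, {_MAX_GENERATIONS - 1}], got {self.index}"
            )
        if not self.diameter_tlc > 0:
            raise ValidationError(
                f"generation {self.index}: diameter must be positive, got {self.diameter_tlc}"
            )
        if not self.diameter_exhale < self.diameter_tlc:
            raise ValidationError(
                f"generation {self.index}: exhale diameter must be below TLC diameter"
            )
        expected = 2 ** self.index
        if self.branch_count == 0:
            object.__setattr__(self, "branch_count", expected)
        elif self.branch_count != expected:
            raise ValidationError(
                f"generation {self.index}: branch_count must be 2^z = {expected}"
            )

    def diameter(self, phase: Literal["inhale", "exhale"]) -> float:
        if phase == "inhale":
            return self.diameter_tlc
        if phase == "exhale":
            return self.diameter_exhale
        raise ValidationError(f"phase must be 'inhale' or 'exhale', got {phase!r}")

    def cross_section(self, phase: Literal["inhale", "exhale"]) -> float:
        """Total cross-sectional area of the generation in m^2."""
        d_m = self.diameter(phase) * 1e-3
        return self.branch_count * math.pi * d_m * d_m / 4.0


@dataclass(frozen=True)
class AirwayTree:
    """Ordered collection of airway generations, indices contiguous from 0."""

    generations: tuple[AirwayGeneration, ...]
    table_version: str = "user-supplied"

    def __post_init__(self) -> None:
        indices = [g.index for g in self.generations]
        if not indices:
            raise ValidationError("an airway tree needs at least one generation")
        if indices != list(range(len(indices))):
            raise ValidationError(
                f"generation indices must be contiguous from 0, got {indices}"
            )

    def __len__(self) -> int:
        return len(self.generations)

    def __iter__(self):
        return iter(self.generations)


@dataclass(frozen=True)
class GasProperties:
    """Density (kg/m^3) and dynamic viscosity (Pa.s) of the carrier gas."""

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.dynamic_viscosity > 0):
            raise ValidationError("gas density and viscosity must be positive")


#: Humidified air at body temperature (37 C, saturated).
BODY_AIR = GasProperties(density=1.12, dynamic_viscosity=1.87e-5)

#: Dry room air at ~20 C, for sensitivity checks.
ROOM_AIR = GasProperties(density=1.20, dynamic_viscosity=1.82e-5)

GAS_PRESETS = {"body": BODY_AIR, "room": ROOM_AIR}


@dataclass(frozen=True)
class FlowCondition:
    """Tracheal volumetric flow rate Q in m^3/s with a free-text label."""

    volumetric_flow: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.volumetric_flow < 0:
            raise ValidationError("volumetric flow must be nonnegative")

    @classmethod
    def from_lpm(cls, q_lpm: float, label: str = "") -> "FlowCondition":
        return cls(liters_per_min_to_m3_per_s(q_lpm), label or f"{q_lpm:g} L/min")


@dataclass(frozen=True)
class GenerationFlowResult:
    """Velocities (m/s) and Reynolds numbers for one generation and flow."""

    index: int
    branch_count: int
    diameter_tlc: float
    diameter_exhale: float
    v_inhale: float
    v_exhale: float
    delta_v: float
    re_inhale: float
    re_exhale: float
    laminar_flag: bool


def load_default_diameters() -> pd.DataFrame:
    """Load the embedded Weibel model-A generation/diameter table."""
    with resources.files("airglt").joinpath("data/weibel_model_a.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _validate_table(rows: Sequence[tuple[int, float]]) -> list[tuple[int, float]]:
    if not 1 <= len(rows) <= _MAX_GENERATIONS:
        raise ValidationError(
            f"diameter table must have 1-{_MAX_GENERATIONS} rows, got {len(rows)}"
        )
    seen: set[int] = set()
    for z, d in rows:
        if z in seen:
            raise ValidationError(f"duplicate generation index {z} in diameter table")
        seen.add(z)
        if not d > 0:
            raise ValidationError(f"generation {z}: diameter must be positive, got {d}")
    return sorted(rows)


def build_weibel_tree(
    diameter_table: Optional[Iterable[tuple[int, float]]] = None,
) -> AirwayTree:
    """Build an airway tree from (generation, TLC diameter mm) pairs.

    With no table, uses the embedded canonical Weibel model-A diameters
    (24 generations).  Exhalation diameters are filled from the bracketed
    narrowing rule in :func:`exhale_diameter`.
    """
    if diameter_table is None:
        df = load_default_diameters()
        rows = list(zip(df["generation"].astype(int), df["diameter_tlc_mm"].astype(float)))
        version = "weibel-1963-model-A/v1"
    else:
        rows = [(int(z), float(d)) for z, d in diameter_table]
        version = "user-supplied"
    rows = _validate_table(rows)
    gens = tuple(
        AirwayGeneration(index=z, diameter_tlc=d, diameter_exhale=exhale_diameter(d))
        for z, d in rows
    )
    return AirwayTree(generations=gens, table_version=version)


def generation_velocity(
    gen: AirwayGeneration,
    flow: FlowCondition,
    phase: Literal["inhale", "exhale"],
) -> float:
    """Mean airflow velocity v = Q / A(z) in m/s for one generation."""
    return flow.volumetric_flow / gen.cross_section(phase)


def reynolds(v: float, d_mm: float, gas: GasProperties = BODY_AIR) -> float:
    """Reynolds number rho * v * d / mu for velocity v (m/s), diameter d (mm)."""
    if not d_mm > 0:
        raise ValidationError(f"diameter must be positive, got {d_mm}")
    if v < 0:
        raise ValidationError(f"velocity must be nonnegative, got {v}")
    return gas.density * v * (d_mm * 1e-3) / gas.dynamic_viscosity


def flow_table(
    tree: AirwayTree,
    flow: FlowCondition,
    gas: GasProperties = BODY_AIR,
) -> list[GenerationFlowResult]:
    """Inhalation/exhalation velocities and Reynolds numbers per generation."""
    results = []
    for gen in tree:
        v_in = generation_velocity(gen, flow, "inhale")
        v_ex = generation_velocity(gen, flow, "exhale")
        re_in = reynolds(v_in, gen.diameter_tlc, gas)
        re_ex = reynolds(v_ex, gen.diameter_exhale, gas)
        results.append(
            GenerationFlowResult(
                index=gen.index,
                branch_count=gen.branch_count,
                diameter_tlc=gen.diameter_tlc,
                diameter_exhale=gen.diameter_exhale,
                v_inhale=v_in,
                v_exhale=v_ex,
                delta_v=v_ex - v_in,
                re_inhale=re_in,
                re_exhale=re_ex,
                laminar_flag=max(re_in, re_ex) < LAMINAR_REYNOLDS_LIMIT,
            )
        )
    return results


def flow_table_frame(
    tree: AirwayTree,
    flow: FlowCondition,
    gas: GasProperties = BODY_AIR,
) -> pd.DataFrame:
    """:func:`flow_table` as a DataFrame mirroring the tabular output."""
    rows = flow_table(tree, flow, gas)
    return pd.DataFrame(
        {
            "generation": [r.index for r in rows],
            "branch_count": [r.branch_count for r in rows],
            "d_inhale_mm": [r.diameter_tlc for r in rows],
            "d_exhale_mm": [r.diameter_exhale for r in rows],
            "v_inhale_m_s": [r.v_inhale for r in rows],
            "v_exhale_m_s": [r.v_exhale for r in rows],
            "delta_v_m_s": [r.delta_v for r in rows],
            "re_inhale": [r.re_inhale for r in rows],
            "re_exhale": [r.re_exhale for r in rows],
            "laminar": [r.laminar_flag for r in rows],
        }
    )


def deepest_generation_with_asymmetry(
    results: Sequence[GenerationFlowResult],
    threshold: float,
) -> Optional[int]:
    """Deepest generation down to which delta_v >= threshold holds everywhere.

    Returns the largest z such that the expiratory-inspiratory velocity
    difference is at least ``threshold`` m/s for all generations up to and
    including z, or None if the condition already fails at the trachea.
    """
    if not results:
        raise ValidationError("results list must be non-empty")
    deepest: Optional[int] = None
    for r in sorted(results, key=lambda r: r.index):
        if r.delta_v >= threshold:
            deepest = r.index
        else:
            break
    return deepest
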