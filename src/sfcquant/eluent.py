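"""SFC gradient program, post-column makeup mixing and eluent descriptors.

In SFC the mobile phase is CO2 (A) with an organic modifier (B, here
methanol with ammonium acetate).  Before electrospray ionization a constant
makeup flow (water/isopropanol) is added, so the liquid reaching the source
is a time-dependent mixture.  Ionization efficiency depends on that mixture,
so the composition at each analyte's elution time is summarized by physical
descriptors: Snyder polarity index, viscosity, surface tension, aqueous pH
and the presence of ammonium ions.

Mixing rules (pure-component constants at 25 C):

* polarity index: volume-fraction-weighted mean,
* viscosity: log-mixing, eta = exp(sum phi_i ln eta_i),
* surface tension: volume-fraction-weighted mean.

These enter the downstream model only as features; the rules are isolated in
:func:`eluent_descriptors` so they can be swapped for calibrated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GradientProgram",
    "EluentState",
    "PURE_COMPONENT_PROPERTIES",
    "percent_b_at",
    "inlet_fractions",
    "eluent_descriptors",
]

# component -> (Snyder polarity index, viscosity mPa*s, surface tension mN/m)
# at 25 C.  CO2 values are rough decompressed-fluid figures; by default the
# descriptors are computed on the condensed (CO2-free) liquid.
PURE_COMPONENT_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "water": (10.2, 0.890, 71.99),
    "methanol": (5.1, 0.544, 22.07),
    "isopropanol": (3.9, 2.038, 20.93),
    "acetonitrile": (5.8, 0.369, 28.66),
    "co2": (0.0, 0.07, 1.0),
}


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear %B program plus flows and makeup composition.

    ``segments`` is a list of ``(t_start_min, t_end_min, pct_b_start,
    pct_b_end)``; segments must be contiguous and non-overlapping.  Flows in
    uL/min.  ``modifier_additive`` is ``(name, mmol_per_L)``.
    """

    segments: tuple[tuple[float, float, float, float], ...]
    column_flow: float = 1500.0
    makeup_flow: float = 200.0
    makeup_composition: Mapping[str, float] = field(
        default_factory=lambda: {"water": 0.9, "isopropanol": 0.1}
    )
    modifier_additive: tuple[str, float] = ("ammonium acetate", 20.0)
    water_ph: float = 7.0

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("gradient program needs at least one segment")
        for (t0, t1, b0, b1) in segs:
            if t1 <= t0:
                raise ValueError("segment end must exceed start")
            if not (0 <= b0 <= 100 and 0 <= b1 <= 100):
                raise ValueError("%B must lie in [0, 100]")
        for prev, nxt in zip(segs, segs[1:]):
            if abs(prev[1] - nxt[0]) > 1e-9:
                raise ValueError("segments must be contiguous")
        if self.column_flow <= 0 or self.makeup_flow < 0:
            raise ValueError("flows must be positive (makeup may be zero)")
        tot = sum(self.makeup_composition.values())
        if self.makeup_composition and abs(tot - 1.0) > 1e-9:
            raise ValueError("makeup composition fractions must sum to 1")

    @property
    def end_time(self) -> float:
        return self.segments[-1][1]

    @classmethod
    def default(cls) -> "GradientProgram":
        """The implemented SFC method: 2% B for 1 min, to 60% within 6 min,
        hold 4 min, back to 2% within 0.1 min; 1.5 mL/min column flow with a
        200 uL/min water/isopropanol 90/10 makeup flow and 20 mmol/L ammonium
        acetate in the modifier."""
        return cls(
            segments=(
                (0.0, 1.0, 2.0, 2.0),
                (1.0, 7.0, 2.0, 60.0),
                (7.0, 11.0, 60.0, 60.0),
                (11.0, 11.1, 60.0, 2.0),
            )
        )


@dataclass(frozen=True)
class EluentState:
    """Eluent descriptors at the ESI inlet for one elution time."""

    fractions: Mapping[str, float]
    viscosity: float  # mPa*s
    surface_tension: float  # mN/m
    polarity_index: float
    ph: float
    nh4_present: bool

    def __post_init__(self) -> None:
        if any(v < -1e-12 for v in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.viscosity <= 0 or self.surface_tension <= 0:
            raise ValueError("viscosity and surface tension must be positive")


def percent_b_at(program: GradientProgram, t: float) -> float:
    """Piecewise-linear %B at time ``t`` (minutes), clamped to the program."""
    t = float(np.clip(t, program.segments[0][0], program.end_time))
    for (t0, t1, b0, b1) in program.segments:
        if t0 <= t <= t1:
            if t1 == t0:
                return b1
            return b0 + (b1 - b0) * (t - t0) / (t1 - t0)
    raise ValueError(f"time {t} outside gradient program")  # pragma: no cover


def inlet_fractions(
    program: GradientProgram, t: float, include_co2: bool = False
) -> dict[str, float]:
    """Volume fractions of the flow reaching the ESI source at time ``t``.

    The column flow splits into CO2 (A) and methanol (B) by %B; the makeup
    flow contributes its components.  With ``include_co2=False`` (default)
    the fractions are renormalized over the condensed components only, since
    CO2 decompresses before ionization.
    """
    b = percent_b_at(program, t) / 100.0
    flows: dict[str, float] = {"co2": program.column_flow * (1.0 - b)}
    flows["methanol"] = flows.get("methanol", 0.0) + program.column_flow * b
    for comp, frac in program.makeup_composition.items():
        flows[comp] = flows.get(comp, 0.0) + program.makeup_flow * frac
    if not include_co2:
        flows.pop("co2", None)
    total = sum(flows.values())
    if total <= 0:
        raise ValueError("no condensed flow at the ESI inlet")
    return {comp: f / total for comp, f in flows.items() if f > 0 or comp in flows}


def eluent_descriptors(
    fractions: Mapping[str, float],
    water_ph: float = 7.0,
    modifier_additive: tuple[str, float] = ("ammonium acetate", 20.0),
) -> EluentState:
    """Compute mixture descriptors from component volume fractions.

    Raises ``ValueError`` when a component is missing from the built-in
    constants table.
    """
    total = sum(fractions.values())
    if total <= 0:
        raise ValueError("fractions must have positive sum")
    norm = {c: v / total for c, v in fractions.items()}
    pol = visc_log = surf = 0.0
    for comp, phi in norm.items():
        if comp not in PURE_COMPONENT_PROPERTIES:
            raise ValueError(f"no property constants for component {comp!r}")
        p, eta, sigma = PURE_COMPONENT_PROPERTIES[comp]
        pol += phi * p
        visc_log += phi * np.log(eta)
        surf += phi * sigma
    additive_name = modifier_additive[0] if modifier_additive else ""
    return EluentState(
        fractions=dict(norm),
        viscosity=float(np.exp(visc_log)),
        surface_tension=float(surf),
        polarity_index=float(pol),
        ph=float(water_ph),
        nh4_present="ammonium" in additive_name.lower(),
    )


def descriptors_at(
    program: GradientProgram, t: float, include_co2: bool = False
) -> EluentState:
    """Convenience: eluent descriptors at elution time ``t``."""
    return eluent_descriptors(
        inlet_fractions(program, t, include_co2=include_co2),
        water_ph=program.water_ph,
        modifier_additive=program.modifier_additive,
    )
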