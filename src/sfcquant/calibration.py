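"""Calibration graphs: isotope-corrected peak areas -> response factors.

The response factor (RF, in M^-1) of an analyte is the slope of the
calibration graph of isotope-corrected signal versus molar concentration,
computed over the linear range only.  Because peak integration software
typically integrates only the main (monoisotopic) peak, raw areas are divided
by the monoisotopic fraction of the molecular formula before fitting.

An analyte is usable for quantification only when at least three
concentration levels fall in the linear range; otherwise it is flagged with
:class:`NoLinearRangeError` and excluded downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ChemicalRecord",
    "CalibrationSeries",
    "ResponseFactorEstimate",
    "CalibrationError",
    "NoLinearRangeError",
    "NonPositiveSlopeError",
    "parse_formula",
    "monoisotopic_fraction",
    "correct_area",
    "detect_linear_range",
    "estimate_response_factor",
]

# Representative isotopic abundances (IUPAC 2021) of the lightest isotope of
# each supported element.  The monoisotopic fraction of a formula is the
# probability that every atom is the lightest isotope.
LIGHTEST_ISOTOPE_ABUNDANCE: dict[str, float] = {
    "C": 0.9893,
    "H": 0.999885,
    "N": 0.99636,
    "O": 0.99757,
    "S": 0.9499,
    "P": 1.0,
    "F": 1.0,
    "Cl": 0.7576,
    "Br": 0.5069,
    "I": 1.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class CalibrationError(ValueError):
    """Base class for calibration failures that flag a chemical."""


class NoLinearRangeError(CalibrationError):
    """Fewer than three levels survive linear-range detection."""


class NonPositiveSlopeError(CalibrationError):
    """The fitted calibration slope is not positive."""


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and per-analyte metadata.

    ``formula`` maps element symbol to atom count; ``retention_time`` is in
    minutes; ``logp`` is optional (octanol-water partition, dimensionless).
    """

    id: str
    name: str
    formula: Mapping[str, int]
    retention_time: float
    logp: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.formula.values()):
            raise ValueError(f"negative element count in formula for {self.id}")
        if self.retention_time < 0:
            raise ValueError(f"negative retention time for {self.id}")


@dataclass
class CalibrationSeries:
    """Replicate peak areas per concentration level for one analyte.

    ``concentrations`` (mol/L) must be strictly increasing; ``areas[i]`` holds
    the replicate areas measured at ``concentrations[i]``.
    """

    chemical_id: str
    concentrations: np.ndarray
    areas: list[np.ndarray]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.areas = [np.atleast_1d(np.asarray(a, dtype=float)) for a in self.areas]
        if len(self.areas) != self.concentrations.size:
            raise ValueError("areas and concentrations must align")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if any(a.size < 1 for a in self.areas):
            raise ValueError("every level needs at least one replicate")

    @property
    def n_levels(self) -> int:
        return self.concentrations.size


@dataclass(frozen=True)
class ResponseFactorEstimate:
    chemical_id: str
    rf: float  # slope, M^-1
    intercept: float  # area units
    linear_levels: tuple[int, ...]
    n_linear: int
    max_rel_residual: float
    isotope_correction_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.isotope_correction_factor < 1.0:
            raise ValueError("isotope correction factor must be >= 1")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``'C10H14N2'`` into ``{'C': 10, 'H': 14, 'N': 2}``.

    Mappings pass through (summed per element).  Raises ``ValueError`` on
    unparseable input.
    """
    if isinstance(formula, Mapping):
        return {el: int(n) for el, n in formula.items() if n}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos or not m.group(0):
            break
        el = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse molecular formula {formula!r}")
    return counts


def monoisotopic_fraction(formula: str | Mapping[str, int]) -> float:
    """Probability that a molecule is the all-lightest-isotope species.

    Equals the product over elements of (lightest-isotope abundance)^count.
    The empty formula yields 1.0.
    """
    counts = parse_formula(formula) if not isinstance(formula, Mapping) else dict(formula)
    frac = 1.0
    for el, n in counts.items():
        if n == 0:
            continue
        try:
            ab = LIGHTEST_ISOTOPE_ABUNDANCE[el]
        except KeyError:
            raise ValueError(
                f"element {el!r} not in the isotopic abundance table "
                f"(supported: {sorted(LIGHTEST_ISOTOPE_ABUNDANCE)})"
            ) from None
        frac *= ab**n
    return frac


def correct_area(area: float | np.ndarray, fraction: float) -> float | np.ndarray:
    """Scale a main-peak area up to the full isotopologue envelope."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"monoisotopic fraction must be in (0, 1], got {fraction}")
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("peak areas must be non-negative")
    out = area / fraction
    return float(out) if out.ndim == 0 else out


def _level_means_rsd(series: CalibrationSeries) -> tuple[np.ndarray, np.ndarray]:
    means = np.array([a.mean() for a in series.areas])
    rsd = np.array(
        [a.std(ddof=1) / m if a.size > 1 and m > 0 else 0.0 for a, m in zip(series.areas, means)]
    )
    return means, rsd


def _worst_relative_residual(conc: np.ndarray, means: np.ndarray) -> tuple[int, float, np.ndarray]:
    """Relative deviation of each level's response ratio from their median.

    In the linear range the per-level response factor area/conc is constant;
    saturated (or otherwise nonlinear) levels deviate from the median ratio
    in proportional terms, which weighs every concentration level equally.
    """
    ratio = means / conc
    center = np.median(ratio)
    denom = max(abs(center), np.finfo(float).tiny)
    rel = np.abs(ratio - center) / denom
    worst = np.flatnonzero(rel >= rel.max() - 1e-15)[-1]  # ties -> highest conc
    return int(worst), float(rel.max()), rel


def detect_linear_range(
    series: CalibrationSeries,
    rel_residual_tol: float = 0.2,
    replicate_rsd_tol: float = 0.3,
) -> list[int]:
    """Automated linear-range detection by greedy residual pruning.

    Levels whose replicate RSD exceeds ``replicate_rsd_tol`` are excluded up
    front.  Then, on the retained levels, the per-level response ratios
    (level-mean area / concentration) are compared with their median: while
    the worst relative deviation exceeds ``rel_residual_tol`` and more than
    three levels remain, the level with the worst deviation is dropped
    (highest concentration preferred on ties) and the median recomputed.
    Returns retained level indices (ascending); raises
    :class:`NoLinearRangeError` when fewer than three acceptable levels
    remain or the three survivors still violate the tolerance.
    """
    if not (0 < rel_residual_tol <= 1 and 0 < replicate_rsd_tol <= 1):
        raise ValueError("tolerances must be in (0, 1]")
    if series.n_levels < 3:
        raise NoLinearRangeError(f"{series.chemical_id}: fewer than 3 levels measured")
    means, rsd = _level_means_rsd(series)
    keep = [i for i in range(series.n_levels) if rsd[i] <= replicate_rsd_tol]
    if len(keep) < 3:
        raise NoLinearRangeError(
            f"{series.chemical_id}: fewer than 3 levels pass the replicate RSD bound"
        )
    while True:
        conc = series.concentrations[keep]
        worst_i, worst, _ = _worst_relative_residual(conc, means[keep])
        if worst <= rel_residual_tol:
            return list(keep)
        if len(keep) <= 3:
            raise NoLinearRangeError(
                f"{series.chemical_id}: no linear range "
                f"(worst relative residual {worst:.3f} > {rel_residual_tol} at 3 levels)"
            )
        del keep[worst_i]


def estimate_response_factor(
    series: CalibrationSeries,
    formula: str | Mapping[str, int] | None = None,
    rel_residual_tol: float = 0.2,
    replicate_rsd_tol: float = 0.3,
) -> ResponseFactorEstimate:
    """Fit the calibration line and report its slope as the response factor.

    Ordinary least squares (with intercept) of isotope-corrected replicate
    areas against molar concentration over the detected linear range.  The
    slope is the RF in M^-1.  A non-positive slope raises
    :class:`NonPositiveSlopeError`.
    """
    frac = monoisotopic_fraction(formula) if formula is not None else 1.0
    keep = detect_linear_range(series, rel_residual_tol, replicate_rsd_tol)
    xs, ys = [], []
    for i in keep:
        areas = correct_area(series.areas[i], frac)
        xs.append(np.full(series.areas[i].size, series.concentrations[i]))
        ys.append(np.atleast_1d(areas))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise NonPositiveSlopeError(f"{series.chemical_id}: non-positive calibration slope")
    means, _ = _level_means_rsd(series)
    _, worst, _ = _worst_relative_residual(series.concentrations[keep], means[keep])
    return ResponseFactorEstimate(
        chemical_id=series.chemical_id,
        rf=float(slope),
        intercept=float(intercept),
        linear_levels=tuple(keep),
        n_linear=len(keep),
        max_rel_residual=worst,
        isotope_correction_factor=1.0 / frac,
    )
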