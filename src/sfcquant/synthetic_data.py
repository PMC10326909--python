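"""Synthetic SFC/ESI/HRMS calibration datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage (calibration, filtering, model training, transfer,
Monte Carlo) is testable with known truth:

* descriptors follow a correlated factor model (collinear blocks, as PaDEL
  descriptor families are);
* true log10 ionization efficiency is a sparse linear combination of a few
  informative descriptors, affinely rescaled to a target span;
* true log10 RF is an affine instrument map of log IE plus lognormal
  instrument noise, by default anchored so that 127 chemicals span response
  factors 4.06e14 to 2.70e18 M^-1 (about four decades);
* calibration peak areas are proportional to concentration within a linear
  range (triplicates at levels geometrically spaced 12.2 to 1750 nmol/L by
  default, with multiplicative area noise) and plateau hard above it;
* retention times are weakly anticorrelated with log RF (target Spearman
  rho about -0.28).

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationSeries, ChemicalRecord, monoisotopic_fraction

__all__ = ["SynthConfig", "SyntheticTruth", "SyntheticDataset", "generate_dataset",
           "truth_report", "write_tables"]

#: Default calibration levels: 8 points geometrically spaced 12.2-1750 nmol/L.
DEFAULT_CONC_LEVELS: tuple[float, ...] = tuple(np.geomspace(12.2e-9, 1750e-9, 8))

# Instrument map defaults chosen so ie_range_target (1.30, 4.20) maps exactly
# onto log10 RF in [log10 4.06e14, log10 2.70e18].
_RF_LO, _RF_HI = np.log10(4.06e14), np.log10(2.70e18)
_IE_LO, _IE_HI = 1.30, 4.20
DEFAULT_INSTRUMENT_SLOPE = float((_RF_HI - _RF_LO) / (_IE_HI - _IE_LO))
DEFAULT_INSTRUMENT_INTERCEPT = float(_RF_LO - DEFAULT_INSTRUMENT_SLOPE * _IE_LO)


@dataclass(frozen=True)
class SynthConfig:
    n_chemicals: int = 127
    n_descriptors: int = 200
    n_informative: int = 5
    beta_scale: float = 1.0  # log10 IE units per standardized descriptor
    ie_range_target: tuple[float, float] = (_IE_LO, _IE_HI)
    instrument_slope: float = DEFAULT_INSTRUMENT_SLOPE
    instrument_intercept: float = DEFAULT_INSTRUMENT_INTERCEPT  # log10 M^-1
    sigma_instrument: float = 0.15  # SD of log10 RF noise
    sigma_area: float = 0.10  # relative SD of peak-area noise
    conc_levels: tuple[float, ...] = DEFAULT_CONC_LEVELS  # mol/L
    n_replicates: int = 3
    saturation_quantile: float = 0.75  # fraction of levels in the linear range
    seed: int = 0
    n_factors: int = 10
    rt_rho_target: float = -0.28  # Spearman rho of retention time vs log RF

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative must not exceed n_descriptors")
        if min(self.n_chemicals, self.n_descriptors, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if self.sigma_instrument < 0 or self.sigma_area < 0:
            raise ValueError("noise SDs must be >= 0")
        levels = np.asarray(self.conc_levels, dtype=float)
        if levels.size < 3 or np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
            raise ValueError("conc_levels must be >= 3 strictly increasing positive values")
        if not 0 < self.saturation_quantile <= 1:
            raise ValueError("saturation_quantile must be in (0, 1]")
        lo, hi = self.ie_range_target
        if not hi > lo:
            raise ValueError("ie_range_target is degenerate (low >= high)")


@dataclass
class SyntheticTruth:
    """Ground truth aligned with chemical order."""

    log_ie: np.ndarray
    log_rf: np.ndarray
    linear_top_level: np.ndarray  # index of the highest linear level, per chemical
    informative_indices: np.ndarray
    instrument_slope: float
    instrument_intercept: float


@dataclass
class SyntheticDataset:
    config: SynthConfig
    chemicals: list[ChemicalRecord]
    descriptor_matrix: pd.DataFrame  # chemicals x descriptors
    calibration: list[CalibrationSeries]
    truth: SyntheticTruth

    def __post_init__(self) -> None:
        n = len(self.chemicals)
        if not (len(self.calibration) == n == len(self.descriptor_matrix)):
            raise ValueError("chemicals, calibration and descriptors must align")
        if self.truth.log_rf.shape != (n,):
            raise ValueError("truth arrays must align with chemical order")


def _random_formula(rng: np.random.Generator) -> dict[str, int]:
    c = int(rng.integers(4, 31))
    return {
        "C": c,
        "H": int(rng.integers(c, 2 * c + 3)),
        "N": int(rng.integers(0, 4)),
        "O": int(rng.integers(0, 7)),
    }


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset; byte-identical given config and seed."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_chemicals, config.n_descriptors

    # correlated factor model: each descriptor loads on one latent factor,
    # giving collinear blocks for the correlation filter to prune
    factor_of = rng.integers(0, config.n_factors, size=p)
    loadings = rng.uniform(0.6, 0.95, size=p)
    factors = rng.standard_normal((n, config.n_factors))
    X = loadings * factors[:, factor_of] + np.sqrt(1 - loadings**2) * rng.standard_normal((n, p))

    # informative descriptors represent distinct chemical property axes:
    # mutually independent and outside the collinear noise blocks, so each
    # carries its own marginal association with log IE
    informative = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    X[:, informative] = rng.standard_normal((n, config.n_informative))
    beta = config.beta_scale * rng.choice([-1.0, 1.0], config.n_informative) * rng.uniform(
        0.8, 1.2, config.n_informative
    )
    raw = X[:, informative] @ beta
    lo, hi = config.ie_range_target
    if n > 1 and np.ptp(raw) > 0:
        log_ie = lo + (raw - raw.min()) * (hi - lo) / np.ptp(raw)
    else:
        log_ie = np.full(n, 0.5 * (lo + hi))
    log_rf = (
        config.instrument_intercept
        + config.instrument_slope * log_ie
        + config.sigma_instrument * rng.standard_normal(n)
    )

    # retention times: weak negative rank correlation with log RF, mapped
    # into the gradient window (about 0.8-10.8 min)
    rho0 = abs(config.rt_rho_target)
    z = (log_rf - log_rf.mean()) / (log_rf.std() or 1.0)
    latent = -np.sign(-config.rt_rho_target) * rho0 * z + np.sqrt(1 - rho0**2) * rng.standard_normal(n)
    rt = 0.8 + 10.0 * (stats.rankdata(latent) - 0.5) / n

    # log P loosely tracks ionization efficiency, spanning about -4.5..5.9
    logp_latent = 0.6 * (log_ie - log_ie.mean()) / (log_ie.std() or 1.0) + 0.8 * rng.standard_normal(n)
    logp = -4.5 + 10.4 * (stats.rankdata(logp_latent) - 0.5) / n

    levels = np.asarray(config.conc_levels, dtype=float)
    n_levels = levels.size
    top = int(np.ceil(config.saturation_quantile * n_levels)) - 1
    top = max(top, 2)  # keep at least 3 linear levels

    chemicals: list[ChemicalRecord] = []
    calibration: list[CalibrationSeries] = []
    rf_lin = np.power(10.0, log_rf)
    for i in range(n):
        cid = f"chem_{i:03d}"
        formula = _random_formula(rng)
        chemicals.append(
            ChemicalRecord(
                id=cid,
                name=f"synthetic compound {i}",
                formula=formula,
                retention_time=float(rt[i]),
                logp=float(logp[i]),
            )
        )
        # only the monoisotopic peak is "integrated": raw areas carry the
        # monoisotopic fraction, which isotope correction undoes downstream
        mono = monoisotopic_fraction(formula)
        areas = []
        for j in range(n_levels):
            c_eff = levels[min(j, top)]  # hard plateau above the linear range
            noise = 1.0 + config.sigma_area * rng.standard_normal(config.n_replicates)
            areas.append(mono * rf_lin[i] * c_eff * noise)
        calibration.append(CalibrationSeries(cid, levels.copy(), areas))

    descriptor_matrix = pd.DataFrame(
        X,
        index=[c.id for c in chemicals],
        columns=[f"d{j:04d}" for j in range(p)],
    )
    truth = SyntheticTruth(
        log_ie=log_ie,
        log_rf=log_rf,
        linear_top_level=np.full(n, top, dtype=int),
        informative_indices=informative,
        instrument_slope=config.instrument_slope,
        instrument_intercept=config.instrument_intercept,
    )
    return SyntheticDataset(config, chemicals, descriptor_matrix, calibration, truth)


def truth_report(dataset: SyntheticDataset) -> pd.DataFrame:
    """Aligned ground-truth table for parameter-recovery tests."""
    return pd.DataFrame(
        {
            "chemical_id": [c.id for c in dataset.chemicals],
            "true_log_ie": dataset.truth.log_ie,
            "true_log_rf": dataset.truth.log_rf,
            "linear_top_level": dataset.truth.linear_top_level,
        }
    )


def _formula_str(formula: dict[str, int]) -> str:
    return "".join(f"{el}{n}" for el, n in formula.items() if n)


def write_tables(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four input tables as CSV.

    chemicals.csv: chemical_id, name, formula, retention_time_min, logp
    descriptors.csv: chemical_id + one column per descriptor
    calibration.csv: chemical_id, concentration_nmol_L, replicate, area
    truth.csv: the :func:`truth_report` table
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chem = pd.DataFrame(
        {
            "chemical_id": [c.id for c in dataset.chemicals],
            "name": [c.name for c in dataset.chemicals],
            "formula": [_formula_str(dict(c.formula)) for c in dataset.chemicals],
            "retention_time_min": [c.retention_time for c in dataset.chemicals],
            "logp": [c.logp for c in dataset.chemicals],
        }
    )
    rows = []
    for series in dataset.calibration:
        for j, conc in enumerate(series.concentrations):
            for r, area in enumerate(series.areas[j]):
                rows.append((series.chemical_id, conc * 1e9, r + 1, area))
    calib = pd.DataFrame(rows, columns=["chemical_id", "concentration_nmol_L", "replicate", "area"])
    desc = dataset.descriptor_matrix.rename_axis("chemical_id").reset_index()
    paths = {
        "chemicals": outdir / "chemicals.csv",
        "descriptors": outdir / "descriptors.csv",
        "calibration": outdir / "calibration.csv",
        "truth": outdir / "truth.csv",
    }
    chem.to_csv(paths["chemicals"], index=False)
    desc.to_csv(paths["descriptors"], index=False)
    calib.to_csv(paths["calibration"], index=False)
    truth_report(dataset).to_csv(paths["truth"], index=False)
    return paths
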