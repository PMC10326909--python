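"""End-to-end orchestration: tables in, quantification artifacts out.

Stage order: calibrate -> append eluent descriptors -> filter descriptors ->
rank-stratified cross-validated RRF training -> quantify with the predicted
response factors -> summarize error factors -> optional Monte Carlo calibrant
study.  Every run writes a manifest recording the config hash, seed and
package version; rerunning with the same config and seed reproduces all
numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrant_mc import aggregate_mc, run_mc_study, samples_frame
from .calibration import (
    CalibrationError,
    CalibrationSeries,
    correct_area,
    estimate_response_factor,
    monoisotopic_fraction,
    parse_formula,
)
from .descriptors import (
    DescriptorMatrix,
    correlation_filter,
    near_zero_variance_filter,
    spearman_profile,
)
from .eluent import GradientProgram, descriptors_at
from .ie_model import RRFHyperparams, cross_validated_predictions, make_folds_rank_stratified
from .transfer_quant import error_factor, summarize_errors

logger = logging.getLogger("sfcquant")

__all__ = ["PipelineConfig", "SchemaError", "run_pipeline", "read_table",
           "load_calibration_table", "load_chemicals_table"]


class SchemaError(ValueError):
    """An input table violates its declared schema."""


@dataclass
class PipelineConfig:
    chemicals_path: str | None = None
    descriptors_path: str | None = None
    calibration_path: str | None = None
    gradient: GradientProgram | None = field(default_factory=GradientProgram.default)
    rel_residual_tol: float = 0.2
    replicate_rsd_tol: float = 0.3
    freq_cut: float = 19.0
    corr_cutoff: float = 0.75
    hyper: RRFHyperparams = field(default_factory=lambda: RRFHyperparams(mtry=86, n_trees=200))
    cv_folds: int = 10
    mc_enabled: bool = False
    mc_k_values: tuple[int, ...] = tuple(range(5, 21))
    mc_n_rep: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "gradient" in kwargs and kwargs["gradient"] is not None:
            g = kwargs["gradient"]
            kwargs["gradient"] = GradientProgram(
                segments=tuple(tuple(s) for s in g["segments"]),
                column_flow=g.get("column_flow", 1500.0),
                makeup_flow=g.get("makeup_flow", 200.0),
                makeup_composition=g.get(
                    "makeup_composition", {"water": 0.9, "isopropanol": 0.1}
                ),
                modifier_additive=tuple(g.get("modifier_additive", ("ammonium acetate", 20.0))),
                water_ph=g.get("water_ph", 7.0),
            )
        if "hyper" in kwargs and kwargs["hyper"] is not None:
            kwargs["hyper"] = RRFHyperparams(**kwargs["hyper"])
        if "mc_k_values" in kwargs:
            kwargs["mc_k_values"] = tuple(kwargs["mc_k_values"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_table(path: str | Path, required: tuple[str, ...], numeric: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV table and validate its schema, naming file/row/column on error."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path}: row {row}, column '{col}': non-numeric value {df[col][row]!r}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"{path}: row {row}, column '{col}': missing value")
        df[col] = coerced
    return df


def load_chemicals_table(path: str | Path) -> pd.DataFrame:
    df = read_table(
        path,
        required=("chemical_id", "name", "formula", "retention_time_min"),
        numeric=("retention_time_min",),
    )
    return df


def load_calibration_table(path: str | Path) -> dict[str, CalibrationSeries]:
    """Parse the long-format calibration table into per-chemical series."""
    df = read_table(
        path,
        required=("chemical_id", "concentration_nmol_L", "replicate", "area"),
        numeric=("concentration_nmol_L", "area"),
    )
    out: dict[str, CalibrationSeries] = {}
    for cid, grp in df.groupby("chemical_id", sort=False):
        concs = np.sort(grp["concentration_nmol_L"].unique()) * 1e-9
        areas = [
            grp.loc[np.isclose(grp["concentration_nmol_L"] * 1e-9, c), "area"].to_numpy()
            for c in concs
        ]
        out[str(cid)] = CalibrationSeries(str(cid), concs, areas)
    return out


def _calibrate_all(
    series_by_id: dict[str, CalibrationSeries],
    formula_by_id: dict[str, dict[str, int]],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    rows, flagged = [], {}
    for cid, series in series_by_id.items():
        try:
            est = estimate_response_factor(
                series,
                formula_by_id.get(cid),
                rel_residual_tol=cfg.rel_residual_tol,
                replicate_rsd_tol=cfg.replicate_rsd_tol,
            )
        except CalibrationError as exc:
            flagged[cid] = str(exc)
            continue
        rows.append(
            {
                "chemical_id": cid,
                "rf_M_inv": est.rf,
                "log10_rf": np.log10(est.rf),
                "n_linear": est.n_linear,
                "linear_levels": ";".join(map(str, est.linear_levels)),
                "isotope_correction_factor": est.isotope_correction_factor,
            }
        )
    return pd.DataFrame(rows), flagged


def _eluent_feature_frame(
    chem: pd.DataFrame, gradient: GradientProgram
) -> pd.DataFrame:
    feats = []
    for _, row in chem.iterrows():
        state = descriptors_at(gradient, float(row["retention_time_min"]))
        feats.append(
            {
                "eluent_viscosity": state.viscosity,
                "eluent_surface_tension": state.surface_tension,
                "eluent_polarity_index": state.polarity_index,
                "eluent_ph": state.ph,
                "eluent_nh4": float(state.nh4_present),
            }
        )
    return pd.DataFrame(feats, index=chem["chemical_id"].astype(str).to_numpy())


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts + manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chem = load_chemicals_table(config.chemicals_path)
    desc_df = read_table(config.descriptors_path, required=("chemical_id",))
    desc_df = desc_df.set_index("chemical_id")
    desc_df.index = desc_df.index.astype(str)
    series_by_id = load_calibration_table(config.calibration_path)

    formula_by_id = {
        str(r["chemical_id"]): parse_formula(r["formula"]) for _, r in chem.iterrows()
    }
    rf_table, flagged = _calibrate_all(series_by_id, formula_by_id, config)
    logger.info("calibrated %d chemicals, %d flagged", len(rf_table), len(flagged))
    if rf_table.empty:
        raise ValueError("no chemical yielded a valid response factor")
    rf_table.to_csv(out / "rf_table.csv", index=False)

    kept_ids = rf_table["chemical_id"].astype(str).tolist()
    chem = chem[chem["chemical_id"].astype(str).isin(kept_ids)].reset_index(drop=True)
    chem = chem.set_index(chem["chemical_id"].astype(str)).loc[kept_ids].reset_index(drop=True)
    X_df = desc_df.loc[kept_ids]
    if config.gradient is not None:
        X_df = pd.concat([X_df, _eluent_feature_frame(chem, config.gradient)], axis=1)

    dm = DescriptorMatrix.from_frame(X_df)
    dm = near_zero_variance_filter(dm, freq_cut=config.freq_cut)
    dm = correlation_filter(dm, cutoff=config.corr_cutoff)
    dm.removal_log().to_csv(out / "descriptor_filter_log.csv", index=False)
    Xk = dm.kept()
    logger.info("descriptor filters: %d -> %d columns", X_df.shape[1], Xk.shape[1])

    y = rf_table["log10_rf"].to_numpy()
    profile, rt_rho = spearman_profile(
        dm, y, retention_time=chem["retention_time_min"].to_numpy()
    )
    profile.to_csv(out / "spearman_profile.csv", index=False)

    hyper = config.hyper
    if hyper.mtry > Xk.shape[1]:
        hyper = RRFHyperparams(
            Xk.shape[1], hyper.coef_reg, hyper.coef_imp, hyper.n_trees, hyper.min_node
        )
    folds = make_folds_rank_stratified(y, k=config.cv_folds, seed=config.seed)
    oof = cross_validated_predictions(Xk.to_numpy(), y, hyper, folds, seed=config.seed)
    pred_table = pd.DataFrame(
        {"chemical_id": kept_ids, "log10_rf_measured": y, "log10_rf_pred": oof, "fold": folds}
    )
    pred_table.to_csv(out / "oof_predictions.csv", index=False)

    # quantify every chemical at its linear-range levels with the predicted RF
    quant_rows = []
    for cid, log_rf_pred in zip(kept_ids, oof):
        series = series_by_id[cid]
        frac = monoisotopic_fraction(formula_by_id[cid]) if cid in formula_by_id else 1.0
        lin = [int(s) for s in rf_table.set_index("chemical_id").loc[cid, "linear_levels"].split(";")]
        rf_pred = 10.0**log_rf_pred
        for j in lin:
            area = float(np.mean(correct_area(series.areas[j], frac)))
            pred_c = area / rf_pred
            spiked = float(series.concentrations[j])
            quant_rows.append(
                {
                    "chemical_id": cid,
                    "spiked_conc_M": spiked,
                    "corrected_area": area,
                    "predicted_conc_M": pred_c,
                    "error_factor": float(error_factor(pred_c, spiked)),
                }
            )
    quant = pd.DataFrame(quant_rows)
    quant.to_csv(out / "quant_results.csv", index=False)
    summary = summarize_errors(quant)
    summary["oof_spearman_rho"] = float(
        pd.Series(oof).corr(pd.Series(y), method="spearman")
    )
    summary["rt_log_rf_spearman_rho"] = rt_rho
    summary["n_chemicals"] = len(kept_ids)
    summary["n_flagged"] = len(flagged)

    results: dict = {"summary": summary, "rf_table": rf_table, "oof": pred_table, "quant": quant}
    if config.mc_enabled:
        chem_mc = pd.DataFrame(
            {
                "chemical_id": kept_ids,
                "retention_time": chem["retention_time_min"].to_numpy(),
                "log_rf": y,
                "log_ie_pred": oof,
            }
        )
        areas_mc = quant.rename(columns={"spiked_conc_M": "conc"})[
            ["chemical_id", "conc", "corrected_area"]
        ]
        samples = run_mc_study(
            chem_mc, areas_mc, k_values=config.mc_k_values, n_rep=config.mc_n_rep, seed=config.seed
        )
        samples_frame(samples).to_csv(out / "mc_samples.csv", index=False)
        agg = aggregate_mc(samples)
        for name, tab in agg.items():
            tab.to_csv(out / f"mc_{name}.csv", index=False)
        results["mc"] = agg

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "summary": {k: (float(v) if v is not None else None) for k, v in summary.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
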