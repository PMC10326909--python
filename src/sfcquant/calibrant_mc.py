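"""Monte Carlo study of calibrant-set selection for calibration transfer.

How many calibration chemicals are needed to transfer relative ionization
efficiency predictions onto a new instrument, and does their retention-time
or predicted-log-IE coverage matter?  For each calibrant count k (default 5
to 20) and each of 200 repetitions, k chemicals are sampled without
replacement, the transfer line is refitted on them, the remaining chemicals
are quantified at all their linear-range levels, and the test-set median
error factor is recorded together with the calibrants' retention-time and
log IE ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .transfer_quant import error_factor, fit_transfer

__all__ = ["MCSample", "run_mc_study", "aggregate_mc", "samples_frame", "plot_mc"]

CHEM_COLUMNS = ("chemical_id", "retention_time", "log_rf", "log_ie_pred")
AREA_COLUMNS = ("chemical_id", "conc", "corrected_area")


@dataclass(frozen=True)
class MCSample:
    k: int
    calibrant_ids: tuple[str, ...]
    rt_range: float  # minutes, max - min over calibrants
    ie_range: float  # log10 units, max - min of predicted log IE
    median_ef: float
    seed: int

    def __post_init__(self) -> None:
        if self.k != len(self.calibrant_ids):
            raise ValueError("k must equal the number of calibrants")
        if self.rt_range < 0 or self.ie_range < 0 or self.median_ef < 1:
            raise ValueError("ranges must be >= 0 and median EF >= 1")


def run_mc_study(
    chem: pd.DataFrame,
    areas: pd.DataFrame,
    k_values: Iterable[int] = range(5, 21),
    n_rep: int = 200,
    seed: int = 0,
) -> list[MCSample]:
    """Run the calibrant-sampling Monte Carlo.

    ``chem`` needs columns ``chemical_id, retention_time, log_rf,
    log_ie_pred`` (one row per chemical); ``areas`` needs ``chemical_id,
    conc, corrected_area`` with one row per linear-range level (level-mean
    corrected areas, conc in mol/L).  Fully seeded; raises ``ValueError``
    when any k >= number of chemicals.
    """
    for col in CHEM_COLUMNS:
        if col not in chem.columns:
            raise ValueError(f"chem table missing column {col!r}")
    for col in AREA_COLUMNS:
        if col not in areas.columns:
            raise ValueError(f"areas table missing column {col!r}")
    chem = chem.reset_index(drop=True)
    n = len(chem)
    ids = chem["chemical_id"].to_numpy()
    rt = chem["retention_time"].to_numpy(dtype=float)
    log_rf = chem["log_rf"].to_numpy(dtype=float)
    log_ie = chem["log_ie_pred"].to_numpy(dtype=float)

    idx_of = {cid: i for i, cid in enumerate(ids)}
    a_chem = areas["chemical_id"].map(idx_of).to_numpy()
    if np.any(pd.isna(a_chem)):
        raise ValueError("areas table contains chemicals absent from the chem table")
    a_chem = a_chem.astype(int)
    a_conc = areas["conc"].to_numpy(dtype=float)
    a_area = areas["corrected_area"].to_numpy(dtype=float)

    k_values = list(k_values)
    if any(k >= n for k in k_values):
        raise ValueError("calibrant count k must be smaller than the number of chemicals")
    samples: list[MCSample] = []
    base = int(seed) % (2**31)
    for k in k_values:
        for rep in range(n_rep):
            sub_seed = (base * 100003 + k * 1009 + rep) % (2**31)
            rng = np.random.default_rng(sub_seed)
            cal = rng.choice(n, size=k, replace=False)
            test_mask = np.ones(n, dtype=bool)
            test_mask[cal] = False
            line = fit_transfer(log_ie[cal], log_rf[cal])
            log_rf_pred = line.slope * log_ie + line.intercept
            rows = test_mask[a_chem]
            pred_conc = a_area[rows] / np.power(10.0, log_rf_pred[a_chem[rows]])
            efs = error_factor(pred_conc, a_conc[rows])
            samples.append(
                MCSample(
                    k=k,
                    calibrant_ids=tuple(ids[np.sort(cal)]),
                    rt_range=float(np.ptp(rt[cal])),
                    ie_range=float(np.ptp(log_ie[cal])),
                    median_ef=float(np.median(efs)),
                    seed=sub_seed,
                )
            )
    return samples


def samples_frame(samples: Sequence[MCSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": [s.k for s in samples],
            "rt_range": [s.rt_range for s in samples],
            "ie_range": [s.ie_range for s in samples],
            "median_ef": [s.median_ef for s in samples],
            "seed": [s.seed for s in samples],
        }
    )


def _binned(df: pd.DataFrame, col: str) -> pd.DataFrame:
    try:
        bins = pd.qcut(df[col], 4, duplicates="drop")
    except ValueError:  # fewer than 2 distinct values
        bins = pd.Series(["all"] * len(df), index=df.index)
    out = (
        df.groupby(bins, observed=True)["median_ef"]
        .agg(mean_median_ef="mean", sd_median_ef="std", n="size")
        .reset_index()
        .rename(columns={col: f"{col}_bin"})
    )
    return out


def aggregate_mc(samples: Sequence[MCSample]) -> dict[str, pd.DataFrame]:
    """Summaries mirroring the three study panels.

    ``by_k``: per-k mean and SD of the median EF, plus the SD of
    log10(median EF) ("log-units"); ``by_rt_range`` and ``by_ie_range``:
    mean median EF over quartile bins of the calibrant coverage.
    """
    if not samples:
        raise ValueError("no Monte Carlo samples to aggregate")
    df = samples_frame(samples)
    df["log10_median_ef"] = np.log10(df["median_ef"])
    by_k = (
        df.groupby("k")
        .agg(
            mean_median_ef=("median_ef", "mean"),
            sd_median_ef=("median_ef", "std"),
            sd_log10_median_ef=("log10_median_ef", "std"),
            n=("median_ef", "size"),
        )
        .reset_index()
    )
    return {
        "by_k": by_k,
        "by_rt_range": _binned(df, "rt_range"),
        "by_ie_range": _binned(df, "ie_range"),
    }


def plot_mc(agg: dict[str, pd.DataFrame], path: str) -> None:
    """Render the three aggregate panels as bar charts (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    panels = [
        ("by_rt_range", "rt_range_bin", "calibrant RT range (min)"),
        ("by_ie_range", "ie_range_bin", "calibrant log IE range"),
        ("by_k", "k", "number of calibrants"),
    ]
    for ax, (key, xcol, label) in zip(axes, panels):
        tab = agg[key]
        ax.bar(
            [str(v) for v in tab[xcol]],
            tab["mean_median_ef"],
            yerr=tab.get("sd_median_ef"),
            color="#7b5ea7",
        )
        ax.set_xlabel(label)
        ax.set_ylabel("mean of median EF")
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
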