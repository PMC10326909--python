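"""Descriptor-matrix preparation and correlation profiling.

Molecular descriptor tables (e.g. PaDEL output) are wide and highly
collinear.  Before model training two filters are applied, mirroring common
caret-style preprocessing:

1. near-zero-variance: drop descriptors whose most common value is >= 19x
   (95/5) as frequent as the second most common, or that are constant;
2. pairwise correlation: greedily remove one member of every descriptor pair
   with |Pearson r| above 0.75, dropping the member with the larger mean
   absolute correlation against the currently kept set.

Spearman rank correlations of individual descriptors against log10 response
factors are used to profile which molecular properties drive electrospray
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptorMatrix",
    "near_zero_variance_filter",
    "correlation_filter",
    "spearman_profile",
]


@dataclass
class DescriptorMatrix:
    """A chemicals x descriptors table with a kept/removed mask.

    ``values`` keeps every column; ``kept_mask`` marks survivors and
    ``removal_reason`` records why each dropped descriptor was removed
    (``"near_zero_variance"`` or ``"correlated"``).
    """

    values: pd.DataFrame
    kept_mask: pd.Series = field(default=None)  # type: ignore[assignment]
    removal_reason: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kept_mask is None:
            self.kept_mask = pd.Series(True, index=self.values.columns)
        if not self.kept_mask.index.equals(self.values.columns):
            raise ValueError("kept_mask must align with descriptor columns")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        return cls(values=df.astype(float))

    @property
    def chemical_ids(self) -> list:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def kept(self) -> pd.DataFrame:
        """The filtered matrix (kept columns only)."""
        return self.values.loc[:, self.kept_mask]

    def removal_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"descriptor": list(self.removal_reason), "reason": list(self.removal_reason.values())}
        )


def near_zero_variance_filter(dm: DescriptorMatrix, freq_cut: float = 19.0) -> DescriptorMatrix:
    """Drop constant columns and columns dominated by a single value.

    A descriptor is removed when the ratio of the count of its most frequent
    value to the count of its second most frequent value is >= ``freq_cut``
    (default 19, i.e. 95/5), or when it takes a single unique value.
    """
    if len(dm.values) < 2:
        raise ValueError("need at least two chemicals")
    mask = dm.kept_mask.copy()
    reasons = dict(dm.removal_reason)
    for col in dm.values.columns[dm.kept_mask]:
        counts = dm.values[col].value_counts().to_numpy()
        if counts.size == 1 or counts[0] / counts[1] >= freq_cut:
            mask[col] = False
            reasons[col] = "near_zero_variance"
    return DescriptorMatrix(dm.values, mask, reasons)


def correlation_filter(dm: DescriptorMatrix, cutoff: float = 0.75) -> DescriptorMatrix:
    """Greedy removal of highly correlated descriptors.

    While any kept pair has |Pearson r| > ``cutoff``: take the most
    correlated pair and remove the member with the larger mean absolute
    correlation against all currently kept descriptors (recomputed after each
    removal).  Ties break toward keeping the earlier column.
    """
    mask = dm.kept_mask.copy()
    reasons = dict(dm.removal_reason)
    cols = list(dm.values.columns[mask])
    if len(cols) >= 2:
        corr = np.abs(np.corrcoef(dm.values[cols].to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        alive = np.ones(len(cols), dtype=bool)
        while True:
            sub = corr[np.ix_(alive, alive)]
            if sub.size == 0 or sub.max() <= cutoff:
                break
            live_idx = np.flatnonzero(alive)
            i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
            i, j = live_idx[i_s], live_idx[j_s]
            if i > j:
                i, j = j, i
            mean_i = corr[i, alive].mean()
            mean_j = corr[j, alive].mean()
            drop = i if mean_i > mean_j else j  # tie -> earlier column survives
            alive[drop] = False
        for pos, col in enumerate(cols):
            if not alive[pos]:
                mask[col] = False
                reasons[col] = "correlated"
    return DescriptorMatrix(dm.values, mask, reasons)


def spearman_profile(
    dm: DescriptorMatrix,
    log_rf: np.ndarray | pd.Series,
    retention_time: np.ndarray | pd.Series | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Tie-corrected Spearman rho of each kept descriptor against log10 RF.

    Returns a table sorted by rho (descending) and, when retention times are
    supplied, the rho of retention time vs log10 RF.
    """
    y = np.asarray(log_rf, dtype=float)
    kept = dm.kept()
    if len(y) != len(kept):
        raise ValueError("log_rf must align with chemicals")
    rows = []
    for col in kept.columns:
        rho = stats.spearmanr(kept[col].to_numpy(), y).statistic
        rows.append((col, float(rho)))
    table = (
        pd.DataFrame(rows, columns=["descriptor", "rho"])
        .sort_values("rho", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    rt_rho = None
    if retention_time is not None:
        rt_rho = float(stats.spearmanr(np.asarray(retention_time, float), y).statistic)
    return table, rt_rho
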