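"""Quantile normalization of Ct values across sample arrays.

Forces every array's Ct distribution onto a common reference — the mean of
order statistics across arrays — while preserving within-array ranks.  This
is the data-driven normalization appropriate for high-throughput qPCR
cards, where no single endogenous control is trustworthy: a per-array
additive technical shift moves every well by the same amount and is removed
exactly.

Missing wells are never imputed.  For an array with ``m`` non-missing wells
out of ``n``, its observed quantiles are interpolated onto the common grid
when building the reference, and each observed value is replaced by the
reference quantile at its (average) rank position ``(r - 1) / (m - 1)``;
for complete data this reduces to the classical exact algorithm (equal
sorted value vectors across arrays), and tied values receive the mean of
the reference values at their tied ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["NormalizationError", "NormalizationReport", "quantile_normalize"]


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationReport:
    """Per-sample diagnostics plus the reference quantile vector."""

    pre_median: pd.Series
    post_median: pd.Series
    n_missing: pd.Series
    reference: np.ndarray  # non-decreasing, length n_features

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre_median": self.pre_median,
                "post_median": self.post_median,
                "n_missing": self.n_missing,
            }
        )


def quantile_normalize(m: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationReport]:
    """Quantile-normalize a Ct matrix (features x samples) across samples.

    Returns the normalized matrix (missing wells stay missing) and a report.
    Raises :class:`NormalizationError` if fewer than two samples are present
    or any sample has fewer than two non-missing wells.
    """
    if m.shape[1] < 2:
        raise NormalizationError("quantile normalization needs at least 2 samples")
    vals = m.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    counts = np.sum(~np.isnan(vals), axis=0)
    for j, c in enumerate(counts):
        if c < 2:
            raise NormalizationError(
                f"sample {m.columns[j]!r} has {c} non-missing values (need >= 2)"
            )

    grid = np.linspace(0.0, 1.0, n_feat)
    # reference: mean across samples of each sample's quantile function on the grid
    ref = np.zeros(n_feat)
    for j in range(n_samp):
        col = vals[:, j]
        obs = np.sort(col[~np.isnan(col)])
        pos = np.linspace(0.0, 1.0, obs.size)
        ref += np.interp(grid, pos, obs)
    ref /= n_samp
    ref = np.maximum.accumulate(ref)  # guard against fp non-monotonicity

    out = np.full_like(vals, np.nan)
    for j in range(n_samp):
        col = vals[:, j]
        mask = ~np.isnan(col)
        obs = col[mask]
        ranks = rankdata(obs, method="average")  # ties -> mean of tied reference values
        pos = (ranks - 1.0) / (obs.size - 1.0)
        out[mask, j] = np.interp(pos, grid, ref)

    norm = pd.DataFrame(out, index=m.index.copy(), columns=m.columns.copy())
    report = NormalizationReport(
        pre_median=m.median(axis=0),
        post_median=norm.median(axis=0),
        n_missing=m.isna().sum(axis=0),
        reference=ref,
    )
    return norm, report
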