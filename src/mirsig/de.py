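"""Paired differential expression on Ct data and signature selection.

For each feature the per-pair difference ``d = Ct(malignant) - Ct(normal)``
is tested against zero with a paired Student's t-test (vectorized across
features) and, for comparison, a Wilcoxon signed-rank test.  Benjamini-
Hochberg FDR adjustment is applied over all testable features.  Because Ct
and abundance are inversely related, a *negative* mean difference means the
miRNA is *up*-regulated in the malignant tissue; direction calls ``+``/``-``
refer to expression.

Signatures are the features passing a strict p-value threshold, ordered by
ascending t-test p with a lexicographic feature-ID tie-break so reports are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .io import complete_pairs

__all__ = [
    "Signature",
    "paired_differences",
    "paired_t",
    "paired_wilcoxon",
    "bh_adjust",
    "de_table",
    "select_signature",
    "compare_tests",
]


@dataclass(frozen=True)
class Signature:
    """An ordered feature set selected at a significance threshold."""

    feature_ids: tuple[str, ...]
    alpha: float

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(self.feature_ids)


def paired_differences(m: pd.DataFrame, a: pd.DataFrame) -> pd.DataFrame:
    """Per-feature, per-case Ct differences (malignant - normal).

    Only intact pairs (``paired`` flag true, one sample of each tissue
    class) contribute; a pair with a missing well in either member yields
    ``NaN`` for that feature.
    """
    pairs = complete_pairs(a)
    if not pairs:
        raise ValueError("no complete (normal, malignant) pairs in annotation")
    cases = [c for c, _, _ in pairs]
    normal = m[[n for _, n, _ in pairs]].to_numpy(dtype=float)
    malig = m[[t for _, _, t in pairs]].to_numpy(dtype=float)
    return pd.DataFrame(malig - normal, index=m.index.copy(), columns=cases)


def paired_t(m: pd.DataFrame, a: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test per feature.

    Returns a frame indexed by feature with columns ``n_pairs_used``,
    ``mean_delta_ct``, ``direction``, ``t_stat``, ``df``, ``p_t`` and
    ``flag``.  Features with fewer than two usable pairs, or with all
    differences exactly zero, are flagged ``untestable`` (p missing);
    nonzero constant differences (sd = 0) are flagged ``degenerate`` and
    reported with p = 0 rather than propagating NaN.
    """
    d = paired_differences(m, a).to_numpy(dtype=float)
    n = np.sum(~np.isnan(d), axis=1)
    mean = np.where(n > 0, np.nansum(d, axis=1) / np.maximum(n, 1), np.nan)
    ss = np.nansum((d - mean[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    sd = np.where(n >= 2, sd, np.nan)

    t = np.full(d.shape[0], np.nan)
    p = np.full(d.shape[0], np.nan)
    flag = np.array([""] * d.shape[0], dtype=object)

    testable = n >= 2
    degen = testable & (sd == 0) & (mean != 0)
    zero = testable & (sd == 0) & (mean == 0)
    ok = testable & (sd > 0)

    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    p[ok] = 2.0 * st.t.sf(np.abs(t[ok]), df=n[ok] - 1)
    t[degen] = np.where(mean[degen] > 0, np.inf, -np.inf)
    p[degen] = 0.0
    flag[degen] = "degenerate"
    flag[zero | ~testable] = "untestable"

    direction = np.where(mean > 0, "-", "+")  # higher Ct in malignant = lower expression
    return pd.DataFrame(
        {
            "n_pairs_used": n,
            "mean_delta_ct": mean,
            "direction": direction,
            "t_stat": t,
            "df": np.where(testable, n - 1, 0),
            "p_t": p,
            "flag": flag,
        },
        index=m.index.copy(),
    )


def paired_wilcoxon(m: pd.DataFrame, a: pd.DataFrame, exact_max_n: int = 25) -> pd.Series:
    """Two-sided Wilcoxon signed-rank p per feature.

    Zero differences are dropped before ranking; the exact null distribution
    is used for n <= ``exact_max_n`` pairs, the normal approximation with
    continuity correction above.  Untestable features get ``NaN``.
    """
    d = paired_differences(m, a)
    p = pd.Series(np.nan, index=m.index.copy(), name="p_wilcoxon")
    for fid, row in d.iterrows():
        x = row.dropna().to_numpy()
        x = x[x != 0.0]
        if x.size < 2:
            continue
        method = "exact" if x.size <= exact_max_n else "approx"
        try:
            res = st.wilcoxon(
                x, alternative="two-sided", method=method, correction=(method == "approx")
            )
            p.loc[fid] = res.pvalue
        except ValueError:
            continue
    return p


def bh_adjust(pvals: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment over the non-missing entries.

    Missing p-values stay missing and do not count toward m.
    """
    arr = np.asarray(pvals, dtype=float)
    mask = ~np.isnan(arr)
    if np.any((arr[mask] < 0) | (arr[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index, name="p_adj")
    return out


def de_table(m: pd.DataFrame, a: pd.DataFrame, wilcoxon: bool = True) -> pd.DataFrame:
    """Full per-feature differential-expression table (t, BH, Wilcoxon)."""
    res = paired_t(m, a)
    res["p_adj"] = bh_adjust(res["p_t"])
    if wilcoxon:
        res["p_wilcoxon"] = paired_wilcoxon(m, a)
    return res


def select_signature(results: pd.DataFrame, alpha: float) -> Signature:
    """Features with ``p_t`` strictly below ``alpha``, ordered by p then ID."""
    sub = results[results["p_t"] < alpha]
    order = sorted(sub.index, key=lambda fid: (sub.at[fid, "p_t"], fid))
    return Signature(tuple(order), alpha)


def compare_tests(results: pd.DataFrame, alpha: float) -> dict:
    """Concordance of t-test and Wilcoxon selections at one threshold.

    Returns the two selected sets, their overlap, and a per-feature table
    flagging which of the tests called each selected feature.
    """
    if "p_wilcoxon" not in results.columns:
        raise ValueError("results lack Wilcoxon p-values; run de_table(wilcoxon=True)")
    t_set = set(results.index[results["p_t"] < alpha])
    w_set = set(results.index[results["p_wilcoxon"] < alpha])
    both = t_set & w_set
    table = pd.DataFrame(
        {
            "in_t": [f in t_set for f in sorted(t_set | w_set)],
            "in_wilcoxon": [f in w_set for f in sorted(t_set | w_set)],
        },
        index=sorted(t_set | w_set),
    )
    smaller = min(len(t_set), len(w_set))
    return {
        "alpha": alpha,
        "n_t": len(t_set),
        "n_wilcoxon": len(w_set),
        "n_overlap": len(both),
        "overlap_of_smaller": len(both) / smaller if smaller else np.nan,
        "table": table,
    }
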