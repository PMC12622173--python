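"""Low-signal filtering, depth normalization and a simplified two-group
differential test for peak count tables.

The differential engine here is a documented stand-in for a full
negative-binomial GLM: pseudocounted log-ratio effect sizes, a two-sided
Welch t-test on log2(normalized count + 1), and Benjamini-Hochberg
adjustment. It is validated by simulation (type-I calibration and planted
fold-change detection), and is isolated behind `differential_test` so a
different engine can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 1.0  # on normalized counts, bounds log-ratios at zero counts


@dataclass(frozen=True)
class Thresholds:
    """Differential-call thresholds.

    min_tag_count: peaks whose maximum raw count across samples falls below
        this are discarded before testing (default 4).
    fc_threshold: linear fold-change cutoff; a call requires
        |log2fc| > log2(fc_threshold) (default 2).
    alpha: BH-adjusted p-value cutoff (default 0.05).
    """

    min_tag_count: int = 4
    fc_threshold: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.fc_threshold <= 1.0:
            raise ValueError(f"fc_threshold must exceed 1, got {self.fc_threshold}")
        if self.min_tag_count < 0:
            raise ValueError("min_tag_count must be non-negative")


def filter_low_signal(counts: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Retain peaks whose maximum count across samples reaches min_tag_count."""
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    keep = arr.max(axis=1) >= thresholds.min_tag_count
    out = counts.loc[keep]
    if out.empty:
        warnings.warn("no peaks survive the low-signal filter", stacklevel=2)
    return out


def normalize_depth(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column so column sums equal the median raw column sum."""
    sums = counts.sum(axis=0).astype(float)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    target = float(np.median(sums.to_numpy()))
    return counts.astype(float) * (target / sums)


def differential_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Two-group differential signal over peaks.

    groups maps sample name -> "A" or "B" (>= 2 samples per group). Returns a
    DataFrame per peak: mean_norm_a, mean_norm_b, log2fc (pseudocounted
    log-ratio B/A on normalized counts), pvalue (Welch t on log2(norm+1)),
    padj (BH), and call in {up_in_b, down_in_b, ns}.
    """
    thresholds = thresholds or Thresholds()
    a_samples = sorted(s for s, g in groups.items() if g == "A")
    b_samples = sorted(s for s, g in groups.items() if g == "B")
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("need at least two samples per group")
    missing = (set(a_samples) | set(b_samples)) - set(counts.columns)
    if missing:
        raise ValueError(f"samples absent from count table: {sorted(missing)}")
    norm = normalize_depth(counts[a_samples + b_samples])
    na = norm[a_samples].to_numpy()
    nb = norm[b_samples].to_numpy()
    mean_a = na.mean(axis=1)
    mean_b = nb.mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    la = np.log2(na + 1.0)
    lb = np.log2(nb + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvalue = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    pvalue = np.asarray(pvalue, dtype=float)
    # zero variance in both groups: p = 1 when the means agree, else 0
    nan_mask = ~np.isfinite(pvalue)
    if nan_mask.any():
        same = np.isclose(lb.mean(axis=1), la.mean(axis=1))
        pvalue[nan_mask & same] = 1.0
        pvalue[nan_mask & ~same] = 0.0
    padj = multipletests(pvalue, method="fdr_bh")[1] if len(pvalue) else pvalue
    lfc_cut = np.log2(thresholds.fc_threshold)
    call = np.full(len(counts), "ns", dtype=object)
    sig = padj < thresholds.alpha
    call[sig & (log2fc > lfc_cut)] = "up_in_b"
    call[sig & (log2fc < -lfc_cut)] = "down_in_b"
    return pd.DataFrame(
        {
            "mean_norm_a": mean_a,
            "mean_norm_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "call": call,
        },
        index=counts.index,
    )
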