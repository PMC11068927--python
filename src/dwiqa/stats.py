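"""VOI summaries of ADC maps and paired comparisons between ADC variants.

Each volume of interest (a vial cylinder or a tissue label) is summarized
by mean, median, sample standard deviation and the nonparametric skew
(mean − median)/SD, a bounded asymmetry measure (|·| ≤ 1).  ADC variants
(e.g. fits on different b-value subsets) are compared per subject with
two-tailed paired Wilcoxon signed-rank tests at the 0.05 level, without
multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .adc import ADCMap


@dataclass(frozen=True)
class VOISummary:
    mean: float
    median: float
    sd: float  # sample (n-1) standard deviation
    np_skew: float  # (mean - median) / sd, 0 when sd == 0
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "np_skew": self.np_skew,
            "n": self.n,
        }


def summarize_values(values) -> VOISummary:
    """Summary statistics of a 1D sample of ADC values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    mean = float(v.mean())
    median = float(np.median(v))
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    skew = (mean - median) / sd if sd > 0 else 0.0
    return VOISummary(mean=mean, median=median, sd=sd, np_skew=float(skew), n=int(v.size))


def voi_summary(adc_map: ADCMap, mask) -> VOISummary:
    """Summary of voxelwise ADC within a mask, restricted to valid voxels."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & adc_map.valid_mask
    if not sel.any():
        raise ValueError("no valid voxels inside the mask")
    return summarize_values(adc_map.adc[sel])


def relative_difference(adc1: float, adc2: float, adc_reference: float) -> float:
    """(ADC1 − ADC2) / ADC_reference."""
    if adc_reference == 0:
        raise ValueError("reference ADC must be nonzero")
    return (adc1 - adc2) / adc_reference


def paired_wilcoxon(x, y) -> float:
    """Two-tailed paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's convention).  The exact null
    distribution is used for n ≤ 25 without ties in |differences|; the
    normal approximation with tie correction otherwise.  Returns NaN when
    every difference is zero (the test is undefined), and raises if fewer
    than 5 nonzero differences remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and equally long")
    diff = x - y
    nz = diff[diff != 0]
    if nz.size == 0:
        return float("nan")
    if nz.size < 5:
        raise ValueError("fewer than 5 nonzero differences")
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "approx" if (has_ties or nz.size > 25) else "exact"
    res = sps.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", correction=False,
        method=method,
    )
    return float(res.pvalue)


def compare_methods(
    summaries: pd.DataFrame,
    statistic: str = "mean",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise paired Wilcoxon comparisons between ADC variants.

    ``summaries`` must have columns subject, method, voi and the statistic
    column ('mean' or 'median'); one row per (subject, method, voi).
    Returns one row per (voi, method pair) with the two-sided p-value and
    a significance flag at ``alpha`` (no multiplicity correction).
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    for col in ("subject", "method", "voi", statistic):
        if col not in summaries.columns:
            raise ValueError(f"summaries missing column {col!r}")
    methods = sorted(summaries["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    rows = []
    for voi, grp in summaries.groupby("voi"):
        wide = grp.pivot(index="subject", columns="method", values=statistic)
        if wide.isna().any().any():
            raise ValueError(f"missing subject/method cells in VOI {voi!r}")
        if len(wide) < 5:
            raise ValueError("need at least 5 subjects")
        for a, b in combinations(methods, 2):
            p = paired_wilcoxon(wide[a].to_numpy(), wide[b].to_numpy())
            rows.append(
                {
                    "voi": voi,
                    "statistic": statistic,
                    "method_a": a,
                    "method_b": b,
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)
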