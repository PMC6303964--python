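"""Whole/partial time-split cross-validation and method-R statistics.

The whole data set contains all records; the partial set drops everything
from the cutoff period onward. Individuals with records on both sides of
the cutoff are excluded entirely; individuals with records only after the
cutoff are the selection candidates, with no own phenotypic information in
the partial data. Comparing their breeding values from the two fits gives

    b0  = mean(g_whole) - mean(g_partial)        (bias; 0 under unbiasedness)
    b1  = Cov(g_whole, g_partial) / Var(g_partial)  (dispersion; 1 ideal)
    rho = Cor(g_whole, g_partial)                (relative accuracy gain)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .phenotypes import PhenotypeRecords


@dataclass
class SplitPlan:
    cutoff: int
    whole: PhenotypeRecords
    partial: PhenotypeRecords
    candidates: list
    excluded: list


def time_split(records: PhenotypeRecords, cutoff: int) -> SplitPlan:
    """Partition records at a period cutoff (partial = periods before it).

    Individuals spanning the cutoff are removed from both sets; candidates
    are individuals whose records all fall at or after the cutoff.
    """
    df = records.df
    before = df.loc[df["period"] < cutoff, "individual_id"].unique()
    after = df.loc[df["period"] >= cutoff, "individual_id"].unique()
    excluded = sorted(set(before) & set(after))
    candidates = sorted(set(after) - set(before))
    if not candidates:
        raise ValueError(f"no candidate individuals after period cutoff {cutoff}")
    keep = ~df["individual_id"].isin(excluded)
    whole = records.subset(keep)
    partial = records.subset(keep & (df["period"] < cutoff))
    return SplitPlan(cutoff=cutoff, whole=whole, partial=partial,
                     candidates=candidates, excluded=excluded)


def method_r(g_whole: np.ndarray, g_partial: np.ndarray,
             sigma_a: float | None = None) -> tuple[float, float, float]:
    """(b0, b1, rho) over the candidate set; vectors must be aligned.

    Sample (n-1) variances and covariances over candidates. If ``sigma_a``
    (the whole-data additive SD) is given, b0 is also interpretable on that
    scale via b0 / sigma_a.
    """
    gw = np.asarray(g_whole, dtype=float)
    gp = np.asarray(g_partial, dtype=float)
    if gw.shape != gp.shape or gw.ndim != 1:
        raise ValueError("breeding-value vectors must be aligned 1-d arrays")
    if gw.size < 3:
        raise ValueError("need at least 3 candidates")
    var_p = float(np.var(gp, ddof=1))
    var_w = float(np.var(gw, ddof=1))
    if var_p <= 0.0:
        raise ValueError("partial-data breeding values have zero variance")
    cov = float(np.cov(gw, gp, ddof=1)[0, 1])
    b0 = float(gw.mean() - gp.mean())
    b1 = cov / var_p
    rho = cov / np.sqrt(var_w * var_p)
    return b0, b1, rho


def predictive_ability(y_star: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and OLS slope of corrected phenotypes y* on
    predictions y_hat over candidate records."""
    ys = np.asarray(y_star, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if ys.shape != yh.shape or ys.ndim != 1 or ys.size < 3:
        raise ValueError("need aligned 1-d vectors with at least 3 records")
    var_h = float(np.var(yh, ddof=1))
    var_s = float(np.var(ys, ddof=1))
    if var_h <= 0.0 or var_s <= 0.0:
        raise ValueError("zero variance in predictive-ability inputs")
    cov = float(np.cov(ys, yh, ddof=1)[0, 1])
    return cov / np.sqrt(var_s * var_h), cov / var_h


@dataclass
class ValidationReport:
    model: str
    b0: float
    b0_in_sigma_a: float | None
    b1: float
    rho: float
    predictive_correlation: float
    predictive_slope: float
    n_candidates: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
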