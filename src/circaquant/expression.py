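"""Cosinor regression for timed expression data and ddCt quantification for qPCR.

A cosinor fit is ordinary least squares of
``y = mesor + b_s*sin(2*pi*t/P) + b_c*cos(2*pi*t/P)`` at fixed period P;
amplitude and acrophase (hours of the fitted maximum) derive from the
two linear coefficients.  ddCt quantification expresses each sample's
target-gene Ct relative to a housekeeping gene (dCt) and then to the
reference-group mean (ddCt); fold change is 2^(-ddCt), so the reference
group's mean fold change is 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CosinorFit", "cosinor_fit", "ddct", "ddct_group_summary"]


@dataclass
class CosinorFit:
    """Least-squares sine+cosine fit at fixed period."""

    mesor: float
    beta_sin: float
    beta_cos: float
    period_h: float
    amplitude: float       # sqrt(beta_sin^2 + beta_cos^2)
    acrophase_h: float     # time of the fitted maximum, in [0, period)
    residual_var: float    # RSS / (n - 3)
    n: int

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        w = 2.0 * np.pi / self.period_h
        return self.mesor + self.beta_sin * np.sin(w * t) + self.beta_cos * np.cos(w * t)


def cosinor_fit(times_h, values, period_h: float = 24.0) -> CosinorFit:
    """Fit a fixed-period cosinor to timed values.

    Requires at least 4 distinct timepoints spanning at least half a
    period (else the sine and cosine regressors are near-collinear and
    the design is rejected as rank deficient).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times_h and values must be 1-D and of equal length")
    if period_h <= 0:
        raise ValueError("period_h must be positive")
    distinct = np.unique(t)
    if len(distinct) < 4:
        raise ValueError(f"need >= 4 distinct timepoints, got {len(distinct)}")
    if distinct.max() - distinct.min() < period_h / 2.0:
        raise ValueError(
            f"timepoints span {distinct.max() - distinct.min():.2f} h, less than "
            f"half the period ({period_h / 2:.2f} h)"
        )
    w = 2.0 * np.pi / period_h
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient cosinor design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    n = len(y)
    mesor, bs, bc = (float(b) for b in beta)
    amplitude = float(np.hypot(bs, bc))
    # y = mesor + A*cos(w*(t - phi)) with bc = A cos(w phi), bs = A sin(w phi)
    acrophase = float(np.arctan2(bs, bc) / w % period_h) if amplitude > 0 else 0.0
    dof = max(n - 3, 1)
    return CosinorFit(
        mesor=mesor, beta_sin=bs, beta_cos=bc, period_h=float(period_h),
        amplitude=amplitude, acrophase_h=acrophase,
        residual_var=float(resid @ resid) / dof, n=n,
    )


def ddct(
    ct_table: pd.DataFrame,
    housekeeping_gene: str,
    reference_group: str,
) -> pd.DataFrame:
    """Per-sample ddCt fold changes.

    ``ct_table`` is tidy with columns sample, group, gene, ct.  For each
    sample and target gene: dCt = Ct_gene - Ct_housekeeping; ddCt = dCt -
    mean(dCt of the reference group for that gene); fold = 2^(-ddCt).
    Samples lacking a housekeeping Ct are excluded with a warning.

    Returns a tidy frame: sample, group, gene, dct, ddct, fold_change.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    hk = (
        ct_table[ct_table["gene"] == housekeeping_gene]
        .set_index("sample")["ct"]
    )
    targets = ct_table[ct_table["gene"] != housekeeping_gene].copy()
    missing = sorted(set(targets["sample"]) - set(hk.index))
    if missing:
        warnings.warn(
            f"samples without housekeeping Ct excluded: {missing}", stacklevel=2
        )
        targets = targets[~targets["sample"].isin(missing)]
    if not (ct_table["group"] == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} not present")
    targets["dct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
    ref_mean = (
        targets[targets["group"] == reference_group]
        .groupby("gene")["dct"]
        .mean()
    )
    targets["ddct"] = targets["dct"] - ref_mean.loc[targets["gene"]].to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "group", "gene", "dct", "ddct", "fold_change"]].reset_index(
        drop=True
    )


def ddct_group_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean +- SEM of fold changes and of dCt, per gene."""
    def sem(x):
        x = np.asarray(x, float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    return (
        per_sample.groupby(["gene", "group"])
        .agg(
            n=("sample", "count"),
            mean_fold=("fold_change", "mean"),
            sem_fold=("fold_change", sem),
            mean_dct=("dct", "mean"),
            sem_dct=("dct", sem),
        )
        .reset_index()
    )
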