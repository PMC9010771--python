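"""Instrument diagnostics: Cochran's Q, the MR-PRESSO global test,
leave-one-out analysis, I²_GX, and the screen inflation factor λ.

These are the checks used to decide whether an IVW estimate can be trusted:
Q detects heterogeneity between per-SNP causal estimates, MR-PRESSO detects
outlier instruments via a simulation null for the residual sum of squares of
leave-one-out fits, leave-one-out flags single SNPs that drive significance,
and λ (genomic-control style) measures p-value inflation across a screen of
many tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .estimators import (
    CHI2_1_MEDIAN,
    InsufficientInstrumentsError,
    MRModel,
    _ivw_core,
)
from .sumstats import InstrumentSet


@dataclass
class SensitivityReport:
    """Bundle of the diagnostics battery for one instrument set."""

    Q: float
    Q_df: int
    Q_p: float
    i2_gx: float
    presso_rss: float | None = None
    presso_p: float | None = None
    presso_sims: int = 0
    loo: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), default=float, **kwargs)


def cochran_q(inst: InstrumentSet) -> dict:
    """Cochran's Q over per-SNP ratio estimates against the IVW mean.

    Q = Σ w_j (θ̂_j − θ̂_IVW)², df = L−1, upper-tail χ² p-value.
    """
    rt = MRModel(inst).ratio_table()
    if len(rt) < 2:
        raise InsufficientInstrumentsError("cochran_q needs at least 2 instruments")
    theta, _, _, Q = _ivw_core(rt.theta, rt.w)
    df = len(rt) - 1
    return {"Q": Q, "Q_df": df, "Q_p": float(stats.chi2.sf(Q, df))}


def _loo_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW point estimates, one per dropped instrument."""
    w = bx**2 / sy**2
    theta_j = by / bx
    sw, swt = w.sum(), (w * theta_j).sum()
    return (swt - w * theta_j) / (sw - w)


def mr_presso_global(inst: InstrumentSet, sims: int = 1000, seed: int = 0) -> dict:
    """MR-PRESSO global outlier test.

    The observed statistic is the weighted residual sum of squares
    RSS = Σ (β_Yj − θ̂_(−j)·β_Xj)²/se_Yj² with θ̂_(−j) the leave-one-out IVW
    estimate.  Its null distribution is simulated by drawing
    β_Xj* ~ N(β_Xj, se_Xj) and β_Yj* ~ N(θ̂_(−j)·β_Xj, se_Yj) and recomputing
    the leave-one-out RSS on each draw; p = (1 + #{RSS* ≥ RSS}) / (sims + 1).
    """
    if sims <= 0:
        raise ValueError("sims must be positive")
    bx, sx, by, sy = inst.arrays()
    L = len(bx)
    if L < 4:
        raise InsufficientInstrumentsError("mr_presso_global needs at least 4 instruments")
    # canonical instrument order makes the simulated p order-invariant
    order = np.argsort(inst.table["rsid"].to_numpy(), kind="stable")
    bx, sx, by, sy = bx[order], sx[order], by[order], sy[order]
    loo = _loo_ivw(bx, by, sy)
    rss_obs = float((((by - loo * bx) / sy) ** 2).sum())

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(sims, L))
    by_star = rng.normal(loo * bx, sy, size=(sims, L))
    # vectorized leave-one-out IVW across simulations
    w = bx_star**2 / sy**2
    theta = by_star / np.where(bx_star == 0, np.nan, bx_star)
    theta = np.nan_to_num(theta)
    sw = w.sum(axis=1, keepdims=True)
    swt = (w * theta).sum(axis=1, keepdims=True)
    loo_star = (swt - w * theta) / (sw - w)
    rss_star = (((by_star - loo_star * bx_star) / sy) ** 2).sum(axis=1)
    p = (1.0 + float((rss_star >= rss_obs).sum())) / (sims + 1.0)
    return {"presso_rss": rss_obs, "presso_p": p, "presso_sims": sims}


def leave_one_out(inst: InstrumentSet, alpha: float = 0.05) -> tuple[list, list]:
    """IVW re-estimates with each instrument dropped in turn.

    Flags are raised when the full-set estimate is significant but any
    leave-one-out estimate is not ("single SNP drives significance"), or when
    any leave-one-out estimate changes sign.
    """
    model = MRModel(inst)
    L = model.L
    if L < 3:
        raise InsufficientInstrumentsError("leave_one_out needs at least 3 instruments")
    full = model.fit("ivw_mre")
    # closed-form delete-one updates of the weighted mean and Cochran's Q
    rt = model.ratio_table()
    w, theta_j = rt.w, rt.theta
    sw = w.sum()
    theta_full = (w * theta_j).sum() / sw
    Q_full = (w * (theta_j - theta_full) ** 2).sum()
    sw_d = sw - w
    theta_d = (sw * theta_full - w * theta_j) / sw_d
    Q_d = (Q_full + sw * (theta_full - theta_d) ** 2
           - w * (theta_j - theta_d) ** 2)
    phi_d = np.maximum(Q_d, 0.0) / (L - 2)
    se_d = np.sqrt(phi_d / sw_d)
    with np.errstate(divide="ignore"):
        p_d = 2 * stats.t.sf(np.abs(theta_d / se_d), L - 2)
    rows = [{"dropped": inst.table["rsid"].iat[i], "theta": float(theta_d[i]),
             "se": float(se_d[i]), "p": float(p_d[i])} for i in range(L)]
    flags = []
    if full.pvalue < alpha and any(r["p"] >= alpha for r in rows):
        flags.append("single SNP drives significance")
    if any(np.sign(r["theta"]) != np.sign(full.theta) and r["theta"] != 0 for r in rows):
        flags.append("leave-one-out sign change")
    return rows, flags


def inflation_lambda(pvalues, scale: str = "chi2") -> float:
    """Inflation factor λ of a collection of p-values.

    ``scale="chi2"`` (default, the genomic-control convention): each p is
    converted to its χ²₁ quantile and λ is the ratio of the observed median
    to the χ²₁ median (0.4549...).  ``scale="pvalue"`` reports the literal
    ratio of the expected median p (0.5) to the observed median p.  Under a
    global null both are ≈ 1; inflation gives λ > 1 on both scales.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("inflation_lambda needs at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if scale == "chi2":
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / CHI2_1_MEDIAN)
    if scale == "pvalue":
        return float(0.5 / np.median(p))
    raise ValueError(f"unknown scale {scale!r}")


def sensitivity_battery(inst: InstrumentSet, presso_sims: int = 1000,
                        seed: int = 0, alpha: float = 0.05) -> SensitivityReport:
    """Run the full diagnostics battery on one instrument set.

    MR-PRESSO requires ≥ 4 instruments and leave-one-out ≥ 3; below those
    counts the corresponding entries are marked not-applicable rather than
    raising, so screens over heterogeneous instrument counts stay total.
    """
    q = cochran_q(inst)
    model = MRModel(inst)
    report = SensitivityReport(Q=q["Q"], Q_df=q["Q_df"], Q_p=q["Q_p"],
                               i2_gx=model.i2_gx())
    if len(inst) >= 4 and presso_sims > 0:
        pres = mr_presso_global(inst, sims=presso_sims, seed=seed)
        report.presso_rss = pres["presso_rss"]
        report.presso_p = pres["presso_p"]
        report.presso_sims = presso_sims
        if pres["presso_p"] < alpha:
            report.flags.append("MR-PRESSO outlier evidence")
    else:
        report.flags.append("MR-PRESSO not applicable (L < 4)" if len(inst) < 4
                            else "MR-PRESSO skipped (sims=0)")
    if len(inst) >= 3:
        report.loo, loo_flags = leave_one_out(inst, alpha=alpha)
        report.flags.extend(loo_flags)
    if q["Q_p"] <= alpha:
        report.flags.append("significant heterogeneity (Cochran Q)")
    return report
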