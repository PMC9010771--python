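"""Two-sample MR estimators.

The central object is :class:`MRModel`, built from a harmonized
:class:`~mrscreen.sumstats.InstrumentSet`; ``fit(method=...)`` returns an
:class:`MRResults` carrying the causal-effect estimate, its standard error
and p-value plus method-specific extras.  Methods:

``ivw_mre``
    Inverse-variance-weighted estimate under a multiplicative random-effects
    model: the weighted mean of per-SNP Wald ratios θ̂_j = β_Yj/β_Xj with
    weights w_j = β_Xj²/se_Yj² — equivalently weighted least squares of β_Y
    on β_X through the origin — with the residual scale φ = Q/(L−1)
    multiplying the variance and inference from the t distribution on L−1
    df (exact small-sample WLS inference, which keeps a null screen's
    p-values calibrated at the 6–14 instrument counts the filter retains).
``egger``
    Weighted regression of β_Y on β_X *with* an intercept estimating average
    directional pleiotropy; same multiplicative scale, t on L−2 df.
``weighted_median``
    Median of the ratio estimates under the inverse-variance weighting,
    consistent when ≥50% of the weight comes from valid instruments;
    bootstrap standard error.
``weighted_mode``
    Mode of the weighted kernel density of ratio estimates (zero modal
    pleiotropy assumption); bootstrap standard error.
``mr_lasso``
    Per-SNP pleiotropy intercepts α_j under an L1 penalty; the penalty is
    relaxed down a grid and stops as soon as the zero-α ("valid") subset is
    homogeneous by Cochran's Q; the reported estimate is IVW on that subset.

All estimators operate on summary data only and assume the two samples are
non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import InstrumentSet

_METHODS = ("ivw_mre", "egger", "weighted_median", "weighted_mode", "mr_lasso", "ratio")

CHI2_1_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator is given fewer instruments than it needs."""


@dataclass
class RatioTable:
    """Per-instrument Wald ratios θ_j = β_Yj/β_Xj and IVW weights w_j = β_Xj²/se_Yj²."""

    rsid: np.ndarray
    theta: np.ndarray
    w: np.ndarray
    excluded: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.theta)


@dataclass
class MRResults:
    """Result of one MR estimator fit.

    Attributes
    ----------
    theta : float
        Causal effect estimate (log-odds of outcome per unit exposure for a
        binary outcome).
    se, pvalue : float
        Standard error and two-sided p-value under the method's reference
        distribution.
    L : int
        Number of instruments used.
    extras : dict
        Method-specific quantities (Egger intercept and its inference,
        MR-Lasso valid set and penalty, bootstrap settings, ...).
    """

    method: str
    theta: float
    se: float
    pvalue: float
    L: int
    exposure_id: str = ""
    outcome_id: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def zvalue(self) -> float:
        return self.theta / self.se

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        crit = stats.norm.ppf(1 - alpha / 2)
        return self.theta - crit * self.se, self.theta + crit * self.se

    def to_row(self) -> dict:
        import json

        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "method": self.method,
            "nsnp": self.L,
            "theta": self.theta,
            "se": self.se,
            "p": self.pvalue,
            "extras_json": json.dumps(
                {k: v for k, v in self.extras.items() if _json_safe(v)}, default=str
            ),
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            f"MR estimate [{self.method}]  {self.exposure_id} -> {self.outcome_id}",
            f"  instruments: {self.L}",
            f"  theta: {self.theta: .6g}   se: {self.se:.6g}   p: {self.pvalue:.3g}",
            f"  95% CI: [{lo:.6g}, {hi:.6g}]",
        ]
        if self.method == "egger":
            lines.append(
                "  intercept: {b0: .6g}   se: {b0_se:.6g}   p: {b0_p:.3g}".format(
                    b0=self.extras["intercept"],
                    b0_se=self.extras["intercept_se"],
                    b0_p=self.extras["intercept_p"],
                )
            )
        if self.method == "mr_lasso":
            lines.append(f"  valid instruments: {len(self.extras['valid_rsids'])}"
                         f"   lambda: {self.extras['penalty']:.4g}")
        return "\n".join(lines)


def _json_safe(v) -> bool:
    return not isinstance(v, (np.ndarray, pd.DataFrame, pd.Series))


class MRModel:
    """Two-sample MR model for one exposure–outcome pair.

    Parameters
    ----------
    instruments : InstrumentSet
        Harmonized instruments (betas signed to a common effect allele).

    Examples
    --------
    >>> res = MRModel(inst).fit()                     # doctest: +SKIP
    >>> res = MRModel(inst).fit(method="egger")       # doctest: +SKIP
    """

    def __init__(self, instruments: InstrumentSet):
        self.instruments = instruments
        self.bx, self.sx, self.by, self.sy = instruments.arrays()
        self.exposure_id = instruments.exposure_id
        self.outcome_id = instruments.outcome_id

    @property
    def L(self) -> int:
        return len(self.bx)

    # -- ratio table ------------------------------------------------------

    def ratio_table(self) -> RatioTable:
        nonzero = self.bx != 0
        excluded = []
        for rsid in self.instruments.table["rsid"][~nonzero]:
            excluded.append({"action": "exclude", "rsid": rsid, "reason": "beta_x_zero"})
        bx, by, sy = self.bx[nonzero], self.by[nonzero], self.sy[nonzero]
        return RatioTable(
            rsid=self.instruments.table["rsid"].to_numpy()[nonzero],
            theta=by / bx,
            w=bx**2 / sy**2,
            excluded=excluded,
        )

    # -- individual estimators -------------------------------------------

    def fit(self, method: str = "ivw_mre", **kwargs) -> MRResults:
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
        return getattr(self, f"_fit_{method}")(**kwargs)

    def fit_all(self, seed: int = 0, boot_reps: int = 1000) -> list[MRResults]:
        """Fit the full estimator battery (IVW, Egger, median, mode, Lasso)."""
        out = [self._fit_ivw_mre()]
        if self.L >= 3:
            out.append(self._fit_egger())
            out.append(self._fit_weighted_median(boot_reps=boot_reps, seed=seed))
            out.append(self._fit_weighted_mode(boot_reps=boot_reps, seed=seed + 1))
            out.append(self._fit_mr_lasso())
        return out

    def _require(self, minimum: int, method: str) -> None:
        if self.L < minimum:
            raise InsufficientInstrumentsError(
                f"{method} needs at least {minimum} instruments, got {self.L}")

    def _result(self, method, theta, se, pvalue, **extras) -> MRResults:
        return MRResults(method=method, theta=float(theta), se=float(se),
                         pvalue=float(pvalue), L=self.L,
                         exposure_id=self.exposure_id, outcome_id=self.outcome_id,
                         extras=extras)

    def _fit_ratio(self) -> MRResults:
        self._require(1, "ratio")
        if self.L != 1:
            raise ValueError("ratio method is for single-instrument sets; use ivw_mre")
        theta = self.by[0] / self.bx[0]
        se = abs(self.sy[0] / self.bx[0])  # first-order delta method
        p = 2 * stats.norm.sf(abs(theta / se))
        return self._result("ratio", theta, se, p)

    def _fit_ivw_mre(self) -> MRResults:
        self._require(2, "ivw_mre")
        rt = self.ratio_table()
        theta, se, phi, Q = _ivw_core(rt.theta, rt.w)
        p = _two_sided_p(theta, se, df=len(rt) - 1)
        return self._result("ivw_mre", theta, se, p, Q=Q, phi=phi,
                            df=len(rt) - 1)

    def _fit_egger(self) -> MRResults:
        self._require(3, "egger")
        # orient all instruments to a non-negative exposure effect
        sign = np.where(self.bx < 0, -1.0, 1.0)
        bx, by = self.bx * sign, self.by * sign
        w = 1.0 / self.sy**2
        # weighted least squares: by = b0 + theta * bx
        sw, swx, swx2 = w.sum(), (w * bx).sum(), (w * bx**2).sum()
        swy, swxy = (w * by).sum(), (w * bx * by).sum()
        det = sw * swx2 - swx**2
        if det <= 0:
            raise ValueError("degenerate design in Egger regression (constant beta_x)")
        theta = (sw * swxy - swx * swy) / det
        b0 = (swx2 * swy - swx * swxy) / det
        resid = by - b0 - theta * bx
        df = self.L - 2
        scale = float((w * resid**2).sum() / df) if df > 0 else np.inf
        se_theta = np.sqrt(scale * sw / det)
        se_b0 = np.sqrt(scale * swx2 / det)
        p = _two_sided_p(theta, se_theta, df=df)
        p0 = _two_sided_p(b0, se_b0, df=df)
        return self._result("egger", theta, se_theta, p,
                            intercept=float(b0), intercept_se=float(se_b0),
                            intercept_p=float(p0), df=df, scale=scale)

    def _fit_weighted_median(self, boot_reps: int = 1000, seed: int = 0) -> MRResults:
        self._require(3, "weighted_median")
        rt = self.ratio_table()
        theta = _weighted_median(rt.theta, rt.w)
        se = self._bootstrap_se(_weighted_median, boot_reps, seed)
        p = 2 * stats.norm.sf(abs(theta / se))
        return self._result("weighted_median", theta, se, p,
                            boot_reps=boot_reps, seed=seed)

    def _fit_weighted_mode(self, phi: float = 1.0, boot_reps: int = 1000,
                           seed: int = 0, grid_points: int = 512) -> MRResults:
        self._require(3, "weighted_mode")
        rt = self.ratio_table()

        def estimator(theta_j, w_j):
            return _weighted_mode(theta_j, w_j, phi=phi, grid_points=grid_points)

        theta = estimator(rt.theta, rt.w)
        se = self._bootstrap_se(estimator, boot_reps, seed)
        p = 2 * stats.norm.sf(abs(theta / se))
        return self._result("weighted_mode", theta, se, p, bandwidth_phi=phi,
                            boot_reps=boot_reps, seed=seed, grid_points=grid_points)

    def _bootstrap_se(self, estimator, boot_reps: int, seed: int) -> float:
        """Parametric bootstrap over the sampling error of both betas."""
        if boot_reps < 2:
            raise ValueError("boot_reps must be >= 2")
        rng = np.random.default_rng(seed)
        bx_star = rng.normal(self.bx, self.sx, size=(boot_reps, self.L))
        by_star = rng.normal(self.by, self.sy, size=(boot_reps, self.L))
        ests = np.empty(boot_reps)
        for b in range(boot_reps):
            bx = bx_star[b]
            ok = bx != 0
            ests[b] = estimator(by_star[b][ok] / bx[ok], bx[ok] ** 2 / self.sy[ok] ** 2)
        return float(ests.std(ddof=1))

    def _fit_mr_lasso(self, n_lambda: int = 50, lambda_ratio: float = 1000.0,
                      q_alpha: float = 0.05) -> MRResults:
        self._require(3, "mr_lasso")
        bx, by, sy = self.bx, self.by, self.sy
        w = 1.0 / sy**2

        def theta_given_alpha(alpha):
            return float((w * bx * (by - alpha)).sum() / (w * bx**2).sum())

        def coordinate_fit(lam):
            alpha = np.zeros(self.L)
            theta = theta_given_alpha(alpha)
            for _ in range(200):
                resid = by - theta * bx
                # soft-threshold each alpha_j at lam / (2 w_j)
                thresh = lam / (2.0 * w)
                alpha_new = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0)
                theta_new = theta_given_alpha(alpha_new)
                if np.max(np.abs(alpha_new - alpha)) < 1e-10 and abs(theta_new - theta) < 1e-12:
                    alpha, theta = alpha_new, theta_new
                    break
                alpha, theta = alpha_new, theta_new
            return theta, alpha

        theta0 = theta_given_alpha(np.zeros(self.L))
        lam_max = float(np.max(2.0 * w * np.abs(by - theta0 * bx)))
        if lam_max == 0:
            lam_max = 1.0
        grid = np.geomspace(lam_max * 1.0001, lam_max / lambda_ratio, n_lambda)

        # heterogeneity stopping rule: relax the penalty from lambda_max down
        # and stop at the first lambda whose zero-alpha ("valid") subset is
        # homogeneous by Cochran's Q — with no pleiotropy this stops at the
        # top of the grid and the estimate reduces to plain IVW
        chosen = None
        for lam in grid:
            theta_l, alpha_l = coordinate_fit(lam)
            valid = np.abs(alpha_l) < 1e-9
            nv = int(valid.sum())
            if nv < 2:
                continue
            q_theta, q_w = (by[valid] / bx[valid]), (bx[valid] ** 2 / sy[valid] ** 2)
            ivw = float((q_w * q_theta).sum() / q_w.sum())
            Q = float((q_w * (q_theta - ivw) ** 2).sum())
            if Q <= stats.chi2.ppf(1 - q_alpha, nv - 1):
                chosen = (lam, valid)
                break
        if chosen is None:
            base = self._fit_ivw_mre()
            base.method = "mr_lasso"
            base.extras.update(valid_rsids=list(self.instruments.table["rsid"]),
                               penalty=float("nan"), fallback_full_set=True)
            return base
        lam, valid = chosen
        sub = self.instruments.subset(np.flatnonzero(valid))
        res = MRModel(sub)._fit_ivw_mre()
        res.method = "mr_lasso"
        res.L = self.L
        res.exposure_id, res.outcome_id = self.exposure_id, self.outcome_id
        res.extras.update(valid_rsids=list(sub.table["rsid"]), penalty=float(lam),
                          n_valid=len(sub), fallback_full_set=False)
        return res

    # -- diagnostics shared with the sensitivity battery -------------------

    def i2_gx(self) -> float:
        """Weak-instrument heterogeneity I²_GX of the exposure associations.

        Values near 1 indicate negligible regression-dilution bias in the
        Egger slope.
        """
        self._require(2, "i2_gx")
        v = 1.0 / self.sx**2
        m = float((v * self.bx).sum() / v.sum())
        q_gx = float((v * (self.bx - m) ** 2).sum())
        if q_gx == 0:
            return 0.0
        return max(0.0, (q_gx - (self.L - 1)) / q_gx)


# -- free-function surface (spec operation names) ---------------------------

def ratio_table(inst: InstrumentSet) -> RatioTable:
    return MRModel(inst).ratio_table()


def ivw_mre(inst: InstrumentSet) -> MRResults:
    return MRModel(inst).fit("ivw_mre")


def egger(inst: InstrumentSet) -> MRResults:
    return MRModel(inst).fit("egger")


def i2_gx(inst: InstrumentSet) -> float:
    return MRModel(inst).i2_gx()


def weighted_median(inst: InstrumentSet, boot_reps: int = 1000, seed: int = 0) -> MRResults:
    return MRModel(inst).fit("weighted_median", boot_reps=boot_reps, seed=seed)


def weighted_mode(inst: InstrumentSet, phi: float = 1.0, boot_reps: int = 1000,
                  seed: int = 0) -> MRResults:
    return MRModel(inst).fit("weighted_mode", phi=phi, boot_reps=boot_reps, seed=seed)


def mr_lasso(inst: InstrumentSet) -> MRResults:
    return MRModel(inst).fit("mr_lasso")


# -- numerical kernels ------------------------------------------------------

def _two_sided_p(estimate: float, se: float, df: int | None = None) -> float:
    """Two-sided p-value; exact-fit degeneracy (se = 0) handled explicitly."""
    if se == 0:
        return 1.0 if estimate == 0 else 0.0
    z = abs(estimate / se)
    return float(2 * stats.t.sf(z, df)) if df else float(2 * stats.norm.sf(z))

def _ivw_core(theta_j: np.ndarray, w_j: np.ndarray) -> tuple[float, float, float, float]:
    """IVW-MRE point estimate, se, residual scale phi and Cochran's Q."""
    if len(theta_j) < 2:
        raise InsufficientInstrumentsError("ivw_mre needs at least 2 instruments")
    sw = w_j.sum()
    theta = float((w_j * theta_j).sum() / sw)
    Q = float((w_j * (theta_j - theta) ** 2).sum())
    phi = Q / (len(theta_j) - 1)
    se = float(np.sqrt(phi / sw))
    return theta, se, phi, Q


def _weighted_median(theta_j: np.ndarray, w_j: np.ndarray) -> float:
    """Weighted median with linear interpolation across cumulative weight."""
    order = np.argsort(theta_j, kind="stable")
    t, w = theta_j[order], w_j[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    if s[0] >= 0.5:
        return float(t[0])
    if s[-1] <= 0.5:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def _weighted_mode(theta_j: np.ndarray, w_j: np.ndarray, phi: float = 1.0,
                   grid_points: int = 512) -> float:
    """Mode of the weighted Gaussian KDE of ratio estimates.

    Bandwidth h = phi * 0.9 * min(sd, IQR/1.349) * L^(-1/5) (modified
    Silverman rule); the density is evaluated on a fixed grid spanning
    [min-3h, max+3h].
    """
    L = len(theta_j)
    sd = float(np.std(theta_j, ddof=1)) if L > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta_j, [75, 25])))
    spread = min(sd, iqr / 1.349) if min(sd, iqr) > 0 else max(sd, iqr / 1.349)
    h = phi * 0.9 * spread * L ** (-0.2)
    if h <= 0 or not np.isfinite(h):
        return float(theta_j[0])
    grid = np.linspace(theta_j.min() - 3 * h, theta_j.max() + 3 * h, grid_points)
    dens = (w_j[None, :] * np.exp(-0.5 * ((grid[:, None] - theta_j[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])
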