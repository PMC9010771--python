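"""Multivariable Mendelian randomization (MVMR).

MVMR regresses the outcome associations of a joint instrument set on the
instrument associations of several exposures simultaneously, estimating each
exposure's *direct* effect conditional on the others — the tool used here to
ask whether an exposure's apparent toxicity survives conditioning on a
candidate mediator.  Instrument strength per exposure is measured by the
conditional F-statistic (>10 is the conventional adequacy bound) and
residual heterogeneity by Q_A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import InsufficientInstrumentsError
from .ldref import ReferencePanel, clump
from .screen import ScreenConfig
from .sumstats import SummaryStats, harmonize


@dataclass
class MVInstrumentSet:
    """Jointly harmonized instruments for d ≥ 2 exposures and one outcome.

    ``beta_x``/``se_x`` are (L × d) arrays; column k holds the instrument
    associations with exposure k, all signed to a common effect allele per
    SNP.
    """

    exposure_ids: list[str]
    outcome_id: str
    rsids: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        L, d = self.beta_x.shape
        if d < 1:
            raise ValueError("need at least one exposure")
        if self.se_x.shape != (L, d) or len(self.beta_y) != L or len(self.se_y) != L:
            raise ValueError("inconsistent array shapes")

    @property
    def L(self) -> int:
        return self.beta_x.shape[0]

    @property
    def d(self) -> int:
        return self.beta_x.shape[1]

    def permute_exposures(self, order: list[int]) -> "MVInstrumentSet":
        return MVInstrumentSet(
            exposure_ids=[self.exposure_ids[i] for i in order],
            outcome_id=self.outcome_id, rsids=self.rsids,
            beta_x=self.beta_x[:, order], se_x=self.se_x[:, order],
            beta_y=self.beta_y, se_y=self.se_y,
            provenance=list(self.provenance))


@dataclass
class MVMRResults:
    """Direct-effect estimates with conditional instrument strength."""

    exposure_ids: list[str]
    theta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    cond_F: np.ndarray
    Q_A: float
    Q_A_df: int
    Q_A_p: float
    L: int

    def summary(self) -> str:
        lines = [f"Multivariable MR ({self.L} instruments, "
                 f"{len(self.exposure_ids)} exposures)"]
        for k, eid in enumerate(self.exposure_ids):
            lines.append(
                f"  {eid}: theta={self.theta[k]: .6g}  se={self.se[k]:.6g}  "
                f"p={self.pvalues[k]:.3g}  cond_F={self.cond_F[k]:.1f}")
        lines.append(f"  heterogeneity Q_A={self.Q_A:.2f} "
                     f"(df={self.Q_A_df}, p={self.Q_A_p:.3g})")
        return "\n".join(lines)


class MVMRModel:
    """Weighted least-squares MVMR model over a joint instrument set."""

    def __init__(self, mv: MVInstrumentSet):
        if mv.L <= mv.d:
            raise InsufficientInstrumentsError(
                f"MVMR needs more instruments ({mv.L}) than exposures ({mv.d})")
        self.mv = mv

    def _check_rank(self, X: np.ndarray) -> None:
        d = X.shape[1]
        if np.linalg.matrix_rank(X) < d:
            # name the most collinear exposure pair
            worst, pair = 0.0, (0, min(1, d - 1))
            for a in range(d):
                for b in range(a + 1, d):
                    xa, xb = X[:, a], X[:, b]
                    denom = np.linalg.norm(xa) * np.linalg.norm(xb)
                    c = abs(float(xa @ xb) / denom) if denom else 1.0
                    if c > worst:
                        worst, pair = c, (a, b)
            ids = self.mv.exposure_ids
            raise np.linalg.LinAlgError(
                f"rank-deficient MVMR design; exposures {ids[pair[0]]!r} and "
                f"{ids[pair[1]]!r} have collinear instrument associations")

    def fit(self) -> MVMRResults:
        mv = self.mv
        w = 1.0 / mv.se_y**2
        X = mv.beta_x
        self._check_rank(X)
        Xw = X * w[:, None]
        xtx = X.T @ Xw
        theta = np.linalg.solve(xtx, Xw.T @ mv.beta_y)
        resid = mv.beta_y - X @ theta
        Q_A = float((w * resid**2).sum())
        df = mv.L - mv.d
        scale = max(Q_A / df, 1.0) if df > 0 else 1.0
        cov = scale * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov))
        p = 2 * stats.norm.sf(np.abs(theta / se))
        cond_F = np.array([self.conditional_F(k) for k in range(mv.d)])
        return MVMRResults(exposure_ids=list(mv.exposure_ids), theta=theta,
                           se=se, pvalues=p, cond_F=cond_F, Q_A=Q_A,
                           Q_A_df=df, Q_A_p=float(stats.chi2.sf(Q_A, df)),
                           L=mv.L)

    def conditional_F(self, k: int) -> float:
        """Conditional instrument strength of exposure k given the others.

        The exposure-k associations are regressed (weights 1/se_Xk², no
        intercept) on the other exposures' associations; the weighted
        residual sum of squares Q_xk divided by L−d is the conditional F.
        With a single exposure this reduces to the mean-χ² marginal strength.
        """
        mv = self.mv
        v = 1.0 / mv.se_x[:, k] ** 2
        xk = mv.beta_x[:, k]
        others = np.delete(mv.beta_x, k, axis=1)
        if others.shape[1] == 0:
            fitted = np.zeros_like(xk)
        else:
            sv = np.sqrt(v)
            coef, *_ = np.linalg.lstsq(others * sv[:, None], xk * sv, rcond=None)
            fitted = others @ coef
        q_xk = float((v * (xk - fitted) ** 2).sum())
        return q_xk / (mv.L - mv.d)


def build_mv_instruments(exposures: list[SummaryStats], outcome: SummaryStats,
                         panel: ReferencePanel,
                         per_exposure_p: list[float] | None = None,
                         cfg: ScreenConfig | None = None) -> MVInstrumentSet:
    """Select and jointly harmonize instruments for several exposures.

    The candidate set is the union of SNPs passing each exposure's p-value
    threshold, clumped jointly by the minimum p across exposures (so the
    strongest instrument of either exposure survives LD pruning).  Every
    retained SNP must be present in all exposures and the outcome; each
    trait's beta is aligned to the first exposure's effect allele.  SNPs lost
    in any trait (including palindromic drops) are recorded in provenance.
    """
    cfg = cfg or ScreenConfig()
    d = len(exposures)
    if d < 2:
        raise ValueError("multivariable MR needs at least two exposures")
    if per_exposure_p is None:
        per_exposure_p = [cfg.instrument_p_max] * d
    if len(per_exposure_p) != d:
        raise ValueError("per_exposure_p must match the number of exposures")

    prov: list[dict] = []
    min_p: dict[str, float] = {}
    for stats_, pmax in zip(exposures, per_exposure_p):
        sel = stats_.table[stats_.table["p"] < pmax]
        for r in sel.itertuples():
            min_p[r.rsid] = min(min_p.get(r.rsid, 1.0), float(r.p))
    if not min_p:
        raise InsufficientInstrumentsError("no SNP passes any exposure threshold")

    clumped = clump(panel, [{"rsid": r, "p": p} for r, p in min_p.items()],
                    r2_max=cfg.clump_r2_max, window_kb=cfg.clump_window_kb)
    for rem in clumped.removed:
        prov.append({"action": "drop", "rsid": rem["rsid"],
                     "reason": f"clump:{rem['reason']}"})

    ref = exposures[0]
    shared = [r for r in clumped.index_snps
              if all(r in e.rsids for e in exposures) and r in outcome.rsids
              and r in ref.rsids]
    for r in clumped.index_snps:
        if r not in shared:
            prov.append({"action": "drop", "rsid": r,
                         "reason": "absent_from_some_trait"})
    if not shared:
        raise InsufficientInstrumentsError("no SNP shared across all traits")

    # align everything to the first exposure's effect allele
    harm_y = harmonize(ref, outcome, snps=shared,
                       palindrome_maf_max=cfg.palindrome_maf_max)
    keep = set(harm_y.table["rsid"])
    harm_x: dict[int, pd.DataFrame] = {}
    for k in range(1, d):
        hk = harmonize(ref, exposures[k], snps=shared,
                       palindrome_maf_max=cfg.palindrome_maf_max)
        harm_x[k] = hk.table.set_index("rsid")
        keep &= set(hk.table["rsid"])
        prov.extend(hk.provenance)
    prov.extend(harm_y.provenance)

    rows = harm_y.table[harm_y.table["rsid"].isin(keep)].set_index("rsid")
    rsids = np.array(sorted(rows.index, key=lambda r: min_p.get(r, 1.0)))
    L = len(rsids)
    if L <= d:
        raise InsufficientInstrumentsError(
            f"only {L} joint instruments for {d} exposures")

    beta_x = np.empty((L, d))
    se_x = np.empty((L, d))
    ref_tab = ref.table.set_index("rsid")
    beta_x[:, 0] = ref_tab.loc[rsids, "beta"].to_numpy(float)
    se_x[:, 0] = ref_tab.loc[rsids, "se"].to_numpy(float)
    for k in range(1, d):
        beta_x[:, k] = harm_x[k].loc[rsids, "beta_y"].to_numpy(float)
        se_x[:, k] = harm_x[k].loc[rsids, "se_y"].to_numpy(float)
    return MVInstrumentSet(
        exposure_ids=[e.trait_id for e in exposures], outcome_id=outcome.trait_id,
        rsids=rsids, beta_x=beta_x, se_x=se_x,
        beta_y=rows.loc[rsids, "beta_y"].to_numpy(float),
        se_y=rows.loc[rsids, "se_y"].to_numpy(float), provenance=prov)


def mvmr_fit(mv: MVInstrumentSet) -> MVMRResults:
    return MVMRModel(mv).fit()


def conditional_F(mv: MVInstrumentSet, k: int) -> float:
    return MVMRModel(mv).conditional_F(k)
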