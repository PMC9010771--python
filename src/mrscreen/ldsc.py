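"""Cross-trait LD-score regression (genetic covariance).

Under a polygenic model, the expected product of two traits' z-scores at a
SNP grows linearly with its LD score ℓ_j:

    E[z1_j · z2_j] = ρ_g · sqrt(n1·n2) · ℓ_j / M + intercept,

where ρ_g is the genetic covariance, M the number of SNPs in the LD-score
reference, and the intercept absorbs sample overlap and confounding.  The
slope of a weighted regression of z1·z2 on ℓ therefore estimates ρ_g after
rescaling; standard errors come from a delete-one block jackknife over
contiguous SNP blocks.  This implementation uses a single-pass
heteroskedasticity weighting 1/(1+ℓ)² rather than the reference tool's
iterative two-step weights — adequate for screening near-zero covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, is_palindromic


class TooFewSNPsError(ValueError):
    pass


@dataclass
class LDSCInput:
    """Aligned per-SNP z-scores, LD scores and sample sizes for two traits."""

    table: pd.DataFrame  # columns: rsid, z1, z2, ld_score
    n1: float
    n2: float
    M: int

    def __post_init__(self) -> None:
        need = {"rsid", "z1", "z2", "ld_score"}
        if not need <= set(self.table.columns):
            raise ValueError(f"LDSCInput table needs columns {sorted(need)}")
        if (self.table["ld_score"] < 1).any():
            raise ValueError("LD scores must be >= 1 (a SNP tags itself)")
        if not np.isfinite(self.table[["z1", "z2"]].to_numpy()).all():
            raise ValueError("non-finite z-scores")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LDSCResult:
    rho_g: float
    rho_g_se: float
    intercept: float
    n_blocks: int
    M: int

    @property
    def zvalue(self) -> float:
        return self.rho_g / self.rho_g_se

    def summary(self) -> str:
        return (f"cross-trait LDSC: genetic covariance rho_g = {self.rho_g:.4g} "
                f"(se {self.rho_g_se:.4g}, {self.n_blocks}-block jackknife), "
                f"intercept = {self.intercept:.4g}")


def ldsc_filter(stats1: SummaryStats, stats2: SummaryStats,
                keep_list: set[str], ld_scores: dict[str, float] | pd.Series,
                maf_min: float = 0.01, min_snps: int = 200,
                M: int | None = None) -> LDSCInput:
    """Intersect, filter and align two traits' summary statistics for LDSC.

    SNPs are kept when present in both traits, in ``keep_list`` (e.g. a
    HapMap3-style list) and in ``ld_scores``; strand-ambiguous (palindromic)
    SNPs and SNPs with MAF < ``maf_min`` (or missing frequency) are removed.
    Trait-2 effects are sign-aligned onto trait 1's effect alleles before
    forming z = beta/se.
    """
    if isinstance(ld_scores, pd.Series):
        ld_scores = ld_scores.to_dict()
    t1 = stats1.table
    pal = np.array([is_palindromic(a, b) for a, b in
                    zip(t1["effect_allele"], t1["other_allele"])])
    maf = np.minimum(t1["eaf"].to_numpy(float), 1 - t1["eaf"].to_numpy(float))
    ok = (~pal & t1["rsid"].isin(keep_list).to_numpy()
          & t1["rsid"].isin(ld_scores).to_numpy()
          & (np.nan_to_num(maf) >= maf_min) & ~np.isnan(maf))
    kept = t1[ok]

    from .sumstats import harmonize

    harm = harmonize(stats1, stats2, snps=list(kept["rsid"]),
                     palindrome_maf_max=0.0)  # palindromes already removed
    h = harm.table
    if len(h) < min_snps:
        raise TooFewSNPsError(f"only {len(h)} SNPs survive LDSC filtering "
                              f"(need >= {min_snps})")
    n1 = float(np.nanmedian(t1["n"])) if t1["n"].notna().any() else float("nan")
    n2_col = stats2.table["n"]
    n2 = float(np.nanmedian(n2_col)) if n2_col.notna().any() else float("nan")
    table = pd.DataFrame({
        "rsid": h["rsid"],
        "z1": h["beta_x"] / h["se_x"],
        "z2": h["beta_y"] / h["se_y"],
        "ld_score": [ld_scores[r] for r in h["rsid"]],
    })
    return LDSCInput(table=table.reset_index(drop=True), n1=n1, n2=n2,
                     M=M if M is not None else len(table))


class LDScoreRegression:
    """Weighted regression of z1·z2 on LD score, with block jackknife."""

    def __init__(self, input: LDSCInput):
        self.input = input

    def fit(self, n_blocks: int = 200, seed: int = 0) -> LDSCResult:
        """Estimate the genetic covariance.

        ``seed`` is accepted for interface uniformity; the estimator itself
        is deterministic.
        """
        inp = self.input
        m = len(inp)
        if m < n_blocks:
            raise TooFewSNPsError(f"{m} SNPs < {n_blocks} jackknife blocks")
        ld = inp.table["ld_score"].to_numpy(float)
        if np.ptp(ld) == 0:
            raise ValueError("constant LD score: slope is unidentified")
        y = (inp.table["z1"] * inp.table["z2"]).to_numpy(float)
        w = 1.0 / (1.0 + ld) ** 2
        X = np.column_stack([ld, np.ones(m)])

        def solve(xtwx, xtwy):
            return np.linalg.solve(xtwx, xtwy)

        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        xtwy = Xw.T @ y
        slope, intercept = solve(xtwx, xtwy)
        scale = inp.M / np.sqrt(inp.n1 * inp.n2)
        rho_g = float(slope * scale)

        # delete-one block jackknife on contiguous blocks
        bounds = np.linspace(0, m, n_blocks + 1).astype(int)
        pseudo = np.empty(n_blocks)
        for b in range(n_blocks):
            lo, hi = bounds[b], bounds[b + 1]
            xb = X[lo:hi]
            wb = w[lo:hi]
            xtwx_b = xtwx - xb.T @ (xb * wb[:, None])
            xtwy_b = xtwy - (xb * wb[:, None]).T @ y[lo:hi]
            pseudo[b] = solve(xtwx_b, xtwy_b)[0] * scale
        jk_mean = pseudo.mean()
        se = float(np.sqrt((n_blocks - 1) / n_blocks
                           * ((pseudo - jk_mean) ** 2).sum()))
        return LDSCResult(rho_g=rho_g, rho_g_se=se, intercept=float(intercept),
                          n_blocks=n_blocks, M=inp.M)


def ldsc_rg(input: LDSCInput, n_blocks: int = 200, seed: int = 0) -> LDSCResult:
    return LDScoreRegression(input).fit(n_blocks=n_blocks, seed=seed)
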