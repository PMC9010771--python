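"""Synthetic-data generators with known ground truth.

Every pipeline stage in this package can be exercised offline: these
generators produce GWAS summary statistics, LD reference panels, screen
fixtures, mediation scenarios, LD-score-regression inputs and rare-variant
case-control cohorts whose generating parameters (the "truth") are recorded
alongside the data, so recovery and calibration can be tested exactly.

Summary statistics are simulated directly at the summary level: the per-SNP
exposure association is its true instrument effect γ_j plus sampling noise
with the standard GWAS standard error se = 1/sqrt(2·maf·(1−maf)·N), and the
outcome association is θ·γ_j plus a per-SNP pleiotropic effect α_j plus its
own noise.  The reference panel supplies genotypes (and hence LD) only where
the method needs them — clumping, proxy search and burden testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ldref import ReferencePanel
from .sumstats import CANONICAL_COLUMNS, SummaryStats

_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SyntheticTruth:
    """Generating parameters of one exposure→outcome MR scenario."""

    theta_true: float
    gamma_j: np.ndarray
    alpha_j: np.ndarray
    pleiotropy_mode: str  # none | balanced | directional
    n_exp: int
    n_out: int
    maf_j: np.ndarray
    ld_block_rho: float
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("gamma_j", "alpha_j", "maf_j"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class ScreenFixture:
    """A multi-metabolite screen: many exposures, one outcome, one panel."""

    exposures: list[SummaryStats]
    outcome: SummaryStats
    panel: ReferencePanel
    causal_ids: list[str]
    truths: dict[str, SyntheticTruth] = field(default_factory=dict)


def gwas_se(maf, n) -> np.ndarray:
    """Standard error of a per-allele GWAS effect for a standardized trait."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def make_panel(n_samples: int = 500, n_snps: int = 100, block_size: int = 10,
               ld_block_rho: float = 0.8, palindromic_frac: float = 0.2,
               seed: int = 0) -> ReferencePanel:
    """Reference panel with blockwise AR(1) LD and Hardy–Weinberg dosages.

    Two latent Gaussian haplotype matrices share an AR(1) correlation
    structure within consecutive blocks of ``block_size`` SNPs; thresholding
    each at the normal quantile of the target allele frequency yields alleles
    whose dosage sum is in Hardy–Weinberg proportions.  ``palindromic_frac``
    of variants receive strand-ambiguous (A/T or C/G) allele pairs.
    """
    if not 0 <= ld_block_rho < 1:
        raise ValueError("ld_block_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, size=n_snps)
    thresholds = stats.norm.ppf(maf)

    alleles = np.empty((n_snps, 2), dtype=object)
    is_pal = rng.random(n_snps) < palindromic_frac
    for i in range(n_snps):
        pool = _PAL_PAIRS if is_pal[i] else _NONPAL_PAIRS
        alleles[i] = pool[rng.integers(len(pool))]

    def haplotypes() -> np.ndarray:
        latent = np.empty((n_samples, n_snps))
        for start in range(0, n_snps, block_size):
            stop = min(start + block_size, n_snps)
            block = rng.standard_normal((n_samples, stop - start))
            for j in range(1, stop - start):
                block[:, j] = (ld_block_rho * block[:, j - 1]
                               + np.sqrt(1 - ld_block_rho**2) * block[:, j])
            latent[:, start:stop] = block
        return (latent < thresholds[None, :]).astype(np.int8)

    dosages = (haplotypes() + haplotypes()).T.astype(np.int8)  # variants x samples
    # blocks sit at distant loci (20 Mb apart, 5 kb spacing within a block),
    # mirroring real instruments: cross-locus pairs fall outside any
    # plausible clump window and are never compared
    idx = np.arange(n_snps)
    block_idx = idx // block_size
    within = idx % block_size
    variants = pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(n_snps)],
        "chrom": "1",
        "pos": block_idx * 20_000_000 + within * 5000 + 1,
        "allele_a": alleles[:, 0],
        "allele_b": alleles[:, 1],
    })
    return ReferencePanel(variants=variants, dosages=dosages)


def make_truth(n_snps: int = 10, theta: float = 0.0, pleiotropy: str = "none",
               n_exp: int = 20000, n_out: int = 30000,
               instrument_f_range: tuple[float, float] = (30.0, 100.0),
               pleiotropy_mean: float = 0.01, pleiotropy_sd: float = 0.005,
               n_invalid: int | None = None, maf: np.ndarray | None = None,
               ld_block_rho: float = 0.0, seed: int = 0) -> SyntheticTruth:
    """Draw a :class:`SyntheticTruth` for one exposure→outcome pair.

    Instrument effects γ_j are sized so the per-SNP F-statistic falls in
    ``instrument_f_range`` (strong instruments by default).  Pleiotropy α_j:
    ``none`` is identically zero; ``balanced`` is mean-zero by construction;
    ``directional`` has mean ``pleiotropy_mean``.  ``n_invalid`` restricts
    pleiotropy to the first that many SNPs (the rest stay valid).
    """
    rng = np.random.default_rng(seed)
    if maf is None:
        maf = rng.uniform(0.1, 0.5, size=n_snps)
    maf = np.asarray(maf, dtype=float)
    se_x = gwas_se(maf, n_exp)
    f = rng.uniform(*instrument_f_range, size=n_snps)
    gamma = np.sqrt(f) * se_x * rng.choice([-1.0, 1.0], size=n_snps)

    alpha = np.zeros(n_snps)
    affected = np.arange(n_snps if n_invalid is None else min(n_invalid, n_snps))
    if pleiotropy == "balanced" and len(affected):
        a = rng.normal(0.0, pleiotropy_sd, size=len(affected))
        alpha[affected] = a - a.mean()
    elif pleiotropy == "directional" and len(affected):
        alpha[affected] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=len(affected))
    elif pleiotropy not in ("none", "balanced", "directional"):
        raise ValueError(f"unknown pleiotropy mode {pleiotropy!r}")

    return SyntheticTruth(theta_true=float(theta), gamma_j=gamma, alpha_j=alpha,
                          pleiotropy_mode=pleiotropy, n_exp=n_exp, n_out=n_out,
                          maf_j=maf, ld_block_rho=ld_block_rho, seed=seed)


def _variant_frame(n: int, rng: np.random.Generator, panel: ReferencePanel | None,
                   offset: int = 0) -> pd.DataFrame:
    if panel is not None:
        if offset + n > panel.n_variants:
            raise ValueError("panel has too few variants for the requested truth")
        sub = panel.variants.iloc[offset:offset + n]
        return pd.DataFrame({
            "rsid": sub["rsid"].to_numpy(), "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "effect_allele": sub["allele_a"].to_numpy(),
            "other_allele": sub["allele_b"].to_numpy(),
        })
    pairs = [_NONPAL_PAIRS[rng.integers(len(_NONPAL_PAIRS))] for _ in range(n)]
    return pd.DataFrame({
        "rsid": [f"rs{offset + i + 1}" for i in range(n)],
        "chrom": "1", "pos": (np.arange(n) + offset + 1) * 5000,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
    })


def _assemble(trait_id: str, variants: pd.DataFrame, eaf, beta, se, n) -> SummaryStats:
    z = np.asarray(beta) / np.asarray(se)
    table = variants.copy()
    table["eaf"] = eaf
    table["beta"] = beta
    table["se"] = se
    table["p"] = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
    table["n"] = n
    return SummaryStats(trait_id=trait_id, table=table[CANONICAL_COLUMNS])


def make_mr_pair(truth: SyntheticTruth, panel: ReferencePanel | None = None,
                 exposure_id: str = "exposure", outcome_id: str = "outcome",
                 panel_offset: int = 0) -> tuple[SummaryStats, SummaryStats]:
    """Simulate a harmonizable exposure/outcome summary-statistics pair.

    β_Xj = γ_j + ε, ε ~ N(0, se_Xj);  β_Yj = θ·γ_j + sign(γ_j)·α_j + ε′,
    ε′ ~ N(0, se_Yj); with se from the MAF/sample-size formula and two-sided
    normal p-values.  Pleiotropic effects α_j are defined relative to the
    exposure-increasing allele (the orientation under which "directional"
    pleiotropy is meaningful and which MR-Egger adopts), hence the sign(γ_j)
    factor when emitting raw-allele-oriented summary statistics.  Effect
    alleles follow the panel's counted allele when a panel is given.
    """
    rng = np.random.default_rng(truth.seed)
    L = len(truth.gamma_j)
    variants = _variant_frame(L, rng, panel, offset=panel_offset)
    se_x = gwas_se(truth.maf_j, truth.n_exp)
    se_y = gwas_se(truth.maf_j, truth.n_out)
    beta_x = truth.gamma_j + rng.normal(0.0, se_x)
    orient = np.where(truth.gamma_j < 0, -1.0, 1.0)
    beta_y = (truth.theta_true * truth.gamma_j + orient * truth.alpha_j
              + rng.normal(0.0, se_y))
    if panel is not None:
        eaf = panel.dosages[panel_offset:panel_offset + L].mean(axis=1) / 2.0
    else:
        eaf = truth.maf_j
    exposure = _assemble(exposure_id, variants, eaf, beta_x, se_x, truth.n_exp)
    outcome = _assemble(outcome_id, variants, eaf, beta_y, se_y, truth.n_out)
    return exposure, outcome


def make_screen_fixture(n_metabolites: int = 200, n_causal: int = 0,
                        theta_causal: float = 0.05,
                        instrument_range: tuple[int, int] = (4, 20),
                        causal_instrument_range: tuple[int, int] = (10, 14),
                        instrument_f_range: tuple[float, float] = (200.0, 2000.0),
                        causal_instrument_f_range: tuple[float, float] = (1000.0, 3000.0),
                        n_exp: int = 20000, n_out: int = 30000,
                        panel_samples: int = 400, palindromic_frac: float = 0.0,
                        seed: int = 0) -> ScreenFixture:
    """A multi-metabolite screen fixture with a mostly-null truth.

    The first ``n_causal`` metabolites get ``theta_causal``; the rest are
    null.  Each metabolite receives its own disjoint set of independent
    instrument SNPs, with counts drawn uniformly from ``instrument_range`` so
    the instrument-count filter has work to do; causal metabolites draw from
    ``causal_instrument_range`` — the upper half of the count-filter window,
    where a ~0.05 log-odds/SD effect retains high power at metabolome-wide
    significance (at L=6 the same effect is undetectable under small-sample
    t calibration, so planting it there would test nothing); their per-SNP
    strength draws from ``causal_instrument_f_range`` (upper cis-loci range,
    sized so the planted effect carries ~99% power at the Bonferroni
    threshold: E[t] = theta/se ~ 9 vs the t threshold ~ 5.4).  Per-SNP
    instrument strength
    ``instrument_f_range`` defaults to F between 200 and 2000 — metabolite
    levels are driven by strong cis-acting loci, which is what makes an
    effect of ~0.05 log-odds per SD detectable at metabolome-wide
    significance.  The shared outcome covers every instrument SNP.
    """
    if n_causal > n_metabolites:
        raise ValueError("n_causal cannot exceed n_metabolites")
    rng = np.random.default_rng(seed)
    counts = rng.integers(instrument_range[0], instrument_range[1] + 1,
                          size=n_metabolites)
    counts[:n_causal] = rng.integers(causal_instrument_range[0],
                                     causal_instrument_range[1] + 1,
                                     size=n_causal)
    total = int(counts.sum())
    panel = make_panel(n_samples=panel_samples, n_snps=total, block_size=1,
                       ld_block_rho=0.0, palindromic_frac=palindromic_frac,
                       seed=int(rng.integers(2**31 - 1)))
    exposures: list[SummaryStats] = []
    truths: dict[str, SyntheticTruth] = {}
    outcome_parts: list[pd.DataFrame] = []
    offset = 0
    for m in range(n_metabolites):
        mid = f"met{m:03d}"
        theta = theta_causal if m < n_causal else 0.0
        maf = panel.maf[offset:offset + counts[m]].clip(0.05, 0.5)
        f_range = causal_instrument_f_range if m < n_causal else instrument_f_range
        truth = make_truth(n_snps=int(counts[m]), theta=theta, pleiotropy="none",
                           n_exp=n_exp, n_out=n_out, maf=maf,
                           instrument_f_range=f_range,
                           seed=int(rng.integers(2**31 - 1)))
        exp, out = make_mr_pair(truth, panel=panel, exposure_id=mid,
                                outcome_id="outcome", panel_offset=offset)
        exposures.append(exp)
        truths[mid] = truth
        outcome_parts.append(out.table)
        offset += counts[m]
    outcome = SummaryStats("outcome", pd.concat(outcome_parts, ignore_index=True))
    causal_ids = [f"met{m:03d}" for m in range(n_causal)]
    return ScreenFixture(exposures=exposures, outcome=outcome, panel=panel,
                         causal_ids=causal_ids, truths=truths)


@dataclass
class MediationTruth:
    """Truth for an exposure whose outcome effect runs through a mediator."""

    theta_direct: float       # direct effect of exposure A on the outcome
    theta_via_mediator: float  # indirect effect of A through mediator B
    mediation_coef: float     # effect of A on B (q); theta_B = via/q
    theta_mediator: float     # direct effect of B on the outcome
    seed: int


def make_mediation_fixture(theta_direct: float = 0.0,
                           theta_via_mediator: float = 0.05,
                           n: int = 50000, n_instruments: tuple[int, int] = (15, 15),
                           mediation_coef: float = -0.5,
                           instrument_f_range: tuple[float, float] = (300.0, 3000.0),
                           seed: int = 0):
    """Two-exposure mediation scenario for multivariable MR.

    Exposure A affects mediator B with coefficient q (``mediation_coef``,
    negative = depletion, emulating an amino acid consuming a vitamin); B
    affects the outcome with θ_B = ``theta_via_mediator``/q, so A's total
    univariable effect is ``theta_direct + theta_via_mediator`` while its
    direct (MVMR) effect is ``theta_direct``.  A and B have disjoint
    instrument sets; every SNP is reported in all three traits.

    Returns ``(exposure_a, exposure_b, outcome, panel, MediationTruth)``.
    """
    rng = np.random.default_rng(seed)
    La, Lb = n_instruments
    q = mediation_coef
    theta_b = theta_via_mediator / q
    total = La + Lb
    panel = make_panel(n_samples=400, n_snps=total, block_size=1,
                       ld_block_rho=0.0, palindromic_frac=0.0,
                       seed=int(rng.integers(2**31 - 1)))
    maf = panel.maf.clip(0.05, 0.5)
    se = gwas_se(maf, n)
    # strong cis-acting instruments: per-SNP ratio noise scales as 1/sqrt(F)
    f = rng.uniform(*instrument_f_range, size=total)
    gamma = np.sqrt(f) * se * rng.choice([-1.0, 1.0], size=total)
    a_idx, b_idx = np.arange(La), np.arange(La, total)

    beta_on_a = np.zeros(total)
    beta_on_a[a_idx] = gamma[a_idx]
    beta_on_b = np.zeros(total)
    beta_on_b[a_idx] = q * gamma[a_idx]
    beta_on_b[b_idx] = gamma[b_idx]
    beta_on_y = theta_direct * beta_on_a + theta_b * beta_on_b

    variants = _variant_frame(total, rng, panel)
    eaf = panel.dosages.mean(axis=1) / 2.0
    n_y = 2 * n

    def noisy(mu, s):
        return mu + rng.normal(0.0, s)

    se_y = gwas_se(maf, n_y)
    exp_a = _assemble("exposure_a", variants, eaf, noisy(beta_on_a, se), se, n)
    exp_b = _assemble("exposure_b", variants, eaf, noisy(beta_on_b, se), se, n)
    outcome = _assemble("outcome", variants, eaf, noisy(beta_on_y, se_y), se_y, n_y)
    truth = MediationTruth(theta_direct=theta_direct,
                           theta_via_mediator=theta_via_mediator,
                           mediation_coef=q, theta_mediator=theta_b, seed=seed)
    return exp_a, exp_b, outcome, panel, truth


def make_ldsc_fixture(rho_g: float = 0.0, M: int = 4000, n1: int = 50000,
                      n2: int = 50000, h2_1: float = 0.4, h2_2: float = 0.4,
                      ld_score_range: tuple[float, float] = (1.0, 150.0),
                      seed: int = 0):
    """Paired z-scores with a specified cross-trait genetic covariance.

    Per SNP j with LD score ℓ_j, the genetic components of (z1, z2) are
    bivariate normal with covariance matrix (ℓ_j/M)·[[h²₁·n1, ρ_g·√(n1·n2)],
    [·, h²₂·n2]], plus independent unit-variance sampling noise — giving
    E[z1·z2] = ρ_g·√(n1·n2)·ℓ_j/M, the single-trait-free regression model.

    Returns ``(LDSCInput, truth_dict)``.
    """
    if abs(rho_g) > np.sqrt(h2_1 * h2_2):
        raise ValueError("|rho_g| cannot exceed sqrt(h2_1 * h2_2)")
    from .ldsc import LDSCInput

    rng = np.random.default_rng(seed)
    ld = rng.uniform(*ld_score_range, size=M)
    scale = ld / M
    v1 = h2_1 * n1 * scale
    v2 = h2_2 * n2 * scale
    c12 = rho_g * np.sqrt(n1 * n2) * scale
    g1 = rng.standard_normal(M) * np.sqrt(v1)
    # conditional draw keeps the exact covariance structure per SNP
    cond_mean = np.divide(c12, v1, out=np.zeros(M), where=v1 > 0) * g1
    cond_var = v2 - np.divide(c12**2, v1, out=np.zeros(M), where=v1 > 0)
    g2 = cond_mean + rng.standard_normal(M) * np.sqrt(np.maximum(cond_var, 0.0))
    z1 = g1 + rng.standard_normal(M)
    z2 = g2 + rng.standard_normal(M)
    table = pd.DataFrame({"rsid": [f"rs{i + 1}" for i in range(M)],
                          "z1": z1, "z2": z2, "ld_score": ld})
    truth = {"rho_g": rho_g, "M": M, "n1": n1, "n2": n2,
             "h2_1": h2_1, "h2_2": h2_2, "seed": seed}
    return LDSCInput(table=table, n1=n1, n2=n2, M=M), truth


def make_cohort(n_cases: int = 500, n_controls: int = 500,
                gene_spec: dict | None = None, covariate_spec: dict | None = None,
                seed: int = 0):
    """Rare-variant case-control cohort for burden testing.

    ``gene_spec`` keys: ``n_variants`` (default 20), ``maf_range``
    (default (5e-4, 5e-3)), ``carrier_log_or`` (default 0.0), and
    ``disruptive_frac`` (default 0.5 — remaining variants are missense).
    Case status is drawn from a logistic model whose intercept targets the
    requested case fraction, with ``carrier_log_or`` on the collapsed carrier
    indicator plus modest sex/platform effects.  Extreme ``carrier_log_or``
    values produce separation scenarios on purpose.

    Returns ``(CohortGenotypes, truth_dict)``.
    """
    from .burden import CohortGenotypes

    gene_spec = dict(gene_spec or {})
    n_variants = int(gene_spec.get("n_variants", 20))
    maf_lo, maf_hi = gene_spec.get("maf_range", (5e-4, 5e-3))
    log_or = float(gene_spec.get("carrier_log_or", 0.0))
    disruptive_frac = float(gene_spec.get("disruptive_frac", 0.5))

    cov_spec = {"sex_log_or": 0.3, "platform_log_or": 0.1, "n_pcs": 10,
                "pc_sd": 1.0, **(covariate_spec or {})}
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls

    maf = rng.uniform(maf_lo, maf_hi, size=n_variants)
    genotypes = rng.binomial(2, maf[:, None], size=(n_variants, n)).astype(np.int8)
    n_disruptive = int(round(disruptive_frac * n_variants))
    classes = np.array(
        ["frameshift"] * n_disruptive + ["missense"] * (n_variants - n_disruptive),
        dtype=object)
    rng.shuffle(classes)
    variants = pd.DataFrame({
        "rsid": [f"gv{i + 1}" for i in range(n_variants)],
        "chrom": "17", "pos": np.arange(1, n_variants + 1) * 100 + 40_000_000,
        "consequence_class": classes,
        "external_maf": maf,
    })

    sex = rng.integers(0, 2, size=n)
    platform = rng.integers(0, 2, size=n)
    pcs = rng.normal(0.0, cov_spec["pc_sd"] * 0.01, size=(n, cov_spec["n_pcs"]))
    covariates = pd.DataFrame({"sex": sex, "platform": platform})
    for k in range(cov_spec["n_pcs"]):
        covariates[f"PC{k + 1}"] = pcs[:, k]

    carrier = (genotypes.sum(axis=0) > 0).astype(float)
    base = np.log(n_cases / n_controls)
    eta = (base + log_or * carrier + cov_spec["sex_log_or"] * (sex - sex.mean())
           + cov_spec["platform_log_or"] * (platform - platform.mean()))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    if y.sum() == 0:
        y[rng.integers(n)] = 1
    if y.sum() == n:
        y[rng.integers(n)] = 0

    cohort = CohortGenotypes(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        y=y, covariates=covariates, variants=variants, genotypes=genotypes)
    truth = {"carrier_log_or": log_or, "n_variants": n_variants,
             "n_carriers": int(carrier.sum()), "maf": maf.tolist(), "seed": seed}
    return cohort, truth
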