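"""The metabolome-wide MR screen.

For each exposure (metabolite): instruments are selected below a liberal
p-value threshold (default 5e-6), clumped for independence (r² ≤ 0.001),
proxied into the outcome where absent (r² ≥ 0.9), harmonized, and fed to the
IVW multiplicative-random-effects estimator plus the sensitivity battery.
The screen-level inflation factor λ is computed before and after an
instrument-count filter (keep 6–14 SNPs by default — too few SNPs give
single variants undue weight, too many invite heterogeneous outliers), and
Bonferroni correction is applied over the analyses that pass the filter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .estimators import MRModel, MRResults
from .ldref import ReferencePanel, clump, find_proxy
from .sensitivity import SensitivityReport, inflation_lambda, sensitivity_battery
from .sumstats import InstrumentSet, SummaryStats, harmonize


@dataclass
class ScreenConfig:
    """Tunable parameters of the screen (defaults follow the study design)."""

    instrument_p_max: float = 5e-06
    clump_r2_max: float = 0.001
    clump_window_kb: float = 10000.0
    proxy_r2_min: float = 0.9
    palindrome_maf_max: float = 0.42
    min_snps: int = 6
    max_snps: int = 14
    alpha: float = 0.05
    q_filter_p: float = 0.05
    presso_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        for name in ("instrument_p_max", "clump_r2_max", "proxy_r2_min",
                     "palindrome_maf_max", "alpha", "q_filter_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ScreenResult:
    """Output of :func:`run_screen`.

    ``rows`` has one line per testable metabolite with the IVW estimate,
    instrument count, filter verdict and Cochran-Q p-value; ``sensitivity``
    maps exposure id → :class:`SensitivityReport`.
    """

    rows: pd.DataFrame
    sensitivity: dict[str, SensitivityReport]
    lambda_before: float
    lambda_after: float
    bonferroni_alpha: float
    bonferroni_alpha_all: float
    hits: list[str]
    config: ScreenConfig
    skipped: list[dict] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return len(self.rows)

    @property
    def n_passing(self) -> int:
        return int(self.rows["passed_filter"].sum())

    def summary(self) -> str:
        return "\n".join([
            f"MR screen: {self.n_tested} metabolites tested, "
            f"{self.n_passing} pass the {self.config.min_snps}-"
            f"{self.config.max_snps} SNP count filter",
            f"  lambda before filter: {self.lambda_before:.3f}",
            f"  lambda after filter:  {self.lambda_after:.3f}",
            f"  Bonferroni alpha (filtered tests): {self.bonferroni_alpha:.3g}",
            f"  hits: {', '.join(self.hits) if self.hits else '(none)'}",
        ])


def per_metabolite_seed(global_seed: int, exposure_id: str) -> int:
    """Stable per-metabolite seed so row results are order-independent."""
    return (int(global_seed) ^ zlib.crc32(exposure_id.encode())) % (2**31 - 1)


def select_instruments(exposure: SummaryStats, outcome: SummaryStats,
                       panel: ReferencePanel, cfg: ScreenConfig | None = None,
                       ) -> InstrumentSet:
    """Instrument-selection pipeline for one exposure.

    Threshold → clump → proxy lookup for SNPs missing from the outcome →
    harmonize.  Proxied instruments keep the exposure association of the
    target SNP; the outcome association is read from the proxy and
    sign-aligned through the dosage-correlation orientation.  All drops and
    substitutions are recorded in the provenance.
    """
    cfg = cfg or ScreenConfig()
    cand = exposure.table[exposure.table["p"] < cfg.instrument_p_max]
    prov: list[dict] = []
    if cand.empty:
        empty = harmonize(exposure, outcome, snps=[])
        empty.provenance.append({"action": "skip", "rsid": None,
                                 "reason": "no_snp_below_threshold"})
        return empty

    clumped = clump(panel, cand[["rsid", "p"]].to_dict("records"),
                    r2_max=cfg.clump_r2_max, window_kb=cfg.clump_window_kb)
    for rem in clumped.removed:
        prov.append({"action": "drop", "rsid": rem["rsid"],
                     "reason": f"clump:{rem['reason']}",
                     "reason_index": rem.get("reason_index")})

    outcome_rsids = outcome.rsids
    direct = [r for r in clumped.index_snps if r in outcome_rsids]
    missing = [r for r in clumped.index_snps if r not in outcome_rsids]

    inst = harmonize(exposure, outcome, snps=direct,
                     palindrome_maf_max=cfg.palindrome_maf_max)
    inst.provenance = prov + inst.provenance

    proxy_rows = []
    for rsid in missing:
        if rsid not in panel:
            inst.log("drop", rsid, reason="missing_from_outcome_and_panel")
            continue
        hit = find_proxy(panel, rsid, outcome_rsids, r2_min=cfg.proxy_r2_min)
        if hit is None:
            inst.log("drop", rsid, reason="no_proxy_above_threshold")
            continue
        exp_row = exposure.lookup(rsid)
        out_row = outcome.lookup(hit.proxy.rsid)
        # align the exposure beta to the panel's counted allele of the target
        tkey = panel.variant_key(rsid)
        if exp_row.effect_allele == tkey.allele_a:
            sign_exp = 1
        elif exp_row.effect_allele == tkey.allele_b:
            sign_exp = -1
        else:
            inst.log("drop", rsid, reason="proxy_target_allele_mismatch")
            continue
        if out_row.effect_allele == hit.proxy.allele_a:
            sign_out = 1
        elif out_row.effect_allele == hit.proxy.allele_b:
            sign_out = -1
        else:
            inst.log("drop", rsid, reason="proxy_allele_mismatch")
            continue
        # chain: exposure allele -> panel target allele -> panel proxy allele
        # -> outcome effect allele
        beta_y = out_row.beta * sign_out * hit.orientation * sign_exp
        proxy_rows.append({
            "rsid": rsid, "chrom": str(exp_row.chrom), "pos": int(exp_row.pos),
            "effect_allele": exp_row.effect_allele,
            "other_allele": exp_row.other_allele,
            "beta_x": float(exp_row.beta), "se_x": float(exp_row.se),
            "beta_y": float(beta_y), "se_y": float(out_row.se),
            "eaf": float(exp_row.eaf) if pd.notna(exp_row.eaf) else np.nan,
            "proxy_of": hit.proxy.rsid,
        })
        inst.log("proxy", rsid, proxy=hit.proxy.rsid, r2=hit.r2,
                 orientation=hit.orientation)
    if proxy_rows:
        inst.table = pd.concat([inst.table, pd.DataFrame(proxy_rows)],
                               ignore_index=True)
    return inst


def run_screen(exposures: list[SummaryStats], outcome: SummaryStats,
               panel: ReferencePanel, cfg: ScreenConfig | None = None,
               ) -> ScreenResult:
    """Run the full screen over a list of metabolite exposures.

    λ_before is the inflation factor over the IVW p-values of every testable
    metabolite; λ_after and the Bonferroni threshold use only analyses whose
    instrument count lies within [min_snps, max_snps].  Metabolites yielding
    fewer than two instruments are skipped (logged) and excluded from both
    λ computations.
    """
    cfg = cfg or ScreenConfig()
    if len(exposures) < 2:
        raise ValueError("a screen needs at least 2 exposures")

    rows = []
    reports: dict[str, SensitivityReport] = {}
    skipped: list[dict] = []
    for exposure in exposures:
        mid = exposure.trait_id
        inst = select_instruments(exposure, outcome, panel, cfg)
        if len(inst) < 2:
            skipped.append({"exposure_id": mid, "L": len(inst),
                            "reason": "fewer_than_two_instruments"})
            continue
        res = MRModel(inst).fit("ivw_mre")
        seed_m = per_metabolite_seed(cfg.seed, mid)
        report = sensitivity_battery(inst, presso_sims=cfg.presso_sims,
                                     seed=seed_m, alpha=cfg.alpha)
        reports[mid] = report
        rows.append({
            "exposure_id": mid, "L": len(inst), "theta": res.theta,
            "se": res.se, "p": res.pvalue,
            "passed_filter": cfg.min_snps <= len(inst) <= cfg.max_snps,
            "Q_p": report.Q_p,
        })

    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no metabolite produced a testable instrument set")
    lambda_before = inflation_lambda(table["p"])
    passing = table[table["passed_filter"]]
    lambda_after = inflation_lambda(passing["p"]) if len(passing) else float("nan")
    n_pass = len(passing)
    bonf = cfg.alpha / n_pass if n_pass else float("nan")
    bonf_all = cfg.alpha / len(table)
    hits = sorted(passing.loc[passing["p"] < bonf, "exposure_id"]) if n_pass else []
    return ScreenResult(rows=table, sensitivity=reports,
                        lambda_before=lambda_before, lambda_after=lambda_after,
                        bonferroni_alpha=bonf, bonferroni_alpha_all=bonf_all,
                        hits=hits, config=cfg, skipped=skipped)


def tune_count_filter(rows: pd.DataFrame,
                      candidate_bounds: list[tuple[int, int]],
                      min_rows: int = 10) -> tuple[int, int]:
    """Choose the instrument-count bounds whose filtered λ is closest to 1.

    Ties go to the widest interval.  Candidates leaving fewer than
    ``min_rows`` analyses are ignored; if none remain, an error is raised.
    """
    if not candidate_bounds:
        raise ValueError("need at least one candidate bound")
    best = None
    for lo, hi in candidate_bounds:
        sub = rows[(rows["L"] >= lo) & (rows["L"] <= hi)]
        if len(sub) < min_rows:
            continue
        lam = inflation_lambda(sub["p"])
        key = (abs(lam - 1.0), -(hi - lo), lo, hi)
        if best is None or key < best[0]:
            best = (key, (lo, hi))
    if best is None:
        raise ValueError(f"every candidate bound leaves fewer than {min_rows} analyses")
    return best[1]


def alternative_q_filter(rows: pd.DataFrame, min_snps: int = 6,
                         q_p: float = 0.05) -> pd.DataFrame:
    """Heterogeneity-based alternative filter: keep L ≥ min_snps and Q_p > q_p."""
    if "Q_p" not in rows.columns:
        raise ValueError("rows must carry a Q_p column (sensitivity battery output)")
    return rows[(rows["L"] >= min_snps) & (rows["Q_p"] > q_p)]


def phewas_crosscheck(hit: str, inst: InstrumentSet,
                      all_exposures: list[SummaryStats],
                      p_max: float = 5e-06) -> dict:
    """Within-screen PheWAS: flag instruments associated with other metabolites.

    Each instrumental SNP of ``hit`` is looked up in every other screened
    metabolite at the instrument-selection threshold; flagged SNPs are
    removed and the IVW estimate recomputed (when ≥ 2 instruments remain).
    """
    flagged = []
    inst_rsids = list(inst.table["rsid"])
    for rsid in inst_rsids:
        others = []
        for stats_ in all_exposures:
            if stats_.trait_id == hit:
                continue
            row = stats_.lookup(rsid)
            if row is not None and row.p < p_max:
                others.append(stats_.trait_id)
        if others:
            flagged.append({"rsid": rsid, "other_traits": others})
    flagged_ids = {f["rsid"] for f in flagged}
    keep = [i for i, r in enumerate(inst_rsids) if r not in flagged_ids]
    rerun: MRResults | None = None
    if len(keep) >= 2:
        sub = inst.subset(keep)
        sub.log("phewas_crosscheck", None, removed=sorted(flagged_ids))
        rerun = MRModel(sub).fit("ivw_mre")
    return {"flagged": flagged, "rerun": rerun,
            "n_removed": len(flagged_ids), "n_remaining": len(keep)}


def replicate(hits: list[str], exposures: list[SummaryStats],
              outcome2: SummaryStats, panel: ReferencePanel,
              cfg: ScreenConfig | None = None) -> dict[str, MRResults | None]:
    """Re-run the per-hit pipeline against a second (replication) outcome."""
    cfg = cfg or ScreenConfig()
    by_id = {e.trait_id: e for e in exposures}
    out: dict[str, MRResults | None] = {}
    for hit in hits:
        if hit not in by_id:
            raise KeyError(f"hit {hit!r} is not among the screened exposures")
        inst = select_instruments(by_id[hit], outcome2, panel, cfg)
        out[hit] = MRModel(inst).fit("ivw_mre") if len(inst) >= 2 else None
    return out
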