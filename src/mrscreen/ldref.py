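"""Reference-panel LD: pairwise r², greedy clumping, and proxy SNP lookup.

The panel is an in-memory dosage matrix (variants × samples, allele counts in
{0,1,2}) from which squared Pearson correlations are computed.  Clumping is
the standard greedy procedure: candidates are ranked by p-value and a SNP is
retained only if it is below the r² ceiling with every already-retained SNP
on the same chromosome within the window.  Proxy lookup returns the highest-r²
partner above a floor together with the sign of the dosage correlation, which
maps the target's effect allele onto the proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .sumstats import VariantKey

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """LD reference panel: variant metadata plus a dosage matrix.

    ``variants``: DataFrame with columns ``rsid chrom pos allele_a allele_b``;
    ``dosages``: int array of shape (n_variants, n_samples) with entries in
    {0, 1, 2} counting copies of ``allele_a``.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.variants) != self.dosages.shape[0]:
            raise ValueError("variant table and dosage matrix are inconsistent")
        self.variants = self.variants.reset_index(drop=True)
        self._index = {r: i for i, r in enumerate(self.variants["rsid"])}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def index_of(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise KeyError(f"variant {rsid!r} not in reference panel") from None

    def dosage(self, rsid: str) -> np.ndarray:
        return self.dosages[self.index_of(rsid)]

    def variant_key(self, rsid: str) -> VariantKey:
        r = self.variants.iloc[self.index_of(rsid)]
        return VariantKey(r.rsid, str(r.chrom), int(r.pos), r.allele_a, r.allele_b)


class ProxyHit(NamedTuple):
    proxy: VariantKey
    r2: float
    orientation: int  # +1: effect alleles aligned; -1: proxy effect allele flipped


@dataclass
class ClumpResult:
    index_snps: list[str]
    removed: list[dict]


def _rsid(v) -> str:
    return v.rsid if isinstance(v, VariantKey) else str(v)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of dosage vectors; 0 for monomorphic input."""
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0:
        warnings.warn("monomorphic variant in r2 computation; returning 0",
                      stacklevel=3)
        return 0.0
    return float((xs @ ys) / denom)


def r_squared(panel: ReferencePanel, a, b) -> float:
    """Squared Pearson correlation between two variants' dosages (symmetric)."""
    ra, rb = _rsid(a), _rsid(b)
    if ra == rb:
        da = panel.dosage(ra)
        return 0.0 if np.ptp(da) == 0 else 1.0
    return _corr(panel.dosage(ra), panel.dosage(rb)) ** 2


def clump(
    panel: ReferencePanel,
    candidates: Sequence[Mapping],
    r2_max: float = 0.001,
    window_kb: float = 10000.0,
) -> ClumpResult:
    """Greedy p-value clumping against the reference panel.

    ``candidates`` are mappings with keys ``rsid`` (or ``key``) and ``p``.
    Sorted ascending by (p, rsid) — the rsid tie-break makes the outcome
    invariant to the input order.  A candidate is retained iff its r² with
    every already-retained SNP on the same chromosome within ``window_kb``
    is ≤ ``r2_max``.  Candidates absent from the panel are dropped and logged.
    """
    items = []
    for c in candidates:
        rsid = _rsid(c.get("key", c.get("rsid")))
        p = float(c["p"])
        if not np.isfinite(p):
            raise ValueError(f"non-finite p-value for candidate {rsid}")
        items.append((p, rsid))
    items.sort()

    index: list[str] = []
    removed: list[dict] = []
    # per kept SNP: rsid, chrom, pos, centered dosage, squared norm
    kept_meta: list[tuple[str, str, int, np.ndarray, float]] = []
    half_window = window_kb * 1000.0
    for p, rsid in items:
        if rsid not in panel:
            removed.append({"rsid": rsid, "reason": "not_in_panel",
                            "reason_index": None, "r2": None})
            logger.debug("clump: %s not in panel, dropped", rsid)
            continue
        vk = panel.variant_key(rsid)
        d = panel.dosage(rsid).astype(float)
        dc = d - d.mean()
        norm = dc @ dc
        blocked_by = None
        blocked_r2 = None
        for k_rsid, k_chrom, k_pos, k_dc, k_norm in kept_meta:
            if k_chrom != vk.chrom or abs(k_pos - vk.pos) > half_window:
                continue
            denom = np.sqrt(norm * k_norm)
            r2 = 0.0 if denom == 0 else float((dc @ k_dc) / denom) ** 2
            if r2 > r2_max:
                blocked_by, blocked_r2 = k_rsid, r2
                break
        if blocked_by is None:
            index.append(rsid)
            kept_meta.append((rsid, vk.chrom, vk.pos, dc, norm))
        else:
            removed.append({"rsid": rsid, "reason": "in_ld_with_index",
                            "reason_index": blocked_by, "r2": blocked_r2})
    return ClumpResult(index_snps=index, removed=removed)


def panel_to_tsv(panel: ReferencePanel, path) -> None:
    """Write a panel as one TSV: variant columns then per-sample dosages."""
    dose = pd.DataFrame(panel.dosages,
                        columns=[f"s{s + 1}" for s in range(panel.n_samples)])
    pd.concat([panel.variants.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False)


def panel_from_tsv(path) -> ReferencePanel:
    """Read a panel written by :func:`panel_to_tsv`."""
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["rsid", "chrom", "pos", "allele_a", "allele_b"]
    missing = [c for c in meta if c not in raw.columns]
    if missing:
        raise ValueError(f"panel file {path} lacks columns {missing}")
    sample_cols = [c for c in raw.columns if c not in meta]
    dosages = raw[sample_cols].to_numpy(dtype=np.int8)
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError("dosages must be allele counts in {0, 1, 2}")
    return ReferencePanel(variants=raw[meta], dosages=dosages)


def panel_from_vcf(path) -> ReferencePanel:
    """Read a biallelic-SNP panel from a VCF with GT fields (needs cyvcf2)."""
    from cyvcf2 import VCF

    rows, dosage_rows = [], []
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        rows.append({"rsid": rec.ID or f"{rec.CHROM}:{rec.POS}",
                     "chrom": str(rec.CHROM), "pos": int(rec.POS),
                     "allele_a": rec.ALT[0], "allele_b": rec.REF})
        gts = rec.genotype.array()[:, :2]
        dosage_rows.append((gts > 0).sum(axis=1))
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    return ReferencePanel(variants=pd.DataFrame(rows),
                          dosages=np.asarray(dosage_rows, dtype=np.int8))


def find_proxy(
    panel: ReferencePanel,
    target,
    available: Iterable,
    r2_min: float = 0.9,
) -> ProxyHit | None:
    """Best LD proxy for ``target`` among ``available`` variants.

    Returns the available panel variant with the highest r² ≥ ``r2_min``
    (ties broken by smaller base-pair distance, then rsid), with the
    orientation (+1/−1) given by the sign of the dosage correlation — a
    negative correlation means the proxy's counted allele tracks the
    *other* allele of the target.  Returns None when nothing qualifies.
    """
    t_rsid = _rsid(target)
    t_idx = panel.index_of(t_rsid)
    t_key = panel.variant_key(t_rsid)
    td = panel.dosages[t_idx].astype(float)
    tdc = td - td.mean()
    t_norm = tdc @ tdc

    best = None  # (-r2, distance, rsid, orientation)
    for cand in available:
        c_rsid = _rsid(cand)
        if c_rsid not in panel:
            continue
        if c_rsid == t_rsid:
            r, dist = 1.0, 0
        else:
            cd = panel.dosage(c_rsid).astype(float)
            cdc = cd - cd.mean()
            denom = np.sqrt(t_norm * (cdc @ cdc))
            r = 0.0 if denom == 0 else float((tdc @ cdc) / denom)
            dist = abs(panel.variant_key(c_rsid).pos - t_key.pos)
        r2 = r * r
        if r2 < r2_min - 1e-12:
            continue
        orientation = 1 if r >= 0 else -1
        entry = (-r2, dist, c_rsid, orientation, r2)
        if best is None or entry[:3] < best[:3]:
            best = entry
    if best is None:
        return None
    _, _, rsid, orientation, r2 = best
    return ProxyHit(proxy=panel.variant_key(rsid), r2=r2, orientation=orientation)
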