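"""Rule-based QTL region calling, merging, co-location and annotation.

Coordinates are 1-based and inclusive on both ends throughout this module.
The calling rules: SNPs above the significance threshold are chained per
chromosome while consecutive gaps stay within ``extend`` (default 200 kb);
each cluster's region is its significant-SNP span padded by ``flank``
(default 50 kb, clamped at position 1).  Same-trait clusters from different
panels merge into one QTL while SNP-span gaps stay within ``merge_gap``
(default 800 kb) and effect signs agree; a sign change inside a chain splits
it at the boundary, which can leave the two flanked regions overlapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from panelqtl.gwas import AssocRecord
from panelqtl.phenostats import TraitMatrix
from panelqtl.simulate import GenotypeMatrix

__all__ = [
    "SigCluster",
    "QtlRegion",
    "ColocPair",
    "GeneAnnotation",
    "call_clusters",
    "apply_stringency",
    "merge_panels",
    "pick_peak",
    "assign_names",
    "coloc",
    "pivot_allele_effects",
    "genes_near",
]


@dataclass
class SigCluster:
    trait: str
    panel: str
    chromosome: str
    members: list[AssocRecord]
    flank: int = 50_000
    single_snp: bool = False
    all_rare: bool = False

    @property
    def snp_span(self) -> tuple[int, int]:
        positions = [r.pos for r in self.members]
        return min(positions), max(positions)

    @property
    def region(self) -> tuple[int, int]:
        lo, hi = self.snp_span
        return max(1, lo - self.flank), hi + self.flank

    @property
    def claimed(self) -> bool:
        return not (self.single_snp or self.all_rare)


@dataclass
class QtlRegion:
    name: str
    trait: str
    chromosome: str
    start: int
    end: int
    members: list[AssocRecord] = field(default_factory=list)
    panels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"QTL {self.name!r}: start must be < end")

    @property
    def size_mb(self) -> float:
        return round((self.end - self.start) / 1e6, 3)

    @property
    def snp_span(self) -> tuple[int, int]:
        positions = [r.pos for r in self.members]
        return min(positions), max(positions)

    @property
    def peak(self) -> AssocRecord:
        return pick_peak(self)

    @property
    def effect_sign(self) -> int:
        eff = self.peak.effect_common
        return (eff > 0) - (eff < 0)


@dataclass
class ColocPair:
    qtl_a: QtlRegion
    qtl_b: QtlRegion
    basis: str  # interspersed | end_gap
    gap: int


@dataclass
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int
    end: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be <= end")


def call_clusters(
    assoc: list[AssocRecord],
    threshold: float = 5.0,
    extend: int = 200_000,
    flank: int = 50_000,
    trait: str | None = None,
    panel: str | None = None,
) -> list[SigCluster]:
    """Greedily chain significant SNPs (strictly above ``threshold``) per
    chromosome into clusters with consecutive gaps <= ``extend``.

    Every significant SNP lands in exactly one cluster; no significant SNPs
    means an empty list.
    """
    sig = [r for r in assoc if r.minus_log10_p > threshold]
    if not sig:
        return []
    trait = trait if trait is not None else sig[0].trait
    panel = panel if panel is not None else sig[0].panel
    clusters: list[SigCluster] = []
    frame = sorted(sig, key=lambda r: (str(r.chrom), r.pos))
    current: list[AssocRecord] = []
    for rec in frame:
        if current and (rec.chrom != current[-1].chrom or rec.pos - current[-1].pos > extend):
            clusters.append(SigCluster(trait, panel, str(current[0].chrom), current, flank))
            current = []
        current.append(rec)
    clusters.append(SigCluster(trait, panel, str(current[0].chrom), current, flank))
    return clusters


def apply_stringency(
    clusters: list[SigCluster],
    min_snps: int = 2,
    min_alt_carriers: int = 6,
) -> list[SigCluster]:
    """Set the ``single_snp`` / ``all_rare`` claim flags in place.

    Flagged clusters are excluded from QTL claims but kept for diagnostics.
    """
    for cl in clusters:
        cl.single_snp = len(cl.members) < min_snps
        cl.all_rare = all(r.n_alt < min_alt_carriers for r in cl.members)
    return clusters


def merge_panels(
    clusters: list[SigCluster],
    merge_gap: int = 800_000,
    flank: int = 50_000,
    claimed_only: bool = True,
) -> list[QtlRegion]:
    """Merge same-trait clusters across panels into QTL regions.

    All member SNPs are pooled per chromosome and sorted by position; a chain
    breaks when the gap to the next SNP exceeds ``merge_gap`` or when the
    effect sign flips (the split lands between the last SNP of one sign and
    the first of the other).  The gap rule is measured between significant-SNP
    positions, not the padded regions.  Each chain becomes an (unnamed) QTL
    whose interval is the chain's SNP span padded by ``flank``.
    """
    pool = [cl for cl in clusters if cl.claimed or not claimed_only]
    if not pool:
        return []
    traits = {cl.trait for cl in pool}
    if len(traits) > 1:
        raise ValueError(f"merge_panels expects one trait, got {sorted(traits)}")
    trait = pool[0].trait

    by_chrom: dict[str, list[tuple[AssocRecord, str]]] = {}
    for cl in pool:
        for rec in cl.members:
            by_chrom.setdefault(cl.chromosome, []).append((rec, cl.panel))

    qtls: list[QtlRegion] = []
    for chrom in sorted(by_chrom, key=str):
        entries = sorted(by_chrom[chrom], key=lambda e: (e[0].pos, e[1], e[0].snp))
        chain: list[tuple[AssocRecord, str]] = []
        for rec, pnl in entries:
            if chain:
                prev = chain[-1][0]
                gap_break = rec.pos - prev.pos > merge_gap
                sign_break = _sign(rec.effect_common) != _sign(prev.effect_common)
                if gap_break or sign_break:
                    qtls.append(_chain_to_qtl(trait, chrom, chain, flank))
                    chain = []
            chain.append((rec, pnl))
        qtls.append(_chain_to_qtl(trait, chrom, chain, flank))
    return qtls


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def _chain_to_qtl(trait, chrom, chain, flank) -> QtlRegion:
    members = [rec for rec, _ in chain]
    panels = sorted({pnl for _, pnl in chain})
    lo = min(r.pos for r in members)
    hi = max(r.pos for r in members)
    return QtlRegion(
        name="", trait=trait, chromosome=str(chrom),
        start=max(1, lo - flank), end=hi + flank,
        members=members, panels=panels,
    )


def pick_peak(qtl: QtlRegion | SigCluster) -> AssocRecord:
    """Member SNP with the maximal -log10(p); ties break to the smallest
    position, then lexicographic panel name."""
    if not qtl.members:
        raise ValueError("cannot pick a peak from an empty region")
    best = qtl.members[0]
    for r in qtl.members[1:]:
        if (-r.minus_log10_p, r.pos, r.panel) < (-best.minus_log10_p, best.pos, best.panel):
            best = r
    return best


def assign_names(qtls: list[QtlRegion], trait_symbol: str | None = None) -> list[QtlRegion]:
    """Name QTL ``q<trait><chrom>`` with ``-k`` ordinals (by start) appended
    only when a chromosome carries more than one QTL for the trait."""
    out = sorted(qtls, key=lambda q: (_chrom_key(q.chromosome), q.start))
    per_chrom: dict[str, list[QtlRegion]] = {}
    for q in out:
        per_chrom.setdefault(q.chromosome, []).append(q)
    for chrom, group in per_chrom.items():
        for k, q in enumerate(group, start=1):
            symbol = trait_symbol if trait_symbol is not None else q.trait
            q.name = f"q{symbol}{chrom}" + (f"-{k}" if len(group) > 1 else "")
    return out


def _chrom_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def coloc(
    qtls_a: list[QtlRegion],
    qtls_b: list[QtlRegion],
    end_gap: int = 500_000,
) -> list[ColocPair]:
    """Cross-trait co-location: significant-SNP spans overlap (interspersed)
    or region ends are within ``end_gap``; symmetric in its arguments."""
    pairs: list[ColocPair] = []
    for qa in qtls_a:
        for qb in qtls_b:
            if qa.trait == qb.trait:
                raise ValueError("coloc expects QTL lists for different traits")
            if str(qa.chromosome) != str(qb.chromosome):
                continue
            sa, sb = qa.snp_span, qb.snp_span
            interspersed = sa[0] <= sb[1] and sb[0] <= sa[1]
            gap = max(0, max(qa.start, qb.start) - min(qa.end, qb.end))
            if interspersed:
                pairs.append(ColocPair(qa, qb, "interspersed", gap))
            elif gap <= end_gap:
                pairs.append(ColocPair(qa, qb, "end_gap", gap))
    return pairs


def pivot_allele_effects(
    peak: AssocRecord,
    G: GenotypeMatrix,
    trait_matrix: TraitMatrix,
    traits: list[str],
) -> pd.DataFrame:
    """Per-allele trait means at the peak SNP with sign concordance.

    Returns one row per trait: mean among common-allele carriers, mean among
    alternate-allele carriers, their difference (alt - common), its sign, an
    ``estimable`` flag, and ``concordant`` (same difference sign as the first
    trait in ``traits``).
    """
    j = G.snp_index(peak.snp)
    col = G.dosages[:, j]
    alt_base = str(G.snp_map.at[j, "alt"])
    alt_dosage = 2.0 if peak.alt_allele == alt_base else 0.0
    acc = pd.Index(G.accessions)
    common_acc = acc[col == (2.0 - alt_dosage)]
    alt_acc = acc[col == alt_dosage]

    rows = []
    anchor_sign: int | None = None
    for t in traits:
        vals = trait_matrix.values[t]
        mc = float(vals.reindex(common_acc).mean())
        ma = float(vals.reindex(alt_acc).mean())
        estimable = len(common_acc) > 0 and len(alt_acc) > 0
        diff = ma - mc if estimable else float("nan")
        sign = _sign(diff) if estimable else 0
        if anchor_sign is None:
            anchor_sign = sign
        rows.append({
            "trait": t,
            "mean_common": mc,
            "mean_alt": ma,
            "diff": diff,
            "sign": sign,
            "estimable": estimable,
            "concordant": bool(estimable and sign != 0 and sign == anchor_sign),
        })
    return pd.DataFrame(rows).set_index("trait")


def genes_near(
    qtls: list[QtlRegion],
    annotations: list[GeneAnnotation],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Genes whose interval distance to a QTL interval is <= ``window``.

    Distance is 0 for overlap, else the inter-interval gap; output is sorted
    by (qtl, distance).  Unmatched chromosome names trigger one warning.
    """
    qtl_chroms = {str(q.chromosome) for q in qtls}
    gene_chroms = {str(g.chromosome) for g in annotations}
    unmatched = sorted(gene_chroms - qtl_chroms)
    if unmatched and qtls:
        warnings.warn(f"annotation chromosomes not present among QTL: {unmatched}")

    rows = []
    for q in qtls:
        hits = []
        for g in annotations:
            if str(g.chromosome) != str(q.chromosome):
                continue
            dist = max(0, max(q.start, g.start) - min(q.end, g.end))
            if dist <= window:
                hits.append((dist, g))
        hits.sort(key=lambda h: (h[0], h[1].gene_id))
        for dist, g in hits:
            rows.append({
                "qtl": q.name, "trait": q.trait, "chrom": q.chromosome,
                "gene_id": g.gene_id, "gene_start": g.start, "gene_end": g.end,
                "distance": dist, "description": g.description,
            })
    return pd.DataFrame(
        rows,
        columns=["qtl", "trait", "chrom", "gene_id", "gene_start",
                 "gene_end", "distance", "description"],
    )
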