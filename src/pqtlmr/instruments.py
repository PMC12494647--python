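"""cis-/trans-pQTL instrument selection from two proteome GWAS.

The workflow combines two independent cohorts that assayed the same
proteins and keeps only variants that are genome-wide significant in at
least one study, unambiguous in strand, replicated across studies with
consistent direction, homogeneous in effect size (pairwise |Z| < 3),
LD-independent (greedy clumping at r² < 0.001), outside the MHC, and not
associated with many different aptamers (a pleiotropy heuristic).  Each
stage's losses are recorded in audit counters so the filter cascade is
externally checkable: union size = retained + sum of losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .ld import ReferencePanel, greedy_clump, ld_corr
from .sumstats import GeneAnnotation, SumStats, VariantAssoc, is_ambiguous_palindromic

GENOME_WIDE_P = 5e-8
REPLICATION_P = 0.05
HET_Z_MAX = 3.0
CIS_WINDOW_BP = 500_000
MHC_CHROM = "6"
MHC_LO = 26_000_000
MHC_HI = 34_000_000
MAX_APTAMERS = 4  # a variant hitting >= MAX_APTAMERS+1 aptamers is deemed pleiotropic
CLUMP_R2 = 0.001
CLUMP_WINDOW_KB = 10_000

AUDIT_STAGES = (
    "union",
    "lost_palindromic",
    "lost_untestable",
    "lost_not_replicated",
    "lost_heterogeneous",
    "lost_not_in_panel",
    "lost_clumped",
    "lost_mhc",
    "lost_multi_aptamer",
    "retained",
)


@dataclass(frozen=True)
class PQTLRecord:
    """A selected pQTL with its source-study provenance."""

    protein_id: str
    assoc: VariantAssoc
    source_study: str
    cis_trans: str  # "cis" | "trans"
    key: str


@dataclass
class InstrumentSet:
    protein_id: str
    gene: GeneAnnotation
    cis: list[PQTLRecord] = field(default_factory=list)
    trans: list[PQTLRecord] = field(default_factory=list)
    audit: dict[str, int] = field(default_factory=lambda: {s: 0 for s in AUDIT_STAGES})

    @property
    def all_instruments(self) -> list[PQTLRecord]:
        return self.cis + self.trans

    def check_audit(self) -> bool:
        losses = sum(v for k, v in self.audit.items() if k.startswith("lost_"))
        return self.audit["union"] == losses + self.audit["retained"]


def significant_union(study_a: SumStats, study_b: SumStats, p_gw: float = GENOME_WIDE_P) -> list[str]:
    """Keys genome-wide significant (p strictly below threshold) in either study."""
    keys = set()
    for key, v in study_a.records.items():
        if v.pval < p_gw:
            keys.add(key)
    for key, v in study_b.records.items():
        if v.pval < p_gw:
            keys.add(key)
    return sorted(keys)


def _align_to(a: VariantAssoc, b: VariantAssoc) -> VariantAssoc:
    """Express b on a's effect allele; error if the allele sets differ."""
    if {a.effect_allele, a.other_allele} != {b.effect_allele, b.other_allele}:
        raise ValueError(
            f"allele sets differ at {a.chrom}:{a.pos}: "
            f"{a.effect_allele}/{a.other_allele} vs {b.effect_allele}/{b.other_allele}"
        )
    return b if b.effect_allele == a.effect_allele else b.flipped()


def cross_replicate(a: VariantAssoc, b: VariantAssoc) -> bool:
    """Replication rule: the other study shows p < 0.05 with the same direction.

    ``a`` is the more significant record; ``b`` is aligned to a's effect
    allele before comparison.  Zero betas never replicate.
    """
    b = _align_to(a, b)
    if a.beta == 0.0 or b.beta == 0.0:
        return False
    return b.pval < REPLICATION_P and math.copysign(1, a.beta) == math.copysign(1, b.beta)


def heterogeneity_z(a: VariantAssoc, b: VariantAssoc) -> float:
    """Pairwise z-statistic for effect-size difference between the two studies."""
    b = _align_to(a, b)
    if a.se <= 0 or b.se <= 0:
        raise ValueError("heterogeneity_z requires positive standard errors")
    return (a.beta - b.beta) / math.sqrt(a.se**2 + b.se**2)


def classify_cis_trans(v: VariantAssoc, g: GeneAnnotation, window_bp: int = CIS_WINDOW_BP) -> str:
    """cis iff within ±window of the gene body (inclusive), same chromosome."""
    if v.chrom == g.chrom and g.gene_start - window_bp <= v.pos <= g.gene_end + window_bp:
        return "cis"
    return "trans"


def in_mhc(
    v: VariantAssoc,
    chrom: str = MHC_CHROM,
    lo: int = MHC_LO,
    hi: int = MHC_HI,
) -> bool:
    return v.chrom == chrom and lo <= v.pos <= hi


def multi_aptamer_filter(
    pqtl_aptamer_map: dict[str, set[str]],
    max_aptamers: int = MAX_APTAMERS,
) -> set[str]:
    """Keys associated with more than ``max_aptamers`` distinct aptamers.

    With the default of 4, a variant seen for five or more aptamers is
    excluded as likely pleiotropic.
    """
    return {k for k, prots in pqtl_aptamer_map.items() if len(prots) >= max_aptamers + 1}


def select_best_source(
    a: VariantAssoc | None,
    b: VariantAssoc | None,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[VariantAssoc, str]:
    """Keep the record from the study with the smaller p-value (ties → study A)."""
    if a is None and b is None:
        raise ValueError("select_best_source: both records absent")
    if b is None:
        return a, label_a
    if a is None:
        return b, label_b
    return (a, label_a) if a.pval <= b.pval else (b, label_b)


def replicated_pqtls(
    study_a: SumStats,
    study_b: SumStats,
    p_gw: float = GENOME_WIDE_P,
    maf_window: float = 0.08,
    het_z_max: float = HET_Z_MAX,
    keep_untestable: bool = False,
    audit: dict[str, int] | None = None,
) -> dict[str, tuple[VariantAssoc, str]]:
    """Union → palindrome → replication/|Z| screen → best-source, before clumping.

    Returns key → (chosen record, source label).  Variants significant in
    only one study and absent from the other cannot be replication-tested;
    they are dropped unless ``keep_untestable``.
    """
    if audit is None:
        audit = {s: 0 for s in AUDIT_STAGES}
    union = significant_union(study_a, study_b, p_gw)
    audit["union"] += len(union)
    chosen: dict[str, tuple[VariantAssoc, str]] = {}
    for key in union:
        va, vb = study_a.get(key), study_b.get(key)
        rep = va if va is not None else vb
        if is_ambiguous_palindromic(rep, maf_window):
            audit["lost_palindromic"] += 1
            continue
        if va is None or vb is None:
            if not keep_untestable:
                audit["lost_untestable"] += 1
                continue
        else:
            lead, other = (va, vb) if va.pval <= vb.pval else (vb, va)
            if not cross_replicate(lead, other):
                audit["lost_not_replicated"] += 1
                continue
            if abs(heterogeneity_z(va, vb)) >= het_z_max:
                audit["lost_heterogeneous"] += 1
                continue
        rec, src = select_best_source(va, vb, study_a.study_label or "A", study_b.study_label or "B")
        chosen[key] = (rec, src)
    return chosen


def build_instruments(
    protein_a: SumStats,
    protein_b: SumStats,
    gene: GeneAnnotation,
    panel: ReferencePanel,
    global_aptamer_map: dict[str, set[str]] | None = None,
    p_gw: float = GENOME_WIDE_P,
    maf_window: float = 0.08,
    het_z_max: float = HET_Z_MAX,
    cis_window_bp: int = CIS_WINDOW_BP,
    clump_r2: float = CLUMP_R2,
    clump_window_kb: int = CLUMP_WINDOW_KB,
    max_aptamers: int = MAX_APTAMERS,
    keep_untestable: bool = False,
) -> InstrumentSet:
    """Run the full instrument-selection cascade for one protein.

    Stage order: significance union, ambiguous-palindrome removal,
    cross-replication + heterogeneity screen (variants present in both
    studies), cis/trans classification, best-source selection, greedy
    clumping (cis and trans lists separately), MHC removal, multi-aptamer
    pleiotropy removal.  ``global_aptamer_map`` maps variant key → set of
    aptamers for which the variant survived the replication stage across
    the whole panel of proteins.
    """
    iset = InstrumentSet(protein_id=gene.protein_id, gene=gene)
    chosen = replicated_pqtls(
        protein_a, protein_b, p_gw, maf_window, het_z_max, keep_untestable, iset.audit
    )

    cis_items: list[tuple[str, float]] = []
    trans_items: list[tuple[str, float]] = []
    records: dict[str, tuple[VariantAssoc, str, str]] = {}
    for key, (rec, src) in chosen.items():
        if key not in panel:
            iset.audit["lost_not_in_panel"] += 1
            continue
        ct = classify_cis_trans(rec, gene, cis_window_bp)
        records[key] = (rec, src, ct)
        (cis_items if ct == "cis" else trans_items).append((key, rec.pval))

    kept: list[str] = []
    for items in (cis_items, trans_items):
        if not items:
            continue
        ld = ld_corr(panel, [k for k, _ in items])
        retained = greedy_clump(items, ld, r2_max=clump_r2, window_kb=clump_window_kb)
        iset.audit["lost_clumped"] += len(items) - len(retained)
        kept.extend(retained)

    excluded_multi = (
        multi_aptamer_filter(global_aptamer_map, max_aptamers) if global_aptamer_map else set()
    )
    for key in kept:
        rec, src, ct = records[key]
        if in_mhc(rec):
            iset.audit["lost_mhc"] += 1
            continue
        if key in excluded_multi:
            iset.audit["lost_multi_aptamer"] += 1
            continue
        pq = PQTLRecord(protein_id=gene.protein_id, assoc=rec, source_study=src, cis_trans=ct, key=key)
        (iset.cis if ct == "cis" else iset.trans).append(pq)
    iset.audit["retained"] = len(iset.cis) + len(iset.trans)
    iset.cis.sort(key=lambda r: (r.assoc.pval, r.key))
    iset.trans.sort(key=lambda r: (r.assoc.pval, r.key))
    assert iset.check_audit(), "audit counters inconsistent with retained instruments"
    return iset


def build_aptamer_map(
    studies: dict[str, tuple[SumStats, SumStats]],
    p_gw: float = GENOME_WIDE_P,
    maf_window: float = 0.08,
    het_z_max: float = HET_Z_MAX,
    keep_untestable: bool = False,
) -> dict[str, set[str]]:
    """Variant key → aptamers for which it survives the replication stage.

    Built across ALL proteins after replication filtering but before
    clumping, so clump order cannot hide a pleiotropic variant.
    """
    amap: dict[str, set[str]] = {}
    for protein_id, (sa, sb) in studies.items():
        chosen = replicated_pqtls(sa, sb, p_gw, maf_window, het_z_max, keep_untestable)
        for key in chosen:
            amap.setdefault(key, set()).add(protein_id)
    return amap
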