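"""Exposure/outcome harmonisation onto a common effect allele.

Two-sample MR needs the instrument-exposure and instrument-outcome
effects expressed for the same allele.  Outcome records whose alleles
are swapped relative to the exposure get their beta negated; records
coded on the complementary strand are re-mapped via base complements
first.  By convention both betas are then oriented so the exposure
effect is positive — the Wald ratio is invariant to this, but it makes
result tables comparable across instruments.  Ambiguous palindromic
pairs are dropped.  Instruments missing from the outcome study can be
replaced by an LD proxy drawn from the protein's own valid instrument
list; the proxy's own exposure and outcome statistics are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .instruments import InstrumentSet, PQTLRecord
from .ld import ReferencePanel, find_proxy, ld_corr
from .sumstats import (
    COMPLEMENT,
    SumStats,
    VariantAssoc,
    is_ambiguous_palindromic,
    is_palindromic,
)

PROXY_R2_MIN = 0.8


@dataclass(frozen=True)
class HarmonisedRecord:
    """One instrument's aligned (β_exposure, β_outcome) pair."""

    key: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    proxy_used: str | None = None
    proxy_r2: float | None = None

    def __post_init__(self) -> None:
        if self.beta_exp <= 0:
            raise ValueError("harmonised beta_exp must be > 0 by orientation convention")
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError("standard errors must be positive")


@dataclass
class HarmonisedSet:
    protein_id: str
    outcome_label: str
    records: list[HarmonisedRecord] = field(default_factory=list)
    n_dropped_palindromic: int = 0
    n_missing_no_proxy: int = 0
    n_allele_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.records)


def _complemented(v: VariantAssoc) -> VariantAssoc:
    from dataclasses import replace

    return replace(
        v,
        effect_allele=COMPLEMENT[v.effect_allele],
        other_allele=COMPLEMENT[v.other_allele],
    )


def harmonise_pair(
    exp: VariantAssoc,
    out: VariantAssoc,
    maf_window: float = 0.08,
) -> tuple[HarmonisedRecord | None, str]:
    """Align one outcome record to one exposure record.

    Returns (record, "ok") or (None, reason) where reason is
    "palindromic_ambiguous" or "allele_mismatch".  For palindromic
    variants strand cannot be checked from alleles; frequency
    concordance (eaf vs 1-eaf distance) resolves orientation when both
    frequencies are available and informative, otherwise the pair is
    dropped as ambiguous.
    """
    exp_set = {exp.effect_allele, exp.other_allele}
    out_set = {out.effect_allele, out.other_allele}

    if is_palindromic(exp):
        # complement is the same allele pair: alleles cannot reveal strand
        if is_ambiguous_palindromic(exp, maf_window) or is_ambiguous_palindromic(out, maf_window):
            return None, "palindromic_ambiguous"
        if out_set != exp_set:
            return None, "allele_mismatch"
        # align by label first, then let frequency concordance decide
        # whether the outcome is strand-flipped (which negates the beta
        # again and reflects the frequency)
        if out.effect_allele == exp.effect_allele:
            b_naive, f_naive = out.beta, out.eaf
        else:
            b_naive, f_naive = -out.beta, 1.0 - out.eaf
        if abs(exp.eaf - f_naive) <= abs(exp.eaf - (1.0 - f_naive)):
            b_aligned, f_aligned = b_naive, f_naive
        else:
            b_aligned, f_aligned = -b_naive, 1.0 - f_naive
        from dataclasses import replace as _replace

        out_aligned = _replace(
            out, effect_allele=exp.effect_allele, other_allele=exp.other_allele,
            beta=b_aligned, eaf=f_aligned,
        )
    else:
        if out_set == exp_set:
            out_aligned = out
        elif {COMPLEMENT[a] for a in out_set} == exp_set:
            out_aligned = _complemented(out)
        else:
            return None, "allele_mismatch"
        if out_aligned.effect_allele != exp.effect_allele:
            out_aligned = out_aligned.flipped()

    beta_exp, beta_out = exp.beta, out_aligned.beta
    if beta_exp < 0:
        beta_exp, beta_out = -beta_exp, -beta_out
    elif beta_exp == 0:
        return None, "zero_exposure_beta"
    rec = HarmonisedRecord(
        key=f"{exp.chrom}:{exp.pos}",
        beta_exp=beta_exp,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out_aligned.se,
    )
    return rec, "ok"


def attach_outcome(
    instr: InstrumentSet,
    outcome: SumStats,
    panel: ReferencePanel,
    r2_min: float = PROXY_R2_MIN,
    cis_only: bool = True,
    maf_window: float = 0.08,
) -> HarmonisedSet:
    """Harmonise a protein's instruments with one outcome GWAS.

    Instruments present in the outcome are harmonised directly.  For an
    instrument absent from the outcome, the best proxy with r² > r2_min
    is sought among the protein's other valid instruments that ARE
    present in the outcome; the proxy variant's own exposure association
    is used on the exposure side.  Instruments with no qualifying proxy
    are counted and skipped.
    """
    from .sumstats import variant_key

    instruments: list[PQTLRecord] = list(instr.cis) if cis_only else list(instr.all_instruments)
    hs = HarmonisedSet(protein_id=instr.protein_id, outcome_label=outcome.trait_label)
    used_keys: set[str] = set()
    pool = [pq.key for pq in instruments if pq.key in outcome.records and pq.key in panel]
    ld = ld_corr(panel, sorted(set(pool) | {pq.key for pq in instruments if pq.key in panel})) if pool else None

    for pq in instruments:
        key = pq.key
        exp_rec, proxy_used, proxy_r2 = pq.assoc, None, None
        out_rec = outcome.get(key)
        if out_rec is None:
            candidates = [k for k in pool if k != key and k not in used_keys]
            proxy = None
            if ld is not None and key in ld.index and candidates:
                proxy = find_proxy(key, candidates, ld, r2_min=r2_min)
            if proxy is None:
                hs.n_missing_no_proxy += 1
                continue
            proxy_pq = next(p for p in instruments if p.key == proxy)
            exp_rec = proxy_pq.assoc
            out_rec = outcome.get(proxy)
            proxy_used, proxy_r2 = proxy, ld.r2(key, proxy)
            key = proxy
        if key in used_keys:
            continue
        rec, reason = harmonise_pair(exp_rec, out_rec, maf_window)
        if rec is None:
            if reason == "palindromic_ambiguous":
                hs.n_dropped_palindromic += 1
            else:
                hs.n_allele_mismatch += 1
            continue
        used_keys.add(key)
        hs.records.append(
            HarmonisedRecord(
                key=key,
                beta_exp=rec.beta_exp,
                se_exp=rec.se_exp,
                beta_out=rec.beta_out,
                se_out=rec.se_out,
                proxy_used=proxy_used,
                proxy_r2=proxy_r2,
            )
        )
    return hs
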