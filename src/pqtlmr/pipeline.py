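"""Proteome-wide scan: instruments → harmonisation → MR → Bonferroni → coloc.

The primary pass uses cis instruments only (trans-pQTLs are more likely
to act through pathways other than the protein, violating the exclusion
restriction); an optional secondary pass repeats the analysis with cis
and trans instruments combined and is labelled so it can never be
confused with the primary results.  Multiple testing is controlled by
Bonferroni across the proteins that enter MR within each outcome — the
denominator is the number of proteins with at least one valid cis
instrument, recomputed from the audit trail.  Protein–outcome pairs
whose primary MR p-value passes the threshold get colocalisation
follow-up on the cis region: the single-causal-variant analysis always,
plus SuSiE-based credible-set colocalisation when the region is large
enough to fine-map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coloc import (
    ColocResult,
    RegionStats,
    coloc_abf,
    coloc_susie,
    evidence_call,
    susie_rss,
)
from .harmonise import attach_outcome
from .instruments import (
    CIS_WINDOW_BP,
    InstrumentSet,
    build_aptamer_map,
    build_instruments,
)
from .ld import ReferencePanel, ld_corr
from .mr import MRResult, run_mr
from .sumstats import GeneAnnotation, SumStats

logger = logging.getLogger(__name__)

MIN_SUSIE_VARIANTS = 25


@dataclass
class ScanConfig:
    alpha: float = 0.05
    p_gw: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    cis_window_bp: int = CIS_WINDOW_BP
    proxy_r2: float = 0.8
    max_aptamers: int = 4
    maf_window: float = 0.08
    het_z_max: float = 3.0
    keep_untestable: bool = False
    cis_only: bool = True
    secondary_cis_trans: bool = False
    coloc_pp_threshold: float = 0.8
    seed: int = 20240601
    n_boot: int = 1000


@dataclass
class ScanReport:
    n_tests: int
    p_threshold: float
    mr_results: list[dict] = field(default_factory=list)
    coloc_results: list[dict] = field(default_factory=list)
    evidence: list[dict] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)
    instruments: dict[str, InstrumentSet] = field(default_factory=dict)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error control: per-test threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def region_stats(
    ss: SumStats, keys: list[str], panel: ReferencePanel
) -> RegionStats:
    """Region summary statistics with betas signed to the panel's counted alleles."""
    beta, se = [], []
    for k in keys:
        v = ss.records[k]
        counted = panel.counted_alleles[panel.index[k]]
        b = v.beta if v.effect_allele == counted else -v.beta
        beta.append(b)
        se.append(v.se)
    n_med = int(np.median([ss.records[k].n or 0 for k in keys])) or None
    return RegionStats(
        keys=list(keys),
        beta=np.array(beta),
        se=np.array(se),
        trait_type=ss.trait_type,
        n=n_med,
    )


def cis_region_keys(
    gene: GeneAnnotation,
    exposure: SumStats,
    outcome: SumStats,
    panel: ReferencePanel,
    window_bp: int = CIS_WINDOW_BP,
) -> list[str]:
    """Cis-window variants present in both traits and the LD panel, by position."""
    lo, hi = gene.gene_start - window_bp, gene.gene_end + window_bp
    keys = []
    for k, v in exposure.records.items():
        if v.chrom == gene.chrom and lo <= v.pos <= hi and k in outcome.records and k in panel:
            keys.append((v.pos, k))
    return [k for _, k in sorted(keys)]


def coloc_followup(
    gene: GeneAnnotation,
    exposure: SumStats,
    outcome: SumStats,
    panel: ReferencePanel,
    cfg: ScanConfig,
) -> tuple[list[ColocResult], str]:
    """Single-variant coloc plus SuSiE credible-set coloc on the cis region."""
    keys = cis_region_keys(gene, exposure, outcome, panel, cfg.cis_window_bp)
    if len(keys) < 2:
        return [], "other"
    t1 = region_stats(exposure, keys, panel)
    t2 = region_stats(outcome, keys, panel)
    results = [coloc_abf(t1, t2)]
    if len(keys) >= MIN_SUSIE_VARIANTS and t1.n and t2.n:
        R = ld_corr(panel, keys)
        fit1 = susie_rss(t1.z, R, n=t1.n)
        fit2 = susie_rss(t2.z, R, n=t2.n)
        if fit1.credible_sets and fit2.credible_sets:
            results.extend(coloc_susie(fit1, fit2))
    return results, evidence_call(results, cfg.coloc_pp_threshold)


def _mr_row(res: MRResult, analysis: str) -> dict:
    return {
        "protein_id": res.protein_id,
        "outcome_label": res.outcome_label,
        "analysis": analysis,
        "method": res.method,
        "estimate": res.estimate,
        "se": res.se,
        "pval": res.pval,
        "nsnp": res.nsnp,
        "Q": res.Q,
        "Q_pval": res.Q_pval,
        "egger_intercept": res.egger_intercept,
        "egger_intercept_p": res.egger_intercept_p,
    }


def run_scan(
    studies: dict[str, tuple[SumStats, SumStats]],
    genes: dict[str, GeneAnnotation],
    outcomes: list[SumStats],
    panel: ReferencePanel,
    cfg: ScanConfig | None = None,
) -> ScanReport:
    """Run the full proteome-wide MR + colocalisation scan in memory.

    ``studies`` maps protein_id → (study A, study B) summary statistics.
    Returns a :class:`ScanReport`; writing files is the CLI's concern.
    """
    cfg = cfg or ScanConfig()
    amap = build_aptamer_map(
        studies, cfg.p_gw, cfg.maf_window, cfg.het_z_max, cfg.keep_untestable
    )
    instruments: dict[str, InstrumentSet] = {}
    for pid in sorted(studies):
        sa, sb = studies[pid]
        iset = build_instruments(
            sa, sb, genes[pid], panel, amap,
            p_gw=cfg.p_gw, maf_window=cfg.maf_window, het_z_max=cfg.het_z_max,
            cis_window_bp=cfg.cis_window_bp, clump_r2=cfg.clump_r2,
            clump_window_kb=cfg.clump_window_kb, max_aptamers=cfg.max_aptamers,
            keep_untestable=cfg.keep_untestable,
        )
        instruments[pid] = iset

    with_cis = [pid for pid, s in instruments.items() if s.cis]
    if not with_cis:
        audit_summary = {pid: s.audit for pid, s in instruments.items()}
        raise RuntimeError(f"no protein yielded valid cis instruments; audit: {audit_summary}")
    n_tests = len(with_cis)
    threshold = bonferroni_threshold(cfg.alpha, n_tests)

    report = ScanReport(n_tests=n_tests, p_threshold=threshold, instruments=instruments)
    for pid, iset in instruments.items():
        row = {"protein_id": pid, **iset.audit}
        report.audit.append(row)

    for outcome in outcomes:
        for pid in sorted(with_cis):
            iset = instruments[pid]
            sa, _ = studies[pid]
            hs = attach_outcome(
                iset, outcome, panel, r2_min=cfg.proxy_r2, cis_only=True,
                maf_window=cfg.maf_window,
            )
            if not hs.records:
                continue
            results = run_mr(hs, n_boot=cfg.n_boot, seed=cfg.seed)
            primary = results[0]  # wald or ivw
            significant = primary.pval < threshold
            for res in results:
                report.mr_results.append(_mr_row(res, "cis_only"))
            if cfg.secondary_cis_trans and iset.trans:
                hs2 = attach_outcome(
                    iset, outcome, panel, r2_min=cfg.proxy_r2, cis_only=False,
                    maf_window=cfg.maf_window,
                )
                if hs2.records:
                    for res in run_mr(hs2, n_boot=cfg.n_boot, seed=cfg.seed):
                        report.mr_results.append(_mr_row(res, "cis_trans_secondary"))
            if not significant:
                continue
            coloc_results, call = coloc_followup(
                genes[pid], sa, outcome, panel, cfg
            )
            for i, cr in enumerate(coloc_results):
                report.coloc_results.append(
                    {
                        "protein_id": pid,
                        "outcome_label": outcome.trait_label,
                        "mode": "abf" if cr.cs1_label is None else "susie",
                        "pair": f"{cr.cs1_label}|{cr.cs2_label}" if cr.cs1_label else "region",
                        **{h: cr.pp[h] for h in cr.pp},
                        "n_variants": cr.n_variants,
                    }
                )
            report.evidence.append(
                {
                    "protein_id": pid,
                    "outcome_label": outcome.trait_label,
                    "mr_method": primary.method,
                    "mr_estimate": primary.estimate,
                    "mr_pval": primary.pval,
                    "nsnp": primary.nsnp,
                    "p_threshold": threshold,
                    "call": call,
                }
            )
    # self-consistency: the Bonferroni denominator must equal the audit count
    n_from_audit = sum(1 for pid, s in instruments.items() if s.cis)
    assert n_from_audit == n_tests, "Bonferroni denominator inconsistent with audit"
    return report


def write_report(report: ScanReport, outdir) -> None:
    """Write the scan outputs as deterministic TSV tables."""
    import os

    from .sumstats import write_results_table

    os.makedirs(outdir, exist_ok=True)
    write_results_table(
        report.mr_results, os.path.join(outdir, "mr_results.tsv"),
        columns=["protein_id", "outcome_label", "analysis", "method", "estimate",
                 "se", "pval", "nsnp", "Q", "Q_pval", "egger_intercept",
                 "egger_intercept_p"],
    )
    write_results_table(
        report.coloc_results, os.path.join(outdir, "coloc_results.tsv"),
        columns=["protein_id", "outcome_label", "mode", "pair", "PP_H0", "PP_H1",
                 "PP_H2", "PP_H3", "PP_H4", "n_variants"],
    )
    write_results_table(
        report.evidence, os.path.join(outdir, "evidence_calls.tsv"),
        columns=["protein_id", "outcome_label", "mr_method", "mr_estimate",
                 "mr_pval", "nsnp", "p_threshold", "call"],
    )
    write_results_table(
        report.audit, os.path.join(outdir, "audit.tsv"),
        columns=["protein_id"] + [s for s in report.audit[0] if s != "protein_id"]
        if report.audit else ["protein_id"],
    )
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(
            f"proteins_tested\t{report.n_tests}\n"
            f"p_threshold\t{report.p_threshold:.6g}\n"
            f"n_mr_results\t{len(report.mr_results)}\n"
            f"n_significant\t{len(report.evidence)}\n"
        )
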