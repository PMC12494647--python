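"""Synthetic GWAS generator with known causal architecture.

Emulates the statistical structure of the real inputs — two independent
cohorts assaying the same protein on a rank-normalised scale, an
LD-structured genome region, and an outcome cohort in which the protein
has a configurable causal effect — so that every pipeline stage can be
exercised against ground truth without any external download.

LD is generated by a thresholded Gaussian copula: two latent haplotype
draws per sample from a blockwise AR(1) multivariate normal, each
dichotomised at the allele-frequency quantile, summed to a 0/1/2
dosage.  Thresholding attenuates the latent correlation rho, so the
realised dosage r is somewhat below rho (measured, not modelled).

Causal effects are specified as fractions of trait variance explained;
per-allele betas follow as sqrt(q / (2 f (1 - f))).  Residual noise for
both protein and outcome is scaled against the *empirical* variance of
the genetic component so the simulated traits have unit variance and
the causal effect of the standardized protein on the standardized
outcome is exactly theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ld import ReferencePanel
from .sumstats import GeneAnnotation, SumStats, VariantAssoc, make_key

# non-palindromic allele pairs cycled across variants
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class SimScenario:
    """Full parameterisation of one synthetic study.

    ``causal_cis`` / ``outcome_direct`` list (variant index, fraction of
    trait variance explained) pairs; ``theta`` is the causal effect of
    the standardized protein on the standardized outcome (log-odds scale
    for binary outcomes via the liability model).
    """

    name: str = "custom"
    n_variants: int = 24
    block_size: int = 8
    rho: float = 0.5
    maf: float = 0.3
    n_a: int = 5000
    n_b: int = 5000
    n_out: int = 5000
    n_panel: int = 10_000
    causal_cis: tuple[tuple[int, float], ...] = ((2, 0.015), (10, 0.015), (18, 0.015))
    theta: float = 0.0
    outcome_type: str = "quantitative"
    case_fraction: float = 0.1
    pleiotropy: str = "none"  # none | balanced | directional
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    outcome_direct: tuple[tuple[int, float], ...] = ()
    n_aptamers: int = 1
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000
    seed: int = 0


@dataclass
class GenomeLayout:
    """Deterministic variant map derived from a scenario."""

    keys: list[str]
    pos: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    maf: np.ndarray
    blocks: list[slice]
    chol: list[np.ndarray]
    gene: GeneAnnotation


def make_layout(scn: SimScenario, protein_id: str = "P1", gene_symbol: str = "GENE1") -> GenomeLayout:
    p = scn.n_variants
    pos = scn.pos_start + scn.pos_step * np.arange(p)
    eff, oth, keys = [], [], []
    for i in range(p):
        a, b = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        eff.append(a)
        oth.append(b)
        keys.append(make_key(scn.chrom, int(pos[i]), a, b))
    blocks = [slice(s, min(s + scn.block_size, p)) for s in range(0, p, scn.block_size)]
    chol = []
    for blk in blocks:
        m = blk.stop - blk.start
        corr = scn.rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        chol.append(np.linalg.cholesky(corr))
    maf = np.full(p, scn.maf, dtype=float)
    gene = GeneAnnotation(
        protein_id=protein_id,
        gene_symbol=gene_symbol,
        chrom=scn.chrom,
        gene_start=int(pos[0]),
        gene_end=int(pos[-1]),
    )
    return GenomeLayout(keys, pos, eff, oth, maf, blocks, chol, gene)


def _draw_genotypes(layout: GenomeLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """n x p dosage matrix from the thresholded-copula haplotype model."""
    p = len(layout.keys)
    g = np.zeros((n, p), dtype=np.float64)
    thresh = stats.norm.ppf(1.0 - layout.maf)
    for blk, L in zip(layout.blocks, layout.chol):
        m = blk.stop - blk.start
        for _hap in range(2):
            latent = rng.standard_normal((n, m)) @ L.T
            g[:, blk] += latent > thresh[blk]
    return g


def _rng(scn: SimScenario, stream: int, seed: int | None) -> np.random.Generator:
    base = scn.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2**31), stream])


def simulate_reference_panel(
    scn: SimScenario, layout: GenomeLayout | None = None, seed: int | None = None
) -> ReferencePanel:
    """Independent reference cohort for LD computation."""
    layout = layout or make_layout(scn)
    rng = _rng(scn, 1, seed)
    g = _draw_genotypes(layout, scn.n_panel, rng)
    # drop monomorphic columns (possible at small panels / rare alleles)
    var = g.var(axis=0)
    keep = var > 0
    return ReferencePanel(
        keys=[k for k, ok in zip(layout.keys, keep) if ok],
        dosages=g.T[keep],
        counted_alleles=[a for a, ok in zip(layout.effect_alleles, keep) if ok],
    )


def _effect_vector(scn: SimScenario, layout: GenomeLayout, pairs) -> np.ndarray:
    beta = np.zeros(scn.n_variants)
    for idx, q in pairs:
        f = layout.maf[idx]
        beta[idx] += np.sqrt(q / (2.0 * f * (1.0 - f)))
    return beta


def protein_effects(scn: SimScenario, layout: GenomeLayout | None = None) -> np.ndarray:
    layout = layout or make_layout(scn)
    return _effect_vector(scn, layout, scn.causal_cis)


def _inverse_normal(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offsets)."""
    ranks = stats.rankdata(y)
    return stats.norm.ppf((ranks - 0.375) / (len(y) + 0.25))


def _marginal_ols(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple linear regression, vectorized across variants."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    sxy = gc.T @ yc
    syy = float(np.sum(yc**2))
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 1e-12)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    pv = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return beta, se, np.clip(pv, 1e-300, 1.0)


def _to_sumstats(
    layout: GenomeLayout,
    g: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    pv: np.ndarray,
    study_label: str,
    trait_label: str,
    trait_type: str,
    n: int,
) -> SumStats:
    eaf = g.mean(axis=0) / 2.0
    ss = SumStats(study_label=study_label, trait_label=trait_label, trait_type=trait_type)
    for j, key in enumerate(layout.keys):
        ss.records[key] = VariantAssoc(
            variant_id=f"rs{j}",
            chrom=layout.gene.chrom,
            pos=int(layout.pos[j]),
            effect_allele=layout.effect_alleles[j],
            other_allele=layout.other_alleles[j],
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pv[j]),
            eaf=float(eaf[j]),
            n=n,
        )
    return ss


def _simulate_trait(
    layout: GenomeLayout, g: np.ndarray, effects: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance trait: genetic component plus matched residual noise."""
    genetic = g @ effects
    var_g = float(genetic.var())
    noise_sd = np.sqrt(max(1e-3, 1.0 - var_g))
    return genetic + rng.normal(0.0, noise_sd, size=len(genetic))


def simulate_protein_gwas(
    scn: SimScenario,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
    protein_label: str = "P1",
    effects: np.ndarray | None = None,
    stream_offset: int = 0,
) -> tuple[SumStats, SumStats]:
    """Two independent cohorts' GWAS of the same (inverse-normalised) protein."""
    layout = layout or make_layout(scn, protein_id=protein_label)
    if effects is None:
        effects = protein_effects(scn, layout)
    out = []
    for stream, (label, n) in enumerate([("A", scn.n_a), ("B", scn.n_b)], start=2):
        rng = _rng(scn, stream + stream_offset, seed)
        g = _draw_genotypes(layout, n, rng)
        y = _inverse_normal(_simulate_trait(layout, g, effects, rng))
        beta, se, pv = _marginal_ols(g, y)
        out.append(_to_sumstats(layout, g, beta, se, pv, label, protein_label, "quantitative", n))
    return out[0], out[1]


def outcome_effect_vector(
    scn: SimScenario, layout: GenomeLayout, rng: np.random.Generator
) -> np.ndarray:
    """Direct per-allele variant effects on the outcome (pleiotropy + distinct causals)."""
    alpha = _effect_vector(scn, layout, scn.outcome_direct)
    if scn.pleiotropy != "none":
        idx = [i for i, _ in scn.causal_cis]
        draws = rng.normal(scn.pleio_mean, scn.pleio_sd, size=len(idx))
        if scn.pleiotropy == "balanced":
            draws -= scn.pleio_mean  # centre at zero
        for i, a in zip(idx, draws):
            alpha[i] += a
    return alpha


def _logistic_gwas(g: np.ndarray, case: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    p = g.shape[1]
    beta = np.empty(p)
    se = np.empty(p)
    pv = np.empty(p)
    for j in range(p):
        X = sm.add_constant(g[:, [j]])
        fit = sm.Logit(case, X).fit(disp=0, maxiter=50)
        beta[j] = fit.params[1]
        se[j] = fit.bse[1]
        pv[j] = fit.pvalues[1]
    return beta, se, np.clip(pv, 1e-300, 1.0)


def simulate_outcome_gwas(
    scn: SimScenario,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
    outcome_label: str = "outcome",
) -> SumStats:
    """Outcome cohort GWAS, independent of both protein cohorts.

    Quantitative outcomes are analysed z-scored; binary outcomes arise
    from a liability-threshold draw at the configured case fraction and
    are analysed by per-variant logistic regression (log-odds betas).
    """
    layout = layout or make_layout(scn)
    rng = _rng(scn, 4, seed)
    g = _draw_genotypes(layout, scn.n_out, rng)
    effects = protein_effects(scn, layout)
    protein = _simulate_trait(layout, g, effects, rng)

    alpha = outcome_effect_vector(scn, layout, _rng(scn, 5, seed))
    direct = g @ alpha
    signal = scn.theta * protein + direct
    var_sig = float(np.var(signal))
    noise_sd = np.sqrt(max(1e-3, 1.0 - var_sig))
    liability = signal + rng.normal(0.0, noise_sd, size=scn.n_out)

    if scn.outcome_type == "binary":
        case = (liability > stats.norm.ppf(1.0 - scn.case_fraction)).astype(float)
        beta, se, pv = _logistic_gwas(g, case)
        ss = _to_sumstats(layout, g, beta, se, pv, "OUT", outcome_label, "binary", scn.n_out)
        ss.case_fraction = float(case.mean())  # type: ignore[attr-defined]
        return ss
    y = (liability - liability.mean()) / liability.std()
    beta, se, pv = _marginal_ols(g, y)
    return _to_sumstats(layout, g, beta, se, pv, "OUT", outcome_label, "quantitative", scn.n_out)


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------

_COLOC_BASE = dict(
    n_variants=120,
    block_size=10,
    rho=0.5,
    n_a=20_000,
    n_b=10_000,
    n_out=50_000,
    n_panel=2_000,
    causal_cis=((60, 0.05),),
)

SCENARIOS = {
    "null": dict(name="null", theta=0.0),
    "causal_shared": dict(name="causal_shared", theta=0.3, **_COLOC_BASE),
    "causal_distinct": dict(
        name="causal_distinct", theta=0.0, outcome_direct=((20, 0.002),), **_COLOC_BASE
    ),
    # true effect present but the outcome cohort far too small to see it:
    # expected z at the causal variant ~ 0.5, indistinguishable from noise
    "underpowered_outcome": dict(
        name="underpowered_outcome",
        theta=0.05,
        **{**_COLOC_BASE, "n_out": 2_000},
    ),
    "recovery": dict(
        name="recovery",
        theta=0.3,
        n_a=20_000,
        n_out=50_000,
        causal_cis=((2, 0.02), (10, 0.02), (18, 0.02)),
    ),
    "pleiotropy_balanced": dict(
        name="pleiotropy_balanced", theta=0.3, pleiotropy="balanced", pleio_sd=0.02
    ),
    "pleiotropy_directional": dict(
        name="pleiotropy_directional",
        theta=0.3,
        pleiotropy="directional",
        pleio_mean=0.03,
        pleio_sd=0.01,
    ),
    "multi_aptamer": dict(name="multi_aptamer", n_aptamers=5, theta=0.0),
}


def scenario_library(name: str, seed: int = 0) -> SimScenario:
    """Named, fully parameterised scenarios for each pipeline behaviour.

    ``null``: no causal protein effect anywhere (type-I error checks).
    ``causal_shared``: one strong cis variant drives both protein and
    outcome through the protein (theta = 0.3).  ``causal_distinct``: the
    outcome has its own causal variant in a different LD block.
    ``underpowered_outcome``: true effect but a small outcome cohort.
    ``pleiotropy_balanced`` / ``pleiotropy_directional``: direct
    instrument-outcome effects with zero / positive mean.
    ``multi_aptamer``: one variant is a significant pQTL for five
    synthetic aptamers, exercising the pleiotropy exclusion.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {sorted(SCENARIOS)}")
    return SimScenario(seed=seed, **SCENARIOS[name])


def simulate_aptamer_panel(
    scn: SimScenario, seed: int | None = None
) -> tuple[dict[str, tuple[SumStats, SumStats]], dict[str, GeneAnnotation], ReferencePanel]:
    """Multi-aptamer study: ``scn.n_aptamers`` proteins sharing causal variant 0.

    Every aptamer is driven by the same variant (index of the first
    configured cis causal) plus one aptamer-specific causal, so the
    shared variant ends up associated with all aptamers and must fall to
    the multi-aptamer exclusion when n_aptamers >= 5.
    """
    shared_idx, shared_q = scn.causal_cis[0]
    studies: dict[str, tuple[SumStats, SumStats]] = {}
    genes: dict[str, GeneAnnotation] = {}
    layout0 = make_layout(scn)
    panel = simulate_reference_panel(scn, layout0, seed)
    own_indices = [i for i, _ in scn.causal_cis[1:]] or [scn.n_variants - 2]
    for a in range(scn.n_aptamers):
        pid = f"APT{a+1}"
        layout = make_layout(scn, protein_id=pid, gene_symbol=f"GENE{a+1}")
        own = own_indices[a % len(own_indices)]
        effects = _effect_vector(scn, layout, ((shared_idx, shared_q), (own, 0.015)))
        sa, sb = simulate_protein_gwas(
            scn, layout, seed=seed, protein_label=pid, effects=effects, stream_offset=10 * (a + 1)
        )
        studies[pid] = (sa, sb)
        genes[pid] = layout.gene
    return studies, genes, panel


def oracle_harmonised_set(
    scn: SimScenario,
    exposure: SumStats,
    outcome: SumStats,
    layout: GenomeLayout | None = None,
):
    """Harmonised set built at the KNOWN causal variants (ground truth).

    Bypasses significance-based selection so estimator properties
    (unbiasedness, type-I error) can be measured free of winner's-curse
    conditioning; exposure effects are taken from a single study.
    """
    from .harmonise import HarmonisedRecord, HarmonisedSet, harmonise_pair

    layout = layout or make_layout(scn)
    hs = HarmonisedSet(protein_id=layout.gene.protein_id, outcome_label=outcome.trait_label)
    for idx, _q in scn.causal_cis:
        key = layout.keys[idx]
        rec, reason = harmonise_pair(exposure.records[key], outcome.records[key])
        if rec is not None:
            hs.records.append(
                HarmonisedRecord(
                    key=key, beta_exp=rec.beta_exp, se_exp=rec.se_exp,
                    beta_out=rec.beta_out, se_out=rec.se_out,
                )
            )
    return hs


@dataclass
class ScanDataset:
    """In-memory multi-protein dataset for an end-to-end scan."""

    studies: dict[str, tuple[SumStats, SumStats]]
    genes: dict[str, GeneAnnotation]
    outcomes: list[SumStats]
    panel: ReferencePanel
    causal_protein: str | None = None


def simulate_scan_dataset(
    n_proteins: int = 20,
    causal_protein_index: int = 7,
    theta: float = 0.3,
    seed: int = 0,
    n_variants_per_protein: int = 24,
    n_a: int = 5000,
    n_b: int = 5000,
    n_out: int = 20_000,
    n_panel: int = 10_000,
    outcome_label: str = "outcome",
) -> ScanDataset:
    """A small proteome: independent gene regions, one causal protein.

    Each protein occupies its own LD-independent region 10 Mb apart on
    one chromosome; only protein ``causal_protein_index`` affects the
    outcome (shared causal variants, effect ``theta``).  The outcome
    cohort is genotyped across all regions so that every protein's
    instruments can be looked up.
    """
    rng_master = np.random.default_rng([seed % (2**31), 99])
    studies: dict[str, tuple[SumStats, SumStats]] = {}
    genes: dict[str, GeneAnnotation] = {}
    layouts = []
    scns = []
    for i in range(n_proteins):
        scn = SimScenario(
            name=f"protein_{i}",
            n_variants=n_variants_per_protein,
            n_a=n_a,
            n_b=n_b,
            n_out=n_out,
            n_panel=n_panel,
            causal_cis=((2, 0.02), (10, 0.02), (18, 0.02)),
            theta=theta if i == causal_protein_index else 0.0,
            pos_start=1_000_000 + 10_000_000 * i,
            seed=int(rng_master.integers(2**31)),
        )
        layout = make_layout(scn, protein_id=f"P{i+1}", gene_symbol=f"GENE{i+1}")
        scns.append(scn)
        layouts.append(layout)
        genes[f"P{i+1}"] = layout.gene
        studies[f"P{i+1}"] = simulate_protein_gwas(scn, layout, protein_label=f"P{i+1}")

    # one panel and one outcome study spanning all regions
    panel_keys: list[str] = []
    panel_rows: list[np.ndarray] = []
    counted: list[str] = []
    out_ss = SumStats(study_label="OUT", trait_label=outcome_label, trait_type="quantitative")
    for scn, layout in zip(scns, layouts):
        pan = simulate_reference_panel(scn, layout)
        panel_keys.extend(pan.keys)
        panel_rows.append(pan.dosages)
        counted.extend(pan.counted_alleles)
        oc = simulate_outcome_gwas(scn, layout, outcome_label=outcome_label)
        out_ss.records.update(oc.records)
    panel = ReferencePanel(
        keys=panel_keys, dosages=np.vstack(panel_rows), counted_alleles=counted
    )
    return ScanDataset(
        studies=studies,
        genes=genes,
        outcomes=[out_ss],
        panel=panel,
        causal_protein=f"P{causal_protein_index+1}",
    )
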