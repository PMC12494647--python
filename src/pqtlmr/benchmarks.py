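"""Benchmark computations used by the acceptance checks.

Each function runs one of the package's calibration studies from
scratch on synthetic data and returns the measured quantity: estimator
oracle agreement, IVW type-I error, parameter recovery, colocalisation
scenario success rates, clump-oracle agreement, and end-to-end scan
determinism.  Seeds are derived from a single base seed so a whole
suite is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from .coloc import RegionStats, coloc_abf, log_abf
from .harmonise import HarmonisedRecord, HarmonisedSet
from .mr import egger, ivw, weighted_median
from .simulate import (
    SimScenario,
    make_layout,
    oracle_harmonised_set,
    scenario_library,
    simulate_outcome_gwas,
    simulate_protein_gwas,
)


def _hset(be, se_e, bo, so):
    hs = HarmonisedSet(protein_id="P", outcome_label="o")
    for i in range(len(be)):
        hs.records.append(
            HarmonisedRecord(
                key=f"1:{i}", beta_exp=float(be[i]), se_exp=float(se_e[i]),
                beta_out=float(bo[i]), se_out=float(so[i]),
            )
        )
    return hs


def estimator_oracle_max_error(n_instances: int = 100, seed: int = 0) -> float:
    """Worst absolute deviation of IVW/Egger from a WLS oracle.

    The oracle is ordinary weighted least squares (statsmodels) of
    beta_out on beta_exp with weights 1/se_out^2 — without the origin
    constraint for Egger, with it for IVW.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng([seed, 101])
    worst = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(4, 20))
        be = rng.uniform(0.05, 0.5, k)
        bo = rng.normal(0.2 * be + rng.normal(0, 0.02), 0.01)
        so = rng.uniform(0.005, 0.05, k)
        hs = _hset(be, np.full(k, 0.01), bo, so)
        w = 1.0 / so**2
        fit0 = sm.WLS(bo, be[:, None], weights=w).fit()
        r_ivw = ivw(hs)
        worst = max(worst, abs(r_ivw.estimate - float(fit0.params[0])))
        fit1 = sm.WLS(bo, sm.add_constant(be), weights=w).fit()
        r_egg = egger(hs)
        worst = max(worst, abs(r_egg.estimate - float(fit1.params[1])))
        worst = max(worst, abs(r_egg.egger_intercept - float(fit1.params[0])))
    return worst


def abf_quadrature_max_error() -> float:
    """Worst |log ABF - quadrature| over a 5x5x5 grid of (beta, se, prior_sd)."""
    worst = 0.0
    for beta in np.linspace(0.0, 0.4, 5):
        for se in np.linspace(0.01, 0.1, 5):
            for w in np.linspace(0.05, 0.3, 5):
                num, _ = integrate.quad(
                    lambda b: stats.norm.pdf(beta, b, se) * stats.norm.pdf(b, 0, w),
                    -12 * w, 12 * w, limit=300, epsabs=0.0, epsrel=1e-10,
                    points=(beta - 4 * se, beta, beta + 4 * se),
                )
                oracle = np.log(num) - stats.norm.logpdf(beta, 0, se)
                worst = max(worst, abs(log_abf(beta, se, w) - oracle))
    return worst


def ivw_type_i_error(n_proteins: int = 2000, alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical IVW rejection rate under the null scenario (theta = 0)."""
    rng = np.random.default_rng([seed, 202])
    rejected = 0
    for _ in range(n_proteins):
        scn = scenario_library("null", seed=int(rng.integers(2**31)))
        layout = make_layout(scn)
        sa, _sb = simulate_protein_gwas(scn, layout)
        out = simulate_outcome_gwas(scn, layout)
        hs = oracle_harmonised_set(scn, sa, out, layout)
        rejected += ivw(hs).pval < alpha
    return rejected / n_proteins


def ivw_recovery_mean(n_seeds: int = 500, seed: int = 0) -> float:
    """Mean IVW estimate under the theta = 0.3 recovery scenario."""
    rng = np.random.default_rng([seed, 303])
    ests = []
    for _ in range(n_seeds):
        scn = scenario_library("recovery", seed=int(rng.integers(2**31)))
        layout = make_layout(scn)
        sa, _sb = simulate_protein_gwas(scn, layout)
        out = simulate_outcome_gwas(scn, layout)
        ests.append(ivw(oracle_harmonised_set(scn, sa, out, layout)).estimate)
    return float(np.mean(ests))


def weighted_median_balanced_pleiotropy_mean(n_seeds: int = 500, seed: int = 0) -> float:
    """Mean weighted-median estimate under balanced pleiotropy, theta = 0.3."""
    rng = np.random.default_rng([seed, 404])
    ests = []
    for _ in range(n_seeds):
        scn = scenario_library("pleiotropy_balanced", seed=int(rng.integers(2**31)))
        layout = make_layout(scn)
        sa, _sb = simulate_protein_gwas(scn, layout)
        out = simulate_outcome_gwas(scn, layout)
        hs = oracle_harmonised_set(scn, sa, out, layout)
        ests.append(weighted_median(hs, n_boot=50, seed=1).estimate)
    return float(np.mean(ests))


def egger_intercept_recovery(n_snps: int = 50, delta: float = 0.03, seed: int = 0):
    """Egger intercept and its 3-se band under directional pleiotropy.

    Summary-level simulation: 50 instruments, true slope 0.3, constant
    directional pleiotropic effect delta on every instrument.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng([seed, 505])
    be = rng.uniform(0.1, 0.5, n_snps)
    so = np.full(n_snps, 0.02)
    bo = rng.normal(0.3 * be + delta, so)
    hs = _hset(be, np.full(n_snps, 0.01), bo, so)
    res = egger(hs)
    fit = sm.WLS(bo, sm.add_constant(be), weights=1.0 / so**2).fit()
    int_se = float(fit.bse[0]) / np.sqrt(fit.scale) * max(1.0, np.sqrt(fit.scale))
    return float(res.egger_intercept), float(int_se)


def coloc_scenario_success_rate(name: str, n_seeds: int = 50, seed: int = 0) -> float:
    """Fraction of seeds in which a coloc scenario produces its expected call.

    causal_shared -> PP(H4) > 0.8; causal_distinct -> PP(H3) > PP(H4);
    underpowered_outcome -> PP(H1) > 0.8.
    """
    rng = np.random.default_rng([seed, 606])
    hits = 0
    for _ in range(n_seeds):
        scn = scenario_library(name, seed=int(rng.integers(2**31)))
        layout = make_layout(scn)
        sa, _sb = simulate_protein_gwas(scn, layout)
        out = simulate_outcome_gwas(scn, layout)
        t1 = RegionStats(
            keys=layout.keys,
            beta=np.array([sa.records[k].beta for k in layout.keys]),
            se=np.array([sa.records[k].se for k in layout.keys]),
            trait_type="quantitative", n=scn.n_a,
        )
        t2 = RegionStats(
            keys=layout.keys,
            beta=np.array([out.records[k].beta for k in layout.keys]),
            se=np.array([out.records[k].se for k in layout.keys]),
            trait_type=out.trait_type, n=scn.n_out,
        )
        pp = coloc_abf(t1, t2).pp
        if name == "causal_shared":
            hits += pp["PP_H4"] > 0.8
        elif name == "causal_distinct":
            hits += pp["PP_H3"] > pp["PP_H4"]
        elif name == "underpowered_outcome":
            hits += pp["PP_H1"] > 0.8
        else:
            raise ValueError(f"no expected call defined for scenario {name!r}")
    return hits / n_seeds


def clump_oracle_agreement(n_draws: int = 500, seed: int = 0) -> float:
    """Fraction of random <=8-variant instances where greedy clumping
    satisfies the independent retained-set characterisation."""
    from .ld import LDMatrix, greedy_clump

    rng = np.random.default_rng([seed, 707])
    ok = 0
    for _ in range(n_draws):
        n = int(rng.integers(2, 9))
        r = np.eye(n)
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0, 0.99, len(iu[0]))
        r[iu] = vals
        r[(iu[1], iu[0])] = vals
        keys = [f"1:{100 + i}:A:G" for i in range(n)]
        ld = LDMatrix(keys=keys, r=r)
        pvals = rng.choice([1e-10, 1e-9, 1e-8, 1e-7], n)
        items = list(zip(keys, pvals))
        r2_max = float(rng.choice([0.001, 0.01, 0.1, 0.5]))
        retained = greedy_clump(items, ld, r2_max=r2_max)
        ok += _clump_definition_holds(items, ld, retained, r2_max)
    return ok / n_draws


def _clump_definition_holds(items, ld, retained, r2_max, window_kb=10_000) -> bool:
    order = {k: (p, k) for k, p in items}
    retained_set = set(retained)

    def conflicts(a, b):
        pa, pb = int(a.split(":")[1]), int(b.split(":")[1])
        same_chrom = a.split(":")[0] == b.split(":")[0]
        return same_chrom and abs(pa - pb) <= window_kb * 1000 and ld.r2(a, b) >= r2_max

    for k, _ in items:
        stronger = [r for r in retained_set if r != k and order[r] < order[k] and conflicts(r, k)]
        if (k in retained_set) == bool(stronger):
            return False
    return True


def multi_aptamer_exclusion_works(seed: int = 0) -> bool:
    """End-to-end: the shared five-aptamer pQTL is removed at the aptamer stage."""
    from .instruments import build_aptamer_map, build_instruments
    from .simulate import simulate_aptamer_panel

    scn = scenario_library("multi_aptamer", seed=seed)
    studies, genes, panel = simulate_aptamer_panel(scn)
    amap = build_aptamer_map(studies)
    shared_key = make_layout(scn).keys[scn.causal_cis[0][0]]
    if len(amap.get(shared_key, set())) < 5:
        return False
    for pid, (sa, sb) in studies.items():
        iset = build_instruments(sa, sb, genes[pid], panel, amap)
        if shared_key in {pq.key for pq in iset.all_instruments}:
            return False
        if iset.audit["lost_multi_aptamer"] < 1:
            return False
    return True


def scan_determinism(seed: int = 0, **sizes) -> bool:
    """Two scans with one seed produce byte-identical output files."""
    import filecmp
    import tempfile
    from pathlib import Path

    from .pipeline import run_scan, write_report
    from .simulate import simulate_scan_dataset

    digests = []
    with tempfile.TemporaryDirectory() as tmp:
        for run in ("r1", "r2"):
            ds = simulate_scan_dataset(seed=seed, **sizes)
            report = run_scan(ds.studies, ds.genes, ds.outcomes, ds.panel)
            outdir = Path(tmp) / run
            write_report(report, outdir)
            digests.append(
                {f.name: f.read_bytes() for f in sorted(outdir.iterdir())}
            )
    return digests[0] == digests[1]
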