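"""Two-sample MR estimators and heterogeneity diagnostics.

All estimators operate on harmonised (β_exposure, β_outcome) pairs.
The per-instrument causal estimate is the Wald ratio β_out/β_exp; with
several instruments the ratios are pooled by inverse-variance weighting
(weights β_exp²/se_out², i.e. first-order ratio variances), with
Cochran's Q as the heterogeneity diagnostic and a multiplicative
random-effects floor on the standard error (the fixed-effect SE is
inflated by sqrt(Q/df) when Q exceeds its degrees of freedom).

Method dispatch mirrors the instrument counts typical of cis-only
analyses: a single instrument admits only the Wald ratio; 2–5
instruments the IVW meta-analysis; 6 or more instruments additionally
the pleiotropy-robust sensitivity estimators (MR-Egger, weighted
median, simple and weighted mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonise import HarmonisedSet

METHODS = ("wald", "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")
DEFAULT_N_BOOT = 1000
SENSITIVITY_MIN_NSNP = 6  # full sensitivity suite requires nsnp > 5


@dataclass(frozen=True)
class MRResult:
    protein_id: str
    outcome_label: str
    method: str
    estimate: float
    se: float
    pval: float
    nsnp: int
    Q: float | None = None
    Q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.nsnp < 1:
            raise ValueError("nsnp must be >= 1")
        if self.se <= 0:
            raise ValueError("se must be positive")


def _normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _arrays(hs: HarmonisedSet):
    be = np.array([r.beta_exp for r in hs.records])
    se_e = np.array([r.se_exp for r in hs.records])
    bo = np.array([r.beta_out for r in hs.records])
    se_o = np.array([r.se_out for r in hs.records])
    return be, se_e, bo, se_o


def wald_ratio(hs: HarmonisedSet) -> MRResult:
    """Single-instrument causal estimate β_out/β_exp with first-order delta SE."""
    if len(hs) != 1:
        raise ValueError("wald_ratio requires exactly one harmonised record")
    r = hs.records[0]
    if r.beta_exp == 0:
        raise ValueError("wald_ratio undefined for zero exposure effect")
    est = r.beta_out / r.beta_exp
    se = r.se_out / abs(r.beta_exp)
    return MRResult(hs.protein_id, hs.outcome_label, "wald", est, se, _normal_p(est / se), 1)


def ivw(hs: HarmonisedSet) -> MRResult:
    """Inverse-variance-weighted meta-analysis of the per-instrument ratios.

    Equivalent to weighted least squares of β_out on β_exp through the
    origin with weights 1/se_out².  Q is Cochran's heterogeneity
    statistic on nsnp−1 df; the SE uses a multiplicative random-effects
    floor max(1, sqrt(Q/df)).
    """
    k = len(hs)
    if k < 2:
        raise ValueError("ivw requires at least two instruments")
    be, _, bo, se_o = _arrays(hs)
    ratios = bo / be
    w = be**2 / se_o**2
    est = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    Q = float(np.sum(w * (ratios - est) ** 2))
    df = k - 1
    se = se_fixed * max(1.0, np.sqrt(Q / df))
    return MRResult(
        hs.protein_id, hs.outcome_label, "ivw", est, se, _normal_p(est / se), k,
        Q=Q, Q_pval=float(stats.chi2.sf(Q, df)),
    )


def egger(hs: HarmonisedSet) -> MRResult:
    """MR-Egger: weighted regression of β_out on β_exp with a free intercept.

    The intercept estimates the average directional pleiotropic effect;
    the slope is the pleiotropy-adjusted causal estimate.  SEs carry the
    same multiplicative residual floor as IVW; p-values use a t
    distribution on nsnp−2 df.
    """
    k = len(hs)
    if k < 3:
        raise ValueError("egger requires at least three instruments")
    be, _, bo, se_o = _arrays(hs)
    w = 1.0 / se_o**2
    X = np.column_stack([np.ones(k), be])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * bo)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = bo - X @ coef
    df = k - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    cov_fixed = np.linalg.inv(XtWX)
    scale = max(1.0, np.sqrt(sigma2))
    se_int, se_slope = np.sqrt(np.diag(cov_fixed)) * scale
    slope, intercept = float(coef[1]), float(coef[0])
    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(slope / se_slope), df)))
    p_int = float(min(1.0, 2.0 * stats.t.sf(abs(intercept / se_int), df)))
    Q = float(np.sum(w * resid**2))
    return MRResult(
        hs.protein_id, hs.outcome_label, "egger", slope, float(se_slope), p_slope, k,
        Q=Q, Q_pval=float(stats.chi2.sf(Q, df)),
        egger_intercept=intercept, egger_intercept_p=p_int,
    )


def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = np.where(s < 0.5)[0]
    if len(below) == 0:
        return float(r[0])
    i = below[-1]
    if i == len(r) - 1:
        return float(r[-1])
    # linear interpolation between the bracketing order statistics
    return float(r[i] + (r[i + 1] - r[i]) * (0.5 - s[i]) / (s[i + 1] - s[i]))


def _boot_se(hs: HarmonisedSet, estimator, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample both betas from their sampling normals."""
    rng = np.random.default_rng(seed)
    be, se_e, bo, se_o = _arrays(hs)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(bo, se_o)
        ests[b] = estimator(be_s, bo_s, se_o)
    return float(ests.std(ddof=1))


def weighted_median(
    hs: HarmonisedSet, n_boot: int = DEFAULT_N_BOOT, seed: int = 20240601
) -> MRResult:
    """Weighted median of the ratio estimates.

    Consistent as long as instruments holding at least half the weight
    are valid.  SE by parametric bootstrap with a fixed seed.
    """
    k = len(hs)
    if k < 3:
        raise ValueError("weighted_median requires at least three instruments")
    be, _, bo, se_o = _arrays(hs)
    est = _weighted_median(bo / be, be**2 / se_o**2)
    se = _boot_se(
        hs, lambda b_e, b_o, s_o: _weighted_median(b_o / b_e, b_e**2 / s_o**2), n_boot, seed
    )
    return MRResult(
        hs.protein_id, hs.outcome_label, "weighted_median", est, se, _normal_p(est / se), k
    )


def _mode_point(ratios: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of a weighted Gaussian KDE of the ratios on a 512-point grid."""
    k = len(ratios)
    s = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    scale = min(s, mad) if mad > 0 else s
    if scale == 0:
        return float(ratios[0])
    h = phi * 0.9 * scale * k ** (-1 / 5)
    lo, hi = ratios.min(), ratios.max()
    grid = np.linspace(lo, hi, 512) if hi > lo else np.array([lo])
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2), axis=0
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    hs: HarmonisedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 20240601,
) -> MRResult:
    """Mode-based estimate: the most common ratio under a smoothed density.

    Simple mode weights all instruments equally; weighted mode uses the
    IVW weights.  The bandwidth is ``phi`` times a modified-Silverman
    scale of the ratios.  Consistent when the largest group of
    instruments sharing a ratio is valid (ZEMPA assumption).
    """
    k = len(hs)
    if k < 3:
        raise ValueError("mode_estimate requires at least three instruments")
    be, _, bo, se_o = _arrays(hs)

    def point(b_e, b_o, s_o):
        wts = b_e**2 / s_o**2 if weighted else np.ones(len(b_e))
        return _mode_point(b_o / b_e, wts, phi)

    est = point(be, bo, se_o)
    se = _boot_se(hs, point, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return MRResult(hs.protein_id, hs.outcome_label, method, est, se, _normal_p(est / se), k)


def run_mr(
    hs: HarmonisedSet, n_boot: int = DEFAULT_N_BOOT, seed: int = 20240601
) -> list[MRResult]:
    """nsnp-conditional dispatch over the estimator suite.

    1 instrument → Wald ratio; 2–5 → IVW with Cochran's Q; ≥6 → IVW plus
    MR-Egger, weighted median, and simple/weighted mode sensitivity
    analyses.
    """
    k = len(hs)
    if k == 0:
        raise ValueError("run_mr: no harmonised instruments")
    if k == 1:
        return [wald_ratio(hs)]
    results = [ivw(hs)]
    if k >= SENSITIVITY_MIN_NSNP:
        results.append(egger(hs))
        results.append(weighted_median(hs, n_boot=n_boot, seed=seed))
        results.append(mode_estimate(hs, weighted=False, n_boot=n_boot, seed=seed))
        results.append(mode_estimate(hs, weighted=True, n_boot=n_boot, seed=seed))
    return results
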