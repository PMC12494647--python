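"""Bayesian colocalisation and SuSiE summary-statistics fine-mapping.

Colocalisation asks whether the protein and the outcome association
signals in a region are driven by the same causal variant.  Each
variant's evidence of association is summarised by a Wakefield
approximate Bayes factor (ABF) computed from (β, se) and a normal prior
on the true effect; the five hypotheses

    H0 neither trait associated        H1 only trait 1
    H2 only trait 2                    H3 both, different causal variants
    H4 both, shared causal variant

get posterior probabilities from sums of ABF products weighted by the
per-variant priors p1, p2 and the shared prior p12.  All sums are in
log space — ABFs overflow double precision beyond |z| ≈ 40.

The single-causal-variant assumption of that computation is relaxed by
first fine-mapping each trait with a Sum of Single Effects (SuSiE)
regression on summary statistics, then colocalising every pair of
credible sets using the per-effect single-effect Bayes factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .ld import LDMatrix

PRIOR_P1 = 1e-4
PRIOR_P2 = 1e-4
PRIOR_P12 = 1e-5
PRIOR_SD_QUANT = 0.15
PRIOR_SD_BINARY = 0.2
HYPOTHESES = ("PP_H0", "PP_H1", "PP_H2", "PP_H3", "PP_H4")


@dataclass
class RegionStats:
    """Per-variant association statistics for one trait over a region."""

    keys: list[str]
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quantitative"
    n: int | None = None
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.keys) == len(self.beta) == len(self.se)):
            raise ValueError("RegionStats vectors must have equal length")
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def prior_sd(self) -> float:
        return PRIOR_SD_BINARY if self.trait_type == "binary" else PRIOR_SD_QUANT


@dataclass
class ColocResult:
    pp: dict[str, float]
    n_variants: int
    priors: tuple[float, float, float]
    cs1_label: str | None = None
    cs2_label: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        assert abs(total - 1.0) < 1e-9, f"posterior probabilities sum to {total}"

    @property
    def best(self) -> str:
        return max(self.pp, key=self.pp.get)


@dataclass
class CredibleSet:
    keys: list[str]
    coverage: float
    purity: float
    pip: dict[str, float]
    effect_index: int


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log Wakefield approximate Bayes factor for association at one variant.

    With V = se², W = prior_sd² and z = beta/se, the marginal likelihood
    ratio of association against the null is
    sqrt(V/(V+W)) · exp(z²W/(2(V+W))); its log is written via the
    shrinkage factor r = W/(V+W) as 0.5·[log(1−r) + r·z²].
    """
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be positive")
    if np.any(np.asarray(prior_sd) <= 0):
        raise ValueError("prior_sd must be positive")
    V = np.asarray(se, dtype=float) ** 2
    W = float(prior_sd) ** 2
    z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
    r = W / (V + W)
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if np.isscalar(beta) else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf if not positive."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def _coloc_from_labf(
    l1: np.ndarray,
    l2: np.ndarray,
    p1: float,
    p2: float,
    p12: float,
    n_variants: int,
) -> dict[str, float]:
    """Hypothesis posteriors from per-variant log Bayes factors (log space)."""
    log_s1 = float(logsumexp(l1))
    log_s2 = float(logsumexp(l2))
    log_s4 = float(logsumexp(l1 + l2))
    # S3 = S1*S2 - S4 (sum over ordered pairs i != j)
    log_s3 = _log_diff_exp(log_s1 + log_s2, log_s4)
    logpost = np.array(
        [
            0.0,
            np.log(p1) + log_s1,
            np.log(p2) + log_s2,
            np.log(p1) + np.log(p2) + log_s3,
            np.log(p12) + log_s4,
        ]
    )
    pp = np.exp(logpost - logsumexp(logpost))
    pp /= pp.sum()
    return dict(zip(HYPOTHESES, pp.tolist()))


def coloc_abf(
    t1: RegionStats,
    t2: RegionStats,
    p1: float = PRIOR_P1,
    p2: float = PRIOR_P2,
    p12: float = PRIOR_P12,
) -> ColocResult:
    """Single-causal-variant colocalisation of two traits over one region.

    Both traits must supply statistics for the identical ordered variant
    list.  Effect-size prior SDs: 0.15 for quantitative traits (SD
    units), 0.2 for binary traits (log-odds).
    """
    if t1.keys != t2.keys:
        raise ValueError("coloc_abf: variant lists differ between traits")
    l1 = log_abf(t1.beta, t1.se, t1.prior_sd)
    l2 = log_abf(t2.beta, t2.se, t2.prior_sd)
    pp = _coloc_from_labf(np.asarray(l1), np.asarray(l2), p1, p2, p12, len(t1.keys))
    return ColocResult(pp=pp, n_variants=len(t1.keys), priors=(p1, p2, p12))


# ---------------------------------------------------------------------------
# SuSiE on summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SusieFit:
    keys: list[str]
    alpha: np.ndarray  # L x p posterior inclusion per effect
    lbf_variable: np.ndarray  # L x p per-variant single-effect log BFs
    prior_variance: np.ndarray  # length L
    credible_sets: list[CredibleSet] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def pip(self) -> np.ndarray:
        return 1.0 - np.prod(1.0 - self.alpha, axis=0)


def _single_effect_lbf(bhat: np.ndarray, shat2: np.ndarray, V: float) -> np.ndarray:
    z2 = bhat**2 / shat2
    r = V / (V + shat2)
    return 0.5 * (np.log1p(-r) + r * z2)


def _optimize_prior_variance(bhat, shat2, log_pi, v_init: float) -> float:
    """Per-effect ML estimate of the prior effect variance, lower bound 0."""

    def neg_loglik(lnV):
        lbf = _single_effect_lbf(bhat, shat2, np.exp(lnV))
        return -float(logsumexp(lbf + log_pi))

    res = minimize_scalar(neg_loglik, bounds=(np.log(1e-8), np.log(1e4)), method="bounded")
    v_opt = float(np.exp(res.x))
    # the null (V -> 0) has loglik 0; keep V only if it improves on it
    if -res.fun <= 0.0:
        return 0.0
    return v_opt


def susie_rss(
    z: np.ndarray,
    R: LDMatrix,
    n: int,
    L: int = 10,
    coverage: float = 0.95,
    min_purity: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-3,
    keys: list[str] | None = None,
) -> SusieFit:
    """SuSiE fine-mapping from z-scores and a reference LD matrix.

    Iterative Bayesian stepwise selection (IBSS): the effect vector is a
    sum of L single effects, each placing posterior mass over variants.
    Works on the standardized (z-score) scale with residual variance
    fixed at 1.  Credible sets are the smallest variant sets reaching
    the coverage target per effect, discarded when purity (minimum
    absolute pairwise LD within the set) falls below ``min_purity``.
    """
    z = np.asarray(z, dtype=float)
    p = len(z)
    Rm = np.asarray(R.r, dtype=float)
    if Rm.shape != (p, p):
        raise ValueError("LD matrix dimensions do not match z")
    if keys is None:
        keys = list(R.keys)
    # guard against slightly non-PSD reference correlation matrices
    Rm = Rm + 1e-6 * np.eye(p)

    # sufficient statistics on the standardized scale
    d = np.full(p, float(n - 1))  # diag(X'X) for standardized X
    Xty = np.sqrt(n - 1) * z
    XtX = (n - 1) * Rm
    log_pi = np.log(np.full(p, 1.0 / p))

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    V = np.full(L, 0.2)
    lbf_var = np.zeros((L, p))
    Xr = np.zeros(p)  # XtX @ (sum_l alpha_l * mu_l)
    for l in range(L):
        Xr += XtX @ (alpha[l] * mu[l])

    converged = False
    it = 0
    prev_fitted = np.zeros(p)
    for it in range(1, max_iter + 1):
        for l in range(L):
            b_l = alpha[l] * mu[l]
            Xr -= XtX @ b_l
            r_l = Xty - Xr
            bhat = r_l / d
            shat2 = 1.0 / d
            V[l] = _optimize_prior_variance(bhat, shat2, log_pi, V[l])
            if V[l] == 0.0:
                lbf = np.zeros(p)
                alpha[l] = np.exp(log_pi)
                mu[l] = 0.0
            else:
                lbf = _single_effect_lbf(bhat, shat2, V[l])
                w = lbf + log_pi
                alpha[l] = np.exp(w - logsumexp(w))
                post_var = 1.0 / (1.0 / V[l] + d)
                mu[l] = post_var * d * bhat
            lbf_var[l] = lbf
            Xr += XtX @ (alpha[l] * mu[l])
        fitted = np.sum(alpha * mu, axis=0)
        if np.max(np.abs(fitted - prev_fitted)) < tol:
            converged = True
            break
        prev_fitted = fitted

    fit = SusieFit(
        keys=keys, alpha=alpha, lbf_variable=lbf_var, prior_variance=V,
        converged=converged, n_iter=it,
    )
    fit.credible_sets = _credible_sets(fit, Rm, coverage, min_purity)
    return fit


def _credible_sets(fit: SusieFit, Rm: np.ndarray, coverage: float, min_purity: float):
    sets: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for l in range(fit.alpha.shape[0]):
        if fit.prior_variance[l] == 0.0:
            continue
        order = np.argsort(-fit.alpha[l], kind="stable")
        csum = np.cumsum(fit.alpha[l][order])
        size = int(np.searchsorted(csum, coverage) + 1)
        size = min(size, len(order))
        idx = order[:size]
        achieved = float(csum[size - 1])
        if achieved < coverage:
            continue
        sub = np.abs(Rm[np.ix_(idx, idx)])
        purity = float(sub.min()) if len(idx) > 1 else 1.0
        if purity < min_purity:
            continue
        ks = frozenset(idx.tolist())
        if ks in seen:
            continue
        seen.add(ks)
        sets.append(
            CredibleSet(
                keys=[fit.keys[i] for i in idx],
                coverage=achieved,
                purity=purity,
                pip={fit.keys[i]: float(fit.alpha[l][i]) for i in idx},
                effect_index=l,
            )
        )
    return sets


def coloc_susie(
    fit1: SusieFit,
    fit2: SusieFit,
    p1: float = PRIOR_P1,
    p2: float = PRIOR_P2,
    p12: float = PRIOR_P12,
) -> list[ColocResult]:
    """Colocalise every pair of surviving credible sets between two traits.

    Uses each effect's per-variant single-effect log Bayes factors in the
    five-hypothesis sums, one result per (trait-1 effect, trait-2 effect)
    pair.  Both traits must be fine-mapped on the identical variant list.
    """
    if fit1.keys != fit2.keys:
        raise ValueError("coloc_susie: variant lists differ between fits")
    results: list[ColocResult] = []
    for cs1 in fit1.credible_sets:
        for cs2 in fit2.credible_sets:
            l1 = fit1.lbf_variable[cs1.effect_index]
            l2 = fit2.lbf_variable[cs2.effect_index]
            pp = _coloc_from_labf(l1, l2, p1, p2, p12, len(fit1.keys))
            results.append(
                ColocResult(
                    pp=pp,
                    n_variants=len(fit1.keys),
                    priors=(p1, p2, p12),
                    cs1_label=f"L{cs1.effect_index}",
                    cs2_label=f"L{cs2.effect_index}",
                )
            )
    return results


def evidence_call(results: list[ColocResult], pp_threshold: float = 0.8) -> str:
    """Three-way evidence call over a set of colocalisation results.

    "H4_shared" when any result supports a shared causal variant above
    the threshold; "H1_underpowered" when the protein signal is present
    but the outcome is too weak to colocalise; otherwise "other".
    """
    if any(r.pp["PP_H4"] > pp_threshold for r in results):
        return "H4_shared"
    if any(r.pp["PP_H1"] > pp_threshold for r in results):
        return "H1_underpowered"
    return "other"
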