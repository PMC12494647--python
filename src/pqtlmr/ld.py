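"""LD reference panel, greedy clumping and proxy lookup.

LD is always computed from a user-supplied reference panel of dosages
(variants x samples, values in [0, 2]), never from the GWAS cohorts —
the two-sample design gives no access to individual-level data.  The
panel stores, per variant, which allele the dosage counts, so that
correlations carry the sign appropriate to each record's effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LDMatrix:
    """Square allelic-correlation matrix r over an ordered variant list."""

    keys: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.index = {k: i for i, k in enumerate(self.keys)}
        if self.r.shape != (len(self.keys), len(self.keys)):
            raise ValueError("LD matrix shape does not match variant list")

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self.index[a], self.index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.corr(a, b) ** 2


@dataclass
class ReferencePanel:
    """Dosage matrix for LD computation.

    ``dosages`` is variants x samples; ``counted_alleles[i]`` is the
    allele whose copies ``dosages[i]`` counts.  Zero-variance variants
    are rejected at construction — they carry no LD information.
    """

    keys: list[str]
    dosages: np.ndarray
    counted_alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate variant keys in reference panel")
        if self.dosages.shape[0] != len(self.keys):
            raise ValueError("dosage row count does not match variant list")
        var = self.dosages.var(axis=1)
        if np.any(var == 0):
            bad = [k for k, v in zip(self.keys, var) if v == 0]
            raise ValueError(f"zero-variance variant(s) in panel: {bad[:5]}")
        if not self.counted_alleles:
            # fall back: count the lexicographically first allele of the key
            self.counted_alleles = [k.split(":")[2] for k in self.keys]
        self.index = {k: i for i, k in enumerate(self.keys)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, key: str) -> bool:
        return key in self.index

    @classmethod
    def from_table(cls, path) -> "ReferencePanel":
        """Read a delimited dosage matrix: first column ``key`` (chrom:pos:a1:a2),
        optional second column ``counted_allele``, remaining columns samples."""
        df = pd.read_csv(path, sep=r"\s+")
        first = df.columns[0]
        keys = df[first].astype(str).tolist()
        if df.columns[1] == "counted_allele":
            counted = df["counted_allele"].astype(str).tolist()
            mat = df.iloc[:, 2:].to_numpy(dtype=float)
        else:
            counted = []
            mat = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(keys=keys, dosages=mat, counted_alleles=counted)

    def to_table(self, path) -> None:
        cols = {"key": self.keys, "counted_allele": self.counted_alleles}
        df = pd.DataFrame(cols)
        mat = pd.DataFrame(
            self.dosages, columns=[f"S{i}" for i in range(self.n_samples)]
        )
        pd.concat([df, mat], axis=1).to_csv(path, sep="\t", index=False)


def ld_corr(panel: ReferencePanel, variants: list[str]) -> LDMatrix:
    """Pearson correlation of dosages for the requested variants.

    The sign convention follows the panel's counted alleles; flipping the
    counted allele of one variant flips the sign of its correlations.
    """
    rows = []
    for k in variants:
        if k not in panel.index:
            raise KeyError(f"variant {k!r} absent from reference panel")
        rows.append(panel.index[k])
    sub = panel.dosages[rows]
    r = np.corrcoef(sub)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(keys=list(variants), r=np.clip(r, -1.0, 1.0))


def _pos_of(key: str) -> tuple[str, int]:
    chrom, pos = key.split(":")[:2]
    return chrom, int(pos)


def greedy_clump(
    assocs,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> list[str]:
    """Greedy LD clumping: keep index SNPs, discard correlated neighbours.

    ``assocs`` is a list of (key, pval) pairs or VariantAssoc-bearing
    tuples; sorted by ascending p (ties by key) internally.  Iteratively
    retain the most significant remaining variant and discard all
    remaining variants on the same chromosome within ``window_kb`` having
    r² >= ``r2_max`` with it.  Retained keys come back in retention order.
    """
    items = sorted(assocs, key=lambda kp: (kp[1], kp[0]))
    remaining = [k for k, _ in items]
    retained: list[str] = []
    window_bp = window_kb * 1000
    while remaining:
        lead = remaining.pop(0)
        retained.append(lead)
        lc, lp = _pos_of(lead)
        keep = []
        for k in remaining:
            c, p = _pos_of(k)
            if c == lc and abs(p - lp) <= window_bp and ld.r2(lead, k) >= r2_max:
                continue
            keep.append(k)
        remaining = keep
    return retained


def find_proxy(
    target: str,
    candidates: list[str],
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> str | None:
    """Best LD proxy for a variant missing from the outcome.

    Returns the candidate with the highest r² to ``target`` among those
    with r² strictly greater than ``r2_min`` (the replacement must tag
    essentially the same signal); ties broken by smaller genomic distance
    then lexicographic key.  None when no candidate qualifies.
    """
    if target not in ld.index:
        raise KeyError(f"proxy target {target!r} absent from LD matrix")
    tc, tp = _pos_of(target)
    best: tuple[float, int, str] | None = None
    for cand in candidates:
        if cand == target:
            continue
        r2 = ld.r2(target, cand)
        if r2 <= r2_min:
            continue
        cc, cp = _pos_of(cand)
        dist = abs(cp - tp) if cc == tc else 10**12
        score = (-r2, dist, cand)
        if best is None or score < best:
            best = score
    return best[2] if best else None
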