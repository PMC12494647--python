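"""GWAS summary-statistics I/O and the variant/allele model.

Every other module builds on the types defined here: a single-study
association record (:class:`VariantAssoc`), a study-level container
(:class:`SumStats`) and a gene annotation used for cis/trans
classification.  Variant identity is positional — ``chrom:pos`` plus the
lexicographically sorted allele pair — so the same site matched across
studies yields the same key regardless of which allele each study calls
the effect allele.  rsIDs are carried as labels only.

Input tables are whitespace- or tab-delimited text with a header
(gzip-transparent, via pandas).  Only biallelic SNPs over {A,C,G,T} are
accepted; indels and malformed rows are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: complementary-strand base mapping
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names expected in input tables
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

#: ambiguity window around EAF 0.5 for palindromic SNPs
DEFAULT_MAF_WINDOW = 0.08


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association record in one study.

    ``beta`` is the per-allele effect of ``effect_allele`` (SD units for
    quantitative traits, log-odds for binary).  ``eaf`` and ``n`` may be
    missing (None).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def is_valid(self) -> bool:
        if self.effect_allele not in VALID_ALLELES:
            return False
        if self.other_allele not in VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (np.isfinite(self.beta) and np.isfinite(self.se) and self.se > 0):
            return False
        if not (0.0 < self.pval <= 1.0):
            return False
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return False
        if self.n is not None and self.n <= 0:
            return False
        return True

    def flipped(self) -> "VariantAssoc":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


def variant_key(v: VariantAssoc) -> str:
    """Positional variant key ``chrom:pos:a1:a2`` with sorted alleles.

    Invariant under swapping effect/other alleles, so records of the same
    site from different studies share a key.
    """
    a1, a2 = sorted((v.effect_allele, v.other_allele))
    return f"{v.chrom}:{v.pos}:{a1}:{a2}"


def make_key(chrom: str, pos: int, a: str, b: str) -> str:
    a1, a2 = sorted((a, b))
    return f"{chrom}:{pos}:{a1}:{a2}"


def is_palindromic(v: VariantAssoc) -> bool:
    """A/T or C/G variant: strand cannot be resolved from alleles alone."""
    return {v.effect_allele, v.other_allele} in ({"A", "T"}, {"C", "G"})


def is_ambiguous_palindromic(v: VariantAssoc, maf_window: float = DEFAULT_MAF_WINDOW) -> bool:
    """True iff the variant is palindromic and its frequency cannot resolve strand.

    A palindromic SNP is ambiguous when its effect-allele frequency lies
    within ``maf_window`` of 0.5 (or is missing entirely).  With the
    default window 0.08, palindromes with MAF in (0.42, 0.5] are dropped.
    """
    if not is_palindromic(v):
        return False
    if v.eaf is None:
        return True
    return abs(v.eaf - 0.5) < maf_window


@dataclass
class SumStats:
    """One study's summary statistics, keyed positionally."""

    study_label: str
    trait_label: str
    trait_type: str  # "quantitative" | "binary"
    records: dict[str, VariantAssoc] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {self.trait_type!r}")

    def add(self, v: VariantAssoc) -> None:
        self.records[variant_key(v)] = v

    def get(self, key: str) -> VariantAssoc | None:
        return self.records.get(key)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: str) -> bool:
        return key in self.records


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic interval of the protein-encoding gene for one aptamer."""

    protein_id: str
    gene_symbol: str
    chrom: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(
                f"{self.protein_id}: gene_start {self.gene_start} > gene_end {self.gene_end}"
            )


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    study_label: str = "",
    trait_label: str = "",
    trait_type: str = "quantitative",
) -> SumStats:
    """Read a delimited summary-statistics table into a validated SumStats.

    ``column_map`` maps field names (keys of :data:`DEFAULT_COLUMN_MAP`)
    to column names in the file; unmapped fields use the defaults.  Rows
    violating record invariants (bad alleles, se<=0, p outside (0,1],
    indels) are dropped and counted in the log.  ``eaf`` and ``n`` columns
    are optional.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+")
    if df.empty:
        raise ValueError(f"{path}: empty summary-statistics file")
    mandatory = ["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval"]
    for fieldname in mandatory:
        if cmap[fieldname] not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {cmap[fieldname]!r}")
    has_id = cmap["variant_id"] in df.columns
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns

    ss = SumStats(study_label=study_label, trait_label=trait_label, trait_type=trait_type)
    n_dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        eaf = float(d[cmap["eaf"]]) if has_eaf and pd.notna(d[cmap["eaf"]]) else None
        n = int(d[cmap["n"]]) if has_n and pd.notna(d[cmap["n"]]) else None
        try:
            v = VariantAssoc(
                variant_id=str(d[cmap["variant_id"]]) if has_id else "",
                chrom=str(d[cmap["chrom"]]),
                pos=int(d[cmap["pos"]]),
                effect_allele=str(d[cmap["effect_allele"]]).upper(),
                other_allele=str(d[cmap["other_allele"]]).upper(),
                beta=float(d[cmap["beta"]]),
                se=float(d[cmap["se"]]),
                pval=float(d[cmap["pval"]]),
                eaf=eaf,
                n=n,
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not v.is_valid():
            n_dropped += 1
            continue
        ss.add(v)
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    return ss


def write_results_table(
    rows: Iterable[Mapping],
    path,
    sort_by: Sequence[str] | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records as a deterministic TSV.

    Rows are sorted by ``protein_id``, ``outcome_label`` (when present)
    then ``method``/remaining string columns so shuffled input yields a
    byte-identical file.  Floats are rendered with 6 significant digits.
    Empty ``rows`` with ``columns`` given produces a header-only file.
    """
    rows = list(rows)
    df = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    if sort_by is None:
        preferred = [c for c in ("protein_id", "outcome_label", "method", "key") if c in df.columns]
        sort_by = preferred or list(df.columns[:1])
    if len(df) and sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)

    def fmt(x):
        if isinstance(x, (float, np.floating)):
            if np.isnan(x):
                return "NA"
            return f"{x:.6g}"
        if x is None:
            return "NA"
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(fmt(x) for x in row) + "\n")


def write_sumstats(ss: SumStats, path, protein_id: str | None = None) -> None:
    """Write a SumStats back to the default tab-delimited column layout."""
    rows = []
    for key in sorted(ss.records):
        v = ss.records[key]
        row = {
            "SNP": v.variant_id or key,
            "CHR": v.chrom,
            "POS": v.pos,
            "EA": v.effect_allele,
            "OA": v.other_allele,
            "EAF": "NA" if v.eaf is None else f"{v.eaf:.6g}",
            "BETA": f"{v.beta:.6g}",
            "SE": f"{v.se:.6g}",
            "P": f"{v.pval:.6g}",
            "N": "NA" if v.n is None else v.n,
        }
        if protein_id is not None:
            row = {"protein_id": protein_id, **row}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_stacked_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    study_label: str = "",
    trait_type: str = "quantitative",
    protein_col: str = "protein_id",
) -> dict[str, SumStats]:
    """Read a stacked per-protein table (protein_id column) into SumStats per protein."""
    df = pd.read_csv(path, sep=r"\s+")
    if protein_col not in df.columns:
        raise ValueError(f"{path}: missing protein column {protein_col!r}")
    out: dict[str, SumStats] = {}
    import io

    for pid, sub in df.groupby(protein_col, sort=True):
        buf = io.StringIO()
        sub.drop(columns=[protein_col]).to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        out[str(pid)] = read_sumstats(
            buf, column_map, study_label=study_label, trait_label=str(pid), trait_type=trait_type
        )
    return out


def read_gene_annotations(path) -> dict[str, GeneAnnotation]:
    """Read a gene-annotation table keyed by protein (aptamer) id.

    Expected columns: protein_id, gene_symbol, chrom, gene_start, gene_end.
    """
    df = pd.read_csv(path, sep=r"\s+")
    needed = {"protein_id", "gene_symbol", "chrom", "gene_start", "gene_end"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        g = GeneAnnotation(
            protein_id=str(row.protein_id),
            gene_symbol=str(row.gene_symbol),
            chrom=str(row.chrom),
            gene_start=int(row.gene_start),
            gene_end=int(row.gene_end),
        )
        out[g.protein_id] = g
    return out
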