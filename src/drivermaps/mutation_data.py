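"""Mutation input handling: MAF-like parsing, site tables, count aggregation.

The coordinate system of the whole model is the *site table*: one row per
possible single-nucleotide change, i.e. three rows (one per alternate
allele) for every sufficiently covered coding position.  Observed somatic
mutations are aggregated across samples onto this table to give the count
vector ``Y_it`` that all downstream likelihoods consume.

Conventions: 1-based inclusive positions (MAF style), all alleles on the
reference plus strand, CpG context taken from the reference flanking bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Nine mutation types, pyrimidine-strand centric.  C>X classes are split by
#: CpG context (reference C immediately followed by G on the pyrimidine
#: strand); T>X classes are not context-split.
MUTATION_TYPE_LABELS = {
    1: "CpG C>T",
    2: "CpG C>A",
    3: "CpG C>G",
    4: "C>T",
    5: "C>A",
    6: "C>G",
    7: "T>A",
    8: "T>C",
    9: "T>G",
}
N_MUTATION_TYPES = 9

REQUIRED_MAF_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


class FormatError(ValueError):
    """Malformed input file (missing columns, bad alleles, ...)."""


def _check_base(b: str, name: str) -> str:
    if not isinstance(b, str) or len(b) != 1 or b.upper() not in BASES:
        raise ValueError(f"{name} must be a single base A/C/G/T, got {b!r}")
    return b.upper()


def classify_mutation_type(ref: str, alt: str, context5: str, context3: str) -> int:
    """Classify a single-nucleotide change into one of 9 mutation types.

    Purine-reference changes are reverse-complemented onto the pyrimidine
    strand first (ref/alt complemented, 5'/3' flanks swapped and
    complemented), so the classification is strand symmetric.
    """
    ref = _check_base(ref, "ref")
    alt = _check_base(alt, "alt")
    context5 = _check_base(context5, "context5")
    context3 = _check_base(context3, "context3")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMP[ref], _COMP[alt]
        context5, context3 = _COMP[context3], _COMP[context5]
    if ref == "C":
        cpg = context3 == "G"
        base_idx = {"T": 0, "A": 1, "G": 2}[alt]
        return (1 + base_idx) if cpg else (4 + base_idx)
    # ref == "T"
    return {"A": 7, "C": 8, "G": 9}[alt]


def _build_type_table() -> np.ndarray:
    """192-entry lookup: type index by (ref, alt, c5, c3) base codes; 0 invalid."""
    tab = np.zeros((4, 4, 4, 4), dtype=np.int8)
    for ir, ref in enumerate(BASES):
        for ia, alt in enumerate(BASES):
            if ref == alt:
                continue
            for i5, c5 in enumerate(BASES):
                for i3, c3 in enumerate(BASES):
                    tab[ir, ia, i5, i3] = classify_mutation_type(ref, alt, c5, c3)
    return tab


_TYPE_TABLE = _build_type_table()
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def classify_mutation_types_vec(ref, alt, context5, context3) -> np.ndarray:
    """Vectorised :func:`classify_mutation_type` over base arrays."""
    code = lambda arr: np.array([_BASE_CODE[b] for b in arr], dtype=np.int8)
    return _TYPE_TABLE[code(ref), code(alt), code(context5), code(context3)].astype(int)


@dataclass
class MutationRecord:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        self.ref = _check_base(self.ref, "ref")
        self.alt = _check_base(self.alt, "alt")
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")


@dataclass
class SampleReport:
    """Per-sample SNV counts and hypermutator filtering outcome."""

    table: pd.DataFrame  # columns: sample_id, n_snv, status ("kept"/"dropped")
    threshold: float
    n_skipped_non_snv: int = 0

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def hypermutator_threshold(per_sample_counts: pd.Series, k: float = 3.0) -> float:
    """'auto' rule: threshold = expm1(mean + k*SD) of log1p per-sample counts."""
    x = np.log1p(per_sample_counts.to_numpy(dtype=float))
    return float(np.expm1(x.mean() + k * x.std(ddof=0)))


def load_mutations(path, hypermutator_max="auto"):
    """Read a MAF-like TSV and apply the hypermutator sample filter.

    Returns ``(records, report)`` where records is a list of
    :class:`MutationRecord` (row order preserved among kept samples) and
    report a :class:`SampleReport`.  Samples whose total retained SNV count
    exceeds the threshold are dropped in full.  Non-SNV rows (multi-base or
    non-ACGT alleles) are skipped with a warning and tallied in the report.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    ref = df["ref"].str.upper()
    alt = df["alt"].str.upper()
    is_snv = (
        ref.isin(list(BASES)) & alt.isin(list(BASES)) & (ref != alt)
    )
    n_skipped = int((~is_snv).sum())
    if n_skipped:
        logger.warning("skipping %d non-SNV rows", n_skipped)
    df = df[is_snv].copy()
    df["ref"] = ref[is_snv]
    df["alt"] = alt[is_snv]
    df["pos"] = df["pos"].astype(int)

    counts = df.groupby("sample_id", sort=True).size()
    if isinstance(hypermutator_max, str):
        if hypermutator_max != "auto":
            raise ValueError("hypermutator_max must be a number or 'auto'")
        threshold = hypermutator_threshold(counts) if len(counts) else np.inf
    else:
        threshold = float(hypermutator_max)
        if threshold <= 0:
            raise ValueError("hypermutator_max must be positive")
    dropped = set(counts.index[counts > threshold])
    report = SampleReport(
        table=pd.DataFrame(
            {
                "sample_id": counts.index,
                "n_snv": counts.to_numpy(),
                "status": ["dropped" if s in dropped else "kept" for s in counts.index],
            }
        ),
        threshold=threshold,
        n_skipped_non_snv=n_skipped,
    )
    kept = df[~df["sample_id"].isin(dropped)]
    records = [
        MutationRecord(r.sample_id, r.chrom, int(r.pos), r.ref, r.alt)
        for r in kept.itertuples(index=False)
    ]
    return records, report


@dataclass
class SiteTable:
    """All possible single-nucleotide changes at covered coding positions.

    ``df`` columns: gene_id, chrom, pos, ref, alt, mutation_type, impact
    (``S``/``NS``), context5, context3, plus background feature columns
    prefixed ``bg:`` (position-level, shared by a position's three alt rows)
    and binary functional feature columns prefixed ``fn:`` (allele-level).
    """

    df: pd.DataFrame
    bg_features: list = field(default_factory=list)
    fn_features: list = field(default_factory=list)

    def __post_init__(self):
        if not isinstance(self.df.index, pd.RangeIndex) or self.df.index.start != 0:
            self.df = self.df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def n_genes(self):
        return self.df["gene_id"].nunique()

    def bg_matrix(self) -> np.ndarray:
        cols = [f"bg:{f}" for f in self.bg_features]
        return self.df[cols].to_numpy(dtype=float) if cols else np.zeros((len(self), 0))

    def fn_matrix(self, features=None) -> np.ndarray:
        feats = self.fn_features if features is None else list(features)
        cols = [f"fn:{f}" for f in feats]
        return self.df[cols].to_numpy(dtype=float) if cols else np.zeros((len(self), 0))

    @property
    def is_syn(self) -> np.ndarray:
        return (self.df["impact"] == "S").to_numpy()

    def validate(self):
        df = self.df
        per_pos = df.groupby(["chrom", "pos"], sort=False, observed=True)
        sizes = per_pos.size()
        if not (sizes == 3).all():
            bad = sizes[sizes != 3].index[:3].tolist()
            raise FormatError(f"positions without exactly 3 alt rows, e.g. {bad}")
        for f in self.bg_features:
            if per_pos[f"bg:{f}"].nunique().max() > 1:
                raise FormatError(f"bg feature {f!r} differs across alt rows of a position")
        for f in self.fn_features:
            vals = df[f"fn:{f}"].to_numpy(dtype=float)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise FormatError(f"fn feature {f!r} is not binary")
        if df.groupby(["chrom", "pos"], observed=True)["gene_id"].nunique().max() > 1:
            raise FormatError("a position maps to more than one gene")
        if not df["mutation_type"].isin(range(1, 10)).all():
            raise FormatError("mutation_type outside 1..9")
        if not df["impact"].isin(["S", "NS"]).all():
            raise FormatError("impact labels must be S or NS")
        return self

    @classmethod
    def from_tsv(cls, path) -> "SiteTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        bg = [c[3:] for c in df.columns if c.startswith("bg:")]
        fn = [c[3:] for c in df.columns if c.startswith("fn:")]
        return cls(df, bg_features=bg, fn_features=fn)

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    def gene_index(self):
        """(codes, gene_ids): integer gene index per row plus id lookup."""
        cat = pd.Categorical(self.df["gene_id"])
        return np.asarray(cat.codes), list(cat.categories)


@dataclass
class UnmatchedReport:
    unmatched: pd.DataFrame          # records at (chrom,pos,alt) absent from the table
    reference_mismatch: pd.DataFrame  # (chrom,pos) present but ref disagrees

    @property
    def n_unmatched(self):
        return len(self.unmatched)

    @property
    def n_reference_mismatch(self):
        return len(self.reference_mismatch)


def aggregate_counts(records, sites: SiteTable):
    """Aggregate mutation records onto the site table.

    Returns ``(counts, report)``: a count vector aligned with site-table rows
    and an :class:`UnmatchedReport`.  ``counts.sum() + n_unmatched +
    n_reference_mismatch == len(records)``.
    """
    counts = np.zeros(len(sites), dtype=np.int64)
    if not records:
        return counts, UnmatchedReport(pd.DataFrame(), pd.DataFrame())
    rec_df = pd.DataFrame(
        [(r.sample_id, r.chrom, r.pos, r.ref, r.alt) for r in records],
        columns=REQUIRED_MAF_COLUMNS,
    )
    key_cols = ["chrom", "pos", "ref", "alt"]
    site_key = pd.MultiIndex.from_frame(sites.df[key_cols])
    row_of = pd.Series(np.arange(len(sites)), index=site_key)
    rec_key = pd.MultiIndex.from_frame(rec_df[key_cols])
    matched_row = row_of.reindex(rec_key)
    hit = matched_row.notna().to_numpy()
    np.add.at(counts, matched_row[hit].to_numpy(dtype=int), 1)

    miss = rec_df[~hit]
    pos_ref = sites.df.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["ref"]
    miss_pos = pd.MultiIndex.from_frame(miss[["chrom", "pos"]])
    known_pos = miss_pos.isin(pos_ref.index)
    ref_mm = miss[known_pos & (miss["ref"].to_numpy() != pos_ref.reindex(miss_pos).to_numpy())]
    truly_unmatched = miss.drop(ref_mm.index)
    if len(ref_mm):
        logger.warning("%d records with reference mismatch", len(ref_mm))
    return counts, UnmatchedReport(truly_unmatched.reset_index(drop=True),
                                   ref_mm.reset_index(drop=True))
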