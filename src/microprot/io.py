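"""Tabular input/output for spectral-count experiments.

The interchange format for count tables is tab-separated UTF-8 with a ``.``
decimal separator and ``#``-prefixed comment lines.  Columns are
``accession, gene, isoform, length`` followed by one integer column per
sample.  Annotation tables come either as GMT (term, description, members...)
or as two/three-column TSV (``term_id, member[, protrusion_flag]``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical metadata columns of the count-table interchange format
META_COLUMNS = ("accession", "gene", "isoform", "length")

_REQUIRED = ("accession", "gene", "length")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform: identity, length and contaminant status."""

    accession: str
    gene_symbol: str
    length_aa: int
    isoform_tag: str | None = None
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValidationError(
                f"protein {self.accession}: length_aa must be >= 1, got {self.length_aa}"
            )


@dataclass
class SpectralCountTable:
    """Proteins x samples integer spectral counts with per-protein metadata.

    ``proteins`` is indexed by accession with columns ``gene``, ``isoform``,
    ``length`` and ``is_contaminant``; ``counts`` shares that index and has one
    column per sample.  ``sample_groups`` optionally maps sample id -> group
    label.
    """

    proteins: pd.DataFrame
    counts: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol ------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def accessions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lengths(self) -> pd.Series:
        return self.proteins["length"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def validate(self) -> None:
        if not self.proteins.index.equals(self.counts.index):
            raise ValidationError("proteins and counts must share one accession index")
        if self.proteins.index.has_duplicates:
            dupes = self.proteins.index[self.proteins.index.duplicated()].unique()
            raise ValidationError(f"duplicate accession(s): {list(dupes)[:5]}")
        counts = self.counts.to_numpy()
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("spectral counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if counts.size and (counts < 0).any():
            raise ValidationError("spectral counts must be non-negative")
        if (self.proteins["length"] < 1).any():
            bad = self.proteins.index[self.proteins["length"] < 1]
            raise ValidationError(f"length_aa must be >= 1 for {list(bad)[:5]}")

    def records(self) -> list[ProteinRecord]:
        out = []
        for acc, row in self.proteins.iterrows():
            iso = row.get("isoform")
            out.append(
                ProteinRecord(
                    accession=str(acc),
                    gene_symbol=str(row["gene"]),
                    length_aa=int(row["length"]),
                    isoform_tag=None if iso in (None, "", np.nan) or pd.isna(iso) else str(iso),
                    is_contaminant=bool(row.get("is_contaminant", False)),
                )
            )
        return out

    def presence(self, sample: str) -> set[str]:
        """Accessions detected (count >= 1) in one sample."""
        col = self.counts[sample]
        return set(col.index[col > 0])

    def subset_samples(self, samples: Sequence[str]) -> "SpectralCountTable":
        groups = {s: g for s, g in self.sample_groups.items() if s in samples}
        return SpectralCountTable(self.proteins.copy(), self.counts[list(samples)].copy(), groups)

    def drop_proteins(self, accessions: Iterable[str]) -> "SpectralCountTable":
        drop = set(accessions)
        keep = [a for a in self.counts.index if a not in drop]
        return SpectralCountTable(
            self.proteins.loc[keep].copy(), self.counts.loc[keep].copy(), dict(self.sample_groups)
        )


@dataclass(frozen=True)
class AnnotationTerm:
    """A flat annotation term (GO-like or subcellular compartment)."""

    term_id: str
    members: frozenset[str]
    term_name: str = ""
    is_protrusion_related: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"term {self.term_id} has no members")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    dialect: str = "tsv",
    column_map: Mapping[str, str] | None = None,
) -> SpectralCountTable:
    """Read a spectral-count table.

    ``column_map`` maps canonical names (``accession``, ``gene``, ``isoform``,
    ``length``) to the file's own header names, which accommodates
    search-engine exports with different labelling.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if "isoform" not in df.columns:
        df["isoform"] = ""
    sample_cols = [c for c in df.columns if c not in META_COLUMNS and c != "is_contaminant"]
    if not sample_cols:
        raise SchemaError(f"no sample columns found in {path}")
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].unique()
        raise ValidationError(f"duplicate accession(s) in {path}: {list(dupes)[:5]}")

    if "is_contaminant" in df.columns:
        contaminant = (
            df["is_contaminant"]
            .map({"True": True, "False": False, "1": True, "0": False})
            .fillna(False)
            .astype(bool)
            .to_numpy()
        )
    else:
        contaminant = np.zeros(len(df), dtype=bool)
    proteins = pd.DataFrame(
        {
            "gene": df["gene"].astype(str).to_numpy(),
            "isoform": df["isoform"].fillna("").astype(str).to_numpy(),
            "length": pd.to_numeric(df["length"], errors="raise").astype(np.int64).to_numpy(),
            "is_contaminant": contaminant,
        },
        index=pd.Index(df["accession"].astype(str), name="accession"),
    )

    counts_raw = df[sample_cols]
    counts_num = counts_raw.apply(pd.to_numeric, errors="coerce")
    if counts_num.isna().any().any():
        bad = counts_num.columns[counts_num.isna().any()].tolist()
        raise ValidationError(f"non-numeric counts in sample column(s) {bad}")
    arr = counts_num.to_numpy(dtype=float)
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError("spectral counts must be integers")
    counts = pd.DataFrame(
        arr.astype(np.int64), index=proteins.index, columns=sample_cols
    )
    return SpectralCountTable(proteins, counts)


def write_count_table(table: SpectralCountTable, path: str | Path) -> None:
    """Write the bit-exact TSV interchange form of a count table."""
    out = table.proteins[["gene", "isoform", "length"]].copy()
    out.insert(0, "accession", table.proteins.index)
    if table.proteins.get("is_contaminant") is not None and table.proteins["is_contaminant"].any():
        out["is_contaminant"] = table.proteins["is_contaminant"]
    for s in table.samples:
        out[s] = table.counts[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA lengths
# ---------------------------------------------------------------------------

_NUC = set("ACGTNacgtn")


def read_lengths_from_fasta(path: str | Path) -> dict[str, int]:
    """Protein lengths (residues, whitespace excluded) keyed by record id."""
    lengths: dict[str, int] = {}
    nuc_chars = 0
    total_chars = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").replace("\t", "")
        if not seq:
            raise ValidationError(f"empty FASTA record {rec.id!r} in {path}")
        lengths[rec.id] = len(seq)
        nuc_chars += sum(ch in _NUC for ch in seq)
        total_chars += len(seq)
    if total_chars and nuc_chars / total_chars > 0.9:
        warnings.warn(
            f"{path}: >90% ACGTN characters; this looks like nucleotide FASTA, "
            "lengths may not be amino acids",
            stacklevel=2,
        )
    return lengths


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y"}


def read_annotation_table(
    path: str | Path,
    format: str = "two_column_tsv",
    protrusion_terms: Iterable[str] | None = None,
) -> list[AnnotationTerm]:
    """Read flat term -> member annotations from TSV or GMT.

    Terms whose member set is empty after de-duplication are dropped with a
    logged warning.  ``protrusion_terms`` flags matching term ids as
    protrusion-related; a TSV third column may carry the flag per row instead.
    """
    flagged = set(protrusion_terms) if protrusion_terms is not None else None
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    row_flags: dict[str, bool] = {}

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if format == "gmt":
        for line in lines:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise SchemaError(f"malformed GMT line in {path}: {line[:60]!r}")
            term_id, desc, *members = parts
            terms.setdefault(term_id, set()).update(m for m in members if m)
            names[term_id] = desc
    elif format == "two_column_tsv":
        for line in lines:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise SchemaError(f"annotation TSV needs >= 2 columns: {line[:60]!r}")
            term_id, member = parts[0], parts[1]
            if member:
                terms.setdefault(term_id, set()).add(member)
            else:
                terms.setdefault(term_id, set())
            if len(parts) >= 3 and parts[2] != "":
                row_flags[term_id] = parts[2].strip().lower() in _TRUTHY
    else:
        raise SchemaError(f"unknown annotation format {format!r}")

    out: list[AnnotationTerm] = []
    for term_id, members in terms.items():
        if not members:
            logger.warning("dropping annotation term %s: no members after dedup", term_id)
            continue
        if flagged is not None:
            is_prot = term_id in flagged
        else:
            is_prot = row_flags.get(term_id, False)
        out.append(
            AnnotationTerm(
                term_id=term_id,
                term_name=names.get(term_id, ""),
                members=frozenset(members),
                is_protrusion_related=is_prot,
            )
        )
    return out


def write_annotation_gmt(terms: Iterable[AnnotationTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in terms:
            members = "\t".join(sorted(t.members))
            fh.write(f"{t.term_id}\t{t.term_name}\t{members}\n")


# ---------------------------------------------------------------------------
# protein lists / summaries
# ---------------------------------------------------------------------------

def write_protein_list(accessions: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{a}\n" for a in sorted(set(accessions))), encoding="utf-8")


def read_protein_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    }


def write_json_report(report: Mapping, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )
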