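"""Candidate-protein selection: total, additive and subtractive lists.

The additive rule keeps proteins seen in at least k replicates of a group
(the conventional "in two samples" validity filter).  The subtractive rule
instead keeps proteins found in a group's union and in *no other* group's
union, surfacing low-abundance group-specific candidates that the additive
filter discards.  Both operate on presence (spectral count >= 1) after
contaminant and negative-control filtering; upstream FDR filtering is assumed
already applied to the input table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import StageOrderError, ValidationError
from .io import SpectralCountTable
from .quantify import AbundanceMatrix

CATEGORIES = ("whole_cell_control", "protrusion", "negative_control")


@dataclass(frozen=True)
class SampleGroup:
    """A named experimental group with its replicate sample ids."""

    name: str
    replicates: tuple[str, ...]
    category: str = "whole_cell_control"
    control_group: str | None = None

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValidationError(f"group {self.name}: needs >= 1 replicate")
        if self.category not in CATEGORIES:
            raise ValidationError(f"group {self.name}: unknown category {self.category!r}")


@dataclass
class CandidateLists:
    """Total / additive / subtractive protein sets for one group."""

    group: str
    total: set[str]
    additive: set[str]
    subtractive: set[str]
    k: int

    def __post_init__(self) -> None:
        if not self.additive <= self.total or not self.subtractive <= self.total:
            raise ValidationError(f"group {self.group}: additive/subtractive must be in total")

    def summary(self) -> dict:
        n = len(self.total)
        pct = lambda s: round(100.0 * len(s) / n, 1) if n else 0.0
        return {
            "group": self.group,
            "k": self.k,
            "n_total": n,
            "n_additive": len(self.additive),
            "n_subtractive": len(self.subtractive),
            "pct_additive": pct(self.additive),
            "pct_subtractive": pct(self.subtractive),
        }


# ---------------------------------------------------------------------------

def collapse_isoforms(table: SpectralCountTable, mode: str = "combine") -> SpectralCountTable:
    """Merge isoforms of one gene product (``combine``) or keep them apart.

    Combine mode sums the spectral counts of all isoforms sharing a gene
    symbol and keeps the longest isoform's length (and its accession as the
    representative row id).  ``separate`` is the identity.
    """
    if mode == "separate":
        return table
    if mode != "combine":
        raise ValidationError(f"unknown isoform mode {mode!r}")
    proteins = table.proteins
    order = np.argsort(-proteins["length"].to_numpy(), kind="stable")
    by_gene: dict[str, str] = {}
    for idx in order:  # first hit per gene = longest isoform
        acc = proteins.index[idx]
        gene = proteins["gene"].iloc[idx]
        by_gene.setdefault(gene, acc)
    rep_for = proteins["gene"].map(by_gene)
    counts = table.counts.groupby(rep_for.to_numpy()).sum()
    keep = counts.index
    new_proteins = proteins.loc[keep].copy()
    new_proteins["isoform"] = ""
    counts.index.name = "accession"
    # preserve the original row order of the representative accessions
    ordered = [a for a in proteins.index if a in set(keep)]
    return SpectralCountTable(
        new_proteins.loc[ordered], counts.loc[ordered].astype(np.int64), dict(table.sample_groups)
    )


def negative_control_presence(
    table: SpectralCountTable, negative_control: SampleGroup, min_replicates: int = 2
) -> set[str]:
    """Accessions detected in at least ``min_replicates`` negative-control samples."""
    reps = [r for r in negative_control.replicates if r in table.counts.columns]
    if not reps:
        return set()
    detected = (table.counts[reps] > 0).sum(axis=1)
    return set(detected.index[detected >= min_replicates])


def apply_filters(
    table: SpectralCountTable | AbundanceMatrix,
    contaminants: Iterable[str] = (),
    negative_control: SampleGroup | None = None,
    policy: str = "exclude",
) -> SpectralCountTable | AbundanceMatrix:
    """Contaminant and negative-control filtering.

    ``exclude`` drops contaminant rows and rows detected in >= 2
    negative-control replicates; ``baseline_subtract`` subtracts the
    negative-control mean abundance per protein (floored at 0) and therefore
    requires an :class:`AbundanceMatrix`, not raw counts; ``none`` is the
    identity.
    """
    if policy == "none":
        return table
    if policy == "exclude":
        if isinstance(table, AbundanceMatrix):
            raise StageOrderError("exclude policy operates on the count table")
        drop = set(contaminants)
        drop |= set(table.proteins.index[table.proteins["is_contaminant"].astype(bool)])
        if negative_control is not None:
            drop |= negative_control_presence(table, negative_control)
        return table.drop_proteins(drop)
    if policy == "baseline_subtract":
        if isinstance(table, SpectralCountTable):
            raise StageOrderError(
                "baseline_subtract operates on NSAF abundances; compute NSAF first"
            )
        if negative_control is None:
            raise ValidationError("baseline_subtract requires a negative-control group")
        reps = [r for r in negative_control.replicates if r in table.values.columns]
        if not reps:
            raise ValidationError("negative-control samples not present in the matrix")
        baseline = table.values[reps].mean(axis=1)
        others = [c for c in table.values.columns if c not in reps]
        adjusted = table.values[others].sub(baseline, axis=0).clip(lower=0.0)
        return AbundanceMatrix(adjusted, stage="size_normalized")
    raise ValidationError(f"unknown filter policy {policy!r}")


def build_candidate_lists(
    presence: Mapping[str, Sequence[set[str]]], k: int = 2
) -> dict[str, CandidateLists]:
    """Total / additive_k / subtractive lists from per-group replicate presence sets.

    ``presence`` maps group name -> list of per-replicate presence sets.
    Subtractive compares each group's total against the union of every other
    group's total (not their additive lists).
    """
    if len(presence) < 2:
        raise ValidationError("need >= 2 groups to build subtractive lists")
    if k < 1:
        raise ValidationError("k must be >= 1")
    totals: dict[str, set[str]] = {}
    additive: dict[str, set[str]] = {}
    for group, reps in presence.items():
        reps = [set(r) for r in reps]
        if k > len(reps):
            raise ValidationError(
                f"group {group}: additive threshold k={k} exceeds {len(reps)} replicates"
            )
        totals[group] = set().union(*reps)
        counts = pd.Series(
            [p for r in reps for p in r], dtype=object
        ).value_counts() if reps else pd.Series(dtype=int)
        additive[group] = set(counts.index[counts >= k])
    out = {}
    for group in presence:
        others = set().union(*(totals[g] for g in presence if g != group))
        out[group] = CandidateLists(
            group=group,
            total=totals[group],
            additive=additive[group],
            subtractive=totals[group] - others,
            k=k,
        )
    return out
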