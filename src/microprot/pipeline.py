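"""End-to-end orchestration: quantify -> correlate -> compare -> select -> enrich.

`run_pipeline` executes the whole analysis from one :class:`RunConfig` (either
an input count table plus group definitions, or a simulation config) and
returns a JSON-serializable report; with an output directory it also writes
the stage tables and the report.  Every default that the analysis depends on
(background size, additive threshold k, filter policy, top-k) is echoed into
the report so a run is self-describing, and identical seeds give byte-identical
reports.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import enrichment as enr
from . import io as mio
from . import multiset, quantify, selection
from .errors import MicroprotError, ValidationError
from .simulate import SimulationConfig, generate_experiment, sample_groups

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: distinct machine-readable error codes per failing stage
STAGE_CODES = {
    "load": 10,
    "filter": 20,
    "quantify": 30,
    "correlate": 40,
    "compare": 50,
    "select": 60,
    "enrich": 70,
    "report": 80,
}


class StageError(MicroprotError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = STAGE_CODES.get(stage, 99)
        super().__init__(f"stage {stage!r} failed (code {self.code}): {cause}")


@dataclass
class RunConfig:
    """One self-contained pipeline run."""

    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    groups: Mapping[str, selection.SampleGroup] | None = None
    annotations_path: str | None = None
    background: int | str = multiset.MOUSE_REVIEWED_PROTEOME
    k: int = 2
    filter_policy: str = "exclude"
    isoform_mode: str = "combine"
    top_k: int = 50
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.counts_path is None):
            raise ValidationError(
                "supply exactly one of a simulation config or an input count table"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulation", None)
        groups_raw = raw.pop("groups", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            groups={
                name: selection.SampleGroup(
                    name=name,
                    replicates=tuple(g["replicates"]),
                    category=g.get("category", "whole_cell_control"),
                )
                for name, g in groups_raw.items()
            }
            if groups_raw
            else None,
            **raw,
        )
        return cfg


def _round_floats(obj, ndigits=10):
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return round(x, ndigits) if math.isfinite(x) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _validate_report(report: dict) -> None:
    required = {
        "schema_version", "config", "per_sample", "correlations",
        "intersections", "candidate_lists", "protrusion_term_pct", "seed",
    }
    missing = required - set(report)
    if missing:
        raise ValidationError(f"report missing sections: {sorted(missing)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- load ------------------------------------------------------------
    stage = "load"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
            table, truth, terms = generate_experiment(sim)
            groups = sample_groups(sim)
        else:
            table = mio.read_count_table(config.counts_path)
            truth = None
            if config.groups is None:
                raise ValidationError("group definitions are required with an input table")
            groups = dict(config.groups)
            terms = (
                mio.read_annotation_table(config.annotations_path, format="gmt")
                if config.annotations_path
                else []
            )
        logger.info("stage load: %d proteins x %d samples", *table.shape)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
        raise StageError(stage, exc) from exc

    neg = next((g for g in groups.values() if g.category == "negative_control"), None)
    analysis_groups = {n: g for n, g in groups.items() if g.category != "negative_control"}

    # ---- isoform handling + filters -------------------------------------
    stage = "filter"
    try:
        correlation_table = table  # isoforms kept separate for correlation
        combined = selection.collapse_isoforms(table, mode=config.isoform_mode)
        filtered = selection.apply_filters(
            combined, negative_control=neg, policy=config.filter_policy
        ) if config.filter_policy in ("exclude", "none") else combined
        logger.info("stage filter: %d -> %d proteins", combined.shape[0], filtered.shape[0])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- quantify --------------------------------------------------------
    stage = "quantify"
    try:
        analysis_samples = [r for g in analysis_groups.values() for r in g.replicates]
        if config.filter_policy == "baseline_subtract" and neg is not None:
            nsaf_full = quantify.compute_nsaf(filtered)
            adjusted = selection.apply_filters(
                nsaf_full, negative_control=neg, policy="baseline_subtract"
            )
            # re-expressed on analysis samples only; factors from adjusted values
            factors = quantify.estimate_size_factors(adjusted)
            normalized = quantify.AbundanceMatrix(
                adjusted.values / factors.factors, stage="size_normalized"
            )
            filtered = filtered.subset_samples(analysis_samples)
            nsaf = quantify.compute_nsaf(filtered)
        else:
            filtered = filtered.subset_samples(analysis_samples)
            nsaf = quantify.compute_nsaf(filtered)
            factors = quantify.estimate_size_factors(nsaf)
            normalized = quantify.apply_size_factors(nsaf, factors)
        nsaf_corr = quantify.compute_nsaf(correlation_table.subset_samples(analysis_samples))
        per_sample = {
            s: {
                "n_proteins": int((filtered.counts[s] > 0).sum()),
                "total_spectra": int(filtered.counts[s].sum()),
                "size_factor": float(factors.factors[s]),
            }
            for s in filtered.samples
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- correlate (replicate pairs within each analysis group) ----------
    stage = "correlate"
    try:
        comparisons = {
            name: list(itertools.combinations(g.replicates, 2))
            for name, g in analysis_groups.items()
            if len(g.replicates) >= 2
        }
        pairs = [p for plist in comparisons.values() for p in plist]
        corr = quantify.correlate_pairs(nsaf_corr, pairs, comparisons=comparisons)
        correlations = {
            "pairs": [
                {
                    "sample_a": row.sample_a,
                    "sample_b": row.sample_b,
                    "n_support": int(row.n_support),
                    "r": float(row.r),
                }
                for row in corr.pairs.itertuples()
            ],
            "r_avg": corr.r_avg,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- compare (multi-set intersections of replicates per group) -------
    stage = "compare"
    try:
        intersections = {}
        for name, g in analysis_groups.items():
            if len(g.replicates) < 2:
                continue
            rep_sets = {r: filtered.presence(r) for r in g.replicates}
            sweep = multiset.combination_sweep(rep_sets, background=config.background)
            full = next(r for r in sweep if len(r.members) == len(g.replicates))
            entry = {
                "n_replicates": len(g.replicates),
                "total_proteins": len(set().union(*rep_sets.values())),
                "combinations": [
                    {
                        "members": list(r.members),
                        "observed": r.observed,
                        "expected": r.expected,
                        "fold_enrichment": r.fold_enrichment,
                        "p_value": r.p_value,
                        "p_display": r.p_display,
                    }
                    for r in sweep
                ],
                "all_replicates": {
                    "observed": full.observed,
                    "fold_enrichment": full.fold_enrichment,
                    "p_display": full.p_display,
                },
            }
            if len(g.replicates) > 2:
                fam = multiset.summarize_family(sweep, family="pairwise", order=2)
                entry["pairwise_family"] = {
                    "fe_avg": fam.fe_avg,
                    "combined_p": fam.combined_p,
                    "combined_p_display": (
                        "< 1.0e-307" if fam.combined_p_floored else format(fam.combined_p, ".3g")
                    ),
                    "method": fam.method,
                }
            intersections[name] = entry
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- select ----------------------------------------------------------
    stage = "select"
    try:
        presence = {
            name: [filtered.presence(r) for r in g.replicates]
            for name, g in analysis_groups.items()
        }
        from collections import Counter

        # groups may have fewer replicates than k (single-sample preparations);
        # clamp per group and record the effective threshold
        k_eff = {name: min(config.k, len(reps)) for name, reps in presence.items()}
        totals = {name: set().union(*reps) for name, reps in presence.items()}
        lists: dict[str, selection.CandidateLists] = {}
        for name, reps in presence.items():
            tally = Counter(itertools.chain.from_iterable(reps))
            additive = {p for p, c in tally.items() if c >= k_eff[name]}
            others = set().union(*(totals[g] for g in presence if g != name))
            lists[name] = selection.CandidateLists(
                group=name,
                total=totals[name],
                additive=additive,
                subtractive=totals[name] - others,
                k=k_eff[name],
            )
        candidate_lists = {name: cl.summary() for name, cl in lists.items()}
        for name in candidate_lists:
            candidate_lists[name]["k_effective"] = k_eff[name]
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- enrich ----------------------------------------------------------
    stage = "enrich"
    try:
        protrusion_term_pct: dict[str, dict[str, float | None]] = {}
        enrichment_tables: dict[str, dict[str, object]] = {}
        if terms:
            gene_of = filtered.proteins["gene"].to_dict()
            # background: every protein identified anywhere in the experiment
            background_genes = {
                gene_of[a] for total in totals.values() for a in total if a in gene_of
            }
            for name, g in analysis_groups.items():
                if g.category != "protrusion":
                    continue
                entry_pct: dict[str, float | None] = {}
                entry_tab: dict[str, object] = {}
                for approach in ("total", "additive", "subtractive"):
                    members = getattr(lists[name], approach)
                    genes = {gene_of[a] for a in members if a in gene_of}
                    if not genes:
                        entry_pct[approach] = None
                        continue
                    ranked = enr.term_enrichment(genes, background_genes, terms)
                    # the top-term view ranks over-represented terms only
                    enriched = ranked[ranked["direction"] == "enriched"].reset_index(drop=True)
                    top = min(config.top_k, len(enriched))
                    entry_pct[approach] = (
                        enr.protrusion_term_percentage(enriched, top) if top else None
                    )
                    entry_tab[approach] = ranked
                protrusion_term_pct[name] = entry_pct
                enrichment_tables[name] = entry_tab
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- report ----------------------------------------------------------
    stage = "report"
    try:
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": config.seed,
            "config": {
                "background": config.background,
                "k": config.k,
                "filter_policy": config.filter_policy,
                "isoform_mode": config.isoform_mode,
                "top_k": config.top_k,
                "simulated": config.simulation is not None,
            },
            "per_sample": per_sample,
            "correlations": correlations,
            "intersections": intersections,
            "candidate_lists": candidate_lists,
            "protrusion_term_pct": protrusion_term_pct,
        }
        report = _round_floats(report)
        _validate_report(report)
        if out_dir:
            mio.write_json_report(report, out_dir / "report.json")
            mio.write_count_table(filtered, out_dir / "counts_filtered.tsv")
            nsaf.values.to_csv(out_dir / "nsaf.tsv", sep="\t", float_format="%.10g")
            normalized.values.to_csv(
                out_dir / "nsaf_normalized.tsv", sep="\t", float_format="%.10g"
            )
            for name, cl in lists.items():
                mio.write_protein_list(cl.subtractive, out_dir / f"{name}_subtractive.txt")
                mio.write_protein_list(cl.additive, out_dir / f"{name}_additive.txt")
            for name, tabs in enrichment_tables.items():
                for approach, df in tabs.items():
                    df.to_csv(
                        out_dir / f"{name}_{approach}_terms.tsv", sep="\t", index=False,
                        float_format="%.10g",
                    )
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return report
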