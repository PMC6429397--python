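"""Synthetic spectral-count experiments with full ground truth.

The generator emulates a laser-capture microproteomic experiment: a core of
abundant proteins shared by all groups, a low-abundance set of proteins
exclusive to each group, "scattered" proteins present in a random subset of
groups, contaminant rows, and negative-control samples that see only a thin
sliver of the core.  Counts are negative binomial around

    mu_ij = depth(group_j) * f_j * w_ij / sum_i w_ij,   w_ij = abundance * length

so that a sample's expected total equals its configured sequencing-style depth
times its true size factor, with length-proportional sampling as spectral
counting assumes.  A protein is observed in a sample only if an independent
Bernoulli detection draw succeeds; the detection probability is logistic in
the log expected count (or a fixed constant when configured), which produces
the replicate-to-replicate presence/absence variation that drives the
additive-vs-subtractive contrast.  Annotation terms are generated alongside,
with protrusion-related terms planted preferentially among the
protrusion-group-exclusive proteins.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .io import AnnotationTerm, SpectralCountTable
from .selection import CandidateLists, SampleGroup


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_replicates: int
    category: str  # whole_cell_control | protrusion | negative_control
    depth: float  # expected total spectra per sample

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.depth <= 0:
            raise ValidationError(f"group {self.name}: bad replicates/depth")


#: default topology: three whole-cell controls, four protrusion groups
#: (growth cones, two bulk-protrusion preparations and a single
#: nanotube-style sample) and a negative control -- 18 samples in all, with
#: protrusion depths well below whole-cell depths.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("CAD", 3, "whole_cell_control", 25000.0),
    GroupSpec("hCAD", 3, "whole_cell_control", 25000.0),
    GroupSpec("dCAD", 2, "whole_cell_control", 25000.0),
    GroupSpec("GC", 3, "protrusion", 4000.0),
    GroupSpec("hCAD_protrusion", 2, "protrusion", 4000.0),
    GroupSpec("dCAD_protrusion", 2, "protrusion", 4000.0),
    GroupSpec("TNT", 1, "protrusion", 2500.0),
    GroupSpec("neg_control", 2, "negative_control", 300.0),
)


@dataclass
class SimulationConfig:
    """Stated world of the synthetic experiment; defaults mirror an
    eight-group, 18-sample microdissection study."""

    n_proteins: int = 2000
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    # protein lengths, log-normal in amino acids
    length_median_aa: float = 400.0
    length_log_sigma: float = 0.45
    # composition
    core_fraction: float = 0.50
    exclusive_fraction: float = 0.04  # per non-negative-control group
    scattered_presence_prob: float = 0.35
    # abundance, log-normal; exclusives sit in a low-abundance regime
    abundance_log_sigma: float = 1.2
    exclusive_abundance_scale: float = 0.15
    # counts and detection
    nb_dispersion: float = 10.0
    detection_slope: float = 1.4
    detection_midpoint: float = 1.0  # expected-count scale
    detection_prob: float | None = None  # fixed override when set
    # nuisance structure
    size_factor_log_sigma: float = 0.15
    contaminant_count: int = 15
    isoform_gene_fraction: float = 0.05
    neg_control_core_fraction: float = 0.05
    # annotations
    n_terms: int = 250
    n_protrusion_terms: int = 40
    term_size_mean: float = 25.0
    protrusion_member_bias: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        n_excl_groups = sum(1 for g in self.groups if g.category != "negative_control")
        if not (0 <= self.core_fraction <= 1 and 0 <= self.exclusive_fraction <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if self.core_fraction + n_excl_groups * self.exclusive_fraction > 1:
            raise ValidationError("core + per-group exclusive fractions exceed 1")
        for val in (
            self.length_median_aa, self.length_log_sigma, self.abundance_log_sigma,
            self.nb_dispersion, self.term_size_mean,
        ):
            if val <= 0:
                raise ValidationError("rates and scales must be positive")
        if self.detection_prob is not None and not (0 < self.detection_prob <= 1):
            raise ValidationError("detection_prob must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated experiment."""

    role: pd.Series  # per accession: "core" | "exclusive:<group>" | "scattered" | "contaminant"
    abundance: pd.DataFrame  # accession x group, true relative abundance
    size_factors: pd.Series  # per sample, geometric mean 1
    protrusion_protein: pd.Series  # per accession, bool
    seed: int

    def exclusives(self, group: str) -> set[str]:
        tag = f"exclusive:{group}"
        return set(self.role.index[self.role == tag])


def _simulate_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = dispersion / (dispersion + mu[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_experiment(
    config: SimulationConfig,
) -> tuple[SpectralCountTable, SyntheticTruth, list[AnnotationTerm]]:
    """Draw one experiment: count table, planted truth, annotation terms."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    groups = config.groups
    excl_groups = [g for g in groups if g.category != "negative_control"]
    prot_groups = [g for g in groups if g.category == "protrusion"]

    # --- identities -------------------------------------------------------
    accessions = np.array([f"P{idx:05d}" for idx in range(n)])
    genes = np.array([f"G{idx:05d}" for idx in range(n)], dtype=object)
    isoform = np.array([""] * n, dtype=object)
    n_iso = int(round(config.isoform_gene_fraction * n / 2))
    if n_iso:
        iso_targets = rng.choice(n, size=2 * n_iso, replace=False).reshape(-1, 2)
        for a_idx, b_idx in iso_targets:
            genes[b_idx] = genes[a_idx]
            isoform[a_idx], isoform[b_idx] = "iso1", "iso2"
    lengths = np.maximum(
        np.round(
            np.exp(rng.normal(np.log(config.length_median_aa), config.length_log_sigma, n))
        ).astype(np.int64),
        30,
    )

    # --- roles ------------------------------------------------------------
    n_core = int(round(config.core_fraction * n))
    n_excl = int(round(config.exclusive_fraction * n))
    role = np.array(["scattered"] * n, dtype=object)
    role[:n_core] = "core"
    pos = n_core
    for g in excl_groups:
        role[pos : pos + n_excl] = f"exclusive:{g.name}"
        pos += n_excl

    # --- per-group true relative abundance --------------------------------
    base = np.exp(rng.normal(0.0, config.abundance_log_sigma, n))
    abundance = pd.DataFrame(0.0, index=accessions, columns=[g.name for g in groups])
    neg_core = rng.random(n_core) < config.neg_control_core_fraction
    for g in groups:
        present = np.zeros(n, dtype=bool)
        if g.category == "negative_control":
            present[:n_core] = neg_core
        else:
            present[role == "core"] = True
            present[role == f"exclusive:{g.name}"] = True
            scattered = role == "scattered"
            present[scattered] = rng.random(scattered.sum()) < config.scattered_presence_prob
        scale = np.where(
            np.char.startswith(role.astype(str), "exclusive"),
            config.exclusive_abundance_scale,
            1.0,
        )
        abundance[g.name] = np.where(present, base * scale, 0.0)

    # --- samples ----------------------------------------------------------
    sample_ids: list[str] = []
    sample_group: dict[str, str] = {}
    depths: list[float] = []
    for g in groups:
        for r in range(1, g.n_replicates + 1):
            sid = f"{g.name}_{r}"
            sample_ids.append(sid)
            sample_group[sid] = g.name
            depths.append(g.depth)
    n_samples = len(sample_ids)
    log_f = rng.normal(0.0, config.size_factor_log_sigma, n_samples)
    log_f -= log_f.mean()
    size_factors = np.exp(log_f)

    # --- counts -----------------------------------------------------------
    counts = np.zeros((n, n_samples), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        g = sample_group[sid]
        ab = abundance[g].to_numpy()
        w = ab * lengths
        total = w.sum()
        if total == 0:
            continue
        mu = depths[j] * size_factors[j] * w / total
        c = _simulate_counts(rng, mu, config.nb_dispersion)
        if config.detection_prob is not None:
            det = rng.random(n) < config.detection_prob
        else:
            with np.errstate(divide="ignore"):
                logit = config.detection_slope * (
                    np.log(np.maximum(mu, 1e-300)) - np.log(config.detection_midpoint)
                )
            det = rng.random(n) < expit(logit)
        counts[:, j] = np.where(det & (mu > 0), c, 0)

    # --- contaminants -----------------------------------------------------
    n_cont = config.contaminant_count
    if n_cont:
        cont_acc = np.array([f"CONT{idx:03d}" for idx in range(n_cont)])
        cont_len = np.maximum(
            np.round(np.exp(rng.normal(np.log(300.0), 0.3, n_cont))).astype(np.int64), 30
        )
        cont_counts = rng.poisson(5.0, size=(n_cont, n_samples))
        accessions = np.concatenate([accessions, cont_acc])
        genes = np.concatenate([genes, np.array([f"Cont{idx}" for idx in range(n_cont)], dtype=object)])
        isoform = np.concatenate([isoform, np.array([""] * n_cont, dtype=object)])
        lengths = np.concatenate([lengths, cont_len])
        counts = np.vstack([counts, cont_counts])
        role = np.concatenate([role, np.array(["contaminant"] * n_cont, dtype=object)])
        abundance = pd.concat(
            [abundance, pd.DataFrame(0.0, index=cont_acc, columns=abundance.columns)]
        )

    proteins = pd.DataFrame(
        {
            "gene": genes,
            "isoform": isoform,
            "length": lengths,
            "is_contaminant": np.char.startswith(accessions.astype(str), "CONT"),
        },
        index=pd.Index(accessions, name="accession"),
    )
    table = SpectralCountTable(
        proteins,
        pd.DataFrame(counts, index=proteins.index, columns=sample_ids),
        sample_group,
    )

    # --- annotations ------------------------------------------------------
    # annotation membership is gene-symbol keyed (annotation sources are
    # gene-centric; isoforms of one gene share membership)
    prot_exclusive = np.zeros(len(accessions), dtype=bool)
    for g in prot_groups:
        prot_exclusive |= role == f"exclusive:{g.name}"
    group_pools = {
        g.name: np.unique(genes[role == f"exclusive:{g.name}"]) for g in prot_groups
    }
    all_pool = np.unique(genes[role != "contaminant"])
    terms: list[AnnotationTerm] = []
    for t in range(config.n_terms):
        size = max(3, int(rng.poisson(config.term_size_mean)))
        is_prot = t < config.n_protrusion_terms and bool(prot_groups)
        if is_prot:
            # each protrusion-related term centres on one protrusion subtype
            # (annotation profiles differ between protrusion types), with the
            # remaining members drawn from the whole identified space
            pool = group_pools[prot_groups[t % len(prot_groups)].name]
            n_from_pool = min(int(round(config.protrusion_member_bias * size)), len(pool))
            members = set(rng.choice(pool, size=n_from_pool, replace=False))
            n_rest = size - n_from_pool
            if n_rest > 0:
                members |= set(rng.choice(all_pool, size=n_rest, replace=False))
        else:
            members = set(rng.choice(all_pool, size=min(size, len(all_pool)), replace=False))
        terms.append(
            AnnotationTerm(
                term_id=f"TERM{t:04d}",
                term_name=("protrusion-related process " if is_prot else "generic process ")
                + str(t),
                members=frozenset(str(m) for m in members),
                is_protrusion_related=is_prot,
            )
        )

    truth = SyntheticTruth(
        role=pd.Series(role, index=proteins.index, name="role"),
        abundance=abundance,
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
        protrusion_protein=pd.Series(prot_exclusive, index=proteins.index, name="protrusion"),
        seed=config.seed,
    )
    return table, truth, terms


def sample_groups(config: SimulationConfig) -> dict[str, SampleGroup]:
    """The group layout of a generated experiment, as selection-stage objects."""
    out = {}
    for g in config.groups:
        out[g.name] = SampleGroup(
            name=g.name,
            replicates=tuple(f"{g.name}_{r}" for r in range(1, g.n_replicates + 1)),
            category=g.category,
        )
    return out


def truth_recovery_report(
    truth: SyntheticTruth,
    lists: dict[str, CandidateLists],
    term_rankings: dict[str, pd.DataFrame] | None = None,
    estimated_size_factors: pd.Series | None = None,
) -> dict:
    """Recovery metrics of the planted structure.

    Per group: sensitivity (recall of planted exclusives) and precision of the
    subtractive and additive lists; optionally the best rank of a planted
    protrusion term per ranking and the max relative error of estimated size
    factors.
    """
    report: dict = {"groups": {}}
    for group, cl in lists.items():
        planted = truth.exclusives(group)
        if not planted:
            continue
        entry = {}
        for approach, found in (("subtractive", cl.subtractive), ("additive", cl.additive)):
            tp = len(found & planted)
            entry[approach] = {
                "sensitivity": tp / len(planted),
                "precision": tp / len(found) if found else float("nan"),
                "n_list": len(found),
                "n_planted": len(planted),
            }
        report["groups"][group] = entry
    if term_rankings is not None:
        ranks = {}
        for name, df in term_rankings.items():
            flagged = np.flatnonzero(df["is_protrusion_related"].to_numpy())
            ranks[name] = int(flagged[0]) + 1 if flagged.size else None
        report["best_protrusion_term_rank"] = ranks
    if estimated_size_factors is not None:
        est = estimated_size_factors.reindex(truth.size_factors.index)
        rel = np.abs(est.to_numpy() / truth.size_factors.to_numpy() - 1.0)
        report["size_factor_max_rel_error"] = float(np.nanmax(rel))
    return report
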