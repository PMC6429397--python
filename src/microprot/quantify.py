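"""NSAF abundance, size-factor normalization and replicate correlation.

NSAF (normalized spectral abundance factor) divides each protein's spectral
count by its length (longer proteins have more peptides available) and
normalizes within each sample so that a sample's abundances sum to one:

    SAF_ij  = SpC_ij / L_i
    NSAF_ij = SAF_ij / sum_k SAF_kj

Depth differences between samples are then corrected with median-of-ratios
size factors (the standard count-data normalization): each sample's factor is
the median, over proteins detected in every sample, of the ratio of that
protein's value to its across-sample geometric mean, rescaled so the factors
themselves have geometric mean one.

Because normalized NSAF values are far from Gaussian, pairwise Pearson
correlation is computed after a Johnson transformation toward normality
(fitted per pair on the pooled positive values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StageOrderError, ValidationError
from .io import SpectralCountTable
from .johnson import JohnsonFit, johnson_transform

STAGES = ("nsaf", "size_normalized", "transformed")


def _pseudo_fill(fit: JohnsonFit, pooled_min: float) -> float:
    """Half-minimum pseudo-abundance for zeros, kept inside the fit's support.

    When the fitted family is bounded below and the half-minimum falls outside
    the support, the fill is placed halfway between the lower bound and the
    smallest fitted value, so undetected proteins map just below every
    detected one without unbounded leverage.
    """
    half = pooled_min / 2.0
    lo, _ = fit.support
    if np.isfinite(lo) and half <= lo:
        half = lo + 0.5 * (pooled_min - lo)
    return half


@dataclass
class AbundanceMatrix:
    """Proteins x samples real-valued abundances at a named pipeline stage."""

    values: pd.DataFrame
    stage: str = "nsaf"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        arr = self.values.to_numpy()
        if self.stage != "transformed" and arr.size and (arr < 0).any():
            raise ValidationError(f"negative abundances at stage {self.stage!r}")
        if self.stage == "nsaf" and arr.size:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("NSAF columns must each sum to 1 within 1e-9")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample scaling factors, geometric mean 1 by convention."""

    factors: pd.Series
    convention: str = "geometric_mean_1"

    def __post_init__(self) -> None:
        arr = self.factors.to_numpy(dtype=float)
        if (arr <= 0).any():
            raise ValidationError("size factors must be positive")
        gm = float(np.exp(np.mean(np.log(arr))))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"size factors must have geometric mean 1 (got {gm})")


@dataclass
class CorrelationSummary:
    """Pearson r per sample pair plus per-comparison averages."""

    pairs: pd.DataFrame  # columns: sample_a, sample_b, n_support, r
    r_avg: dict[str, float] = field(default_factory=dict)
    fits: dict[tuple[str, str], JohnsonFit] = field(default_factory=dict)


# ---------------------------------------------------------------------------

def compute_nsaf(table: SpectralCountTable) -> AbundanceMatrix:
    """Spectral counts -> NSAF; every sample column sums to 1, zeros preserved."""
    lengths = table.lengths.to_numpy(dtype=float)
    counts = table.counts.to_numpy(dtype=float)
    saf = counts / lengths[:, None]
    colsum = saf.sum(axis=0)
    dead = np.flatnonzero(colsum == 0)
    if dead.size:
        names = [table.samples[i] for i in dead]
        raise ValidationError(f"sample(s) with all-zero counts: {names}")
    nsaf = saf / colsum[None, :]
    return AbundanceMatrix(
        pd.DataFrame(nsaf, index=table.counts.index, columns=table.samples), stage="nsaf"
    )


def estimate_size_factors(matrix: AbundanceMatrix) -> SizeFactors:
    """Median-of-ratios size factors over proteins detected in every sample."""
    vals = matrix.values.to_numpy(dtype=float)
    everywhere = (vals > 0).all(axis=1)
    if not everywhere.any():
        raise ValidationError(
            "no protein detected in every sample; add a pseudo-count or restrict "
            "to a common protein subset before estimating size factors"
        )
    sub = vals[everywhere]
    log_ref = np.mean(np.log(sub), axis=1)  # per-protein geometric mean, log scale
    log_ratios = np.log(sub) - log_ref[:, None]
    log_s = np.median(log_ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1 convention
    return SizeFactors(pd.Series(np.exp(log_s), index=matrix.values.columns))


def apply_size_factors(matrix: AbundanceMatrix, factors: SizeFactors) -> AbundanceMatrix:
    if matrix.stage != "nsaf":
        raise StageOrderError("size factors are applied to the NSAF stage")
    scaled = matrix.values / factors.factors
    return AbundanceMatrix(scaled, stage="size_normalized")


def transform_matrix(matrix: AbundanceMatrix, pseudo: str = "half_min") -> tuple[AbundanceMatrix, JohnsonFit]:
    """Johnson-transform a whole matrix with one pooled fit.

    Zeros are mapped through the fitted transform at a half-minimum
    pseudo-abundance (clamped onto the fit's support).
    """
    vals = matrix.values.to_numpy(dtype=float)
    pos = vals[vals > 0]
    if pos.size < 20:
        raise ValidationError("need >= 20 positive abundances to fit a transform")
    _, fit = johnson_transform(pos)
    fill = _pseudo_fill(fit, pos.min()) if pseudo == "half_min" else float(pseudo)
    filled = np.where(vals > 0, vals, fill)
    out = np.asarray(fit.transform(fit.clamp_to_support(filled)))
    return (
        AbundanceMatrix(
            pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
            stage="transformed",
        ),
        fit,
    )


def correlate_pairs(
    matrix: AbundanceMatrix,
    pairs: Sequence[tuple[str, str]],
    comparisons: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    support: str = "union",
) -> CorrelationSummary:
    """Pearson r per sample pair, on Johnson-transformed abundances.

    The comparison support per pair is the set of proteins detected
    (abundance > 0) in at least one member (``support="union"``, default) or
    in both (``"intersection"``).  If the matrix is not already at the
    transformed stage, a Johnson transform is fitted per pair on the pooled
    positive support values, and zeros are mapped through the fit at a
    half-minimum pseudo-abundance.  Pairs with support below 3 proteins are
    skipped with a warning and excluded from r_avg.
    """
    if support not in ("union", "intersection"):
        raise ValidationError(f"unknown support rule {support!r}")
    rows = []
    fits: dict[tuple[str, str], JohnsonFit] = {}
    for a, b in pairs:
        va = matrix.values[a].to_numpy(dtype=float)
        vb = matrix.values[b].to_numpy(dtype=float)
        if matrix.stage == "transformed":
            mask = np.ones_like(va, dtype=bool)
            xa, xb = va, vb
        else:
            det_a, det_b = va > 0, vb > 0
            mask = (det_a | det_b) if support == "union" else (det_a & det_b)
            if mask.sum() < 3:
                warnings.warn(
                    f"pair ({a}, {b}): support {int(mask.sum())} < 3, skipped", stacklevel=2
                )
                continue
            pooled = np.concatenate([va[mask & det_a], vb[mask & det_b]])
            if np.unique(pooled).size < 3 or pooled.size < 20:
                # tiny support: fall back to raw values, Pearson is still defined
                xa, xb = va, vb
            else:
                _, fit = johnson_transform(pooled)
                fits[(a, b)] = fit
                fill = _pseudo_fill(fit, pooled.min())
                xa = np.asarray(fit.transform(fit.clamp_to_support(np.where(det_a, va, fill))))
                xb = np.asarray(fit.transform(fit.clamp_to_support(np.where(det_b, vb, fill))))
        n_sup = int(mask.sum())
        if n_sup < 3:
            warnings.warn(f"pair ({a}, {b}): support {n_sup} < 3, skipped", stacklevel=2)
            continue
        sa, sb = xa[mask], xb[mask]
        if np.ptp(sa) == 0 or np.ptp(sb) == 0:
            r = 1.0 if np.array_equal(sa, sb) else float("nan")
        else:
            r = float(stats.pearsonr(sa, sb).statistic)
        rows.append({"sample_a": a, "sample_b": b, "n_support": n_sup, "r": r})

    pairs_df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "n_support", "r"])
    r_avg: dict[str, float] = {}
    if comparisons:
        done = {(row["sample_a"], row["sample_b"]): row["r"] for row in rows}
        for name, plist in comparisons.items():
            rs = [done[p] for p in plist if p in done and np.isfinite(done[p])]
            if rs:
                r_avg[name] = float(np.mean(rs))
    return CorrelationSummary(pairs=pairs_df, r_avg=r_avg, fits=fits)
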