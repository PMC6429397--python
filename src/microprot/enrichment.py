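"""2x2 contingency enrichment of functional and localization annotations.

Fold enrichment is the proportion ratio of a category between a sample list
and a background population:

    FE = (a / n_s) / (b / N_b)

with ``a`` annotated proteins among the ``n_s`` sample proteins and ``b``
among the ``N_b`` background proteins.  In the default *inclusive* mode the
sample is a subset of the background, FE is computed against the full
background proportion, and the odds ratio and chi-square tests use the
sample-vs-whole-background layout

                 annotated   not annotated
    sample           a          n_s - a
    background       b          N_b - b

(the layout under which published protrusion-localization p-values are
reproduced exactly).  ``exclusive`` mode uses the same table for two disjoint
populations.

Significance comes from Pearson's chi-square and Yates's continuity-corrected
chi-square, both with one degree of freedom, converted to p-values through the
chi-square upper tail.  Benjamini-Hochberg adjusted p-values are emitted as an
extra column next to the raw ones, never replacing them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import AnnotationTerm


@dataclass(frozen=True)
class ContingencyResult:
    """Enrichment/depletion of one category in a sample vs a background."""

    hits_sample: int
    size_sample: int
    hits_background: int
    size_background: int
    fold_enrichment: float
    odds_ratio: float
    chi2_pearson: float
    chi2_yates: float
    p_pearson: float
    p_yates: float
    direction: str  # "enriched" | "depleted" | "none"
    term_id: str = ""
    term_name: str = ""

    @property
    def pct_sample(self) -> float:
        return 100.0 * self.hits_sample / self.size_sample

    @property
    def pct_background(self) -> float:
        return 100.0 * self.hits_background / self.size_background


def _chi2_stats(table: np.ndarray) -> tuple[float, float, float, float]:
    """Pearson and Yates chi-square (df=1) with upper-tail p-values."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if n == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 0.0, 1.0, 1.0
    expected = np.outer(row, col) / n
    dev = np.abs(table - expected)
    pearson = float((dev**2 / expected).sum())
    dev_y = np.maximum(dev - 0.5, 0.0)
    yates = float((dev_y**2 / expected).sum())
    return pearson, yates, float(stats.chi2.sf(pearson, 1)), float(stats.chi2.sf(yates, 1))


def contingency_enrichment(
    a: int,
    n_s: int,
    b: int,
    N_b: int,
    background_mode: str = "inclusive",
    term_id: str = "",
    term_name: str = "",
) -> ContingencyResult:
    """2x2 enrichment of ``a``/``n_s`` sample hits vs ``b``/``N_b`` background hits.

    ``inclusive`` (default): the sample is part of the background, so FE is
    the sample proportion over the full background proportion; the 2x2 table
    contrasts the sample row with the whole background row.  ``exclusive``:
    sample and background are disjoint populations (same table shape, but
    ``b >= a`` is not required and the background need not contain the
    sample).
    """
    if not (0 <= a <= n_s):
        raise ValidationError(f"need 0 <= a <= n_s (got a={a}, n_s={n_s})")
    if not (0 <= b <= N_b):
        raise ValidationError(f"need 0 <= b <= N_b (got b={b}, N_b={N_b})")
    if background_mode == "inclusive":
        if N_b < n_s:
            raise ValidationError("inclusive background must contain the sample")
        if b < a:
            raise ValidationError("inclusive background hits must include sample hits")
    elif background_mode != "exclusive":
        raise ValidationError(f"unknown background_mode {background_mode!r}")
    rest_hits = b
    rest_size = N_b
    fe_denom = b / N_b if N_b else 0.0

    p_sample = a / n_s if n_s else 0.0
    fe = math.inf if fe_denom == 0 and p_sample > 0 else (
        p_sample / fe_denom if fe_denom > 0 else 0.0
    )
    table = np.array([[a, n_s - a], [rest_hits, rest_size - rest_hits]], dtype=float)
    if (table < 0).any():
        raise ValidationError("inconsistent 2x2 counts (negative complement cell)")
    pearson, yates, p_p, p_y = _chi2_stats(table)
    num = a * (rest_size - rest_hits)
    den = (n_s - a) * rest_hits
    odds = math.inf if den == 0 and num > 0 else (num / den if den else float("nan"))
    direction = "enriched" if fe > 1 else ("depleted" if fe < 1 else "none")
    return ContingencyResult(
        hits_sample=a,
        size_sample=n_s,
        hits_background=b,
        size_background=N_b,
        fold_enrichment=fe,
        odds_ratio=odds,
        chi2_pearson=pearson,
        chi2_yates=yates,
        p_pearson=p_p,
        p_yates=p_y,
        direction=direction,
        term_id=term_id,
        term_name=term_name,
    )


def term_enrichment(
    sample: set[str],
    background: set[str],
    annotations: Sequence[AnnotationTerm],
) -> pd.DataFrame:
    """Per-term contingency enrichment of a sample list against a background.

    Proteins without any annotation still count in the totals.  Terms with no
    background members are skipped.  Rows are ranked by Pearson p ascending,
    ties broken by fold enrichment descending then term id; BH-adjusted
    p-values are appended as ``p_bh``.
    """
    if not sample:
        raise ValidationError("empty sample set")
    if not sample <= background:
        raise ValidationError("sample must be a subset of the background")
    rows = []
    for term in annotations:
        b = len(term.members & background)
        if b == 0:
            continue
        a = len(term.members & sample)
        res = contingency_enrichment(
            a, len(sample), b, len(background), "inclusive", term.term_id, term.term_name
        )
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "is_protrusion_related": term.is_protrusion_related,
                "hits_sample": a,
                "size_sample": len(sample),
                "hits_background": b,
                "size_background": len(background),
                "fold_enrichment": res.fold_enrichment,
                "odds_ratio": res.odds_ratio,
                "chi2_pearson": res.chi2_pearson,
                "chi2_yates": res.chi2_yates,
                "p_pearson": res.p_pearson,
                "p_yates": res.p_yates,
                "direction": res.direction,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "is_protrusion_related", "hits_sample",
                "size_sample", "hits_background", "size_background",
                "fold_enrichment", "odds_ratio", "chi2_pearson", "chi2_yates",
                "p_pearson", "p_yates", "direction", "p_bh",
            ]
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p_pearson"].to_numpy(), method="fdr_bh")[1]
    # rank: p ascending, FE descending (inf first), term_id for determinism
    df = df.sort_values(
        by=["p_pearson", "fold_enrichment", "term_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def protrusion_term_percentage(ranked_terms: pd.DataFrame, top_k: int = 50) -> float:
    """Percent of the top-k ranked terms that are flagged protrusion-related."""
    if top_k > len(ranked_terms):
        raise ValidationError(
            f"top_k={top_k} exceeds the {len(ranked_terms)} ranked terms"
        )
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    head = ranked_terms.iloc[:top_k]
    return 100.0 * float(head["is_protrusion_related"].sum()) / top_k


def localization_profile(
    sample: set[str],
    control: set[str],
    annotations: Sequence[AnnotationTerm],
) -> pd.DataFrame:
    """Per-compartment enrichment/depletion of a sample against a control list.

    The control is the background population (exclusive mode when disjoint
    from the sample, inclusive when it contains it).  Compartments absent from
    the control are skipped with a warning.
    """
    if not sample or not control:
        raise ValidationError("sample and control must be non-empty")
    mode = "inclusive" if sample <= control else "exclusive"
    rows = []
    for term in annotations:
        b = len(term.members & control)
        if b == 0:
            warnings.warn(
                f"compartment {term.term_id}: absent from the control background, skipped",
                stacklevel=2,
            )
            continue
        a = len(term.members & sample)
        res = contingency_enrichment(
            a, len(sample), b, len(control), mode, term.term_id, term.term_name
        )
        rows.append(
            {
                "compartment": term.term_id,
                "name": term.term_name,
                "hits_sample": a,
                "size_sample": len(sample),
                "hits_control": b,
                "size_control": len(control),
                "fold_enrichment": res.fold_enrichment,
                "odds_ratio": res.odds_ratio,
                "chi2_pearson": res.chi2_pearson,
                "chi2_yates": res.chi2_yates,
                "p_pearson": res.p_pearson,
                "p_yates": res.p_yates,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compartment", "name", "hits_sample", "size_sample", "hits_control",
            "size_control", "fold_enrichment", "odds_ratio", "chi2_pearson",
            "chi2_yates", "p_pearson", "p_yates", "direction",
        ],
    )
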