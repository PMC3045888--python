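"""Annotation-term prevalence comparisons and family x species screening.

Three generic comparisons cover the annotation-level analyses: a
hypergeometric over/under-representation test for term counts between a
focal dataset and the union, normalised domain-percentage comparison between
two datasets, and a rule-based screen of an orthologous-family x species
count matrix for families specific to, or prominent in, a focal species set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .errors import ParameterError


@dataclass
class TermCounts:
    """Term -> annotated-cluster counts for one dataset."""

    dataset_id: str
    counts: dict = field(default_factory=dict)
    total_annotated: int = 0

    def __post_init__(self):
        bad = [t for t, c in self.counts.items() if c > self.total_annotated]
        if bad:
            raise ParameterError(f"term counts exceed total_annotated: {bad[:3]}")


def hypergeom_term_test(k: int, n: int, K: int, N: int):
    """Over/under-representation tails for one term.

    ``X ~ Hypergeometric(N, K, n)``: population ``N`` with ``K`` marked,
    sample ``n``, observed ``k`` marked.  Returns ``(p_over, p_under)`` =
    ``(P[X >= k], P[X <= k])``.
    """
    if not (0 <= k <= min(n, K)):
        raise ParameterError("need 0 <= k <= min(n, K)")
    if K > N or n > N:
        raise ParameterError("margins exceed population size")
    dist = hypergeom(N, K, n)
    p_over = float(dist.sf(k - 1))
    p_under = float(dist.cdf(k))
    return min(p_over, 1.0), min(p_under, 1.0)


def term_enrichment_table(focal: TermCounts, union: TermCounts) -> pd.DataFrame:
    """Hypergeometric test of every union term in the focal dataset, with
    Benjamini–Hochberg FDR columns alongside the raw tails."""
    if focal.total_annotated > union.total_annotated:
        raise ParameterError("focal total exceeds union total")
    rows = []
    for term, big_k in sorted(union.counts.items()):
        k = min(focal.counts.get(term, 0), big_k)
        p_over, p_under = hypergeom_term_test(
            k, focal.total_annotated, big_k, union.total_annotated
        )
        rows.append((term, k, big_k, p_over, p_under))
    df = pd.DataFrame(rows, columns=["term", "k_focal", "K_union", "p_over", "p_under"])
    if not df.empty:
        df["fdr_over"] = false_discovery_control(df["p_over"])
        df["fdr_under"] = false_discovery_control(df["p_under"])
    return df.set_index("term")


def domain_prevalence(counts_a: TermCounts, counts_b: TermCounts) -> pd.DataFrame:
    """Normalised per-term percentages of two datasets, sorted by absolute
    difference (the comparative-histogram view of domain content)."""
    if counts_a.total_annotated <= 0 or counts_b.total_annotated <= 0:
        raise ParameterError("totals must be > 0")
    terms = sorted(set(counts_a.counts) | set(counts_b.counts))
    rows = []
    for t in terms:
        pa = 100.0 * counts_a.counts.get(t, 0) / counts_a.total_annotated
        pb = 100.0 * counts_b.counts.get(t, 0) / counts_b.total_annotated
        rows.append((t, pa, pb, pa - pb, (pa / pb) if pb > 0 else np.inf))
    df = pd.DataFrame(
        rows,
        columns=["term",
                 f"pct_{counts_a.dataset_id}", f"pct_{counts_b.dataset_id}",
                 "difference", "ratio"],
    ).set_index("term")
    return df.reindex(df["difference"].abs().sort_values(ascending=False).index)


def family_prevalence_screen(
    matrix: pd.DataFrame,
    focal,
    min_focal: int = 3,
    max_other: int = 1,
    prominent_ratio: float = 3.0,
) -> pd.Series:
    """Label each family row as ``specific``, ``prominent`` or ``background``.

    * specific: total focal members >= ``min_focal`` and every non-focal
      species has zero members;
    * prominent: total focal members >= ``min_focal``, every non-focal count
      <= ``max_other``, and the focal total is at least ``prominent_ratio``
      times the largest non-focal count;
    * background: everything else.
    """
    focal = list(focal)
    unknown = set(focal) - set(matrix.columns)
    if unknown:
        raise ParameterError(f"unknown species: {sorted(unknown)}")
    if (matrix.to_numpy() < 0).any():
        raise ParameterError("family counts must be nonnegative")
    other = [c for c in matrix.columns if c not in focal]
    focal_sum = matrix[focal].sum(axis=1)
    other_max = matrix[other].max(axis=1) if other else pd.Series(0, index=matrix.index)

    labels = pd.Series("background", index=matrix.index, name="label")
    enough = focal_sum >= min_focal
    labels[enough & (other_max == 0)] = "specific"
    prominent = (
        enough
        & (other_max > 0)
        & (other_max <= max_other)
        & (focal_sum >= prominent_ratio * other_max)
    )
    labels[prominent] = "prominent"
    return labels
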