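"""Digital differential expression from EST library counts.

Two complementary tests identify contigs whose EST frequency differs across
cDNA libraries:

* the Audic–Claverie (AC) exact test — the probability of observing count
  ``y`` in one library given count ``x`` in another, conditional on library
  sizes ``n1`` and ``n2``::

      p(y | x) = (n2/n1)^y * (x+y)! / (x! y! (1 + n2/n1)^(x+y+1))

  with a two-sided p-value by tail doubling; and

* the R statistic — a log-likelihood-ratio measure of count heterogeneity
  over all libraries at once,
  ``R = sum_j x_j ln(x_j / (N_j * sum(x)/sum(N)))``, with an asymptotic
  chi-square(m-1) null for ``2R``.

The selection procedure merges related libraries, drops shallow libraries
and low-count contigs, applies the R test at a Bonferroni-adjusted level,
marks contigs whose AC p-value against every other library drops below the
per-comparison threshold for at least one library, and returns the union.
Selected profiles (row-normalised frequencies) feed a correlation-distance
hierarchical clustering for heat-map rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, complete, leaves_list, single, to_tree
from scipy.stats import chi2

from .errors import DataError, ParameterError

_LINKAGES = {"average": average, "complete": complete, "single": single}


# ---------------------------------------------------------------------------
# Audic–Claverie exact test
# ---------------------------------------------------------------------------

def _log_ac_term(y: int, x: int, log_r: float, log_1p_r: float) -> float:
    return (
        y * log_r
        + math.lgamma(x + y + 1)
        - math.lgamma(x + 1)
        - math.lgamma(y + 1)
        - (x + y + 1) * log_1p_r
    )


def ac_tails(x: int, y: int, n1: int, n2: int):
    """Lower and upper tail probabilities ``(P[Y <= y], P[Y >= y])`` of the
    AC conditional law of ``y`` given ``x``.

    Terms are evaluated in log space; the upper tail is summed directly with
    geometric truncation (the conditional law of ``y`` is negative binomial,
    so terms beyond the mean decay at rate ``r/(1+r)``).
    """
    if n1 < 1 or n2 < 1:
        raise ParameterError("library totals must be >= 1")
    if not (0 <= x <= n1) or not (0 <= y <= n2):
        raise ParameterError("counts must lie within their library totals")
    r = n2 / n1
    log_r, log_1p_r = math.log(r), math.log1p(r)

    lower = math.fsum(
        math.exp(_log_ac_term(yy, x, log_r, log_1p_r)) for yy in range(y + 1)
    )
    # upper tail: sum from y upward until terms vanish relative to the total
    terms = []
    yy = y
    term = math.exp(_log_ac_term(y, x, log_r, log_1p_r))
    running = 0.0
    mode = r * (x + 1)  # terms increase until roughly here, then decay
    while term > 0.0 and (yy < mode + 10 or term > 1e-16 * max(running, 1e-300)):
        terms.append(term)
        running += term
        yy += 1
        term = term * r * (x + yy) / (yy * (1.0 + r))
    upper = math.fsum(terms)
    return min(lower, 1.0), min(upper, 1.0)


def ac_pvalue(x: int, y: int, n1: int, n2: int, two_sided: bool = True) -> float:
    """AC p-value for counts ``x`` (library of size ``n1``) vs ``y``
    (library of size ``n2``).

    The two-sided value is ``min(1, 2 * min(lower, upper))`` over the tails
    of the conditional law.  The argument pair is first put into a canonical
    orientation (the smaller ``(count, total)`` pair conditions), so the
    p-value is symmetric under swapping ``(x, n1) <-> (y, n2)``.
    """
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    lower, upper = ac_tails(x, y, n1, n2)
    if not two_sided:
        return min(lower, upper)
    p = min(1.0, 2.0 * min(lower, upper))
    # snap float-summation residue: at x == y, n1 == n2 the lower tail is
    # exactly 1/2, so the two-sided value is exactly 1
    if 1.0 - p < 5e-13:
        p = 1.0
    return p


# ---------------------------------------------------------------------------
# R statistic
# ---------------------------------------------------------------------------

def r_statistic(counts, totals):
    """R statistic and its asymptotic p-value for one contig.

    ``counts`` are the contig's ESTs per library, ``totals`` the library
    sizes.  Returns ``(R, p)`` with ``p`` from ``2R ~ chi-square(m-1)``.
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.size < 2:
        raise ParameterError("R statistic needs at least two libraries")
    if n.sum() <= 0:
        raise ParameterError("library totals must sum to > 0")
    if (x < 0).any() or (n <= 0).any():
        raise ParameterError("negative counts or empty libraries")
    rate = x.sum() / n.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(x > 0, x * np.log(x / (n * rate)), 0.0)
    r = float(contrib.sum())
    r = max(r, 0.0)  # guards float residue; the statistic is nonnegative
    p = float(chi2.sf(2.0 * r, df=x.size - 1))
    return r, p


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class DeConfig:
    alpha: float = 0.05
    min_library_ests: int = 300
    min_contig_ests: int = 3
    merge_map: dict = field(default_factory=dict)  # library_id -> merged group id
    bonferroni: bool = True
    ac_threshold: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.min_contig_ests < 3:
            raise ParameterError("min_contig_ests must be >= 3 (more than two ESTs)")


@dataclass
class DeResult:
    contig_id: str
    r_value: float
    r_pvalue: float
    ac_matrix: pd.DataFrame  # library x library pairwise AC p-values
    significant_by: set
    profile: pd.Series  # normalised per-library fractions (sums to 1)


def merge_libraries(matrix: pd.DataFrame, merge_map: dict) -> pd.DataFrame:
    """Sum count columns into merged library groups per ``merge_map``;
    unmapped libraries keep their own id."""
    groups = {lib: merge_map.get(lib, lib) for lib in matrix.columns}
    return matrix.T.groupby(matrix.columns.map(groups)).sum().T


def select_de_contigs(matrix: pd.DataFrame, cfg: DeConfig | None = None):
    """Differentially expressed contigs: union of the R and AC selections.

    Steps: merge libraries, drop libraries below ``min_library_ests`` total
    ESTs, drop contigs below ``min_contig_ests``, apply the R test at
    ``alpha / n_tested`` (Bonferroni), mark a contig AC-significant when for
    at least one library its AC p-value against every other library is below
    ``ac_threshold``, and return the union.
    """
    cfg = cfg or DeConfig()
    if matrix.empty:
        raise ParameterError("count matrix is empty")
    merged = merge_libraries(matrix, cfg.merge_map)
    lib_totals = merged.sum(axis=0)
    kept_libs = lib_totals[lib_totals >= cfg.min_library_ests].index
    if len(kept_libs) < 2:
        raise DataError("fewer than two libraries survive the depth filter")
    merged = merged[kept_libs]
    totals = merged.sum(axis=0)
    tested = merged[merged.sum(axis=1) >= cfg.min_contig_ests]
    if tested.empty:
        return []

    n_tested = len(tested)
    r_cut = cfg.alpha / n_tested if cfg.bonferroni else cfg.alpha
    libs = list(tested.columns)
    total_vec = totals[libs].to_numpy()

    results = []
    for contig_id, row in tested.iterrows():
        counts = row.to_numpy()
        r_val, r_p = r_statistic(counts, total_vec)
        ac = pd.DataFrame(np.ones((len(libs), len(libs))), index=libs, columns=libs)
        for i in range(len(libs)):
            for j in range(i + 1, len(libs)):
                p = ac_pvalue(int(counts[i]), int(counts[j]),
                              int(total_vec[i]), int(total_vec[j]))
                ac.iat[i, j] = ac.iat[j, i] = p
        sig = set()
        if r_p < r_cut:
            sig.add("R")
        arr = ac.to_numpy().copy()
        np.fill_diagonal(arr, 0.0)  # self-comparison never blocks the rule
        if (arr < cfg.ac_threshold).all(axis=1).any():
            sig.add("AC")
        if sig:
            results.append(
                DeResult(
                    contig_id=contig_id,
                    r_value=r_val,
                    r_pvalue=r_p,
                    ac_matrix=ac,
                    significant_by=sig,
                    profile=row / row.sum(),
                )
            )
    return results


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------

def correlation_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed distance vector: 1 - Pearson correlation of row profiles.

    Zero-variance profiles are uncorrelated-by-convention: distance 1 to
    every other profile (0 to an identical constant profile would be
    undefined; the convention keeps the matrix valid).
    """
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0.0 or norms[j] == 0.0:
                dist.append(1.0)
            else:
                corr = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
                dist.append(1.0 - max(-1.0, min(1.0, corr)))
    return np.asarray(dist)


def profile_cluster(results, linkage: str = "average"):
    """Hierarchically cluster DE contig profiles by correlation distance.

    Returns ``(linkage_matrix, leaf_order, reordered_profiles)`` where
    ``reordered_profiles`` is the normalised contig x library matrix in leaf
    order, ready for grayscale heat-map rendering.
    """
    if len(results) < 2:
        raise ParameterError("need at least two profiles to cluster")
    if linkage not in _LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}")
    profiles = pd.DataFrame({r.contig_id: r.profile for r in results}).T
    dist = correlation_distance_matrix(profiles)
    z = _LINKAGES[linkage](dist)
    order = leaves_list(z)
    return z, list(profiles.index[order]), profiles.iloc[order]


def linkage_to_newick(z, labels) -> str:
    """Serialise a scipy linkage tree as a Newick string (branch lengths are
    merge-height differences)."""
    tree = to_tree(z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    root = tree
    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def plot_heatmap(profiles: pd.DataFrame, path, z=None):
    """Grayscale heat map of normalised profiles (black = high frequency),
    optionally with a row dendrogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if z is not None:
        fig, (ax_d, ax_h) = plt.subplots(
            1, 2, figsize=(10, max(4, 0.12 * len(profiles))),
            gridspec_kw={"width_ratios": [1, 4]},
        )
        dendrogram(z, orientation="left", no_labels=True, ax=ax_d,
                   color_threshold=0, link_color_func=lambda _: "k")
        ax_d.set_axis_off()
    else:
        fig, ax_h = plt.subplots(figsize=(8, max(4, 0.12 * len(profiles))))
    ax_h.imshow(profiles.to_numpy(), aspect="auto", cmap="gray_r",
                interpolation="nearest")
    ax_h.set_xticks(range(profiles.shape[1]))
    ax_h.set_xticklabels(profiles.columns, rotation=90, fontsize=6)
    ax_h.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
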