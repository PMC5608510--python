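"""Overlap, correlation, clustering and directionality statistics on gene sets.

Coregulator-dependent gene sets are compared with upper-tail (enrichment)
hypergeometric tests against a declared universe — by default the analysis
panel of nominated AR target genes, not the genome; this choice materially
changes the p-values and is exposed everywhere. Direction tags record
whether the magnitude of androgen regulation increased or decreased after
coregulator loss, enabling the conditional directionality-consistency
percentages and Pearson-correlation-based set combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

INCREASED = "increased"
DECREASED = "decreased"


@dataclass(frozen=True)
class SignedGeneSet:
    """A labeled gene set with a per-gene direction tag.

    ``directions`` maps gene -> "increased" / "decreased" (effect of
    coregulator loss on the magnitude of androgen regulation) or None when
    the direction is unknown/conflicting (only produced by set merging).
    """

    label: str
    directions: Mapping[str, str | None]

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.directions)

    def tagged(self, direction: str) -> frozenset[str]:
        return frozenset(g for g, d in self.directions.items() if d == direction)

    def __len__(self) -> int:
        return len(self.directions)

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, coregulator: str) -> "SignedGeneSet":
        """Build the affected set for one coregulator from a long calls table.

        "+" categories tag genes as increased, "−" categories as decreased.
        """
        sub = calls[(calls["coregulator"] == coregulator) & (calls["category"] != "unaffected")]
        directions = {
            str(g): (INCREASED if cat.endswith("+") else DECREASED)
            for g, cat in zip(sub["gene"], sub["category"])
        }
        return cls(coregulator, directions)


@dataclass(frozen=True)
class OverlapStat:
    label_a: str
    label_b: str
    N: int  # universe size
    K: int  # |A|
    n: int  # |B|
    k: int  # |A ∩ B|
    p_value: float  # upper-tail P(X >= k), X ~ Hypergeom(N, K, n)


def hypergeometric_overlap(
    set_a: SignedGeneSet | set,
    set_b: SignedGeneSet | set,
    universe: Sequence[str] | set,
) -> OverlapStat:
    """Upper-tail hypergeometric significance of the overlap of two gene sets."""
    la = set_a.label if isinstance(set_a, SignedGeneSet) else "A"
    lb = set_b.label if isinstance(set_b, SignedGeneSet) else "B"
    a = set(set_a.members if isinstance(set_a, SignedGeneSet) else set_a)
    b = set(set_b.members if isinstance(set_b, SignedGeneSet) else set_b)
    uni = set(universe)
    offenders = sorted((a | b) - uni)
    if offenders:
        raise ValueError(f"set members outside universe: {offenders}")
    N, K, n, k = len(uni), len(a), len(b), len(a & b)
    # P(X >= k); scipy's sf works in log space internally
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return OverlapStat(la, lb, N, K, n, k, p)


@dataclass(frozen=True)
class PairwiseOverlap:
    counts: pd.DataFrame  # symmetric; diagonal = set sizes
    p_values: pd.DataFrame  # symmetric; diagonal NaN
    n_pairs: int
    n_significant: dict[float, int]  # alpha -> number of pairs with p < alpha


def pairwise_overlap_matrix(
    sets: Sequence[SignedGeneSet],
    universe: Sequence[str] | set,
    alphas: Sequence[float] = (0.05, 0.01),
) -> PairwiseOverlap:
    """All unordered pairwise hypergeometric overlap tests among ``sets``.

    m sets yield C(m, 2) tests (17 sets -> 136). The count matrix is
    symmetric with set sizes on the diagonal.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = [s.label for s in sets]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate set labels")
    m = len(sets)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    pvals = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for s in sets:
        counts.loc[s.label, s.label] = len(s)
    n_sig = {float(a): 0 for a in alphas}
    n_pairs = 0
    for sa, sb in combinations(sets, 2):
        st = hypergeometric_overlap(sa, sb, universe)
        counts.loc[sa.label, sb.label] = counts.loc[sb.label, sa.label] = st.k
        pvals.loc[sa.label, sb.label] = pvals.loc[sb.label, sa.label] = st.p_value
        for a in n_sig:
            if st.p_value < a:
                n_sig[a] += 1
        n_pairs += 1
    return PairwiseOverlap(counts, pvals, n_pairs, n_sig)


def directionality_consistency(
    set_a: SignedGeneSet, set_b: SignedGeneSet
) -> dict[str, float | int]:
    """Conditional directionality agreement between two signed gene sets.

    Reports the overlap size, the four conditional percentages — e.g.
    ``a_increased_in_b_pct``: of A-increased genes that are also members of
    B, the percent that are B-increased — and the counts of overlap genes
    with consistent vs opposite tags. Percentages are on the 0–100 scale;
    an empty denominator yields NaN.
    """

    def _pct(source: SignedGeneSet, other: SignedGeneSet, direction: str) -> float:
        in_other = source.tagged(direction) & other.members
        if not in_other:
            return float("nan")
        agree = sum(1 for g in in_other if other.directions.get(g) == direction)
        return 100.0 * agree / len(in_other)

    overlap = set_a.members & set_b.members
    consistent = sum(
        1
        for g in overlap
        if set_a.directions.get(g) is not None
        and set_a.directions.get(g) == set_b.directions.get(g)
    )
    opposite = sum(
        1
        for g in overlap
        if None not in (set_a.directions.get(g), set_b.directions.get(g))
        and set_a.directions.get(g) != set_b.directions.get(g)
    )
    return {
        "overlap": len(overlap),
        "a_increased_in_b_pct": _pct(set_a, set_b, INCREASED),
        "b_increased_in_a_pct": _pct(set_b, set_a, INCREASED),
        "a_decreased_in_b_pct": _pct(set_a, set_b, DECREASED),
        "b_decreased_in_a_pct": _pct(set_b, set_a, DECREASED),
        "consistent": consistent,
        "opposite": opposite,
    }


def effect_correlation(delta_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between coregulator columns of interaction effects.

    Zero-variance columns get correlation 0 with the others (warned), so the
    matrix stays total and the r >= r_min combination rule stays defined;
    the diagonal is kept at 1.
    """
    if delta_matrix.shape[1] < 2:
        raise ValueError("need >= 2 coregulator columns")
    if delta_matrix.shape[0] < 3:
        raise ValueError("need >= 3 genes")
    corr = delta_matrix.corr(method="pearson")
    const = delta_matrix.std(ddof=0) == 0
    if const.any():
        warnings.warn(
            f"zero-variance columns, correlations set to 0: {list(const[const].index)}"
        )
        for c in const[const].index:
            corr.loc[c, :] = 0.0
            corr.loc[:, c] = 0.0
            corr.loc[c, c] = 1.0
    return corr


def combine_pairs(
    corr: pd.DataFrame,
    sets: Sequence[SignedGeneSet],
    r_min: float = 0.25,
    top_k: int | None = None,
) -> list[tuple[str, str, float, SignedGeneSet]]:
    """Merge the most-correlated pairs of gene sets (Pearson r >= r_min).

    Pairs are returned in descending r (ties broken by label order, so the
    result is invariant to column reordering); ``top_k`` keeps only the
    strongest pairs. Each merged set is the union of the two member sets;
    direction tags are retained where the two sets agree and dropped (None)
    where they conflict.
    """
    by_label = {s.label: s for s in sets}
    pairs = []
    for la, lb in combinations(sorted(corr.index), 2):
        r = float(corr.loc[la, lb])
        if r >= r_min:
            pairs.append((la, lb, r))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    if top_k is not None:
        pairs = pairs[:top_k]
    merged = []
    for la, lb, r in pairs:
        sa, sb = by_label[la], by_label[lb]
        directions: dict[str, str | None] = {}
        for g in sa.members | sb.members:
            da, db = sa.directions.get(g), sb.directions.get(g)
            if g in sa.members and g in sb.members:
                directions[g] = da if da == db else None
            else:
                directions[g] = da if g in sa.members else db
        merged.append((la, lb, r, SignedGeneSet(f"{la}|{lb}", directions)))
    return merged


@dataclass(frozen=True)
class ClusterResult:
    leaf_order: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge tree)
    newick: str
    constant_profiles: list[str] = field(default_factory=list)


def cluster_genes(call_matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering on 1 − Pearson row distances.

    ``call_matrix`` holds genes × coregulators entries in {−1, 0, +1} (or any
    numeric profile). Genes with a constant profile have an undefined Pearson
    correlation; they are assigned distance 1 to every other gene and flagged.
    Returns the heatmap leaf order, the scipy merge tree, and a newick
    rendering of the tree.
    """
    if call_matrix.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    X = call_matrix.to_numpy(dtype=float)
    const = X.std(axis=1) == 0
    if not (~const).sum() >= 2:
        raise ValueError("need >= 2 genes with non-constant profiles")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0  # constant-profile rows -> distance 1
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(Z)
    gene_ids = [str(g) for g in call_matrix.index]
    newick = _linkage_to_newick(Z, gene_ids)
    return ClusterResult(
        [gene_ids[i] for i in leaves],
        Z,
        newick,
        [g for g, c in zip(gene_ids, const) if c],
    )


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
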