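"""Phylogenetic plumbing for the null models: Newick I/O, rooting at the
longest branch, cophenetic (tip-to-tip path length) distances, and the
Mantel correlogram used to verify phylogenetic signal in niche differences.

Trees are scikit-bio ``TreeNode`` objects throughout. Tree construction
(alignment, NJ, ML optimisation) is upstream of this package; it consumes a
Newick file with branch lengths.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .tables import CountTable

__all__ = [
    "parse_newick",
    "write_newick",
    "read_tree",
    "write_tree",
    "root_longest_branch",
    "cophenetic",
    "mantel_correlogram",
    "niche_from_sample_scores",
    "niche_from_profiles",
    "trait_distance_matrix",
]

logger = logging.getLogger(__name__)


class NewickError(ValueError):
    """Raised for malformed Newick input."""


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a TreeNode, validating tip uniqueness."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # format sniffing on StringIO
            tree = TreeNode.read(StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise NewickError(f"malformed Newick: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) == 0:
        raise NewickError("tree has no tips")
    if any(t is None for t in tips):
        raise NewickError("unnamed tip in tree")
    seen, dups = set(), set()
    for t in tips:
        (dups if t in seen else seen).add(t)
    if dups:
        raise NewickError(f"duplicate tip labels: {sorted(dups)}")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_tree(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_tree(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def root_longest_branch(tree: TreeNode) -> TreeNode:
    """Re-root a tree at the midpoint of its longest branch.

    Tip-to-tip path lengths are unchanged by rooting. Ties for the longest
    branch are broken deterministically (first in preorder traversal) and
    logged.
    """
    if tree.count(tips=True) < 2:
        raise ValueError("need at least 2 tips to root")
    branches = [
        n for n in tree.preorder(include_self=False) if n.length is not None
    ]
    if not branches:
        raise ValueError("tree has no branch lengths")
    max_len = max(n.length for n in branches)
    ties = [n for n in branches if n.length == max_len]
    if len(ties) > 1:
        logger.info(
            "tie for longest branch (%d branches of length %g); "
            "using first in preorder", len(ties), max_len,
        )
    target = ties[0]
    return tree.root_at(target, above=target.length / 2.0, reset=True)


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix."""
    for n in tree.preorder(include_self=False):
        if n.length is None:
            raise ValueError(f"missing branch length at node {n.name!r}")
    return tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# Niche proxies and the Mantel correlogram
# ---------------------------------------------------------------------------

def trait_distance_matrix(traits: pd.Series) -> DistanceMatrix:
    """Pairwise absolute trait differences as a DistanceMatrix."""
    v = traits.to_numpy(dtype=float)
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(d, ids=[str(i) for i in traits.index])


def niche_from_sample_scores(table: CountTable, sample_scores: pd.Series) -> DistanceMatrix:
    """Niche proxy: abundance-weighted mean of a per-sample score, per taxon.

    For every taxon the proxy is the mean of ``sample_scores`` weighted by
    that taxon's counts across samples; the niche distance is the absolute
    difference of proxies. Suitable when an environmental value per sample is
    known (e.g. synthetic data).
    """
    scores = sample_scores.loc[table.sample_ids].to_numpy(dtype=float)
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = table.counts.index[totals == 0].tolist()
        raise ValueError(f"taxa with zero total counts: {bad}")
    proxy = (counts @ scores) / totals
    return trait_distance_matrix(pd.Series(proxy, index=table.counts.index))


def niche_from_profiles(table: CountTable) -> DistanceMatrix:
    """Niche proxy: Euclidean distance between per-taxon occurrence profiles.

    Each taxon's profile is its vector of relative abundances across samples,
    normalised to sum 1; taxa with similar habitat usage are close.
    """
    rel = table.relative_abundance().to_numpy()
    totals = rel.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = table.counts.index[totals.ravel() == 0].tolist()
        raise ValueError(f"taxa with zero total counts: {bad}")
    prof = rel / totals
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(prof, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in table.counts.index])


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj_sorted = np.minimum(
        np.maximum.accumulate((m - np.arange(m)) * pvals[order]), 1.0
    )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _progressive_holm(pvals: np.ndarray) -> np.ndarray:
    """Progressive Holm correction: class k is Holm-adjusted among classes 1..k."""
    return np.array([_holm(pvals[: k + 1])[k] for k in range(len(pvals))])


def mantel_correlogram(
    niche_dist: DistanceMatrix,
    phylo_dist: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel correlogram of niche distances against phylogenetic distance classes.

    Phylogenetic distances are binned into ``n_classes`` equal-width classes
    (Sturges' rule by default). For each class the statistic is the negated
    Pearson correlation between the unrolled niche distances and the 0/1
    within-class indicator, so that positive r at short distances means
    closely related taxa have similar niches. p-values come from permuting
    taxa of the niche matrix (two-tailed) with progressive Holm correction
    across classes. Classes with fewer than 2 pairs are dropped and logged.
    """
    ids = list(phylo_dist.ids)
    if set(ids) != set(niche_dist.ids):
        raise ValueError("matrices must share taxon ids")
    niche = niche_dist.filter(ids).data
    phylo = phylo_dist.data
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    pvec = phylo[iu]
    nvec = niche[iu]

    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(len(pvec))))  # Sturges
    edges = np.linspace(pvec.min(), pvec.max(), n_classes + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.digitize(pvec, edges) - 1

    indicators, midpoints, kept = [], [], []
    for k in range(n_classes):
        mask = which == k
        if mask.sum() < 2:
            logger.info("distance class %d has <2 pairs; dropped", k)
            continue
        indicators.append(mask.astype(float))
        midpoints.append(0.5 * (edges[k] + min(edges[k + 1], pvec.max())))
        kept.append(k)
    if not indicators:
        raise ValueError("no distance class has at least 2 pairs")
    ind = np.vstack(indicators)  # (K, n_pairs)

    def stats(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean()
        xs = np.sqrt((xc**2).sum())
        ic = ind - ind.mean(axis=1, keepdims=True)
        is_ = np.sqrt((ic**2).sum(axis=1))
        return -(ic @ xc) / (is_ * xs)

    r_obs = stats(nvec)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        npm = niche[np.ix_(perm, perm)][iu]
        exceed += np.abs(stats(npm)) >= np.abs(r_obs)
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    df = pd.DataFrame(
        {
            "class_index": kept,
            "class_midpoint": midpoints,
            "n_pairs": ind.sum(axis=1).astype(int),
            "mantel_r": r_obs,
            "p_value": pvals,
            "p_corrected": _progressive_holm(pvals),
        }
    )
    return df
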