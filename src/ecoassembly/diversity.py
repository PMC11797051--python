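"""Alpha and beta diversity: Hill numbers, Chao1, Bray-Curtis, PCoA,
one-way PERMANOVA, SIMPER, two-sample test selection, shared-ASV fractions.

Alpha diversity follows the Hill-number framing: the order-1 diversity is
the exponential of Shannon entropy (natural log), i.e. the effective number
of equally abundant taxa, and evenness is that number divided by the
observed richness. Beta diversity is Bray-Curtis; the pipeline computes
dissimilarities internally and converts to similarity (1 - d) only at the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults

from .tables import CountTable

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova_oneway",
    "PermanovaResult",
    "simper",
    "compare_groups",
    "GroupComparison",
    "shared_asv_fraction",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    s = int(np.count_nonzero(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s)
    if f2 == 0:
        # classic form degenerates; fall back to bias-corrected convention
        return s + f1 * (f1 - 1) / 2.0
    return s + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: CountTable, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample richness S, Chao1, exp-Shannon (Hill order 1) and evenness.

    Shannon entropy H uses natural log; ``shannon_exp`` = e^H and
    ``evenness`` = e^H / S. Chao1 is bias-corrected by default:
    S + F1(F1-1) / (2(F2+1)) with F1/F2 the singleton/doubleton counts.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"empty samples: {bad}")
    rows = {}
    for sample in table.sample_ids:
        c = table.counts[sample].to_numpy()
        c = c[c > 0]
        p = c / c.sum()
        h = -np.sum(p * np.log(p))
        s = len(c)
        rows[sample] = {
            "richness": s,
            "chao1": _chao1(c, bias_corrected=bias_corrected),
            "shannon_exp": float(np.exp(h)),
            "evenness": float(np.exp(h)) / s,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(x, y) = sum |x_t - y_t| / sum (x_t + y_t). Similarity, where the
    reporting mirrors similarity conventions, is 1 - d.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero samples cannot be compared: {bad}")
    mat = table.counts.to_numpy(dtype=float).T
    d = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(s) for s in table.sample_ids])


def _classical_scaling(d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def pcoa(dm: DistanceMatrix, lingoes: bool = False) -> OrdinationResults:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers -0.5 * D^2 and eigendecomposes. Negative eigenvalues
    (non-Euclidean input) are reported as-is, with zero coordinates and zero
    proportion explained; set ``lingoes=True`` to apply the Lingoes additive
    correction instead. Axes are ordered by decreasing eigenvalue.
    """
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    d2 = dm.data.astype(float) ** 2
    eigvals, eigvecs = _classical_scaling(d2)
    if lingoes and eigvals[-1] < 0:
        c = -eigvals[-1]
        d2c = d2 + 2.0 * c
        np.fill_diagonal(d2c, 0.0)
        eigvals, eigvecs = _classical_scaling(d2c)
    # numerical dust around zero is clipped for the coordinate scaling only
    pos = np.where(eigvals > 1e-10 * max(abs(eigvals[0]), 1.0), eigvals, 0.0)
    coords = eigvecs * np.sqrt(pos)
    total_pos = pos.sum()
    prop = pos / total_pos if total_pos > 0 else np.zeros_like(pos)
    axes = [f"PC{i + 1}" for i in range(len(eigvals))]
    return OrdinationResults(
        short_method_name="PCoA",
        long_method_name="Principal Coordinate Analysis",
        eigvals=pd.Series(eigvals, index=axes),
        samples=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        proportion_explained=pd.Series(prop, index=axes),
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PERMANOVA pseudo-F = {self.pseudo_f:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations)"
        )


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    a = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova_oneway(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free label permutation.

    The pseudo-F is computed from within/between sums of squared distances;
    the p-value is (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    labels = np.asarray(
        grouping.loc[list(dm.ids)] if isinstance(grouping, pd.Series) else grouping
    )
    if len(labels) != dm.shape[0]:
        raise ValueError("grouping length must match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    d2 = dm.data.astype(float) ** 2
    n = d2.shape[0]
    a = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    f_obs = _permanova_f(d2, labels, groups)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    labels_perm = labels[perms]  # (n_perm, n)
    ss_within = np.zeros(n_perm)
    for g, n_g in zip(groups, counts):
        m = (labels_perm == g).astype(float)
        ss_within += ((m @ d2) * m).sum(axis=1) / (2.0 * n_g)
    f_perm = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        group_sizes={g: int(c) for g, c in zip(groups.tolist(), counts)},
    )


def simper(table: CountTable, grouping) -> pd.DataFrame:
    """SIMPER: per-taxon contribution to between-group Bray-Curtis dissimilarity.

    For every between-group sample pair the per-taxon contribution is
    |x_t - y_t| / sum_k (x_k + y_k); these sum to the pair's Bray-Curtis
    dissimilarity. Contributions are averaged over all between-group pairs
    and reported with percent and cumulative-percent columns, sorted
    descending.
    """
    labels = (
        grouping.loc[table.sample_ids]
        if isinstance(grouping, pd.Series)
        else pd.Series(list(grouping), index=table.sample_ids)
    )
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"SIMPER requires exactly two groups, got {list(groups)}")
    ids_a = labels.index[labels == groups[0]]
    ids_b = labels.index[labels == groups[1]]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both groups must be non-empty")

    xa = table.counts[ids_a].to_numpy(dtype=float)  # taxa x nA
    xb = table.counts[ids_b].to_numpy(dtype=float)  # taxa x nB
    n_pairs = xa.shape[1] * xb.shape[1]
    contrib = np.zeros(table.n_taxa)
    for i in range(xa.shape[1]):
        diff = np.abs(xa[:, [i]] - xb)              # taxa x nB
        denom = (xa[:, i].sum() + xb.sum(axis=0))   # nB
        contrib += (diff / denom).sum(axis=1)
    contrib /= n_pairs

    total = contrib.sum()
    df = pd.DataFrame(
        {
            "average_contribution": contrib,
            "percent": 100.0 * contrib / total if total > 0 else 0.0,
        },
        index=table.counts.index,
    ).sort_values("average_contribution", ascending=False)
    df["cumulative_percent"] = df["percent"].cumsum()
    df.index.name = "taxon_id"
    return df


# ---------------------------------------------------------------------------
# Two-sample comparison with test-selection logic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    test: str           # "student_t" | "welch_t" | "wilcoxon_rank_sum"
    statistic: float
    p_value: float
    shapiro_p: tuple    # (group a, group b)
    variance_f_p: float | None


def compare_groups(values_a, values_b, alpha: float = 0.05) -> GroupComparison:
    """Two-sample comparison with the standard test-selection cascade.

    Shapiro-Wilk on both groups; if either is non-normal (p < alpha) use the
    Wilcoxon rank-sum test. Otherwise an F-test of variances decides between
    Welch's t-test (unequal variance, F-test p < alpha) and Student's t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")

    sw_a = sps.shapiro(a).pvalue
    sw_b = sps.shapiro(b).pvalue
    if sw_a < alpha or sw_b < alpha:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
            (float(sw_a), float(sw_b)), None,
        )

    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfn, dfd = len(a) - 1, len(b) - 1
    p_f = 2.0 * min(sps.f.cdf(f, dfn, dfd), sps.f.sf(f, dfn, dfd))
    p_f = min(p_f, 1.0)
    if p_f < alpha:
        res = sps.ttest_ind(a, b, equal_var=False)
        name = "welch_t"
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    return GroupComparison(
        name, float(res.statistic), float(res.pvalue),
        (float(sw_a), float(sw_b)), float(p_f),
    )


def shared_asv_fraction(table: CountTable, focal_sample, reference_samples) -> float:
    """Fraction of the focal sample's taxa also present in the reference set.

    The "unique" fraction is 1 minus the returned value.
    """
    focal = table.counts[focal_sample]
    focal_taxa = set(focal.index[focal > 0])
    if not focal_taxa:
        raise ValueError(f"focal sample {focal_sample!r} has no taxa")
    ref = table.counts[list(reference_samples)].sum(axis=1)
    ref_taxa = set(ref.index[ref > 0])
    return len(focal_taxa & ref_taxa) / len(focal_taxa)
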