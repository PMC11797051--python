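"""Phylogenetic null models for community assembly.

Within-sample clustering is measured by the mean nearest taxon distance
(MNTD) and its standardized effect size, the nearest taxon index
NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null). Between-sample
turnover uses betaMNTD and betaNTI = (betaMNTD_obs - mean_null) / sd_null.
The null model shuffles taxon labels across the tips of the phylogeny
(equivalently, relabels the cophenetic distance matrix) while holding the
community abundance structure fixed; abundances are never shuffled.

Classification of pairwise comparisons follows the standard two-sided
threshold: betaNTI > 2 -> heterogeneous selection (phylogenetic turnover
greater than chance), betaNTI < -2 -> homogeneous selection, |betaNTI| <= 2
-> stochastic assembly. NTI > 2 indicates a community more phylogenetically
clustered than chance, NTI < -2 overdispersion.

For small taxon pools (<= 8) the null distribution can be enumerated
exhaustively over all pool permutations instead of sampled.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .tables import CountTable

__all__ = [
    "mntd",
    "bmntd",
    "nti",
    "beta_nti",
    "classify_process",
    "summarize_processes",
    "PROCESS_CLASSES",
]

PROCESS_CLASSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "stochastic",
    "undefined",
)

_EXHAUSTIVE_LIMIT = 8


def _as_matrix(d) -> tuple[np.ndarray, list]:
    if isinstance(d, DistanceMatrix):
        return d.data.astype(float), list(d.ids)
    raise TypeError("d must be a skbio DistanceMatrix")


def _mntd_from_positions(
    dmat: np.ndarray, positions: np.ndarray, weights: np.ndarray | None
) -> float:
    sub = dmat[np.ix_(positions, positions)].copy()
    np.fill_diagonal(sub, np.inf)
    mins = sub.min(axis=1)
    if weights is None:
        return float(mins.mean())
    return float(np.dot(weights, mins))


def mntd(community, d: DistanceMatrix, weighted: bool = False) -> float:
    """Mean nearest taxon distance of one community.

    Unweighted: mean over present taxa of the distance to the closest other
    present taxon. Weighted: the same per-taxon minima averaged with
    relative-abundance weights.
    """
    dmat, ids = _as_matrix(d)
    counts = (
        community.reindex(ids).fillna(0).to_numpy(dtype=float)
        if isinstance(community, pd.Series)
        else np.asarray(community, dtype=float)
    )
    if len(counts) != len(ids):
        raise ValueError("community vector length must match distance matrix")
    present = np.flatnonzero(counts > 0)
    if len(present) < 2:
        raise ValueError("MNTD undefined for communities with <2 taxa present")
    weights = None
    if weighted:
        w = counts[present]
        weights = w / w.sum()
    return _mntd_from_positions(dmat, present, weights)


def bmntd(x, y, d: DistanceMatrix, weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance (betaMNTD).

    0.5 * [sum_t w_t min_u d(t, u) + sum_u w_u min_t d(u, t)] where t runs
    over taxa present in x, u over taxa present in y; a taxon shared by both
    communities finds itself at distance zero. Weights are relative
    abundances if ``weighted`` else 1/richness.
    """
    dmat, ids = _as_matrix(d)

    def vec(c):
        return (
            c.reindex(ids).fillna(0).to_numpy(dtype=float)
            if isinstance(c, pd.Series)
            else np.asarray(c, dtype=float)
        )

    cx, cy = vec(x), vec(y)
    px, py = np.flatnonzero(cx > 0), np.flatnonzero(cy > 0)
    if len(px) == 0 or len(py) == 0:
        raise ValueError("betaMNTD undefined for empty communities")
    return _bmntd_from_positions(dmat, px, py, cx[px], cy[py], weighted)


def _bmntd_from_positions(
    dmat: np.ndarray,
    px: np.ndarray,
    py: np.ndarray,
    wx_raw: np.ndarray,
    wy_raw: np.ndarray,
    weighted: bool,
) -> float:
    sub = dmat[np.ix_(px, py)]
    min_x = sub.min(axis=1)
    min_y = sub.min(axis=0)
    if weighted:
        wx = wx_raw / wx_raw.sum()
        wy = wy_raw / wy_raw.sum()
    else:
        wx = np.full(len(px), 1.0 / len(px))
        wy = np.full(len(py), 1.0 / len(py))
    return float(0.5 * (np.dot(wx, min_x) + np.dot(wy, min_y)))


def _null_permutations(
    pool_size: int, runs: int | str, seed: int | None
) -> tuple[list[np.ndarray], bool]:
    """Permutations of pool indices for the taxa-labels null.

    runs="exhaustive" enumerates all pool_size! permutations (pool must be
    small); an integer samples that many uniformly at random.
    """
    if runs == "exhaustive":
        if pool_size > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive null limited to pools of <= {_EXHAUSTIVE_LIMIT} taxa "
                f"(got {pool_size}: {math.factorial(pool_size)} permutations)"
            )
        perms = [np.array(p) for p in itertools.permutations(range(pool_size))]
        return perms, True
    rng = np.random.default_rng(seed)
    return [rng.permutation(pool_size) for _ in range(int(runs))], False


def _null_sd(nulls: np.ndarray, exhaustive: bool) -> float:
    """Null sd with a degeneracy guard.

    A null distribution whose spread is pure floating-point noise (all
    permutations yield the same statistic, e.g. a saturated community) is
    reported as exactly zero so the index is flagged undefined.
    """
    sd = float(nulls.std(ddof=0 if exhaustive else 1))
    scale = max(abs(float(nulls.mean())), 1.0)
    return 0.0 if sd <= 1e-10 * scale else sd


def _resolve_pool(table: CountTable, d: DistanceMatrix, null_pool) -> list:
    ids = list(d.ids)
    if null_pool is None:
        present = table.counts.sum(axis=1) > 0
        pool = [t for t in table.counts.index[present]]
    else:
        pool = list(null_pool)
    missing = set(map(str, pool)) - set(ids)
    if missing:
        raise ValueError(f"pool taxa missing from distance matrix: {sorted(missing)}")
    present_any = set(table.counts.index[table.counts.sum(axis=1) > 0])
    not_covered = present_any - set(pool)
    if not_covered:
        raise ValueError(
            f"null pool must cover all taxa present in the table; "
            f"missing {sorted(map(str, not_covered))[:5]}"
        )
    return pool


def nti(
    table: CountTable,
    d: DistanceMatrix,
    runs: int | str = 999,
    seed: int | None = None,
    weighted: bool = False,
    null_pool: Iterable | None = None,
) -> pd.DataFrame:
    """Nearest taxon index per sample against a tip-shuffle null.

    For each sample the taxon labels of the distance matrix restricted to
    ``null_pool`` (default: all taxa present anywhere in the table, i.e. the
    metacommunity) are permuted ``runs`` times and MNTD recomputed with
    identical weighting. NTI = -(obs - null mean) / null sd; samples where
    the null has zero variance get NaN and a diagnostic note.
    """
    dmat, ids = _as_matrix(d)
    pool = _resolve_pool(table, d, null_pool)
    id_pos = {t: i for i, t in enumerate(ids)}
    pool_positions = np.array([id_pos[str(t)] for t in pool])
    pool_index = {t: i for i, t in enumerate(pool)}
    perms, exhaustive = _null_permutations(len(pool), runs, seed)

    rows = {}
    for sample in table.sample_ids:
        counts = table.counts[sample]
        present_taxa = counts.index[counts > 0]
        if len(present_taxa) < 2:
            raise ValueError(
                f"sample {sample!r} has <2 taxa present; MNTD undefined"
            )
        w = counts[present_taxa].to_numpy(dtype=float)
        weights = w / w.sum() if weighted else None
        obs_pos = np.array([id_pos[str(t)] for t in present_taxa])
        obs = _mntd_from_positions(dmat, obs_pos, weights)

        in_pool = np.array([pool_index[t] for t in present_taxa])
        nulls = np.empty(len(perms))
        for k, perm in enumerate(perms):
            pos = pool_positions[perm[in_pool]]
            nulls[k] = _mntd_from_positions(dmat, pos, weights)
        mean_null = nulls.mean()
        sd_null = _null_sd(nulls, exhaustive)
        value = -(obs - mean_null) / sd_null if sd_null > 0 else np.nan
        rows[sample] = {
            "mntd_obs": obs,
            "null_mean": mean_null,
            "null_sd": sd_null,
            "nti": value,
            "runs": len(perms),
            "weighted": weighted,
            "note": "" if sd_null > 0 else "null sd = 0; NTI undefined",
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def beta_nti(
    table: CountTable,
    d: DistanceMatrix,
    runs: int | str = 999,
    seed: int | None = None,
    weighted: bool = True,
    samples: Sequence | None = None,
    null_pool: Iterable | None = None,
) -> pd.DataFrame:
    """betaNTI for every unordered sample pair, with process classification.

    The null pool defaults to all taxa present in the analysed samples
    (run the function per sample group to reproduce per-group metacommunity
    pools). One tip-label shuffle per run is shared by all pairs, and
    betaMNTD is recomputed under each shuffle with identical weighting.
    betaNTI = (obs - null mean) / null sd.
    """
    sub = table if samples is None else table.select_samples(list(samples))
    if sub.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dmat, ids = _as_matrix(d)
    pool = _resolve_pool(sub, d, null_pool)
    id_pos = {t: i for i, t in enumerate(ids)}
    pool_positions = np.array([id_pos[str(t)] for t in pool])
    pool_index = {t: i for i, t in enumerate(pool)}
    perms, exhaustive = _null_permutations(len(pool), runs, seed)

    # per-sample present positions (within pool) and weights
    info = {}
    for sample in sub.sample_ids:
        counts = sub.counts[sample]
        present = counts.index[counts > 0]
        if len(present) == 0:
            raise ValueError(f"sample {sample!r} is empty")
        info[sample] = (
            np.array([pool_index[t] for t in present]),
            counts[present].to_numpy(dtype=float),
        )

    obs_positions = {s: pool_positions[i] for s, (i, _) in info.items()}
    rows = []
    pairs = list(itertools.combinations(sub.sample_ids, 2))
    null_vals = np.empty((len(pairs), len(perms)))
    for k, perm in enumerate(perms):
        mapped = pool_positions[perm]
        for j, (a, b) in enumerate(pairs):
            ia, wa = info[a]
            ib, wb = info[b]
            null_vals[j, k] = _bmntd_from_positions(
                dmat, mapped[ia], mapped[ib], wa, wb, weighted
            )
    for j, (a, b) in enumerate(pairs):
        ia, wa = info[a]
        ib, wb = info[b]
        obs = _bmntd_from_positions(
            dmat, obs_positions[a], obs_positions[b], wa, wb, weighted
        )
        mean_null = null_vals[j].mean()
        sd_null = _null_sd(null_vals[j], exhaustive)
        value = (obs - mean_null) / sd_null if sd_null > 0 else np.nan
        rows.append(
            {
                "sample_i": a,
                "sample_j": b,
                "bmntd_obs": obs,
                "null_mean": mean_null,
                "null_sd": sd_null,
                "bnti": value,
                "process": classify_process(value),
                "runs": len(perms),
                "weighted": weighted,
            }
        )
    return pd.DataFrame(rows)


def classify_process(bnti: float) -> str:
    """Map a betaNTI value to its assembly-process class.

    > +2: heterogeneous selection; < -2: homogeneous selection; values in
    [-2, 2] (boundaries included): stochastic; non-finite: undefined.
    """
    if bnti is None or not np.isfinite(bnti):
        return "undefined"
    if bnti > 2.0:
        return "heterogeneous_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    return "stochastic"


def summarize_processes(
    results: pd.DataFrame, group_col: str | None = None
) -> pd.DataFrame:
    """Fractions of pairwise comparisons in each assembly-process class.

    ``results`` is a beta_nti output frame, optionally with an added group
    column; fractions are per group over its within-group pairs, and
    ``n_pairs`` satisfies n(n-1)/2 for n within-group samples.
    """
    if group_col is None:
        grouped = [("all", results)]
    else:
        grouped = list(results.groupby(group_col))
    rows = {}
    for name, df in grouped:
        frac = df["process"].value_counts(normalize=True)
        rows[name] = {c: float(frac.get(c, 0.0)) for c in PROCESS_CLASSES}
        rows[name]["n_pairs"] = len(df)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = group_col or "group"
    out["n_pairs"] = out["n_pairs"].astype(int)
    return out
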