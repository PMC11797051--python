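"""Synthetic communities assembled under known ecological processes.

The generator emulates a gnotobiotic fish-rearing amplicon study: a 2x2
factorial design (water treatment x host strain), four replicate flasks per
cell, four gut samples plus one rearing-water sample per flask, repeated
added-water samples, and sparse negative controls — each sample sequenced
to a common read depth by multinomial draws.

Ecology. Taxa live on a simulated phylogeny (pure-birth Yule tree). The
niche is phylogenetically conserved by construction: under selection, a
taxon's fitness is a Gaussian function of its cophenetic distance to a
focal "ecotype" tip, truncated at a hard washout radius beyond which the
taxon cannot persist (flow-through flasks wash out maladapted lineages).
The radius is set so that roughly ``guild_size`` taxa can persist, making
the selected guild a phylogenetically compact neighbourhood. Sampling
weights for one community are

    p_t  proportional to  m_t * n_t * o_t * f(t)

with m a lognormal metacommunity profile shared by all samples, n a
per-sample lognormal drift noise, o a per-sample Bernoulli occupancy mask
(founder effects: a taxon may simply never have colonised this individual
or flask), and f the truncated-Gaussian niche filter.

Scenarios. homogeneous_selection: every flask sample is filtered toward one
shared focal ecotype. heterogeneous_selection: the two water treatments are
filtered toward two phylogenetically distant focal ecotypes. neutral: no
filter (the sigma -> infinity limit). Added-water samples are always drawn
neutrally — they are the source community, sampled before it experiences
the flask environment — which also keeps the dataset-wide metacommunity
broader than any selected guild.

Brownian-motion trait evolution (``evolve_trait_bm``) is provided for
phylogenetic-signal analyses; at this problem size a single Brownian trait
band is far less phylogenetically compact than the guild construction, so
the experiment generator selects on tree distance directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables import CountTable

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "evolve_trait_bm",
    "assemble_sample",
    "generate_experiment",
    "write_manifest",
    "read_manifest",
]

PROCESSES = ("homogeneous_selection", "heterogeneous_selection", "neutral")


@dataclass
class ScenarioConfig:
    """Full parameterisation of a synthetic experiment.

    ``guild_size`` controls selection strength: the washout radius around a
    focal ecotype is the cophenetic distance to its guild_size-th nearest
    neighbour, and the Gaussian niche width is half that radius.
    ``sample_noise_logsd`` is the sd of per-sample lognormal drift noise;
    ``occupancy`` the per-sample probability that a taxon colonised at all.
    """

    n_taxa: int = 200
    birth_rate: float = 1.0
    bm_rate: float = 1.0
    metacommunity_logmean: float = 0.0
    metacommunity_logsd: float = 0.75
    process: str = "homogeneous_selection"
    guild_size: int = 40
    sample_noise_logsd: float = 1.0
    occupancy: float = 0.5
    read_depth: int = 11000
    water_treatments: tuple = ("Add-r", "Add-K")
    strains: tuple = ("wild", "aquaculture")
    flasks_per_group: int = 4
    gut_per_flask: int = 4
    added_water_days: tuple = (14, 16, 18, 21)
    sampling_day: int = 22
    n_controls: int = 2
    n_contaminant_taxa: int = 3
    contaminant_reads_max: int = 3  # per control, below the default QC cap
    added_water_mixture: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not 2 <= self.guild_size < self.n_taxa:
            raise ValueError("guild_size must be in [2, n_taxa)")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed=None) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_taxa`` tips.

    Starting from a single lineage, a uniformly chosen lineage splits after
    an exponential waiting time with rate birth_rate * (#lineages); waiting
    times accumulate onto every active branch. Tips are labelled t0001,
    t0002, ... deterministically.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode(length=None)
    active = [root]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length = (node.length or 0.0) + wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        children = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(children)
        active.extend(children)
    # final waiting interval so every tip has a positive pendant branch
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = (node.length or 0.0) + wait
    root.length = None
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:04d}"
    return root


def evolve_trait_bm(tree: TreeNode, bm_rate: float = 1.0, seed=None) -> pd.Series:
    """Brownian-motion trait values at the tips.

    Root trait 0; each child adds an independent Normal(0, bm_rate * branch
    length) increment, so tip variance grows linearly with depth and closely
    related tips stay similar.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        if node.length is None:
            raise ValueError("tree must have branch lengths")
        sd = float(np.sqrt(bm_rate * node.length))
        values[id(node)] = values[id(node.parent)] + (
            rng.normal(0.0, sd) if sd > 0 else 0.0
        )
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait")


def assemble_sample(
    metacommunity: pd.Series,
    traits: pd.Series,
    env: float | None,
    sigma: float | None,
    depth: int,
    seed=None,
    max_deviation: float | None = None,
) -> pd.Series:
    """Draw one community: multinomial reads under Gaussian niche selection.

    Sampling weights are p_t proportional to m_t * exp(-(trait_t - env)^2 /
    (2 sigma^2)); ``env=None`` or ``sigma=None``/inf gives the neutral limit
    p_t = m_t. ``max_deviation``, if set, zeroes the weight of taxa whose
    trait deviates from env by more than that amount (hard washout edge).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not np.isclose(metacommunity.sum(), 1.0):
        raise ValueError("metacommunity must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = metacommunity.to_numpy(dtype=float).copy()
    if env is not None and sigma is not None and np.isfinite(sigma):
        t = traits.loc[metacommunity.index].to_numpy(dtype=float)
        dev = np.abs(t - env)
        w = w * np.exp(-(dev**2) / (2.0 * sigma**2))
        if max_deviation is not None:
            w[dev > max_deviation] = 0.0
    if not np.any(w > 0):
        raise ValueError(
            "all sampling weights are zero; selection too strict "
            "(increase sigma or move env toward the trait range)"
        )
    counts = rng.multinomial(depth, w / w.sum())
    return pd.Series(counts, index=metacommunity.index, name="count")


def _densest_focal(dmat: np.ndarray, guild_size: int, candidates=None) -> int:
    """Tip whose guild_size-th nearest neighbour is closest (densest guild)."""
    kth = np.sort(dmat, axis=1)[:, guild_size]
    if candidates is not None:
        masked = np.full_like(kth, np.inf)
        masked[candidates] = kth[candidates]
        kth = masked
    return int(np.argmin(kth))


def _flask_label(treatment: str, strain: str, k: int) -> str:
    return f"F-{treatment}-{strain}-{k + 1}"


def generate_experiment(config: ScenarioConfig):
    """Generate a full synthetic experiment.

    Returns ``(table, metadata, tree, manifest)``: a CountTable including
    negative-control samples with sparse contamination, a metadata frame,
    the phylogeny, and a truth manifest recording the process, focal
    ecotypes, niche widths and seeds.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(3)
    rng_tree = np.random.default_rng(seeds[0])
    rng_meta = np.random.default_rng(seeds[1])
    rng_samples = np.random.default_rng(seeds[2])

    tree = simulate_tree(config.n_taxa, config.birth_rate, rng_tree)
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    dmat = dm.data
    taxa = ids

    log_m = rng_meta.normal(
        config.metacommunity_logmean, config.metacommunity_logsd, config.n_taxa
    )
    meta_main = pd.Series(np.exp(log_m), index=taxa)
    meta_main /= meta_main.sum()
    # independent second profile, mixed in for the added-water source
    log_m2 = rng_meta.normal(
        config.metacommunity_logmean, config.metacommunity_logsd, config.n_taxa
    )
    meta_aw = pd.Series(np.exp(log_m2), index=taxa)
    mix = config.added_water_mixture
    meta_aw = mix * meta_aw / meta_aw.sum() + (1.0 - mix) * meta_main
    meta_aw /= meta_aw.sum()

    # niche per treatment: Gaussian in cophenetic distance to a focal
    # ecotype, truncated at the washout radius containing ~guild_size taxa
    def guild(focal: int):
        dist = pd.Series(dmat[focal], index=taxa)
        radius = float(np.sort(dmat[focal])[config.guild_size])
        return {"focal": taxa[focal], "dist": dist, "radius": radius,
                "sigma": radius / 2.0}

    if config.process == "neutral":
        niche_by_treatment = {t: None for t in config.water_treatments}
    elif config.process == "homogeneous_selection":
        g = guild(_densest_focal(dmat, config.guild_size))
        niche_by_treatment = {t: g for t in config.water_treatments}
    else:  # heterogeneous_selection
        focal_a = _densest_focal(dmat, config.guild_size)
        # second focal: densest guild among the half of tips farthest from
        # the first, so the two niches are phylogenetically divergent
        far = np.flatnonzero(dmat[focal_a] >= np.median(dmat[focal_a]))
        focal_b = _densest_focal(dmat, config.guild_size, candidates=far)
        ga, gb = guild(focal_a), guild(focal_b)
        niche_by_treatment = {
            config.water_treatments[0]: ga,
            config.water_treatments[1]: gb,
        }

    def draw(meta: pd.Series, niche):
        noise = np.exp(
            rng_samples.normal(0.0, config.sample_noise_logsd, config.n_taxa)
        )
        if config.occupancy < 1.0:
            mask = rng_samples.random(config.n_taxa) < config.occupancy
            if not mask.any():
                mask[:] = True
            noise = noise * mask
        m = meta.to_numpy() * noise
        if m.sum() == 0 or (
            niche is not None
            and not np.any((m > 0) & (niche["dist"].to_numpy() <= niche["radius"]))
        ):
            m = meta.to_numpy().copy()  # degenerate mask; fall back to full pool
        m = pd.Series(m / m.sum(), index=taxa)
        if niche is None:
            return assemble_sample(m, niche_placeholder, None, None,
                                   config.read_depth, rng_samples)
        return assemble_sample(
            m, niche["dist"], 0.0, niche["sigma"], config.read_depth,
            rng_samples, max_deviation=niche["radius"],
        )

    niche_placeholder = pd.Series(0.0, index=taxa)

    columns: dict[str, pd.Series] = {}
    md_rows = []

    for treatment in config.water_treatments:
        niche = niche_by_treatment[treatment]
        for strain in config.strains:
            for k in range(config.flasks_per_group):
                flask = _flask_label(treatment, strain, k)
                for g in range(config.gut_per_flask):
                    sid = f"{flask}-gut{g + 1}"
                    columns[sid] = draw(meta_main, niche)
                    md_rows.append(
                        (sid, "gut", treatment, strain, flask, config.sampling_day)
                    )
                sid = f"{flask}-RW"
                columns[sid] = draw(meta_main, niche)
                md_rows.append(
                    (sid, "rearing_water", treatment, strain, flask,
                     config.sampling_day)
                )
        for day in config.added_water_days:
            # source water, sampled before it enters the flasks: neutral
            sid = f"AW-{treatment}-d{day}"
            columns[sid] = draw(meta_aw, None)
            md_rows.append((sid, "added_water", treatment, "none", "", day))

    # negative controls: a few contaminant taxa at trace read counts
    contaminants = [
        str(t) for t in rng_samples.choice(
            taxa, size=min(config.n_contaminant_taxa, len(taxa)), replace=False
        )
    ]
    for c in range(config.n_controls):
        sid = f"NC{c + 1}"
        col = pd.Series(0, index=taxa, dtype=int)
        for t in contaminants:
            if config.contaminant_reads_max > 0:
                col[t] = int(
                    rng_samples.integers(0, config.contaminant_reads_max + 1)
                )
        columns[sid] = col
        md_rows.append(
            (sid, "negative_control", "none", "none", "", config.sampling_day)
        )

    counts = pd.DataFrame(columns, index=taxa)
    counts.index.name = "taxon_id"
    table = CountTable(counts)
    metadata = pd.DataFrame(
        md_rows,
        columns=["sample_id", "sample_type", "water_treatment", "strain",
                 "flask_id", "day_dph"],
    ).set_index("sample_id")

    manifest = {
        "process": config.process,
        "seed": config.seed,
        "n_taxa": config.n_taxa,
        "read_depth": config.read_depth,
        "guild_size": config.guild_size,
        "metacommunity_logsd": config.metacommunity_logsd,
        "sample_noise_logsd": config.sample_noise_logsd,
        "occupancy": config.occupancy,
        "contaminant_taxa": ",".join(contaminants),
    }
    for t, niche in niche_by_treatment.items():
        if niche is None:
            manifest[f"focal[{t}]"] = ""
            manifest[f"sigma[{t}]"] = ""
        else:
            manifest[f"focal[{t}]"] = niche["focal"]
            manifest[f"sigma[{t}]"] = niche["sigma"]
            manifest[f"radius[{t}]"] = niche["radius"]
    return table, metadata, tree, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Flat ``key = value`` text manifest."""
    lines = [f"{k} = {v}" for k, v in manifest.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition(" = ")
        out[k] = v
    return out
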