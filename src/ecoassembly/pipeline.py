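"""End-to-end analysis pipeline: QC -> diversity -> ordination -> null models.

``run_pipeline`` reads a count table, metadata and tree (or generates a
synthetic scenario), applies the QC filters and depth normalization, and
writes the full report bundle: alpha-diversity table, Bray-Curtis matrix,
PCoA coordinates, PERMANOVA results for the stated contrasts, SIMPER table,
shared-ASV fractions, NTI table, betaNTI pair table and process summary,
plus a manifest echoing every effective parameter and seed so any output
can be reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, diversity, phylo, synthetic, tables

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one full pipeline run.

    Either ``table_path``/``metadata_path``/``tree_path`` point to input
    files, or ``scenario`` holds a synthetic ScenarioConfig to generate them.
    """

    output_dir: str | Path = "results"
    table_path: str | Path | None = None
    metadata_path: str | Path | None = None
    tree_path: str | Path | None = None
    scenario: synthetic.ScenarioConfig | None = None
    min_reads: int = 8
    min_reads_mode: str = "total"
    control_read_cap: int = 4
    abundance_floor: float = 0.001
    normalize_depth: int = 11000
    drop_taxa: tuple = ()
    nti_runs: int = 999
    bnti_runs: int = 999
    nti_weighted: bool = False
    bnti_weighted: bool = True
    # "table": all taxa of the filtered table (single metacommunity);
    # "group": taxa present in the analysed group's samples
    null_pool: str = "table"
    n_permutations: int = 9999
    prune_tree_to_table: bool = False
    seed: int = 0

    def derived_seed(self, offset: int) -> int:
        return (int(self.seed) * 1000 + offset) % (2**31 - 1)


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        table, metadata, tree, manifest = synthetic.generate_experiment(
            config.scenario
        )
        return table, metadata, tree, manifest
    if not (config.table_path and config.metadata_path and config.tree_path):
        raise ValueError("need either a scenario or table/metadata/tree paths")
    table = tables.read_count_table(config.table_path)
    metadata = tables.read_metadata(config.metadata_path)
    tree = phylo.read_tree(config.tree_path)
    return table, metadata, tree, {}


def _check_tree_coverage(table: tables.CountTable, tree, prune: bool):
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if str(t) not in tips]
    if missing and not prune:
        raise ValueError(
            f"{len(missing)} taxa in table but not in tree "
            f"(e.g. {missing[:5]}); pass prune_tree_to_table=True to drop them"
        )
    if missing:
        logger.warning("pruning %d table taxa absent from tree", len(missing))
        table = table.select_taxa([t for t in table.taxon_ids if str(t) in tips])
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of the in-memory results keyed like the output files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, metadata, tree, truth = _load_inputs(config)
    metadata = tables.validate_metadata(metadata, table)

    # ---- QC ---------------------------------------------------------------
    controls = metadata.index[metadata["sample_type"] == "negative_control"]
    controls = [c for c in controls if c in set(table.sample_ids)]
    if controls:
        table = tables.subtract_control_asvs(
            table, controls, config.control_read_cap, config.abundance_floor
        )
    if config.drop_taxa:
        table = tables.drop_taxa(table, config.drop_taxa)
    table = tables.filter_min_reads(table, config.min_reads, config.min_reads_mode)
    table = tables.normalize_scaling(table, config.normalize_depth)
    table = _check_tree_coverage(table, tree, config.prune_tree_to_table)
    metadata = metadata.loc[table.sample_ids]

    results: dict = {}
    tables.write_count_table(table, out / "filtered_table.tsv")
    tables.write_metadata(metadata.reset_index(), out / "metadata.tsv")

    # ---- diversity --------------------------------------------------------
    alpha = diversity.alpha_diversity(table)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    results["alpha_diversity"] = alpha

    bc = diversity.bray_curtis(table)
    pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)).to_csv(
        out / "bray_curtis.tsv", sep="\t"
    )
    results["bray_curtis"] = bc

    ord_res = diversity.pcoa(bc)
    ord_res.samples.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {
            "eigenvalue": ord_res.eigvals,
            "proportion_explained": ord_res.proportion_explained,
        }
    ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t")
    results["pcoa"] = ord_res

    # ---- PERMANOVA contrasts ----------------------------------------------
    bio = metadata
    perm_rows = []

    def contrast(name, sample_ids, labels, offset):
        sample_ids = [str(s) for s in sample_ids]
        if len(set(labels)) < 2 or min(pd.Series(labels).value_counts()) < 2:
            logger.info("skipping contrast %s (degenerate groups)", name)
            return
        sub = bc.filter(sample_ids)
        res = diversity.permanova_oneway(
            sub, np.asarray(labels), config.n_permutations,
            seed=config.derived_seed(offset),
        )
        perm_rows.append(
            {"contrast": name, "pseudo_F": res.pseudo_f, "p_value": res.p_value,
             "n_permutations": res.n_permutations,
             "group_sizes": ";".join(f"{k}={v}" for k, v in res.group_sizes.items())}
        )

    gut = bio.index[bio["sample_type"] == "gut"]
    rw = bio.index[bio["sample_type"] == "rearing_water"]
    if len(gut) >= 4:
        contrast("gut: strain", gut, bio.loc[gut, "strain"], 1)
        contrast("gut: water_treatment", gut, bio.loc[gut, "water_treatment"], 2)
    gut_rw = list(gut) + list(rw)
    if len(gut) >= 2 and len(rw) >= 2:
        contrast("gut vs rearing_water", gut_rw, bio.loc[gut_rw, "sample_type"], 3)
    permanova_df = pd.DataFrame(perm_rows)
    permanova_df.to_csv(out / "permanova.tsv", sep="\t", index=False)
    results["permanova"] = permanova_df

    # ---- SIMPER (gut Add-K vs Add-r when available) ------------------------
    if len(gut) >= 2:
        labels = bio.loc[gut, "water_treatment"]
        if labels.nunique() == 2:
            simper_df = diversity.simper(table.select_samples(list(gut)), labels)
            simper_df.to_csv(out / "simper_gut_water_treatment.tsv", sep="\t")
            results["simper"] = simper_df

    # ---- shared ASV fractions (gut vs water) -------------------------------
    water = bio.index[bio["sample_type"].isin(["rearing_water", "added_water"])]
    if len(gut) and len(water):
        shared = pd.Series(
            {
                g: diversity.shared_asv_fraction(table, g, list(water))
                for g in gut
            },
            name="shared_fraction",
        )
        shared.rename_axis("sample_id").to_csv(out / "shared_asv_fractions.tsv", sep="\t")
        results["shared_fractions"] = shared

    # ---- null models -------------------------------------------------------
    dm = phylo.cophenetic(tree)
    pool = (
        [t for t in table.taxon_ids if table.counts.loc[t].sum() > 0]
        if config.null_pool == "table"
        else None
    )

    nti_samples = [
        s for s in bio.index[bio["sample_type"].isin(["gut", "rearing_water"])]
        if (table.counts[s] > 0).sum() >= 2
    ]
    nti_df = assembly.nti(
        table.select_samples(nti_samples), dm, runs=config.nti_runs,
        seed=config.derived_seed(10), weighted=config.nti_weighted,
        null_pool=pool if pool is not None else list(table.taxon_ids),
    )
    nti_df = nti_df.join(bio[["sample_type", "water_treatment"]])
    nti_df.to_csv(out / "nti.tsv", sep="\t")
    results["nti"] = nti_df

    bnti_frames = []
    for i, (stype, treat) in enumerate(
        [("gut", t) for t in sorted(bio["water_treatment"].unique()) if t != "none"]
        + [("rearing_water", t) for t in sorted(bio["water_treatment"].unique())
           if t != "none"]
    ):
        group = bio.index[
            (bio["sample_type"] == stype) & (bio["water_treatment"] == treat)
        ]
        if len(group) < 2:
            continue
        res = assembly.beta_nti(
            table, dm, runs=config.bnti_runs, seed=config.derived_seed(20 + i),
            weighted=config.bnti_weighted, samples=list(group), null_pool=pool,
        )
        res.insert(0, "group", f"{stype}-{treat}")
        bnti_frames.append(res)
    if bnti_frames:
        bnti_df = pd.concat(bnti_frames, ignore_index=True)
        bnti_df.to_csv(out / "bnti_pairs.tsv", sep="\t", index=False)
        summary = assembly.summarize_processes(bnti_df, "group")
        summary.to_csv(out / "process_summary.tsv", sep="\t")
        results["bnti"] = bnti_df
        results["process_summary"] = summary

    # ---- manifest ----------------------------------------------------------
    manifest = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("scenario",) and not isinstance(v, (dict,))
    }
    manifest["output_dir"] = str(config.output_dir)
    manifest["drop_taxa"] = ",".join(map(str, config.drop_taxa))
    if config.scenario is not None:
        for k, v in asdict(config.scenario).items():
            manifest[f"scenario.{k}"] = v
    for k, v in truth.items():
        manifest[f"truth.{k}"] = v
    synthetic.write_manifest(manifest, out / "manifest.txt")
    results["manifest"] = manifest
    return results
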