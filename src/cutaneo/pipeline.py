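"""End-to-end orchestration: simulate -> alpha -> beta -> ordination ->
PERMANOVA -> community typing -> markers -> longitudinal summary.

Every stochastic stage draws its seed from the master seed by a fixed
offset, so changing one stage's seed never perturbs another. Each stage
writes its own TSV/JSON outputs into the run directory and the manifest
records seeds, row counts and SHA-256 digests; a failing optional stage is
recorded and does not abort the rest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import community_typing as typing_mod
from . import markers as markers_mod
from . import ordination as ord_mod
from . import permanova as perm_mod
from .io import (
    CountTable,
    SampleMetadata,
    collapse_taxonomy,
    to_relative,
    write_count_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from .simulate import SKIN_GENERA, SimulationConfig, simulate_cohort, simulate_longitudinal

logger = logging.getLogger("cutaneo")

#: fixed per-stage seed offsets from the master seed
STAGE_SEED_OFFSETS = {
    "simulate": 0, "alpha": 1, "beta": 2, "ordination": 3,
    "permanova": 4, "typing": 5, "markers": 6, "longitudinal": 7,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of a full run; round-trips through JSON."""

    out_dir: str = "cutaneo_run"
    master_seed: int = 0
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    beta_metric: str = "weighted-unifrac"
    rarefaction_depths: tuple = (500, 1000, 2000)
    rarefaction_reps: int = 10
    trend_depth: int = 2000
    k_max: int = 10
    permanova_terms: tuple = ("skin_type", "body_site", "microenvironment")
    n_permutations: int = 999
    run_gap: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key in ("rarefaction_depths", "permanova_terms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated cohort and write a report bundle.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seeds": {}, "stages": {}, "files": {}}

    sim_seed = stage_seed(config.master_seed, "simulate")
    manifest["seeds"]["simulate"] = sim_seed
    sim_cfg = SimulationConfig(cohort_seed=sim_seed, **config.simulation)
    table, metadata, taxonomy, tree, truth = simulate_cohort(sim_cfg)
    write_count_table(table, out / "counts.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    write_tree(tree, out / "tree.nwk")
    (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), sort_keys=True))
    manifest["stages"]["simulate"] = {
        "ok": True, "n_samples": table.shape[1], "n_taxa": table.shape[0]}

    genus_table = collapse_taxonomy(table, taxonomy, "genus")
    genus_profiles = to_relative(genus_table)
    results: dict = {"table": table, "metadata": metadata, "taxonomy": taxonomy,
                     "tree": tree, "truth": truth}

    def run_stage(name, fn):
        try:
            results[name] = fn()
            manifest["stages"][name] = {"ok": True}
        except Exception as exc:     # optional stages must not abort the run
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"ok": False, "error": f"{name}: {exc}"}

    def alpha_stage():
        seed = stage_seed(config.master_seed, "alpha")
        manifest["seeds"]["alpha"] = seed
        curve = alpha_mod.rarefaction_curve(
            table, sorted(config.rarefaction_depths), reps=config.rarefaction_reps,
            seed=seed, index="shannon")
        trend = alpha_mod.group_alpha_trend(curve, metadata, depth=config.trend_depth)
        shannon = table.data.apply(alpha_mod.shannon_index, axis=0)
        shannon.name = "shannon"
        rel = alpha_mod.relative_alpha(shannon, metadata)
        sharing = alpha_mod.taxa_sharing(table, metadata)
        curve.mean.to_csv(out / "alpha_rarefaction_mean.tsv", sep="\t")
        rel.to_csv(out / "alpha_relative.tsv", sep="\t")
        return {"curve": curve, "trend": trend, "relative": rel, "sharing": sharing}

    def beta_stage():
        dm = beta_mod.pairwise_distances(table, tree, config.beta_metric)
        summary = beta_mod.beta_group_summary(dm, metadata)
        dm.write_tsv(out / f"beta_{config.beta_metric}.tsv")
        summary.summary.to_csv(out / "beta_group_summary.tsv", sep="\t", index=False)
        return {"dm": dm, "summary": summary}

    run_stage("alpha", alpha_stage)
    run_stage("beta", beta_stage)

    def ordination_stage():
        dm = results["beta"]["dm"]
        res = ord_mod.pcoa(dm, cailliez=True)
        tests = ord_mod.axis_group_test(res, metadata, axes=(1, 2))
        res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        pd.Series(res.eigenvalues).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t")
        return {"ordination": res, "axis_tests": tests}

    def permanova_stage():
        seed = stage_seed(config.master_seed, "permanova")
        manifest["seeds"]["permanova"] = seed
        dm = results["beta"]["dm"]
        res = perm_mod.adonis(dm, metadata, list(config.permanova_terms),
                              B=config.n_permutations, seed=seed)
        res.table.to_csv(out / "permanova.tsv", sep="\t")
        return res

    def typing_stage():
        seed = stage_seed(config.master_seed, "typing")
        manifest["seeds"]["typing"] = seed
        res = typing_mod.typify(genus_profiles, metadata,
                                k_range=range(2, config.k_max + 1),
                                gap=config.run_gap, seed=seed)
        res.labels.to_csv(out / "cutaneotype_labels.tsv", sep="\t")
        res.ch_curve.to_csv(out / "cutaneotype_ch_curve.tsv", sep="\t")
        if res.contingency is not None:
            res.contingency.to_csv(out / "cutaneotype_contingency.tsv", sep="\t")
        return res

    def markers_stage():
        profiles = to_relative(table)
        battery = markers_mod.differential_abundance(table, taxonomy, metadata)
        combined = markers_mod.combined_genera_marker(genus_profiles, metadata)
        otu_profiles = profiles
        keep = markers_mod.abundant_taxa(otu_profiles, 0.001)
        prev = markers_mod.prevalence_chi2(table, metadata, keep[:50])
        dp = markers_mod.double_positive_predictor(table, metadata, truth.marker_otus)
        genus_keep = markers_mod.abundant_taxa(genus_profiles, 0.01)
        sev = markers_mod.severity_correlation(genus_profiles, metadata, genus_keep)
        chim = markers_mod.chimera_qc_summary(table, metadata.chimera_flags, metadata)
        battery.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        sev.to_csv(out / "severity_correlation.tsv", sep="\t", index=False)
        return {"differential": battery, "combined_genera": combined,
                "prevalence": prev, "double_positive": dp, "severity": sev,
                "chimera": chim}

    run_stage("ordination", ordination_stage)
    run_stage("permanova", permanova_stage)
    run_stage("typing", typing_stage)
    run_stage("markers", markers_stage)

    (out / "config.json").write_text(config.to_json())
    # digests cover the scientific outputs; config.json embeds out_dir and
    # is reproducible by construction
    for f in sorted(out.glob("*.tsv")) + [out / "truth.json"]:
        manifest["files"][f.name] = _digest(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


# ---------------------------------------------------------------------------
# Longitudinal summary
# ---------------------------------------------------------------------------

def longitudinal_summary(per_week: dict, beta_metric: str = "unweighted-unifrac") -> dict:
    """Trend report over the longitudinal weeks.

    For each week: triplet-relative Shannon diversity, intragroup beta
    means +/- SEM, cutaneotype-2 prevalence per skin type with pairwise
    Fisher exact tests, and combined skin-genera abundance per skin type.
    Weeks with no complete triplet are skipped with a warning.
    """
    report = {}
    for week in sorted(per_week):
        table, metadata, taxonomy, tree, truth = per_week[week]
        if not metadata.complete_triplets():
            logger.warning("week %s has no complete triplets; skipped", week)
            continue
        entry = {}

        shannon = table.data.apply(alpha_mod.shannon_index, axis=0)
        shannon.name = "shannon"
        rel = alpha_mod.relative_alpha(shannon, metadata)
        types = metadata.data.loc[rel.index, "skin_type"]
        entry["relative_alpha"] = {
            t: {"mean": float(rel[types == t].mean()),
                "sem": float(rel[types == t].std(ddof=1) / np.sqrt((types == t).sum()))}
            for t in ("unaffected", "lesion")
        }

        dm = beta_mod.pairwise_distances(table, tree, beta_metric)
        summary = beta_mod.beta_group_summary(dm, metadata)
        entry["intragroup_beta"] = {
            row["category"]: {"mean": row["mean"], "sem": row["sem"]}
            for _, row in summary.summary.iterrows()
            if row["category"].startswith("within-")
        }

        genus_profiles = to_relative(collapse_taxonomy(table, taxonomy, "genus"))
        d = squareform(
            pdist(genus_profiles.data.to_numpy().T, metric="jensenshannon"))
        dm_jsd = beta_mod.DistanceMatrix(genus_profiles.sample_ids, d, "sqrt-jsd")
        labels, _ = typing_mod.pam(dm_jsd, 2)
        assoc = typing_mod.cutaneotype_association(labels, metadata)
        enriched = assoc.lesion_enriched_cluster
        md_types = metadata.data["skin_type"]
        prev = {}
        for t in ("control", "unaffected", "lesion"):
            sel = labels.index[md_types.loc[labels.index] == t]
            prev[t] = float((labels.loc[sel] == enriched).mean())
        fisher = {}
        for a, b in (("control", "lesion"), ("control", "unaffected"),
                     ("unaffected", "lesion")):
            ids_a = labels.index[md_types.loc[labels.index] == a]
            ids_b = labels.index[md_types.loc[labels.index] == b]
            tab = [
                [int((labels.loc[ids_a] == enriched).sum()),
                 int((labels.loc[ids_a] != enriched).sum())],
                [int((labels.loc[ids_b] == enriched).sum()),
                 int((labels.loc[ids_b] != enriched).sum())],
            ]
            fisher[f"{a}-{b}"] = float(fisher_exact(tab)[1])
        entry["cutaneotype2_prevalence"] = prev
        entry["cutaneotype2_fisher_p"] = fisher

        combined = markers_mod.combined_genera_marker(genus_profiles, metadata)
        entry["combined_genera"] = combined["four_genera"]["group_summary"]

        report[week] = entry
    return report
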