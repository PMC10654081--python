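"""End-to-end pipeline orchestration.

A :class:`RunConfig` either points at input files (OTU table, tree,
taxonomy, metadata) or embeds a simulation scenario; ``run_pipeline``
executes the selected stages in dependency order (ingest/simulate ->
rarefy -> diversity -> assembly -> network -> biomarkers), writes every
artifact as UTF-8 TSV/JSON/GraphML/Newick under the output directory,
and returns a manifest listing each output with the parameters and seed
that produced it.  Identical config + seed reproduces identical tabular
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tomllib
from dataclasses import dataclass

import pandas as pd

from ._errors import ValidationError
from . import assembly as _assembly
from . import biomarkers as _biomarkers
from . import diversity as _diversity
from . import network as _network
from . import synthetic as _synthetic
from .phylo import prune_to_table, read_tree, write_tree
from .table import (check_frame_covers, filter_prevalence, rarefy,
                    read_community, read_sample_frame, read_taxonomy,
                    to_relative, write_community, write_sample_frame,
                    write_taxonomy)

logger = logging.getLogger(__name__)

ALL_STAGES = ("diversity", "assembly", "network", "biomarkers")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (dict with paths: table, tree, taxonomy,
    metadata) or ``scenario`` (a ScenarioConfig) must be set.
    """

    output_dir: str
    seed: int = 0
    inputs: dict | None = None
    scenario: _synthetic.ScenarioConfig | None = None
    stages: tuple = ALL_STAGES
    rarefaction_depth: int | None = 10_000
    n_null: int = 999
    rho_threshold: float = 0.7
    correlation_alpha: float = 0.01
    min_prevalence: float = 0.2
    min_mean_ra: float = 1e-4
    robustness_step: float = 0.05
    robustness_reps: int = 100
    cv_folds: int = 10
    cv_repeats: int = 5
    lda_threshold: float = 4.0
    lefse_alpha: float = 0.05
    permanova_terms: tuple = ("age_group", "longitude_group")
    n_permutations: int = 999
    focal_class: str | None = None

    def validate(self) -> None:
        if (self.inputs is None) == (self.scenario is None):
            raise ValidationError(
                "exactly one of input paths or a simulation scenario is required")
        if self.inputs is not None:
            required = {"table", "tree", "taxonomy", "metadata"}
            missing_keys = required - set(self.inputs)
            if missing_keys:
                raise ValidationError(f"missing input path(s): {sorted(missing_keys)}")
            absent = [p for p in self.inputs.values() if not os.path.exists(p)]
            if absent:
                raise ValidationError(f"input file(s) not found: {absent}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        scenario = None
        if "scenario" in doc:
            scenario = _synthetic.ScenarioConfig(**doc.pop("scenario"))
        run = doc.pop("run", {})
        params = {**run, **{k: v for k, v in doc.items() if not isinstance(v, dict)}}
        if "inputs" in doc:
            params["inputs"] = doc["inputs"]
        if "stages" in params:
            params["stages"] = tuple(params["stages"])
        if "permanova_terms" in params:
            params["permanova_terms"] = tuple(params["permanova_terms"])
        return cls(scenario=scenario, **params)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    if dry_run:
        return {"dry_run": True, "stages": list(config.stages)}
    os.makedirs(config.output_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, filename: str, writer) -> None:
        path = os.path.join(config.output_dir, filename)
        writer(path)
        outputs[name] = path

    # ---- ingest or simulate ------------------------------------------
    if config.scenario is not None:
        scen = dataclasses.replace(config.scenario, seed=config.seed)
        tree = _synthetic.simulate_tree(scen)
        table, frame, truth = _synthetic.simulate_communities(tree, scen)
        taxonomy = _synthetic.simulate_taxonomy(tree, seed=config.seed)
        emit("table", "otu_table.tsv", lambda p: write_community(table, p))
        emit("metadata", "metadata.tsv", lambda p: write_sample_frame(frame, p))
        emit("taxonomy", "taxonomy.tsv", lambda p: write_taxonomy(taxonomy, p))
        emit("tree", "tree.nwk", lambda p: write_tree(tree, p))
        emit("ground_truth", "ground_truth.json",
             lambda p: json.dump(truth, open(p, "w"), indent=1, default=str))
    else:
        table = read_community(config.inputs["table"])
        tree = read_tree(config.inputs["tree"])
        taxonomy = read_taxonomy(config.inputs["taxonomy"])
        frame = read_sample_frame(config.inputs["metadata"])
    check_frame_covers(table, frame)

    # ---- rarefy and close --------------------------------------------
    if config.rarefaction_depth and not table.is_relative:
        table = rarefy(table, config.rarefaction_depth, seed=config.seed)
        frame = frame.loc[table.sample_ids]
    rel = to_relative(table) if not table.is_relative else table

    if "diversity" in config.stages:
        alpha = _diversity.alpha_indices(table)
        emit("alpha", "alpha_diversity.tsv",
             lambda p: alpha.to_csv(p, sep="\t"))
        trends = _diversity.alpha_age_trends(alpha, frame)
        emit("alpha_trends", "alpha_age_trends.tsv",
             lambda p: trends.to_csv(p, sep="\t"))
        bc = _diversity.bray_curtis(rel)
        emit("bray_curtis", "bray_curtis.tsv", bc.write_tsv)
        rel_tree, sheared = prune_to_table(rel, tree)
        wu = _diversity.weighted_unifrac(rel_tree, sheared)
        emit("weighted_unifrac", "weighted_unifrac.tsv", wu.write_tsv)
        ord_res = _diversity.nmds(wu, seed=config.seed)
        emit("nmds", "nmds_coordinates.tsv",
             lambda p: ord_res.coordinates.to_csv(p, sep="\t", index_label="sample_id"))
        emit("nmds_stress", "nmds_stress.json",
             lambda p: json.dump({"stress": ord_res.stress}, open(p, "w")))
        perma = _diversity.permanova(wu, frame, list(config.permanova_terms),
                                     n_perm=config.n_permutations, seed=config.seed)
        emit("permanova", "permanova.tsv",
             lambda p: perma.to_dataframe().to_csv(p, sep="\t", index=False))

    if "assembly" in config.stages:
        res = _assembly.beta_nti(rel, tree, n_null=config.n_null, seed=config.seed)
        emit("beta_nti_pairs", "beta_nti_pairs.tsv",
             lambda p: res.to_csv(p, sep="\t", index=False))
        emit("beta_nti_matrix", "beta_nti_matrix.tsv",
             lambda p: _assembly.beta_nti_matrix(res).to_csv(p, sep="\t"))
        fractions = _assembly.assembly_fractions(res, frame, "age_group")
        emit("assembly_fractions", "assembly_fractions.tsv",
             lambda p: fractions.to_csv(p, sep="\t"))

    if "network" in config.stages:
        topo_rows = {}
        for gname, members in frame.groupby("age_group", observed=True):
            sub = rel.select_samples([s for s in members.index if s in rel.sample_ids])
            if sub.n_samples < 5:
                logger.warning("network: group %s has < 5 samples, skipped", gname)
                continue
            filt = filter_prevalence(sub, config.min_prevalence, config.min_mean_ra)
            edges = _network.correlation_screen(filt, config.rho_threshold,
                                                config.correlation_alpha)
            mean_ra = filt.data.mean(axis=1)
            g = _network.build_network(edges, taxonomy=taxonomy, mean_ra=mean_ra)
            emit(f"network_{gname}", f"network_{gname}.graphml",
                 lambda p, g=g: _network.write_graphml(g, p))
            emit(f"edges_{gname}", f"edges_{gname}.tsv",
                 lambda p, g=g: _network.write_edge_list(g, p))
            if g.number_of_edges():
                topo_rows[str(gname)] = _network.topology(g, seed=config.seed).to_series()
                if config.focal_class is not None:
                    counts = _network.focal_class_edges(g, taxonomy,
                                                        config.focal_class)
                    emit(f"focal_edges_{gname}", f"focal_edges_{gname}.tsv",
                         lambda p, c=counts: pd.Series(c).to_csv(
                             p, sep="\t", header=["count"]))
                if g.number_of_nodes() >= 5:
                    curve = _network.robustness(g, step=config.robustness_step,
                                                n_reps=config.robustness_reps,
                                                seed=config.seed)
                    df = pd.DataFrame({"removal_fraction": curve.removal_fractions,
                                       "mean_remaining": curve.mean_remaining,
                                       "sd_remaining": curve.sd_remaining})
                    emit(f"robustness_{gname}", f"robustness_{gname}.tsv",
                         lambda p, df=df: df.to_csv(p, sep="\t", index=False))
        if topo_rows:
            emit("network_topology", "network_topology.tsv",
                 lambda p: pd.DataFrame(topo_rows).T.to_csv(p, sep="\t",
                                                            index_label="group"))

    if "biomarkers" in config.stages:
        sel = _biomarkers.rf_select(rel, frame, folds=config.cv_folds,
                                    repeats=config.cv_repeats, seed=config.seed)
        emit("rf_importances", "rf_importances.tsv",
             lambda p: sel.to_dataframe().to_csv(p, sep="\t", index_label="taxon_id"))
        emit("rf_cv_curve", "rf_cv_curve.tsv",
             lambda p: sel.cv_error_curve.rename("cv_mse").to_csv(
                 p, sep="\t", index_label="n_features"))
        lef = _biomarkers.lefse(rel, frame, alpha=config.lefse_alpha,
                                lda_threshold=config.lda_threshold, seed=config.seed)
        emit("lefse", "lefse_scores.tsv", lambda p: lef.to_csv(p, sep="\t"))

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("inputs", "scenario") and not isinstance(v, dict)
        },
        "outputs": {name: {"path": path, "sha256": _sha256(path)}
                    for name, path in sorted(outputs.items())},
    }
    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
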