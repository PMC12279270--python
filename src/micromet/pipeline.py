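"""End-to-end orchestration: simulate-or-read -> preprocess -> diversity ->
univariate -> networks -> differential -> enrichment, with a run manifest.

Every stage writes TSV artifacts into the output directory and registers
them (with SHA-256 checksums and row counts) in the manifest, so a rerun
with the same configuration and inputs is bit-for-bit reproducible. A single
run seed fans out into per-stage child seeds by stable hashing of stage
names, making each stage reproducible independently of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, diversity, enrichment, network, preprocess
from .config import AnalysisConfig
from .io import FLOAT_FMT, InputBundle, PathwayLibrary, read_inputs, write_network
from .simulate import (
    SimulatedBundle,
    SimulationConfig,
    generate_cohort,
    make_pathway_library,
    write_bundle,
)
from .univariate import pairwise_rank_tests

log = logging.getLogger("micromet")


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return zlib.crc32(f"{run_seed}:{stage}".encode()) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    outputs: dict[str, str]
    checksums: dict[str, str]
    row_counts: dict[str, int]
    warnings: list[str]
    input_checksums: dict[str, str] = dataclasses.field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


class _ManifestWriter:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.outputs: dict[str, str] = {}
        self.checksums: dict[str, str] = {}
        self.row_counts: dict[str, int] = {}
        self.warnings: list[str] = []

    def add(self, name: str, path: Path, rows: int) -> None:
        self.outputs[name] = str(path)
        self.checksums[name] = _sha256(path)
        self.row_counts[name] = rows

    def write_df(self, name: str, df: pd.DataFrame, index: bool = False,
                 index_label: str | None = None) -> Path:
        path = self.outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index,
                  index_label=index_label)
        self.add(name, path, len(df))
        return path


def run_pipeline(
    analysis_cfg: AnalysisConfig,
    outdir: str | Path,
    sim_cfg: SimulationConfig | None = None,
    input_paths: dict[str, str] | None = None,
) -> RunManifest:
    """Run the full analysis and return the manifest.

    Either ``sim_cfg`` (simulate a cohort) or ``input_paths`` (read a cohort
    from disk; keys counts/taxonomy/biomass/metabolites/design and optional
    tree/library) must be given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mw = _ManifestWriter(outdir)
    seeds = {
        stage: stage_seed(analysis_cfg.rng_seed, stage)
        for stage in ("simulate", "diversity", "ordination")
    }

    truth = None
    library: PathwayLibrary | None = None
    input_checksums: dict[str, str] = {}
    if sim_cfg is not None:
        sim_cfg = dataclasses.replace(sim_cfg, rng_seed=seeds["simulate"])
        bundle_sim: SimulatedBundle = generate_cohort(sim_cfg)
        truth = bundle_sim.truth
        library = make_pathway_library(sim_cfg)
        simdir = outdir / "simulated_inputs"
        for name, path in write_bundle(bundle_sim, simdir).items():
            mw.add(f"sim_{name}", Path(path), -1)
        bundle: InputBundle = bundle_sim.as_input_bundle(library=library)
    elif input_paths is not None:
        bundle = read_inputs(**input_paths)
        library = bundle.library
        input_checksums = {
            k: _sha256(Path(v)) for k, v in input_paths.items() if v
        }
    else:
        raise ValueError("either sim_cfg or input_paths is required")

    for name, drop in bundle.dropped_samples.items():
        mw.warnings.append(f"dropped samples absent from {name}: {drop}")

    # ---- preprocess -------------------------------------------------------
    absolute = preprocess.to_absolute(bundle.counts, bundle.biomass)
    genus_abs = preprocess.aggregate_genus(absolute, bundle.taxonomy)
    genus_kept, prev_report = preprocess.prevalence_filter(
        genus_abs, analysis_cfg.prevalence_min
    )
    mw.write_df("prevalence_report", prev_report.data, index=True,
                index_label="genus")
    kept_genera = set(prev_report.kept_features())
    asv_genus = bundle.taxonomy.genus_of(absolute.feature_ids)
    kept_asvs = [a for a in absolute.feature_ids if asv_genus[a] in kept_genera]
    if not kept_asvs:
        raise ValueError("prevalence filter removed every genus")
    absolute_kept = absolute.with_values(absolute.data.loc[kept_asvs])
    clr = preprocess.clr_transform(absolute_kept, analysis_cfg.clr_pseudocount)
    conditioned = preprocess.condition_metabolites(bundle.metabolites)
    if conditioned.dropped_features:
        mw.warnings.append(
            f"dropped entirely-missing metabolites: {conditioned.dropped_features}"
        )
    mw.write_df("genus_abundance", genus_kept.data, index=True,
                index_label="genus")
    mw.write_df("metabolites_imputed", conditioned.imputed.data, index=True,
                index_label="metabolite_id")

    # ---- diversity --------------------------------------------------------
    alpha = diversity.alpha_diversity(bundle.counts, bundle.tree)
    mw.write_df("alpha_diversity", alpha, index=True, index_label="sample_id")
    dm = diversity.aitchison_distance(clr)
    dm_df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    mw.write_df("aitchison_distance", dm_df, index=True, index_label="sample_id")
    ordn = diversity.ordinate(dm, "pcoa", k=2, seed=seeds["ordination"])
    mw.write_df("pcoa_coordinates", ordn.coordinates, index=True,
                index_label="sample_id")
    groups = bundle.design.groups
    perma = diversity.permanova(dm, groups, analysis_cfg.n_permutations,
                                seeds["diversity"])
    disp = diversity.dispersion_test(dm, groups, analysis_cfg.n_permutations,
                                     seeds["diversity"])
    tests = pd.DataFrame(
        [dataclasses.asdict(perma) | {"test": "permanova"},
         dataclasses.asdict(disp) | {"test": "dispersion"}]
    )
    mw.write_df("beta_diversity_tests", tests)

    # ---- univariate -------------------------------------------------------
    uni_genus = pairwise_rank_tests(genus_kept, bundle.design, analysis_cfg)
    mw.write_df("univariate_genus", uni_genus, index=True,
                index_label="feature_id")
    uni_met = pairwise_rank_tests(conditioned.log_imputed, bundle.design,
                                  analysis_cfg)
    mw.write_df("univariate_metabolites", uni_met, index=True,
                index_label="feature_id")

    # ---- association networks -------------------------------------------
    taxa_table = genus_kept if analysis_cfg.genus_first else absolute_kept
    taxonomy = None if analysis_cfg.genus_first else bundle.taxonomy
    net = network.build_networks(
        taxa_table, conditioned.imputed, bundle.design, analysis_cfg, taxonomy
    )
    mw.write_df("correlation_results_full", net.full_results)
    for cohort, cnet in net.networks.items():
        path = outdir / f"network_{cohort}.tsv"
        write_network(cnet.edges, path, "tsv")
        mw.add(f"network_{cohort}", path, len(cnet.edges))
        gpath = outdir / f"network_{cohort}.graphml"
        write_network(cnet.edges, gpath, "graphml")
        mw.add(f"network_{cohort}_graphml", gpath, len(cnet.edges))
    strong_sets = network.strong_positive_genus_sets(
        net, taxonomy, analysis_cfg.r_threshold
    )
    if len(strong_sets) >= 2:
        venn = network.cross_state_sets(strong_sets)
        mw.write_df("venn_regions", venn)
        mw.write_df("variable_genera", network.variable_genera(strong_sets))

    # ---- differential -----------------------------------------------------
    medians = differential.median_pair_correlations(net.full_results, taxonomy)
    mw.write_df("median_pair_correlations", medians)
    anticorr = differential.anticorrelation_clusters(
        medians,
        analysis_cfg.median_pos_threshold,
        analysis_cfg.median_neg_threshold,
        disease="either",
    )
    mw.write_df("anticorrelation_scatter", anticorr)
    mw.write_df("anticorrelation_selected", anticorr[anticorr["selected"]])
    collapsed = {
        cohort: network.collapse_to_genus(cnet, taxonomy)
        for cohort, cnet in net.networks.items()
    }
    if len(collapsed) >= 2:
        rewiring = differential.rewiring_scores(collapsed)
        mw.write_df("rewiring_scores", rewiring)

    # ---- enrichment -------------------------------------------------------
    if library is not None:
        background = list(conditioned.imputed.feature_ids)
        frames = []
        for cohort, pairs in strong_sets.items():
            query = sorted({m for _, m in pairs})
            res = enrichment.ora(
                query, background, library,
                invert_ratio=analysis_cfg.invert_enrichment_ratio,
            )
            res.insert(0, "cohort", cohort)
            if len(res):
                frames.append(res)
        if frames:
            mw.write_df("enrichment", pd.concat(frames, ignore_index=True))

    # ---- recovery (simulated runs) ---------------------------------------
    if truth is not None and len(truth):
        recovery = evaluate_recovery(net, anticorr, truth, taxonomy)
        mw.write_df("recovery", pd.DataFrame([recovery]))

    manifest = RunManifest(
        config=dataclasses.asdict(analysis_cfg)
        | ({"simulation": _simcfg_dict(sim_cfg)} if sim_cfg else {}),
        seeds=seeds,
        outputs=mw.outputs,
        checksums=mw.checksums,
        row_counts=mw.row_counts,
        warnings=mw.warnings,
        input_checksums=input_checksums,
    )
    manifest.save(outdir / "manifest.json")
    return manifest


def _simcfg_dict(sim_cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(sim_cfg)
    d["planted_edges"] = [dataclasses.asdict(e) if dataclasses.is_dataclass(e)
                          else e for e in sim_cfg.planted_edges]
    return d


def evaluate_recovery(
    net: network.NetworkResult,
    anticorr: pd.DataFrame,
    truth: pd.DataFrame,
    taxonomy=None,
) -> dict:
    """Planted-edge recall/precision and sign-flip recall against a truth
    table.

    Recall counts planted (genus, metabolite, group) triples found in the
    correct cohort's filtered network; precision counts filtered edges whose
    (genus, metabolite, cohort) matches a planted triple. With no planted
    edges precision is undefined and reported as missing alongside the false
    edge count. Sign-flip recall covers planted pairs with a positive target
    in HC and a negative one in a disease cohort.
    """
    if truth is None:
        raise ValueError("truth table required")
    found: dict[str, set[tuple[str, str]]] = {}
    for cohort, cnet in net.networks.items():  # both signs count
        edges = cnet.edges
        if taxonomy is not None and len(edges):
            genus = taxonomy.genus_of(list(edges["taxon_id"])).to_numpy()
        else:
            genus = edges["genus"].to_numpy()
        found[cohort] = set(zip(genus, edges["metabolite_id"]))
    planted = {
        (r.genus, r.metabolite, r.group) for r in truth.itertuples(index=False)
    }
    n_found = sum(
        1 for g, m, grp in planted if grp in found and (g, m) in found[grp]
    )
    edges_total = 0
    edges_matching = 0
    for cohort, pairs in found.items():
        for g, m in pairs:
            edges_total += 1
            if (g, m, cohort) in planted:
                edges_matching += 1
    wide = truth.pivot_table(
        index=["genus", "metabolite"], columns="group",
        values="target_spearman_rho", aggfunc="first",
    )
    signflip_pairs = []
    for (g, m), row in wide.iterrows():
        hc = row.get("HC", np.nan)
        for d in ("CD", "UC"):
            dv = row.get(d, np.nan)
            if hc > 0 and dv < 0:
                signflip_pairs.append((g, m, d))
    selected = {
        (r.genus, r.metabolite_id, r.contrast.removeprefix("HCvs"))
        for r in anticorr[anticorr["selected"]].itertuples(index=False)
    }
    sf_found = sum(1 for t in signflip_pairs if t in selected)
    return {
        "planted_edges": len(planted),
        "recall": n_found / len(planted) if planted else np.nan,
        "filtered_edges": edges_total,
        "precision": edges_matching / edges_total if edges_total else np.nan,
        "false_edges": edges_total - edges_matching,
        "signflip_planted": len(signflip_pairs),
        "signflip_recall": sf_found / len(signflip_pairs)
        if signflip_pairs
        else np.nan,
    }
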