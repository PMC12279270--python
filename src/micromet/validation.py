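"""Replicated simulation studies that quantify what the pipeline recovers.

Three studies, each run at the cohort's group sizes (HC 20 / CD 23 / UC 37):

* ``recovery_study`` — planted Spearman-0.7 genus-metabolite edges in every
  cohort; measures how often the (q <= 0.05, rho >= 0.5) network filter
  recovers them per cohort size, and how often a planted edge shows up in
  the wrong cohort's network.
* ``signflip_study`` — genus-metabolite pairs planted at +0.6 in HC and
  -0.6 in CD (genera with several co-associating strains); measures the
  selection rate of the (median >= 0.4 / <= -0.4) anticorrelation rule and
  the false-selection rate of null pairs.
* ``null_study`` — nothing planted; measures how often a cohort's BH family
  produces any strongly positive edge, and how often univariate genus
  contrasts reach q < 0.05.

Each study regenerates its cohorts from scratch per replicate and runs the
same preprocessing and network code as the main pipeline (absolute
abundance, genus prevalence filter, ASV-level correlation, BH per cohort).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .differential import anticorrelation_clusters, median_pair_correlations
from .network import NetworkResult, build_networks
from .preprocess import condition_metabolites, prevalence_filter, to_absolute
from .preprocess import aggregate_genus
from .simulate import PlantedEdge, SimulationConfig, generate_cohort
from .univariate import pairwise_rank_tests


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _run_network_stage(
    sim_cfg: SimulationConfig, cfg: AnalysisConfig
) -> tuple[NetworkResult, "pd.DataFrame"]:
    """Simulate one cohort and run preprocessing + network construction."""
    bundle = generate_cohort(sim_cfg)
    absolute = to_absolute(bundle.counts, bundle.biomass)
    genus_abs = aggregate_genus(absolute, bundle.taxonomy)
    _, report = prevalence_filter(genus_abs, cfg.prevalence_min)
    kept = set(report.kept_features())
    genus_of = bundle.taxonomy.genus_of(absolute.feature_ids)
    kept_asvs = [a for a in absolute.feature_ids if genus_of[a] in kept]
    taxa = absolute.with_values(absolute.data.loc[kept_asvs])
    mets = condition_metabolites(bundle.metabolites).imputed
    res = build_networks(taxa, mets, bundle.design, cfg, bundle.taxonomy)
    return res, bundle.truth


def recovery_config(seed: int = 0) -> SimulationConfig:
    """Twelve 2-strain genera, ten metabolites, ten rho-0.7 edges per
    cohort (two driver strains each); every (genus, metabolite) pair is
    planted in exactly one cohort so misassignment is well defined."""
    edges = []
    for group, offset in (("HC", 0), ("CD", 3), ("UC", 6)):
        for i in range(10):
            edges.append(
                PlantedEdge(f"g{i + 1:03d}", f"m{(i + offset) % 10 + 1:03d}",
                            group, 0.7)
            )
    return SimulationConfig(
        n_genera=12,
        asvs_per_genus=2,
        n_metabolites=10,
        planted_edges=edges,
        drivers_per_edge=2,
        rng_seed=seed,
    )


def recovery_study(
    n_replicates: int = 100, seed: int = 0, cfg: AnalysisConfig | None = None
) -> dict:
    cfg = cfg or AnalysisConfig()
    per_group_hits = {"HC": 0, "CD": 0, "UC": 0}
    per_group_total = {"HC": 0, "CD": 0, "UC": 0}
    misassigned = 0
    mis_total = 0
    for s in _child_seeds(seed, n_replicates):
        sim_cfg = dataclasses.replace(recovery_config(), rng_seed=s)
        res, truth = _run_network_stage(sim_cfg, cfg)
        found = {
            cohort: set(zip(net.edges["genus"], net.edges["metabolite_id"]))
            for cohort, net in res.networks.items()
        }
        for row in truth.itertuples(index=False):
            pair = (row.genus, row.metabolite)
            per_group_total[row.group] += 1
            if pair in found.get(row.group, ()):  # recovered in place
                per_group_hits[row.group] += 1
            for other in found:
                if other != row.group:
                    mis_total += 1
                    if pair in found[other]:
                        misassigned += 1
    return {
        "recovery_rate": {
            g: per_group_hits[g] / per_group_total[g] for g in per_group_hits
        },
        "misassignment_rate": misassigned / mis_total,
        "n_replicates": n_replicates,
    }


def signflip_config(seed: int = 0) -> SimulationConfig:
    """Four sign-flip genera (eight co-associating strains each) planted at
    +0.6 in HC and -0.6 in CD, over a background of eight 2-strain null
    genera."""
    edges = []
    for i in range(4):
        genus, met = f"g{i + 1:03d}", f"m{i + 1:03d}"
        edges.append(PlantedEdge(genus, met, "HC", 0.6))
        edges.append(PlantedEdge(genus, met, "CD", -0.6))
    return SimulationConfig(
        n_genera=12,
        asvs_per_genus=[8] * 4 + [2] * 8,
        n_metabolites=10,
        planted_edges=edges,
        drivers_per_edge=8,
        rng_seed=seed,
    )


def signflip_study(
    n_replicates: int = 100, seed: int = 0, cfg: AnalysisConfig | None = None
) -> dict:
    cfg = cfg or AnalysisConfig()
    hits = total = 0
    null_hits = null_total = 0
    for s in _child_seeds(seed, n_replicates):
        sim_cfg = dataclasses.replace(signflip_config(), rng_seed=s)
        res, truth = _run_network_stage(sim_cfg, cfg)
        medians = median_pair_correlations(res.full_results)
        scatter = anticorrelation_clusters(
            medians, cfg.median_pos_threshold, cfg.median_neg_threshold, "CD"
        )
        planted_pairs = {
            (row.genus, row.metabolite)
            for row in truth.itertuples(index=False)
            if row.group == "HC"
        }
        for row in scatter.itertuples(index=False):
            pair = (row.genus, row.metabolite_id)
            if pair in planted_pairs:
                total += 1
                hits += int(row.selected)
            else:
                null_total += 1
                null_hits += int(row.selected)
    return {
        "selection_rate": hits / total,
        "null_selection_rate": null_hits / null_total,
        "n_replicates": n_replicates,
    }


def null_study(
    n_replicates: int = 200, seed: int = 0, cfg: AnalysisConfig | None = None
) -> dict:
    cfg = cfg or AnalysisConfig()
    families = families_with_edge = 0
    feature_calls = feature_total = 0
    for s in _child_seeds(seed, n_replicates):
        sim_cfg = SimulationConfig(rng_seed=s)
        bundle = generate_cohort(sim_cfg)
        absolute = to_absolute(bundle.counts, bundle.biomass)
        genus_abs = aggregate_genus(absolute, bundle.taxonomy)
        genus_kept, _ = prevalence_filter(genus_abs, cfg.prevalence_min)
        mets = condition_metabolites(bundle.metabolites).imputed
        res = build_networks(absolute, mets, bundle.design, cfg,
                             bundle.taxonomy)
        for cohort, net in res.networks.items():
            families += 1
            if (net.edges["rho"] >= cfg.r_threshold).any():
                families_with_edge += 1
        uni = pairwise_rank_tests(genus_kept, bundle.design, cfg)
        qcols = [c for c in uni.columns if c.endswith("_q")]
        feature_calls += int((uni[qcols] < 0.05).any(axis=1).sum())
        feature_total += len(uni)
    return {
        "strong_edge_family_rate": families_with_edge / families,
        "univariate_call_rate": feature_calls / feature_total,
        "n_replicates": n_replicates,
    }
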