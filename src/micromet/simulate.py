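"""Gaussian-copula synthetic cohorts with planted genus-metabolite associations.

The generator emulates the statistical structure a qPCR-scaled 16S +
metabolomics integration study assumes: negative-binomial ASV counts,
lognormal metabolite concentrations, a per-sample total bacterial load, three
cohorts (HC / CD / UC at the 20 / 23 / 37 participants of a typical inception
cohort), and cohort-specific planted Spearman correlations between designated
"driver" strains of a genus and a metabolite. Because Spearman correlation is
invariant under the monotone quantile transforms applied to the latent
Gaussian margins, a planted target rho is exact in expectation: the latent
Pearson correlation is set to ``2 sin(pi rho / 6)`` (the Gaussian-copula
rank-correlation identity).

Each planted (genus, metabolite, group) edge correlates the genus' first
``drivers_per_edge`` ASVs with the metabolite. The drivers load on the
metabolite's latent factor with independent residuals, so a genus mixes
associated and null strains whenever ``drivers_per_edge`` is smaller than the
genus' strain count — the regime the genus-collapse and median-summary logic
is designed for.

Biomass is generated as the sample's library size (rescaled to a typical
total of ~1e10 16S copies/g) times a lognormal qPCR measurement error, i.e.
the measured load is consistent with the size of the community that produced
the counts. Under this coupling the absolute-abundance transform preserves
each taxon's cross-sample ranks up to measurement error; an independently
drawn load would instead inject sample-level multiplicative noise that
scrambles them (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    BiomassSeries,
    CohortDesign,
    FeatureTable,
    InputBundle,
    PathwayLibrary,
    TaxonomyTable,
)

GROUP_ORDER = ("HC", "CD", "UC")

_PHYLA = ("Firmicutes", "Bacteroidota", "Proteobacteria", "Actinobacteriota")


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclasses.dataclass(frozen=True)
class PlantedEdge:
    """One planted genus-metabolite Spearman correlation in one cohort."""

    genus: str
    metabolite: str
    group: str
    rho: float


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``asvs_per_genus`` may be a single int or one int per genus;
    ``n_asvs`` is always the sum. ``nb_dispersion`` is the negative-binomial
    size parameter (smaller = more overdispersed). Biomass parameters are on
    the natural-log scale: ``biomass_log_mean`` sets the typical total 16S
    copies per gram and ``biomass_log_sd`` the qPCR measurement error.
    """

    group_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"HC": 20, "CD": 23, "UC": 37}
    )
    n_genera: int = 15
    asvs_per_genus: int | Sequence[int] = 2
    n_metabolites: int = 10
    planted_edges: list[PlantedEdge] = dataclasses.field(default_factory=list)
    drivers_per_edge: int = 1
    nb_dispersion: float = 0.5
    asv_log_mean: float = math.log(300.0)
    asv_log_sd: float = 1.0
    biomass_log_mean: float = math.log(1e10)
    biomass_log_sd: float = 0.15
    metabolite_log_sd: float = 1.0
    missing_rate: float = 0.0
    unlabeled_genus_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUP_ORDER:
                raise SimulationError(f"unknown group {g!r}")
            if n < 3:
                raise SimulationError(f"group {g} needs >= 3 samples, got {n}")
        if isinstance(self.asvs_per_genus, int):
            self.asvs_per_genus = [self.asvs_per_genus] * self.n_genera
        else:
            self.asvs_per_genus = list(self.asvs_per_genus)
        if len(self.asvs_per_genus) != self.n_genera:
            raise SimulationError(
                "asvs_per_genus must have one entry per genus "
                f"({len(self.asvs_per_genus)} != {self.n_genera})"
            )
        if any(a < 1 for a in self.asvs_per_genus):
            raise SimulationError("each genus needs at least one ASV")
        for e in self.planted_edges:
            if abs(e.rho) >= 1:
                raise SimulationError(f"|target rho| must be < 1: {e}")
            if e.group not in GROUP_ORDER:
                raise SimulationError(f"unknown group in planted edge: {e}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must be in [0, 1)")
        if self.drivers_per_edge < 1:
            raise SimulationError("drivers_per_edge must be >= 1")

    @property
    def n_asvs(self) -> int:
        return sum(self.asvs_per_genus)

    def genus_names(self) -> list[str]:
        return [f"g{i + 1:03d}" for i in range(self.n_genera)]

    def metabolite_names(self) -> list[str]:
        return [f"m{i + 1:03d}" for i in range(self.n_metabolites)]


@dataclasses.dataclass
class SimulatedBundle:
    """A generated cohort bundle plus the planted ground truth."""

    counts: FeatureTable
    taxonomy: TaxonomyTable
    biomass: BiomassSeries
    metabolites: FeatureTable
    design: CohortDesign
    truth: pd.DataFrame  # columns: genus, metabolite, group, target_spearman_rho

    def as_input_bundle(self, library: PathwayLibrary | None = None) -> InputBundle:
        from .io import align_bundle

        return align_bundle(
            self.counts, self.taxonomy, self.biomass, self.metabolites,
            self.design, library=library,
        )


def spearman_to_latent_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho_s`` under a Gaussian copula.

    The identity is ``rho_p = 2 sin(pi rho_s / 6)``; it is odd and monotone
    and maps (-1, 1) into (-1, 1).
    """
    if abs(rho_s) >= 1:
        raise ValueError(f"|rho_s| must be < 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _nb_quantile(u: np.ndarray, mean: float, size: float) -> np.ndarray:
    p = size / (size + mean)
    return stats.nbinom.ppf(u, size, p)


def generate_cohort(cfg: SimulationConfig) -> SimulatedBundle:
    """Generate one fully reproducible synthetic cohort bundle.

    Per group a latent multivariate normal is drawn in which each planted
    edge's driver ASVs load on the planted metabolite's latent factor at the
    copula-mapped Pearson correlation; all other latents are independent.
    ASV margins map through negative-binomial quantiles (heterogeneous means,
    common dispersion) and metabolite margins through lognormal quantiles.
    """
    genera = cfg.genus_names()
    mets = cfg.metabolite_names()
    gset, mset = set(genera), set(mets)
    for e in cfg.planted_edges:
        if e.genus not in gset:
            raise SimulationError(f"planted edge names unknown genus: {e}")
        if e.metabolite not in mset:
            raise SimulationError(f"planted edge names unknown metabolite: {e}")
    seen: set[tuple[str, str, str]] = set()
    for e in cfg.planted_edges:
        key = (e.genus, e.metabolite, e.group)
        if key in seen:
            raise SimulationError(f"duplicate planted edge: {key}")
        seen.add(key)

    # feasibility: a genus' drivers load on every planted metabolite of that
    # genus within a group; the squared loadings must sum below one
    by_genus_group: dict[tuple[str, str], list[PlantedEdge]] = {}
    for e in cfg.planted_edges:
        by_genus_group.setdefault((e.genus, e.group), []).append(e)
    for (genus, group), edges in by_genus_group.items():
        ssq = sum(spearman_to_latent_pearson(e.rho) ** 2 for e in edges)
        if ssq >= 1.0:
            raise SimulationError(
                "infeasible correlation block (not positive definite) for "
                f"genus {genus} in group {group}: edges {edges}"
            )
        if cfg.drivers_per_edge > min(
            cfg.asvs_per_genus[genera.index(genus)] for _ in edges
        ):
            raise SimulationError(
                f"genus {genus} has fewer ASVs than drivers_per_edge"
            )

    rng = np.random.default_rng(cfg.rng_seed)

    asv_ids: list[str] = []
    asv_genus: list[str] = []
    genus_members: dict[str, list[int]] = {}
    k = 0
    for gi, genus in enumerate(genera):
        members = []
        for _ in range(cfg.asvs_per_genus[gi]):
            asv_ids.append(f"asv{k + 1:04d}")
            asv_genus.append(genus)
            members.append(k)
            k += 1
        genus_members[genus] = members

    asv_means = np.exp(rng.normal(cfg.asv_log_mean, cfg.asv_log_sd, cfg.n_asvs))

    sample_ids: list[str] = []
    group_labels: list[str] = []
    count_cols: list[np.ndarray] = []
    met_cols: list[np.ndarray] = []
    met_log_means = rng.normal(0.0, 1.0, cfg.n_metabolites)

    for group in GROUP_ORDER:
        n = cfg.group_sizes.get(group, 0)
        if n == 0:
            continue
        z_met = rng.standard_normal((cfg.n_metabolites, n))
        z_asv = rng.standard_normal((cfg.n_asvs, n))
        for (genus, egroup), edges in sorted(by_genus_group.items()):
            if egroup != group:
                continue
            loadings = [(mets.index(e.metabolite), spearman_to_latent_pearson(e.rho))
                        for e in edges]
            resid = math.sqrt(1.0 - sum(l * l for _, l in loadings))
            drivers = genus_members[genus][: cfg.drivers_per_edge]
            for a in drivers:
                z = np.zeros(n)
                for mi, l in loadings:
                    z += l * z_met[mi]
                z_asv[a] = z + resid * rng.standard_normal(n)
        u_asv = stats.norm.cdf(z_asv)
        counts = np.empty_like(u_asv)
        for a in range(cfg.n_asvs):
            counts[a] = _nb_quantile(u_asv[a], asv_means[a], cfg.nb_dispersion)
        count_cols.append(counts)
        met_cols.append(
            np.exp(met_log_means[:, None] + cfg.metabolite_log_sd * z_met)
        )
        sample_ids.extend(f"s{group}{i + 1:03d}" for i in range(n))
        group_labels.extend([group] * n)

    counts = np.concatenate(count_cols, axis=1)
    met_vals = np.concatenate(met_cols, axis=1)

    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise SimulationError("a sample drew an all-zero community; "
                              "increase ASV means or dispersion")
    qpcr_err = rng.normal(0.0, cfg.biomass_log_sd, len(sample_ids))
    biomass_vals = np.exp(cfg.biomass_log_mean + qpcr_err) * lib / np.median(lib)

    if cfg.missing_rate > 0:
        mask = rng.random(met_vals.shape) < cfg.missing_rate
        met_vals = met_vals.copy()
        met_vals[mask] = np.nan

    counts_ft = FeatureTable(
        pd.DataFrame(counts, index=asv_ids, columns=sample_ids), "asv_counts"
    )
    mets_ft = FeatureTable(
        pd.DataFrame(met_vals, index=mets, columns=sample_ids),
        "metabolite_concentration",
    )
    biomass = BiomassSeries(pd.Series(biomass_vals, index=sample_ids))
    design = CohortDesign(
        pd.DataFrame({"group": group_labels}, index=sample_ids)
    )

    n_unlabeled = int(round(cfg.unlabeled_genus_fraction * cfg.n_asvs))
    unlabeled = set(
        rng.choice(cfg.n_asvs, size=n_unlabeled, replace=False).tolist()
        if n_unlabeled else []
    )
    tax_rows = []
    for i, (asv, genus) in enumerate(zip(asv_ids, asv_genus)):
        gi = genera.index(genus)
        tax_rows.append(
            {
                "kingdom": "Bacteria",
                "phylum": _PHYLA[gi % len(_PHYLA)],
                "class": f"class_{gi % 6 + 1}",
                "order": f"order_{gi % 8 + 1}",
                "family": f"family_{gi + 1:03d}",
                "genus": "" if i in unlabeled else genus,
            }
        )
    taxonomy = TaxonomyTable(pd.DataFrame(tax_rows, index=asv_ids))

    truth = pd.DataFrame(
        [
            {
                "genus": e.genus,
                "metabolite": e.metabolite,
                "group": e.group,
                "target_spearman_rho": e.rho,
            }
            for e in cfg.planted_edges
        ],
        columns=["genus", "metabolite", "group", "target_spearman_rho"],
    )
    return SimulatedBundle(counts_ft, taxonomy, biomass, mets_ft, design, truth)


def make_pathway_library(
    cfg: SimulationConfig, n_pathways: int = 4, seed: int | None = None
) -> PathwayLibrary:
    """A small synthetic metabolite-set library over the simulated metabolites.

    Metabolites are dealt round-robin (after a seeded shuffle) into
    ``n_pathways`` sets, so pathways are non-empty and jointly cover the
    measured universe. Intended for exercising the over-representation
    stage on simulated runs.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    mets = cfg.metabolite_names()
    order = rng.permutation(len(mets))
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for p in range(n_pathways):
        members = [mets[i] for i in order[p::n_pathways]]
        if not members:
            continue
        pid = f"pw{p + 1:02d}"
        pathways[pid] = frozenset(members)
        names[pid] = f"synthetic pathway {p + 1}"
    return PathwayLibrary(pathways, names, namespace="synthetic")


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, str]:
    """Write the full bundle + truth table as TSVs; returns name -> path."""
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "asv_counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "biomass": outdir / "biomass.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
    }
    _io.write_feature_table(bundle.counts, paths["counts"])
    _io.write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    _io.write_biomass(bundle.biomass, paths["biomass"])
    _io.write_feature_table(bundle.metabolites, paths["metabolites"])
    _io.write_design(bundle.design, paths["design"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False,
                        float_format=_io.FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}
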