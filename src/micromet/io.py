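"""On-disk formats and validated in-memory carriers.

Everything the pipeline reads or writes goes through this module: TSV
feature tables (features x samples), a Silva-style taxonomy table, the
per-sample qPCR biomass series, the cohort design table, GMT metabolite-set
libraries, newick trees, and association networks as edge-list TSV or
GraphML. TSV is the canonical dialect (tab-separated, '.' decimal, UTF-8);
floats are written with 12 significant digits so a write/read round trip is
the identity for all practical purposes.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger("micromet")

FLOAT_FMT = "%.12g"

#: Recognised feature-table kinds.
KINDS = frozenset(
    {
        "asv_counts",
        "absolute_abundance",
        "genus_abundance",
        "metabolite_concentration",
        "clr_values",
    }
)

GROUPS = ("HC", "CD", "UC")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

NETWORK_COLUMNS = ["cohort", "taxon_id", "genus", "metabolite_id", "rho", "p", "q"]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its contract."""


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise FormatError(f"duplicate {what}: {dups}")


@dataclasses.dataclass
class FeatureTable:
    """A features x samples matrix of non-negative reals.

    ``kind`` tags what the values are (ASV counts, 16S copies/sample,
    concentrations, CLR values). Missing cells (NaN) are only permitted in
    metabolite tables, where they denote unmeasured concentrations and are
    imputed downstream.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature-table kind: {self.kind!r}")
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        nan_ok = self.kind == "metabolite_concentration"
        if np.isinf(values).any():
            raise FormatError("feature table contains non-finite values")
        if not nan_ok and np.isnan(values).any():
            raise FormatError(f"missing values are not permitted in {self.kind}")
        if self.kind != "clr_values":
            with np.errstate(invalid="ignore"):
                if (values < 0).any():
                    raise FormatError(f"negative values in {self.kind} table")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(), self.kind)

    def with_values(self, data: pd.DataFrame, kind: str | None = None) -> "FeatureTable":
        return FeatureTable(data, kind or self.kind)


@dataclasses.dataclass
class TaxonomyTable:
    """Silva-style lineage (kingdom..genus, optional species) per ASV.

    A missing genus is carried as NaN/empty; such ASVs are later retained
    as family-tagged pseudo-genera rather than dropped.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ASV ids")
        missing_cols = [r for r in RANKS if r not in self.data.columns]
        if missing_cols:
            raise FormatError(f"taxonomy table missing rank columns: {missing_cols}")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)

    def genus_of(self, asv_ids: Sequence[str]) -> pd.Series:
        """Genus label per ASV; unlabelled ASVs become '<family>_unclassified'."""
        missing = [a for a in asv_ids if a not in self.data.index]
        if missing:
            raise KeyError(f"ASVs absent from taxonomy: {missing}")
        sub = self.data.loc[list(asv_ids)]
        genus = sub["genus"].astype("string")
        family = sub["family"].astype("string")
        blank_g = genus.isna() | (genus.str.strip() == "")
        blank_f = family.isna() | (family.str.strip() == "")
        fallback = family.where(~blank_f, "unknown_family") + "_unclassified"
        return genus.where(~blank_g, fallback).astype(str)


@dataclasses.dataclass
class BiomassSeries:
    """Per-sample total bacterial 16S copies (copies per gram of stool)."""

    series: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.series.index, "sample ids")
        vals = self.series.to_numpy(dtype=float)
        if np.isnan(vals).any() or np.isinf(vals).any() or (vals <= 0).any():
            raise FormatError("biomass values must be strictly positive and finite")
        self.series = self.series.astype(float)
        self.series.index = self.series.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.series.index)

    def select_samples(self, sample_ids: Sequence[str]) -> "BiomassSeries":
        return BiomassSeries(self.series.loc[list(sample_ids)].copy())


@dataclasses.dataclass
class CohortDesign:
    """Sample-to-cohort assignment plus carried (unmodelled) covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        if "group" not in self.data.columns:
            raise FormatError("design table needs a 'group' column")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown cohort labels: {sorted(bad)} (expected {GROUPS})")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def samples_of(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])

    def select_samples(self, sample_ids: Sequence[str]) -> "CohortDesign":
        return CohortDesign(self.data.loc[list(sample_ids)].copy())


@dataclasses.dataclass
class PathwayLibrary:
    """Named metabolite sets (GMT), with a declared identifier namespace."""

    pathways: dict[str, frozenset[str]]
    names: dict[str, str]
    namespace: str = "custom"

    def __post_init__(self) -> None:
        empty = [p for p, members in self.pathways.items() if not members]
        if empty:
            raise FormatError(f"empty pathways not allowed: {empty}")

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


@dataclasses.dataclass
class InputBundle:
    """Validated, sample-aligned inputs for one analysis run."""

    counts: FeatureTable
    taxonomy: TaxonomyTable
    biomass: BiomassSeries
    metabolites: FeatureTable
    design: CohortDesign
    tree: TreeNode | None = None
    library: PathwayLibrary | None = None
    dropped_samples: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids


# ---------------------------------------------------------------------------
# table readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].str.strip() != "")
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"non-numeric cell in {path} at row {row!r}, column {col!r}"
                ) from None
            df[col] = coerced
    return df


def read_feature_table(path: str | Path, kind: str) -> FeatureTable:
    return FeatureTable(_read_tsv_matrix(path), kind)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="asv_id")


def read_biomass(path: str | Path) -> BiomassSeries:
    df = _read_tsv_matrix(path)
    return BiomassSeries(df.iloc[:, 0])


def write_biomass(biomass: BiomassSeries, path: str | Path) -> None:
    biomass.series.to_frame("total_16s_copies").to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="sample_id"
    )


def read_design(path: str | Path) -> CohortDesign:
    return CohortDesign(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


def write_design(design: CohortDesign, path: str | Path) -> None:
    design.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path, namespace: str = "custom") -> PathwayLibrary:
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT rows need >= 3 tab-separated fields"
                )
            pid, name, *members = fields
            if pid in pathways:
                raise FormatError(f"duplicate pathway id {pid!r} in {path}")
            pathways[pid] = frozenset(m for m in members if m)
            names[pid] = name
    return PathwayLibrary(pathways, names, namespace)


def write_gmt(library: PathwayLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in library.pathways:
            members = "\t".join(sorted(library.pathways[pid]))
            fh.write(f"{pid}\t{library.names.get(pid, pid)}\t{members}\n")


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    leaves = [t.name for t in tree.tips()]
    _check_unique(leaves, "tree leaf labels")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------


def read_inputs(
    counts: str | Path,
    taxonomy: str | Path,
    biomass: str | Path,
    metabolites: str | Path,
    design: str | Path,
    tree: str | Path | None = None,
    library: str | Path | None = None,
) -> InputBundle:
    """Read all inputs and align them on their common sample set.

    The sample universe is the intersection of the sample ids of the counts,
    biomass, metabolite and design tables; every table is reordered to that
    common order and dropped samples are logged per input.
    """
    bundle = align_bundle(
        read_feature_table(counts, "asv_counts"),
        read_taxonomy(taxonomy),
        read_biomass(biomass),
        read_feature_table(metabolites, "metabolite_concentration"),
        read_design(design),
        tree=read_tree(tree) if tree else None,
        library=read_gmt(library) if library else None,
    )
    return bundle


def align_bundle(
    counts: FeatureTable,
    taxonomy: TaxonomyTable,
    biomass: BiomassSeries,
    metabolites: FeatureTable,
    design: CohortDesign,
    tree: TreeNode | None = None,
    library: PathwayLibrary | None = None,
) -> InputBundle:
    """Intersect sample ids across tables and reorder to a common order."""
    universes = {
        "counts": counts.sample_ids,
        "biomass": biomass.sample_ids,
        "metabolites": metabolites.sample_ids,
        "design": design.sample_ids,
    }
    common = set(universes["counts"])
    for ids in universes.values():
        common &= set(ids)
    if not common:
        raise FormatError("empty sample intersection across inputs")
    # preserve the counts table's sample order
    order = [s for s in universes["counts"] if s in common]
    dropped = {
        name: sorted(set(ids) - common) for name, ids in universes.items()
    }
    for name, drop in dropped.items():
        if drop:
            log.warning("dropping %d sample(s) absent elsewhere from %s: %s",
                        len(drop), name, drop)
    missing_tax = [f for f in counts.feature_ids if f not in taxonomy.data.index]
    if missing_tax:
        raise FormatError(f"ASVs missing from taxonomy: {missing_tax}")
    return InputBundle(
        counts=counts.select_samples(order),
        taxonomy=taxonomy,
        biomass=biomass.select_samples(order),
        metabolites=metabolites.select_samples(order),
        design=design.select_samples(order),
        tree=tree,
        library=library,
        dropped_samples={k: v for k, v in dropped.items() if v},
    )


# ---------------------------------------------------------------------------
# association networks
# ---------------------------------------------------------------------------


def write_network(edges: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write association edges as an edge-list TSV or bipartite GraphML.

    The TSV columns are exactly ``cohort, taxon_id, genus, metabolite_id,
    rho, p, q``; extra columns in ``edges`` are ignored on write.
    """
    missing = [c for c in NETWORK_COLUMNS if c not in edges.columns]
    if missing:
        raise FormatError(f"edge table missing columns: {missing}")
    out = edges.loc[:, NETWORK_COLUMNS]
    if format == "tsv":
        out.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False)
    elif format == "graphml":
        g = nx.Graph()
        for row in out.itertuples(index=False):
            t = f"taxon:{row.taxon_id}"
            m = f"metabolite:{row.metabolite_id}"
            g.add_node(t, bipartite="taxon", genus=str(row.genus))
            g.add_node(m, bipartite="metabolite")
            g.add_edge(t, m, cohort=str(row.cohort), rho=float(row.rho),
                       p=float(row.p), q=float(row.q))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cohort": str, "taxon_id": str,
                                            "genus": str, "metabolite_id": str})
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"network file missing columns: {missing}")
    return df
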