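"""Raw tables -> analysis-ready matrices.

Absolute-abundance scaling by qPCR biomass, genus aggregation, pooled
prevalence filtering, the centered log-ratio transform, and metabolite
conditioning (half-minimum imputation plus a log copy for univariate use).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import BiomassSeries, FeatureTable, TaxonomyTable

log = logging.getLogger("micromet")


def to_absolute(counts: FeatureTable, biomass: BiomassSeries) -> FeatureTable:
    """Rescale compositional counts to ecosystem (absolute) abundance.

    ``value(f, s) = count(f, s) / library_size(s) * total_16s_copies(s)``,
    so each sample's column sum equals its measured biomass exactly.
    """
    if counts.kind != "asv_counts":
        raise ValueError(f"expected asv_counts, got {counts.kind}")
    missing = [s for s in counts.sample_ids if s not in biomass.series.index]
    if missing:
        raise KeyError(f"samples without biomass: {missing}")
    lib = counts.data.sum(axis=0)
    zero = list(lib.index[lib == 0])
    if zero:
        raise ValueError(f"zero library size for samples: {zero}")
    scale = biomass.series.loc[counts.sample_ids] / lib
    return FeatureTable(counts.data.mul(scale, axis=1), "absolute_abundance")


def aggregate_genus(table: FeatureTable, taxonomy: TaxonomyTable) -> FeatureTable:
    """Sum ASV rows into genera; unlabelled ASVs become family pseudo-genera.

    An ASV without a genus label is retained under ``<family>_unclassified``
    rather than dropped, so family-level findings survive aggregation.
    Per-sample totals are conserved.
    """
    genus = taxonomy.genus_of(table.feature_ids)
    out = table.data.groupby(genus.to_numpy()).sum()
    out.index.name = "genus"
    kind = "genus_abundance" if table.kind != "asv_counts" else "asv_counts"
    return FeatureTable(out.sort_index(), kind)


@dataclasses.dataclass
class PrevalenceReport:
    """Per-feature presence fractions and the keep/remove verdict."""

    data: pd.DataFrame  # columns: n_present, fraction_present, kept

    def kept_features(self) -> list[str]:
        return list(self.data.index[self.data["kept"]])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")


def prevalence_filter(
    table: FeatureTable, prevalence_min: float
) -> tuple[FeatureTable, PrevalenceReport]:
    """Remove features present (value > 0) in fewer than ``prevalence_min``
    of all samples.

    Prevalence is computed on the pooled sample set, before any cohort
    splitting, screening out rare taxa and sequencing artifacts.
    """
    if table.n_features == 0:
        raise ValueError("prevalence_filter on an empty table")
    present = (table.data > 0).sum(axis=1)
    frac = present / table.n_samples
    kept = frac >= prevalence_min
    report = PrevalenceReport(
        pd.DataFrame(
            {"n_present": present, "fraction_present": frac, "kept": kept}
        )
    )
    if not kept.any():
        log.warning("prevalence filter removed every feature")
    return (
        FeatureTable(table.data.loc[kept].copy(), table.kind)
        if kept.any()
        else FeatureTable(table.data.loc[kept], table.kind),
        report,
    )


def clr_transform(table: FeatureTable, pseudocount: float = 0.5) -> FeatureTable:
    """Centered log-ratio transform, one sample (column) at a time.

    ``x'(f, s) = ln(v + pc) - mean_f ln(v + pc)``; every sample's CLR values
    sum to zero. A positive pseudocount is required whenever zeros are
    present.
    """
    values = table.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("CLR input must be non-negative")
    if pseudocount <= 0 and (values == 0).any():
        raise ValueError("non-positive pseudocount with zeros present")
    logv = np.log(values + pseudocount)
    clr = logv - logv.mean(axis=0, keepdims=True)
    return FeatureTable(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        "clr_values",
    )


@dataclasses.dataclass
class ConditionedMetabolites:
    """Imputed concentrations plus a log copy for univariate testing.

    Rank-based operations (Spearman networks) consume ``imputed``; the log
    transform is strictly monotone, so it cannot change any rank-based
    statistic and exists only for location-style univariate summaries.
    """

    imputed: FeatureTable
    log_imputed: FeatureTable
    dropped_features: list[str]


def condition_metabolites(table: FeatureTable) -> ConditionedMetabolites:
    """Impute missing cells as half the feature's minimum observed positive
    value; drop features with no observed values."""
    if table.kind != "metabolite_concentration":
        raise ValueError(f"expected metabolite_concentration, got {table.kind}")
    data = table.data.copy()
    dropped = list(data.index[data.isna().all(axis=1)])
    if dropped:
        log.warning("dropping entirely-missing metabolites: %s", dropped)
        data = data.drop(index=dropped)
    for feat in data.index[data.isna().any(axis=1)]:
        row = data.loc[feat]
        positive = row[row > 0]
        fill = positive.min() / 2.0 if len(positive) else 0.0
        data.loc[feat] = row.fillna(fill)
    imputed = FeatureTable(data, "metabolite_concentration")
    logged = FeatureTable(
        np.log(data.where(data > 0, np.nan)).fillna(
            np.log(data[data > 0].min().min() / 2.0) if (data > 0).any().any() else 0.0
        ),
        "clr_values",  # carries negatives; reuse the unconstrained tag
    )
    return ConditionedMetabolites(imputed, logged, dropped)
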