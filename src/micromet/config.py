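"""Analysis configuration: the thresholds that define the whole pipeline.

The defaults mirror the analysis conventions of qPCR-scaled 16S /
metabolomics integration studies: Spearman edges are kept at ``|rho| >= 0.5``
and BH-FDR ``q <= 0.05``; genera must be present in at least 20% of all
samples; the healthy-vs-disease sign-flip rule uses median correlations
``>= 0.4`` (healthy) and ``<= -0.4`` (disease); univariate contrasts are
called significant at ``q < 0.1``; permutation tests run 999 permutations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable thresholds and switches for the analysis pipeline.

    Parameters
    ----------
    r_threshold:
        Minimum absolute Spearman correlation for a network edge.
    fdr_alpha:
        BH-FDR cutoff applied to each cohort's correlation family.
    prevalence_min:
        Minimum fraction of all samples in which a genus must be present.
    median_pos_threshold, median_neg_threshold:
        Median-correlation cutoffs for the healthy/disease sign-flip rule.
    q_significance:
        q-value below which univariate contrasts are flagged significant.
    n_permutations:
        Permutations for PERMANOVA and the dispersion test.
    clr_pseudocount:
        Offset added before the centered log-ratio transform. The default,
        half of one 16S copy, sits below any observed positive absolute
        abundance.
    bh_family:
        ``"per_contrast"`` corrects each pairwise contrast across features
        (how per-feature q-values are conventionally reported next to an
        omnibus p); ``"per_feature"`` corrects the three contrasts within
        each feature.
    genus_first:
        Correlate genus-aggregated abundances instead of ASVs.
    global_bh:
        Pool all cohorts' correlation p-values into one BH family instead
        of one family per cohort.
    invert_enrichment_ratio:
        Report expected/observed instead of observed/expected.
    """

    r_threshold: float = 0.5
    fdr_alpha: float = 0.05
    prevalence_min: float = 0.20
    median_pos_threshold: float = 0.4
    median_neg_threshold: float = -0.4
    q_significance: float = 0.1
    n_permutations: int = 999
    clr_pseudocount: float = 0.5
    rng_seed: int = 0
    bh_family: str = "per_contrast"
    genus_first: bool = False
    global_bh: bool = False
    invert_enrichment_ratio: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if not (0.0 <= self.prevalence_min <= 1.0):
            raise ValueError(
                f"prevalence_min must be in [0, 1], got {self.prevalence_min}"
            )
        if not (0.0 < self.r_threshold <= 1.0):
            raise ValueError(f"r_threshold must be in (0, 1], got {self.r_threshold}")
        if self.n_permutations < 99:
            raise ValueError(
                f"n_permutations must be >= 99, got {self.n_permutations}"
            )
        if self.bh_family not in ("per_contrast", "per_feature"):
            raise ValueError(f"unknown bh_family: {self.bh_family!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
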