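"""Per-feature cohort comparisons: Kruskal-Wallis omnibus, pairwise rank
tests, Benjamini-Hochberg q-values.

The omnibus is the tie-corrected Kruskal-Wallis H with a chi-square
reference; pairwise contrasts use the two-sided rank-sum test with the
tie-corrected normal approximation (for two groups this is a monotone
function of two-group Kruskal-Wallis, so the p-values agree). Outputs label
the omnibus column ``anova_p`` to mirror the conventional figure captions,
but the statistic is always the rank-based one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .io import CohortDesign, FeatureTable

CONTRASTS = (("HC", "CD"), ("HC", "UC"), ("CD", "UC"))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group in Kruskal-Wallis input")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("Kruskal-Wallis needs a total n of at least 5")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical: no separation by construction
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} m p_(j) / j`` clipped to 1. NaN entries are
    excluded from the family and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def _rank_sum_contrast(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum contrast (tie-corrected normal approximation)."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def pairwise_rank_tests(
    features: FeatureTable,
    design: CohortDesign,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Omnibus + three pairwise contrasts per feature, with BH q-values.

    The BH family is, by default, one contrast across all features (the way
    per-feature q-values are reported beside an omnibus p); setting
    ``cfg.bh_family = "per_feature"`` corrects the three contrasts within
    each feature instead. Contrasts where either group has fewer than three
    samples are reported as missing.
    """
    cfg = cfg or AnalysisConfig()
    groups = {g: design.samples_of(g) for g in ("HC", "CD", "UC")}
    rows = []
    for feat in features.feature_ids:
        vals = features.data.loc[feat]
        by_group = {g: vals.loc[s].to_numpy(dtype=float) for g, s in groups.items()}
        nonempty = [v for v in by_group.values() if len(v) > 0]
        try:
            _, omni_p = kruskal_wallis(*nonempty)
        except ValueError:
            omni_p = np.nan
        row: dict[str, float | str] = {"feature_id": feat, "anova_p": omni_p}
        for a, b in CONTRASTS:
            key = f"{a}vs{b}"
            if len(by_group[a]) < 3 or len(by_group[b]) < 3:
                row[f"{key}_stat"] = np.nan
                row[f"{key}_p"] = np.nan
            else:
                s, p = _rank_sum_contrast(by_group[a], by_group[b])
                row[f"{key}_stat"] = s
                row[f"{key}_p"] = p
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature_id")

    if cfg.bh_family == "per_contrast":
        for a, b in CONTRASTS:
            key = f"{a}vs{b}"
            table[f"{key}_q"] = bh_adjust(table[f"{key}_p"].to_numpy())
    else:
        pcols = [f"{a}vs{b}_p" for a, b in CONTRASTS]
        qmat = np.vstack(
            [bh_adjust(table.loc[f, pcols].to_numpy()) for f in table.index]
        )
        for i, (a, b) in enumerate(CONTRASTS):
            table[f"{a}vs{b}_q"] = qmat[:, i]
    qcols = [f"{a}vs{b}_q" for a, b in CONTRASTS]
    table["significant"] = (table[qcols] < cfg.q_significance).any(axis=1)
    # column order: omnibus, then stat/p/q per contrast, then the flag
    ordered = ["anova_p"]
    for a, b in CONTRASTS:
        ordered += [f"{a}vs{b}_stat", f"{a}vs{b}_p", f"{a}vs{b}_q"]
    ordered.append("significant")
    return table[ordered]
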