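"""Per-cohort taxon-metabolite Spearman association networks.

For each cohort independently, every taxon x metabolite pair is tested by
Spearman correlation; Benjamini-Hochberg FDR is applied across all of that
cohort's pairs (degenerate constant-vector pairs are excluded from the
family); the filtered network keeps edges with ``q <= fdr_alpha`` and
``|rho| >= r_threshold``, both signs retained. "Strongly positive" edges
(``rho >= +r_threshold``) feed the cross-cohort set analyses: Venn-style
region counts of shared/unique genus-metabolite edges and per-genus
association-variability rankings.

Correlations are computed at ASV level and then collapsed to genus, so a
genus' multiple strains contribute individual correlation values — the
substrate for median-per-pair summaries; a genus-first mode is available as
a configuration switch.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import CohortDesign, FeatureTable, TaxonomyTable
from .univariate import bh_adjust

log = logging.getLogger("micromet")

COHORTS = ("HC", "CD", "UC")

RESULT_COLUMNS = [
    "cohort", "taxon_id", "genus", "metabolite_id",
    "rho", "p", "q", "n_samples", "degenerate",
]


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n by full enumeration.

    Enumerates every ordering of one rank vector; the p-value is the
    fraction of orderings whose |rho| is at least |rho_obs|.
    """
    n = len(rx)
    cx = rx - rx.mean()
    denom_x = math.sqrt((cx**2).sum())
    cy = ry - ry.mean()
    denom_y = math.sqrt((cy**2).sum())
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(cx @ cy[list(perm)]) / (denom_x * denom_y)
        total += 1
        if abs(rho) >= target:
            count += 1
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Tie-safe Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of average-ranked values. For n >= 10 the
    p-value uses the t approximation with n - 2 degrees of freedom; for
    n < 10 it is the exact permutation p by complete enumeration. A constant
    input yields (0.0, 1.0) and is considered degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 4:
        raise ValueError("spearman needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        denom = max(1.0 - rho * rho, 1e-300)
        t = rho * math.sqrt((n - 2) / denom)
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        return rho, float(min(p, 1.0))
    return rho, _spearman_exact_p(rx, ry, rho)


def _spearman_matrix(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and t-approximation p between rows of x and y.

    Returns (rho, p, degenerate_x, degenerate_y).
    """
    n = x.shape[1]
    rx = stats.rankdata(x, axis=1).astype(float)
    ry = stats.rankdata(y, axis=1).astype(float)
    degx = np.ptp(x, axis=1) == 0
    degy = np.ptp(y, axis=1) == 0
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    nx = np.sqrt((rx**2).sum(axis=1, keepdims=True))
    ny = np.sqrt((ry**2).sum(axis=1, keepdims=True))
    nx[nx == 0] = 1.0
    ny[ny == 0] = 1.0
    rho = (rx / nx) @ (ry / ny).T
    rho = np.clip(rho, -1.0, 1.0)
    denom = np.maximum(1.0 - rho**2, 1e-300)
    t = rho * np.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    rho[degx, :] = 0.0
    rho[:, degy] = 0.0
    p[degx, :] = 1.0
    p[:, degy] = 1.0
    return rho, np.minimum(p, 1.0), degx, degy


@dataclasses.dataclass
class CorrelationNetwork:
    """Filtered bipartite taxon-metabolite network for one cohort."""

    cohort: str
    edges: pd.DataFrame  # RESULT_COLUMNS subset passing the filters
    taxa: list[str]
    metabolites: list[str]

    def strong_positive(self, r_threshold: float = 0.5) -> pd.DataFrame:
        return self.edges[self.edges["rho"] >= r_threshold]


@dataclasses.dataclass
class NetworkResult:
    """Per-cohort filtered networks plus the full unfiltered test table."""

    networks: dict[str, CorrelationNetwork]
    full_results: pd.DataFrame  # RESULT_COLUMNS, every tested pair


def build_networks(
    taxa: FeatureTable,
    metabolites: FeatureTable,
    design: CohortDesign,
    cfg: AnalysisConfig | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> NetworkResult:
    """Per-cohort Spearman networks with BH-FDR and magnitude filtering.

    ``taxa`` may be an ASV-level or genus-level table; with a taxonomy each
    ASV's genus is carried on its edges (genus-level tables carry the taxon
    id itself). Cohorts with fewer than four samples are skipped with a
    warning. With ``cfg.global_bh`` the BH family pools all cohorts.
    """
    cfg = cfg or AnalysisConfig()
    if list(taxa.sample_ids) != list(metabolites.sample_ids):
        raise ValueError("taxa and metabolite tables must be sample-aligned")
    if taxonomy is not None:
        genus_map = taxonomy.genus_of(taxa.feature_ids)
    else:
        genus_map = pd.Series(taxa.feature_ids, index=taxa.feature_ids)

    frames = []
    for cohort in COHORTS:
        samples = [s for s in design.samples_of(cohort) if s in taxa.sample_ids]
        n = len(samples)
        if n == 0:
            continue
        if n < 4:
            log.warning("cohort %s has %d < 4 samples; skipped", cohort, n)
            continue
        x = taxa.data.loc[:, samples].to_numpy(dtype=float)
        y = metabolites.data.loc[:, samples].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(
                "metabolite table contains missing values; run "
                "condition_metabolites first"
            )
        rho, p, degx, degy = _spearman_matrix(x, y)
        if n < 10:  # exact enumeration for tiny cohorts
            rx = stats.rankdata(x, axis=1)
            ry = stats.rankdata(y, axis=1)
            for i in range(x.shape[0]):
                for j in range(y.shape[0]):
                    if degx[i] or degy[j]:
                        continue
                    p[i, j] = _spearman_exact_p(rx[i], ry[j], rho[i, j])
        deg = np.add.outer(degx.astype(bool), degy.astype(bool))
        frame = pd.DataFrame(
            {
                "cohort": cohort,
                "taxon_id": np.repeat(taxa.feature_ids, y.shape[0]),
                "genus": np.repeat(genus_map.to_numpy(), y.shape[0]),
                "metabolite_id": np.tile(metabolites.feature_ids, x.shape[0]),
                "rho": rho.ravel(),
                "p": p.ravel(),
                "n_samples": n,
                "degenerate": deg.ravel(),
            }
        )
        frames.append(frame)
    if not frames:
        raise ValueError("no cohort had enough samples for correlation analysis")
    full = pd.concat(frames, ignore_index=True)

    full["q"] = np.nan
    if cfg.global_bh:
        ok = ~full["degenerate"]
        full.loc[ok, "q"] = bh_adjust(full.loc[ok, "p"].to_numpy())
    else:
        for cohort in full["cohort"].unique():
            ok = (full["cohort"] == cohort) & ~full["degenerate"]
            full.loc[ok, "q"] = bh_adjust(full.loc[ok, "p"].to_numpy())
    full = full[RESULT_COLUMNS]

    networks = {}
    for cohort in full["cohort"].unique():
        sub = full[full["cohort"] == cohort]
        keep = (
            (sub["q"] <= cfg.fdr_alpha)
            & (sub["rho"].abs() >= cfg.r_threshold)
            & ~sub["degenerate"]
        )
        edges = sub[keep].copy()
        networks[cohort] = CorrelationNetwork(
            cohort=cohort,
            edges=edges.reset_index(drop=True),
            taxa=sorted(edges["taxon_id"].unique()),
            metabolites=sorted(edges["metabolite_id"].unique()),
        )
    return NetworkResult(networks, full)


def collapse_to_genus(
    network: CorrelationNetwork, taxonomy: TaxonomyTable | None = None
) -> pd.DataFrame:
    """Regroup ASV-level edges by (genus, metabolite).

    Each genus edge carries the list of its member-ASV correlation values,
    so downstream summaries can see a genus' full mixture of associating
    strains.
    """
    edges = network.edges
    if taxonomy is not None and len(edges):
        genus = taxonomy.genus_of(list(edges["taxon_id"]))
        edges = edges.assign(genus=genus.to_numpy())
    if not len(edges):
        return pd.DataFrame(
            columns=["cohort", "genus", "metabolite_id", "n_asvs", "rho_values"]
        )
    grouped = (
        edges.groupby(["genus", "metabolite_id"], sort=True)["rho"]
        .agg(list)
        .reset_index()
        .rename(columns={"rho": "rho_values"})
    )
    grouped.insert(0, "cohort", network.cohort)
    grouped["n_asvs"] = grouped["rho_values"].map(len)
    return grouped[["cohort", "genus", "metabolite_id", "n_asvs", "rho_values"]]


def strong_positive_genus_sets(
    result: NetworkResult,
    taxonomy: TaxonomyTable | None = None,
    r_threshold: float = 0.5,
) -> dict[str, set[tuple[str, str]]]:
    """Per cohort, the set of (genus, metabolite) pairs with a strongly
    positive (rho >= r_threshold) edge."""
    out: dict[str, set[tuple[str, str]]] = {}
    for cohort, net in result.networks.items():
        strong = net.strong_positive(r_threshold)
        if taxonomy is not None and len(strong):
            genus = taxonomy.genus_of(list(strong["taxon_id"])).to_numpy()
        else:
            genus = strong["genus"].to_numpy()
        out[cohort] = set(zip(genus, strong["metabolite_id"]))
    return out


def cross_state_sets(
    edge_sets: Mapping[str, set[tuple[str, str]]]
) -> pd.DataFrame:
    """Venn-region counts and edge lists for per-cohort edge sets.

    Every non-empty cohort combination gets a region named by the sorted
    cohorts it contains (e.g. ``HC``, ``HC&CD``, ``HC&CD&UC``); the region
    holds the edges present in exactly those cohorts. Region counts sum to
    the size of the union.
    """
    if len(edge_sets) < 2:
        raise ValueError("cross-state comparison needs >= 2 cohorts")
    cohorts = [c for c in COHORTS if c in edge_sets] or sorted(edge_sets)
    regions: dict[str, list] = {}
    union = set().union(*edge_sets.values())
    for edge in union:
        members = tuple(c for c in cohorts if edge in edge_sets[c])
        regions.setdefault("&".join(members), []).append(edge)
    rows = []
    for r in range(1, len(cohorts) + 1):
        for combo in itertools.combinations(cohorts, r):
            name = "&".join(combo)
            edges = sorted(regions.get(name, []))
            rows.append(
                {"region": name, "count": len(edges),
                 "edges": ";".join(f"{g}|{m}" for g, m in edges)}
            )
    return pd.DataFrame(rows)


def variable_genera(
    edge_sets: Mapping[str, set[tuple[str, str]]]
) -> pd.DataFrame:
    """Rank genera by strongly-positive metabolite counts and cross-state
    variability.

    Variability is the number of associated metabolites not shared by all
    states in which the genus has any association; a genus seen in a single
    state contributes all its metabolites (nothing can be shared across
    states). Ties rank lexicographically by genus name.
    """
    cohorts = [c for c in COHORTS if c in edge_sets] or sorted(edge_sets)
    per_genus: dict[str, dict[str, set[str]]] = {}
    for cohort in cohorts:
        for genus, met in edge_sets[cohort]:
            per_genus.setdefault(genus, {}).setdefault(cohort, set()).add(met)
    rows = []
    for genus, states in per_genus.items():
        union: set[str] = set().union(*states.values())
        if len(states) >= 2:
            shared = set.intersection(*states.values())
            variability = len(union - shared)
        else:
            variability = len(union)
        row = {"genus": genus, "variability": variability,
               "n_metabolites_union": len(union)}
        for cohort in cohorts:
            row[f"n_{cohort}"] = len(states.get(cohort, ()))
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["variability", "genus"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
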