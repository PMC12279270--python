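"""Cross-state differential analyses.

Median genus-metabolite correlations (over all tested member strains, not
only significant ones), healthy/disease anticorrelation (sign-flip)
selection, and a DyNet-style node-rewiring score.

The rewiring score follows the Dn idea concretely: for each node, one
zero-filled weight vector per state over the union of its partners across
states, the centroid of those vectors, and Dn = the mean Euclidean distance
of the state vectors from the centroid; a degree-corrected variant divides
by the union degree. The original application's exact normalisation is not
published in closed form, so this definition is fixed here and oracle-tested
against an independent brute-force computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TaxonomyTable

STATES = ("HC", "CD", "UC")


def median_pair_correlations(
    full_results: pd.DataFrame, taxonomy: TaxonomyTable | None = None
) -> pd.DataFrame:
    """Per-(genus, metabolite, cohort) median of member-ASV correlations.

    Consumes the unfiltered test table so that pairs non-significant in one
    state still have a value there. Degenerate pairs are ignored. The median
    of an even count is the mean of the central pair.
    """
    res = full_results[~full_results["degenerate"]].copy()
    if taxonomy is not None:
        res["genus"] = taxonomy.genus_of(list(res["taxon_id"])).to_numpy()
    grouped = (
        res.groupby(["genus", "metabolite_id", "cohort"], sort=True)["rho"]
        .agg(median_rho="median", n_asvs="size")
        .reset_index()
    )
    return grouped


def pivot_medians(summaries: pd.DataFrame) -> pd.DataFrame:
    """Wide (genus, metabolite) x cohort view of the median correlations."""
    wide = summaries.pivot_table(
        index=["genus", "metabolite_id"],
        columns="cohort",
        values="median_rho",
        aggfunc="first",
    )
    wide.columns.name = None
    return wide


def anticorrelation_clusters(
    summaries: pd.DataFrame,
    pos_threshold: float = 0.4,
    neg_threshold: float = -0.4,
    disease: str = "either",
) -> pd.DataFrame:
    """Sign-flip pairs: healthy median >= pos and disease median <= neg.

    ``disease`` is ``"CD"``, ``"UC"`` or ``"either"`` (the union of both
    contrasts). Returns the scatterplot data for every pair tested in both
    cohorts of a contrast: healthy median, disease median and the selection
    flag. Pairs untested in one cohort are excluded from that contrast.
    """
    wide = pivot_medians(summaries)
    if "HC" not in wide.columns:
        raise ValueError("summaries lack the HC cohort")
    diseases = ("CD", "UC") if disease == "either" else (disease,)
    frames = []
    for d in diseases:
        if d not in wide.columns:
            raise ValueError(f"summaries lack the {d} cohort")
        sub = wide[["HC", d]].dropna()
        frames.append(
            pd.DataFrame(
                {
                    "genus": [g for g, _ in sub.index],
                    "metabolite_id": [m for _, m in sub.index],
                    "contrast": f"HCvs{d}",
                    "healthy_median_rho": sub["HC"].to_numpy(),
                    "disease_median_rho": sub[d].to_numpy(),
                    "selected": (
                        (sub["HC"] >= pos_threshold) & (sub[d] <= neg_threshold)
                    ).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def rewiring_scores(
    state_networks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """DyNet-style Dn rewiring score for every node of the state networks.

    ``state_networks`` maps state -> genus-level edge table with columns
    ``genus``, ``metabolite_id`` and a weight column ``rho`` (for collapsed
    tables with several strains the median of ``rho_values`` is used).
    Scores are computed for both node sides (genera and metabolites); a
    node's Dn is zero iff its weighted neighbourhood is identical in every
    state.
    """
    if len(state_networks) < 2:
        raise ValueError("rewiring needs >= 2 states")
    states = [s for s in STATES if s in state_networks] or sorted(state_networks)
    # per state: {(node, partner): weight} for both bipartite sides
    weights: dict[str, dict[tuple[str, str], float]] = {}
    genera: set[str] = set()
    mets: set[str] = set()
    for s in states:
        table = state_networks[s]
        w: dict[tuple[str, str], float] = {}
        for row in table.itertuples(index=False):
            genus = str(row.genus)
            met = str(row.metabolite_id)
            if "rho_values" in table.columns:
                weight = float(np.median(row.rho_values))
            else:
                weight = float(row.rho)
            if genus in mets or met in genera:
                raise ValueError(
                    f"node namespace collision between genera and metabolites: "
                    f"{genus!r} / {met!r}"
                )
            w[(genus, met)] = weight
            genera.add(genus)
            mets.add(met)
        weights[s] = w

    rows = []
    for node in sorted(genera) + sorted(mets):
        side = 0 if node in genera else 1
        partners = sorted(
            {
                pair[1 - side]
                for s in states
                for pair in weights[s]
                if pair[side] == node
            }
        )
        if not partners:
            continue
        vecs = np.array(
            [
                [
                    weights[s].get((node, p) if side == 0 else (p, node), 0.0)
                    for p in partners
                ]
                for s in states
            ]
        )
        centroid = vecs.mean(axis=0)
        dn = float(np.linalg.norm(vecs - centroid, axis=1).mean())
        rows.append(
            {
                "node_id": node,
                "node_type": "genus" if side == 0 else "metabolite",
                "dn": dn,
                "union_degree": len(partners),
                "degree_corrected_dn": dn / len(partners),
            }
        )
    return pd.DataFrame(
        rows, columns=["node_id", "node_type", "dn", "union_degree",
                       "degree_corrected_dn"]
    )
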