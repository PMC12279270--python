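"""Hypergeometric over-representation analysis of metabolite sets.

Given a query set (e.g. the metabolites in a cohort's strongly positive
network edges), a measured background, and a pathway library, each pathway
is tested by the upper-tail hypergeometric probability of drawing at least
the observed number of pathway members in a query of that size. The
enrichment ratio is observed/expected hits with
``expected = |query| * K / N`` (pathway members in background over
background size); q-values are BH across tested pathways.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats

from .io import PathwayLibrary
from .univariate import bh_adjust

log = logging.getLogger("micromet")

ORA_COLUMNS = [
    "pathway_id", "pathway_name", "pathway_size", "observed_hits",
    "expected_hits", "enrichment_ratio", "p", "q",
]


def ora(
    query: Iterable[str],
    background: Iterable[str],
    library: PathwayLibrary,
    invert_ratio: bool = False,
) -> pd.DataFrame:
    """Over-representation of the query against each library pathway.

    Pathways with no member in the background are skipped (and logged);
    rows are sorted by p-value then pathway name. ``invert_ratio`` reports
    expected/observed instead of the standard observed/expected.
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query metabolites missing from background: {stray}")
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for pid, members in library.items():
        in_bg = members & background
        big_k = len(in_bg)
        if big_k == 0:
            log.warning("pathway %s has no member in the background; skipped", pid)
            continue
        k = len(in_bg & query)
        expected = n_query * big_k / n_bg
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_query)) if n_query else 1.0
        if invert_ratio:
            ratio = expected / k if k else float("nan")
        else:
            ratio = k / expected if expected > 0 else float("nan")
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": library.names.get(pid, pid),
                "pathway_size": big_k,
                "observed_hits": k,
                "expected_hits": expected,
                "enrichment_ratio": ratio,
                "p": min(p, 1.0),
                "q": None,
            }
        )
    if n_query == 0 or not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "pathway_name"]).reset_index(drop=True)
    return out[ORA_COLUMNS]
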