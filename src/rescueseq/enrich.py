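"""Hypergeometric gene-set over-representation with Bonferroni / BH control.

For a query list of n genes drawn from a universe of N genes, a set with K
members in the universe and k in the query has upper-tail p-value
P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly.  GO-style
collections are Bonferroni-corrected; pathway-style collections use BH.
The rich factor k/K sizes enrichment bubbles in the field's standard plots.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callback import CALLED_BACK_CLASSES, TREATMENT_DOWN, TREATMENT_UP, UP_CALLED_BACK
from .detest import bh_adjust
from .io import GeneSetCollection


def hypergeom_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Exact upper-tail hypergeometric p per term.

    The query and every term are intersected with the universe first; terms
    with no query overlap are reported with p = 1.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = set(query) & universe_set
    if not query_set:
        raise ValueError("query is empty after restriction to the universe")
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for gs in sets:
        members = set(gs.genes) & universe_set
        K = len(members)
        k = len(members & query_set)
        # P(X >= k) = survival function at k-1; exact, sf(-1) = 1 when k = 0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": gs.term_id,
                "category": gs.description,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "rich_factor": k / K if K > 0 else np.nan,
                "p_value": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def correct_pvalues(
    results: pd.DataFrame,
    method: str = "bonferroni",
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Add corrected_p and a significance flag (corrected_p <= threshold).

    Bonferroni multiplies by the number of testable terms, i.e. terms with at
    least one member in the universe (K >= 1); BH is the step-up procedure
    over the same terms.  Terms with K = 0 keep a missing corrected p.
    """
    if results.empty:
        raise ValueError("no enrichment results to correct")
    out = results.copy()
    testable = out["K"] >= 1
    m = int(testable.sum())
    corrected = np.full(len(out), np.nan)
    if method == "bonferroni":
        corrected[testable.to_numpy()] = np.minimum(
            out.loc[testable, "p_value"].to_numpy() * m, 1.0
        )
    elif method == "bh":
        corrected[testable.to_numpy()] = bh_adjust(out.loc[testable, "p_value"].to_numpy())
    else:
        raise ValueError(f"unknown correction method {method!r}; use 'bonferroni' or 'bh'")
    out["corrected_p"] = corrected
    out["m_tests"] = m
    out["significant"] = out["corrected_p"] <= threshold
    return out


def enrich_by_level(
    assignments: pd.DataFrame,
    sets: GeneSetCollection,
    universe: Sequence[str],
    method: str = "bonferroni",
    threshold: float = 0.05,
) -> dict[tuple[int, str], pd.DataFrame]:
    """Enrichment tables for each (level, direction class) of one treatment.

    Six tables: levels 1-3 crossed with the up/down call-back classes
    (level 3 uses the treatment-specific directions).  Empty query lists
    yield empty tables with a warning rather than an error.
    """
    out: dict[tuple[int, str], pd.DataFrame] = {}
    for level in (1, 2, 3):
        for dir_class in CALLED_BACK_CLASSES:
            wanted = (
                (TREATMENT_UP if dir_class == UP_CALLED_BACK else TREATMENT_DOWN)
                if level == 3
                else dir_class
            )
            genes = assignments.index[
                (assignments["level"] == level) & (assignments["direction"] == wanted)
            ]
            genes = [g for g in genes if g in set(universe)]
            if not genes:
                warnings.warn(f"empty query for level {level} / {dir_class}")
                out[(level, dir_class)] = pd.DataFrame(
                    columns=["term_id", "category", "N", "K", "n", "k",
                             "rich_factor", "p_value", "corrected_p", "m_tests",
                             "significant"]
                )
                continue
            table = hypergeom_enrich(genes, sets, universe)
            out[(level, dir_class)] = correct_pvalues(table, method=method, threshold=threshold)
    return out


def enrichment_long_format(
    tables: Mapping[tuple[int, str], pd.DataFrame]
) -> pd.DataFrame:
    """Stack per-(level, direction) tables into one long table for plotting."""
    frames = []
    for (level, dir_class), df in tables.items():
        if df.empty:
            continue
        d = df.copy()
        d.insert(0, "level", level)
        d.insert(1, "direction_class", dir_class)
        frames.append(d)
    if not frames:
        return pd.DataFrame(
            columns=["level", "direction_class", "term_id", "category", "N", "K",
                     "n", "k", "rich_factor", "p_value", "corrected_p", "m_tests",
                     "significant"]
        )
    return pd.concat(frames, ignore_index=True)
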