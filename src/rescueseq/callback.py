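"""Call-back gene classification and cross-treatment intersections.

A call-back gene is one the injury shifts (model vs normal control) and a
treatment shifts back in the opposite direction (treatment vs model).  Genes
are assigned to three mutually exclusive evidence tiers per treatment:

* level 1 — strong bidirectional change: |log2FC| > 0.5 and FDR < 0.05 in
  both contrasts, with opposite signs;
* level 2 — the same pattern at the weaker |log2FC| > 0.1 threshold;
* level 3 — treatment-specific change: no injury effect (model FDR > 0.05)
  but |log2FC| > 0.1 with FDR < 0.05 in the treatment contrast.

Direction: "up-called-back" genes are suppressed by injury and restored
upward by treatment (model log2FC < 0, treatment log2FC > 0);
"down-called-back" is the inverse; level-3 genes are "treatment-up" or
"treatment-down" by the sign of the treatment contrast.  Levels are
assigned in order 1 -> 2 -> 3, so the tiers partition the gene universe
together with "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UP_CALLED_BACK = "up-called-back"
DOWN_CALLED_BACK = "down-called-back"
TREATMENT_UP = "treatment-up"
TREATMENT_DOWN = "treatment-down"
NONE = "none"

CALLED_BACK_CLASSES = (UP_CALLED_BACK, DOWN_CALLED_BACK)


@dataclass(frozen=True)
class CallbackThresholds:
    level1_lfc: float = 0.5
    level2_lfc: float = 0.1
    level3_treat_lfc: float = 0.1
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if not self.level1_lfc > self.level2_lfc > 0:
            raise ValueError("need level1_lfc > level2_lfc > 0")


def classify_callback(
    model_de: pd.DataFrame,
    treat_de: pd.DataFrame,
    thresholds: CallbackThresholds = CallbackThresholds(),
) -> pd.DataFrame:
    """Assign each gene a (level, direction) from the two DE tables.

    ``model_de`` is the injury contrast (model arm vs normal control),
    ``treat_de`` the rescue contrast (treatment vs model); both must cover
    the same gene universe.  Genes untested in a contrast (missing FDR, e.g.
    all-zero counts) can never reach any level: the tiers require a tested,
    FDR-gated result in the contrasts they cite.
    """
    asym = set(model_de.index).symmetric_difference(treat_de.index)
    if asym:
        raise ValueError(f"gene universes differ between DE tables: {sorted(asym)[:10]}")
    treat_de = treat_de.reindex(model_de.index)

    lm = model_de["log2fc"].to_numpy()
    fm = model_de["fdr"].to_numpy()
    lt = treat_de["log2fc"].to_numpy()
    ft = treat_de["fdr"].to_numpy()
    t = thresholds

    # NaN fdr fails every comparison, which implements the "tested" gate
    with np.errstate(invalid="ignore"):
        model_sig = fm < t.fdr
        treat_sig = ft < t.fdr
        model_unaltered = fm > t.fdr
        opposite = lm * lt < 0
        level1 = (
            model_sig & treat_sig & opposite
            & (np.abs(lm) > t.level1_lfc) & (np.abs(lt) > t.level1_lfc)
        )
        level2 = (
            ~level1 & model_sig & treat_sig & opposite
            & (np.abs(lm) > t.level2_lfc) & (np.abs(lt) > t.level2_lfc)
        )
        level3 = (
            ~level1 & ~level2 & model_unaltered & treat_sig
            & (np.abs(lt) > t.level3_treat_lfc)
        )

    level = np.zeros(len(lm), dtype=np.int64)
    level[level1] = 1
    level[level2] = 2
    level[level3] = 3

    direction = np.full(len(lm), NONE, dtype=object)
    called = level1 | level2
    direction[called & (lm < 0)] = UP_CALLED_BACK
    direction[called & (lm > 0)] = DOWN_CALLED_BACK
    direction[level3 & (lt > 0)] = TREATMENT_UP
    direction[level3 & (lt < 0)] = TREATMENT_DOWN

    return pd.DataFrame(
        {
            "level": level,
            "direction": direction,
            "lfc_model": lm,
            "fdr_model": fm,
            "lfc_treat": lt,
            "fdr_treat": ft,
        },
        index=model_de.index,
    )


def shared_callback(
    assignments_by_treatment: Mapping[str, pd.DataFrame],
    direction_class: str,
) -> dict[int, dict[str, set[str]]]:
    """Per-level shared and per-treatment-unique gene sets for one direction.

    ``direction_class`` is "up-called-back" or "down-called-back"; for
    level 3 the corresponding treatment-specific direction ("treatment-up" /
    "treatment-down") is used, since call-back directions do not exist there.
    Returns {level: {"shared": set, "<treatment>_unique": set, ...}}.
    """
    if direction_class not in CALLED_BACK_CLASSES:
        raise ValueError(
            f"direction_class must be one of {CALLED_BACK_CLASSES}, got {direction_class!r}"
        )
    if len(assignments_by_treatment) < 2:
        raise ValueError("need at least 2 treatments to intersect")
    level3_dir = TREATMENT_UP if direction_class == UP_CALLED_BACK else TREATMENT_DOWN

    out: dict[int, dict[str, set[str]]] = {}
    for level in (1, 2, 3):
        wanted = level3_dir if level == 3 else direction_class
        sets = {
            trt: set(df.index[(df["level"] == level) & (df["direction"] == wanted)])
            for trt, df in assignments_by_treatment.items()
        }
        shared = set.intersection(*sets.values())
        entry: dict[str, set[str]] = {"shared": shared}
        for trt, genes in sets.items():
            others = set.union(*(g for t, g in sets.items() if t != trt))
            entry[f"{trt}_unique"] = genes - others
        out[level] = entry
    return out


def upset_counts(deg_lists: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Exclusive intersection sizes over every non-empty combination of lists.

    Each element of the union is counted exactly once, in the row for the
    precise combination of lists containing it, so the sizes sum to |union|.
    """
    names = list(deg_lists)
    if len(names) < 2:
        raise ValueError("need at least 2 lists")
    sets = {name: set(genes) for name, genes in deg_lists.items()}
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            exclusive = inside - outside
            rows.append(
                {
                    "combination": "&".join(combo),
                    "degree": r,
                    "size": len(exclusive),
                }
            )
    return pd.DataFrame(rows)
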