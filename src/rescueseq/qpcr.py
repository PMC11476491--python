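"""2^-ddCt relative expression and RNA-seq concordance.

Each target gene's Ct is normalized within-sample against a reference gene
(dCt = Ct_target - Ct_reference), then against the mean dCt of a calibrator
arm (ddCt), and converted to a fold change 2^-ddCt under the assumption of
perfect doubling per cycle.  Concordance with RNA-seq compares log2 fold
changes by Pearson correlation and sign agreement.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_arm: str = "NC",
) -> pd.DataFrame:
    """Per-gene per-arm relative expression by the 2^-ddCt method.

    ``ct`` has columns gene_id, sample_id, arm, ct.  dCt is computed within
    sample (target and reference Ct from the same sample); samples lacking a
    reference Ct are excluded with a warning.  Fold = 2^-ddCt, so the
    calibrator arm has mean fold 1 by construction.  Returns one row per
    (gene, arm) with mean ddCt, mean/sd fold, and replicate count.
    """
    ref = ct.loc[ct["gene_id"] == reference_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    targets = ct.loc[ct["gene_id"] != reference_gene].copy()
    has_ref = targets["sample_id"].isin(ref.index)
    if not has_ref.all():
        dropped = sorted(targets.loc[~has_ref, "sample_id"].unique())
        warnings.warn(f"samples without reference Ct excluded: {dropped}")
        targets = targets.loc[has_ref]
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()

    rows = []
    for gene, sub in targets.groupby("gene_id", sort=False):
        calib = sub.loc[sub["arm"] == calibrator_arm, "delta_ct"]
        if calib.empty:
            raise ValueError(f"gene {gene!r} has no measurements in calibrator arm "
                             f"{calibrator_arm!r}")
        calib_mean = calib.mean()
        for arm, arm_sub in sub.groupby("arm", sort=False):
            ddct_reps = arm_sub["delta_ct"].to_numpy() - calib_mean
            folds = 2.0 ** (-ddct_reps)
            rows.append(
                {
                    "gene_id": gene,
                    "arm": arm,
                    "delta_delta_ct": float(np.mean(ddct_reps)),
                    "fold": float(np.mean(folds)),
                    "fold_sd": float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
                    "log2_fold": float(np.mean(-ddct_reps)),
                    "n_replicates": len(folds),
                }
            )
    return pd.DataFrame(rows)


class ConcordanceResult(NamedTuple):
    pearson_r: float
    pearson_p: float
    sign_agreement: float
    n_pairs: int
    pairs: pd.DataFrame  # gene/arm, qpcr_log2fc, rnaseq_log2fc


def concordance(
    qpcr_log2fc: pd.Series,
    rnaseq_log2fc: pd.Series,
) -> ConcordanceResult:
    """Agreement between qPCR and RNA-seq log2 fold changes.

    Both series are indexed identically (typically (gene, contrast) pairs);
    only shared, finite entries are compared.  Requires >= 3 pairs.
    """
    joined = pd.DataFrame({"qpcr": qpcr_log2fc, "rnaseq": rnaseq_log2fc}).dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 paired measurements, got {len(joined)}")
    r, p = stats.pearsonr(joined["qpcr"], joined["rnaseq"])
    signs = np.sign(joined["qpcr"]) == np.sign(joined["rnaseq"])
    return ConcordanceResult(
        pearson_r=float(r),
        pearson_p=float(p),
        sign_agreement=float(signs.mean()),
        n_pairs=len(joined),
        pairs=joined,
    )


def qpcr_vs_de_pairs(
    rel_expr: pd.DataFrame,
    de_tables: dict[str, pd.DataFrame],
    calibrator_arm: str = "NC",
) -> tuple[pd.Series, pd.Series]:
    """Assemble aligned log2 fold-change vectors from ddct output and DE tables.

    ``de_tables`` maps arm -> DE table for the contrast (arm vs calibrator).
    Returns (qpcr, rnaseq) series indexed by (gene_id, contrast), so pairs
    from differently calibrated runs (e.g. vs normal control and vs the
    injury model) can be concatenated before computing concordance.
    """
    q_idx, q_vals, r_vals = [], [], []
    for arm, de in de_tables.items():
        sub = rel_expr.loc[rel_expr["arm"] == arm]
        for _, row in sub.iterrows():
            gene = row["gene_id"]
            if gene in de.index:
                q_idx.append((gene, f"{arm}_vs_{calibrator_arm}"))
                q_vals.append(row["log2_fold"])
                r_vals.append(de.loc[gene, "log2fc"])
    idx = (
        pd.MultiIndex.from_tuples(q_idx, names=["gene_id", "contrast"])
        if q_idx
        else None
    )
    return (
        pd.Series(q_vals, index=idx, name="qpcr_log2fc"),
        pd.Series(r_vals, index=idx, name="rnaseq_log2fc"),
    )
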