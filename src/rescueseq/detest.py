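"""Per-gene negative-binomial differential expression between two arms.

The model is NB with Var = mu + alpha * mu^2 on size-factor-normalized
counts.  Per-gene dispersions are method-of-moments estimates shrunk
conservatively toward a fitted mean trend alpha(mu) = a0 + a1/mu by taking
the maximum of the gene estimate and the trend.  Significance is a
two-sided Wald test of the log2 fold change, with the standard error from
the delta method under the per-arm NB variances.  Multiplicity is handled
with Benjamini-Hochberg step-up FDR over the tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .quantify import size_factors

LOG2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class Contrast:
    """numerator_arm vs denominator_arm, e.g. Contrast('ADM', 'NC')."""

    numerator_arm: str
    denominator_arm: str

    def __post_init__(self) -> None:
        if self.numerator_arm == self.denominator_arm:
            raise ValueError("contrast arms must be distinct")

    def __str__(self) -> str:
        return f"{self.numerator_arm}_vs_{self.denominator_arm}"

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse 'NUM:DEN' (or 'NUM_vs_DEN')."""
        sep = ":" if ":" in text else "_vs_"
        parts = text.split(sep)
        if len(parts) != 2:
            raise ValueError(f"cannot parse contrast {text!r}; expected NUM:DEN")
        return cls(parts[0], parts[1])


class DispersionFit(NamedTuple):
    dispersions: pd.Series      # shrunk per-gene values used by the test
    gene_estimates: pd.Series   # raw method-of-moments (floored at 0)
    trend: tuple[float, float]  # fitted (a0, a1) of alpha(mu) = a0 + a1/mu


def _contrast_groups(counts: CountMatrix, contrast: Contrast) -> tuple[list[str], list[str]]:
    num = counts.samples_of(contrast.numerator_arm)
    den = counts.samples_of(contrast.denominator_arm)
    for arm, group in ((contrast.numerator_arm, num), (contrast.denominator_arm, den)):
        if len(group) == 0:
            raise ValueError(f"unknown or empty arm {arm!r}")
        if len(group) < 2:
            raise ValueError(f"arm {arm!r} has {len(group)} replicate(s); need >= 2")
    return num, den


def estimate_dispersions(
    counts: CountMatrix,
    contrast: Contrast,
    factors: pd.Series | None = None,
) -> DispersionFit:
    """Per-gene NB dispersion for a two-arm contrast.

    The raw per-gene estimate averages the within-arm moment estimators
    (s^2 - mu)/mu^2 on normalized counts.  The trend is an ordinary
    least-squares fit of the *untruncated* moment estimates on 1/mu (the
    truncation at zero would bias the trend upward); the reported value is
    max(gene estimate, trend, floor).
    """
    num, den = _contrast_groups(counts, contrast)
    if factors is None:
        factors = size_factors(counts, total_count_fallback=True)
    norm = counts.counts[num + den].to_numpy(dtype=float) / factors[num + den].to_numpy()

    raw_parts = []
    for group in (num, den):
        sub = norm[:, [i for i, s in enumerate(num + den) if s in group]]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mom = (var - mu) / mu**2
        raw_parts.append(np.where(mu > 0, mom, np.nan))
    stacked = np.column_stack(raw_parts)
    valid = np.isfinite(stacked)
    n_valid = valid.sum(axis=1)
    raw = np.where(
        n_valid > 0,
        np.where(valid, stacked, 0.0).sum(axis=1) / np.maximum(n_valid, 1),
        np.nan,
    )

    base_mean = norm.mean(axis=1)
    ok = np.isfinite(raw) & (base_mean > 0)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0 = max(float(coef[0]), DISPERSION_FLOOR)
        a1 = max(float(coef[1]), 0.0)
    else:
        a0 = max(float(np.nanmedian(raw)) if ok.any() else DISPERSION_FLOOR, DISPERSION_FLOOR)
        a1 = 0.0

    gene_est = np.where(np.isfinite(raw), np.maximum(raw, 0.0), 0.0)
    with np.errstate(divide="ignore"):
        trend_vals = a0 + a1 / np.maximum(base_mean, 1e-12)
    shrunk = np.maximum(np.maximum(gene_est, trend_vals), DISPERSION_FLOOR)
    idx = counts.gene_ids
    return DispersionFit(
        dispersions=pd.Series(shrunk, index=idx, name="dispersion"),
        gene_estimates=pd.Series(gene_est, index=idx, name="dispersion_mom"),
        trend=(a0, a1),
    )


def nb_test(
    counts: CountMatrix,
    contrast: Contrast,
    dispersions: pd.Series | DispersionFit | None = None,
    factors: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test of the log2 fold change (numerator vs denominator).

    Returns a table indexed by gene_id with base_mean, log2fc, dispersion,
    p_value, fdr.  Genes with zero counts in every sample of both arms get
    missing p and are excluded from the BH ranking.
    """
    num, den = _contrast_groups(counts, contrast)
    if factors is None:
        factors = size_factors(counts, total_count_fallback=True)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, contrast, factors)
    if isinstance(dispersions, DispersionFit):
        dispersions = dispersions.dispersions
    alpha = dispersions.reindex(counts.gene_ids).to_numpy()

    norm_num = counts.counts[num].to_numpy(dtype=float) / factors[num].to_numpy()
    norm_den = counts.counts[den].to_numpy(dtype=float) / factors[den].to_numpy()
    m_num = norm_num.mean(axis=1)
    m_den = norm_den.mean(axis=1)
    base_mean = np.concatenate([norm_num, norm_den], axis=1).mean(axis=1)

    log2fc = np.log2((m_num + pseudocount) / (m_den + pseudocount))

    # delta-method variance of the arm means under the NB model:
    # Var(X_j / s_j) = q/s_j + alpha * q^2, with q estimated by the arm mean
    def _mean_var(m: np.ndarray, group: list[str]) -> np.ndarray:
        inv_s = (1.0 / factors[group].to_numpy())[None, :]
        per_sample = m[:, None] * inv_s + alpha[:, None] * m[:, None] ** 2
        return per_sample.sum(axis=1) / len(group) ** 2

    var_num = _mean_var(m_num, num)
    var_den = _mean_var(m_den, den)
    se2 = var_num / ((m_num + pseudocount) * LOG2) ** 2 + var_den / (
        (m_den + pseudocount) * LOG2
    ) ** 2

    untested = (m_num == 0) & (m_den == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, log2fc / np.sqrt(se2), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    p[untested] = np.nan

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": alpha,
            "p_value": p,
        },
        index=counts.gene_ids,
    )
    result["fdr"] = bh_adjust(result["p_value"])
    return result


def bh_adjust(p_values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing values stay missing."""
    arr = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(arr, np.nan)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="fdr")
    return out


def call_degs(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed genes: fdr < threshold and |log2FC| >= threshold."""
    sig = (results["fdr"] < fdr_threshold) & (results["log2fc"].abs() >= lfc_threshold)
    degs = results.loc[sig.fillna(False)].copy()
    degs["direction"] = np.where(degs["log2fc"] > 0, "up", "down")
    return degs
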