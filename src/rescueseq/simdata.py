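"""Synthetic injury-rescue count datasets with known ground truth.

The generator emulates a four-arm podocyte injury-rescue design: a normal
control arm (NC), an injury model arm (ADM, adriamycin-treated), and one or
more treatment arms (default W1CC, W5CC) in which a drug partially or fully
reverses the injury signature.  Genes are assigned to archetypes:

* ``restored_up`` — suppressed by injury, restored upward by every treatment
  (the "up-called-back" pattern);
* ``restored_down`` — induced by injury, pushed back down by treatment;
* ``partial_restored`` — injured in a random direction, with only a fraction
  of the injury effect reversed (exercises the weak call-back band);
* ``injury_only`` — perturbed by injury, untouched by treatment;
* ``treatment_only`` — unaffected by injury, perturbed by treatment only
  (the "specific altered" pattern);
* ``null`` — no effect anywhere.

Counts are negative binomial with mean ``s_j * q_gi`` (per-sample depth
factor times the arm-specific expected expression) and a mean-dependent
dispersion trend ``alpha(mu) = a0 + a1 / mu`` (Var = mu + alpha * mu^2).
Everything is driven by an explicit seed; no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, GeneSetCollection

ARCHETYPES = (
    "restored_up",
    "restored_down",
    "partial_restored",
    "injury_only",
    "treatment_only",
    "null",
)

#: Archetypes whose injury effect is (at least partly) reversed by treatment.
RESTORED_ARCHETYPES = ("restored_up", "restored_down", "partial_restored")

DEFAULT_ARCHETYPE_FRACTIONS = {
    "restored_up": 0.15,
    "restored_down": 0.15,
    "partial_restored": 0.10,
    "injury_only": 0.10,
    "treatment_only": 0.10,
    "null": 0.40,
}

# Thresholds of the three-tier call-back definition (strict > comparisons),
# used to derive each gene's expected level from its true effects.
LEVEL1_LFC = 0.5
LEVEL2_LFC = 0.1
LEVEL3_TREAT_LFC = 0.1


@dataclass
class SimConfig:
    """Parameters of one simulated injury-rescue dataset."""

    n_genes: int = 2000
    n_replicates_per_arm: int = 3
    treatments: tuple[str, ...] = ("W1CC", "W5CC")
    baseline_log_mean_range: tuple[float, float] = (0.0, 14.0)
    dispersion_model: tuple[float, float] = (0.05, 0.0)
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    injury_effect_log2fc: float = 1.5
    rescue_fraction: float = 1.0
    partial_rescue_fraction: float = 0.3
    library_size_log_sd: float = 0.1
    seed: int = 0

    normal_arm: str = "NC"
    model_arm: str = "ADM"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates_per_arm < 2:
            raise ValueError("n_replicates_per_arm must be >= 2 (variance estimable)")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.archetype_fractions.values()):
            raise ValueError("archetype_fractions must be non-negative")
        lo, hi = self.baseline_log_mean_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ValueError("baseline_log_mean_range must be a finite (lo, hi) pair")
        if not math.isfinite(self.injury_effect_log2fc):
            raise ValueError("injury_effect_log2fc must be finite")
        # largest simulated log2 mean must stay representable as a double
        if hi + abs(self.injury_effect_log2fc) * (1 + self.rescue_fraction) > 1000:
            raise ValueError(
                "baseline_log_mean_range and injury_effect_log2fc give a "
                "non-finite expected mean"
            )
        a0, a1 = self.dispersion_model
        # alpha(mu) = a0 + a1/mu must stay positive over the simulated range
        mu_min = 2.0 ** (lo - abs(self.injury_effect_log2fc))
        mu_max = 2.0 ** (hi + abs(self.injury_effect_log2fc))
        if a0 + a1 / mu_min <= 0 or a0 + a1 / mu_max <= 0:
            raise ValueError("dispersion_model yields non-positive dispersion over the mean range")
        if not 0.0 <= self.rescue_fraction:
            raise ValueError("rescue_fraction must be >= 0")
        if self.library_size_log_sd < 0:
            raise ValueError("library_size_log_sd must be >= 0")

    @property
    def arms(self) -> tuple[str, ...]:
        return (self.normal_arm, self.model_arm, *self.treatments)

    def dispersion_at(self, mu: np.ndarray | float) -> np.ndarray | float:
        a0, a1 = self.dispersion_model
        return a0 + a1 / np.maximum(mu, 1e-12)


def expected_level(
    true_injury_log2fc: float,
    true_rescue_log2fc: float,
    level1_lfc: float = LEVEL1_LFC,
    level2_lfc: float = LEVEL2_LFC,
    level3_treat_lfc: float = LEVEL3_TREAT_LFC,
) -> int:
    """Call-back level implied by the *true* effects (0 means none).

    In the truth table a contrast counts as significant exactly when its true
    effect is nonzero, so the tier rules reduce to threshold checks on the
    true log2 fold changes.
    """
    mi, ti = true_injury_log2fc, true_rescue_log2fc
    opposite = mi * ti < 0
    if abs(mi) > level1_lfc and abs(ti) > level1_lfc and opposite:
        return 1
    if abs(mi) > level2_lfc and abs(ti) > level2_lfc and opposite:
        return 2
    if mi == 0 and abs(ti) > level3_treat_lfc:
        return 3
    return 0


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its ground-truth table.

    Returns the counts (with arms, gene lengths, and the true depth factors
    attached) and a per-gene truth table with columns ``archetype``,
    ``baseline_mean``, ``true_injury_log2fc``, and per treatment
    ``true_rescue_log2fc_<T>`` / ``expected_level_<T>``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    # archetype assignment: deterministic counts from fractions, shuffled
    counts_per = {a: int(round(config.archetype_fractions.get(a, 0.0) * n)) for a in ARCHETYPES}
    assigned = sum(counts_per.values())
    counts_per["null"] += n - assigned  # absorb rounding remainder
    if counts_per["null"] < 0:
        # remainder was negative: trim from the largest bucket instead
        counts_per["null"] = 0
        while sum(counts_per.values()) > n:
            biggest = max(counts_per, key=counts_per.get)
            counts_per[biggest] -= 1
    archetypes = np.array([a for a in ARCHETYPES for _ in range(counts_per[a])])
    rng.shuffle(archetypes)

    lo, hi = config.baseline_log_mean_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=n)

    m = config.injury_effect_log2fc
    signs = rng.choice([-1.0, 1.0], size=n)
    injury = np.zeros(n)
    injury[archetypes == "restored_up"] = -m
    injury[archetypes == "restored_down"] = m
    mask = archetypes == "partial_restored"
    injury[mask] = m * signs[mask]
    mask = archetypes == "injury_only"
    injury[mask] = m * signs[mask]

    rescue: dict[str, np.ndarray] = {}
    for treatment in config.treatments:
        r = np.zeros(n)
        restored = np.isin(archetypes, ("restored_up", "restored_down"))
        r[restored] = -injury[restored] * config.rescue_fraction
        part = archetypes == "partial_restored"
        r[part] = -injury[part] * config.partial_rescue_fraction
        tonly = archetypes == "treatment_only"
        r[tonly] = m * signs[tonly]
        rescue[treatment] = r

    arm_effects = {config.normal_arm: np.zeros(n), config.model_arm: injury}
    for treatment in config.treatments:
        arm_effects[treatment] = injury + rescue[treatment]

    n_rep = config.n_replicates_per_arm
    sample_ids, sample_arms = [], []
    for arm in config.arms:
        for rep in range(1, n_rep + 1):
            sample_ids.append(f"{arm}_{rep}")
            sample_arms.append(arm)
    depth = np.exp(rng.normal(0.0, config.library_size_log_sd, size=len(sample_ids)))

    matrix = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, (sid, arm) in enumerate(zip(sample_ids, sample_arms)):
        q = baseline * 2.0 ** arm_effects[arm]
        if not np.all(np.isfinite(q)):
            raise ValueError("non-finite expected mean; check baseline_log_mean_range "
                             "and injury_effect_log2fc")
        mean = depth[j] * q
        alpha = np.asarray(config.dispersion_at(q), dtype=float)
        poisson_like = alpha <= 1e-12
        col = np.empty(n, dtype=np.int64)
        if poisson_like.any():
            col[poisson_like] = rng.poisson(mean[poisson_like])
        if (~poisson_like).any():
            size = 1.0 / alpha[~poisson_like]
            p = size / (size + mean[~poisson_like])
            col[~poisson_like] = rng.negative_binomial(size, p)
        matrix[:, j] = col

    counts = pd.DataFrame(matrix, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    arms = pd.Series(sample_arms, index=sample_ids, name="arm")
    lengths = pd.Series(rng.integers(500, 5001, size=n), index=counts.index, name="length")
    cm = CountMatrix(
        counts=counts,
        arms=arms,
        gene_lengths=lengths,
        depth_factors=pd.Series(depth, index=sample_ids, name="depth_factor"),
    )

    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "baseline_mean": baseline,
            "true_injury_log2fc": injury,
        },
        index=counts.index,
    )
    for treatment in config.treatments:
        truth[f"true_rescue_log2fc_{treatment}"] = rescue[treatment]
        truth[f"expected_level_{treatment}"] = [
            expected_level(mi, ti) for mi, ti in zip(injury, rescue[treatment])
        ]
    return cm, truth


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_fraction: float = 0.3,
    restored_weight: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Build GMT-serializable gene sets, a fraction enriched for restored genes.

    Enriched sets draw ``restored_weight`` of their members from
    restored-archetype genes and the rest uniformly; plain sets are uniform
    draws from the whole gene universe.  Enriched term ids are recorded in
    ``GeneSetCollection.enriched_terms`` (the enrichment oracle).
    """
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must be in [0, 1]")
    lo, hi = set_size_range
    genes = np.asarray(truth.index)
    if hi > len(genes):
        raise ValueError("set sizes cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    restored = np.asarray(truth.index[truth["archetype"].isin(RESTORED_ARCHETYPES)])
    n_enriched = int(round(enriched_fraction * n_sets))

    sets: list[GeneSet] = []
    flagged: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        term = f"SET{i:04d}"
        if i < n_enriched and len(restored) > 0:
            k_restored = min(int(round(restored_weight * size)), len(restored))
            members = set(rng.choice(restored, size=k_restored, replace=False))
            pool = np.asarray([g for g in genes if g not in members])
            extra = rng.choice(pool, size=size - len(members), replace=False)
            members.update(extra)
            flagged.append(term)
            description = "enriched"
        else:
            members = set(rng.choice(genes, size=size, replace=False))
            description = "background"
        sets.append(GeneSet(term, description, tuple(sorted(members))))
    return GeneSetCollection(sets, enriched_terms=tuple(flagged))


def simulate_ct_table(
    truth: pd.DataFrame,
    genes: list[str],
    reference_gene: str,
    config: SimConfig | None = None,
    base_ct: float = 20.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct values consistent with the simulated expression truth.

    Ct drops by one cycle per doubling of expression:
    ``Ct = base_ct - log2(relative expression in arm) + N(0, noise_sd)``.
    The reference gene must have the null archetype, so its Ct is constant
    across arms up to noise (a valid normalizer).
    """
    config = config or SimConfig()
    missing = [g for g in [*genes, reference_gene] if g not in truth.index]
    if missing:
        raise ValueError(f"genes not in truth table: {missing}")
    if truth.loc[reference_gene, "archetype"] != "null":
        raise ValueError(
            f"reference gene {reference_gene} has archetype "
            f"{truth.loc[reference_gene, 'archetype']!r}; a null-archetype gene is required"
        )
    rng = np.random.default_rng(seed)
    rows = []
    all_genes = [reference_gene] + [g for g in genes if g != reference_gene]
    for gene in all_genes:
        mi = truth.loc[gene, "true_injury_log2fc"]
        for arm in config.arms:
            if arm == config.normal_arm:
                eff = 0.0
            elif arm == config.model_arm:
                eff = mi
            else:
                eff = mi + truth.loc[gene, f"true_rescue_log2fc_{arm}"]
            for rep in range(1, n_replicates + 1):
                ct = base_ct - eff + rng.normal(0.0, noise_sd) if noise_sd > 0 else base_ct - eff
                rows.append((gene, f"{arm}_q{rep}", arm, ct))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "arm", "ct"])
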