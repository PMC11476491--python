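"""NB dispersion estimation, Wald testing, BH adjustment, DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescueseq.detest import (
    Contrast,
    bh_adjust,
    call_degs,
    estimate_dispersions,
    nb_test,
)
from rescueseq.io import CountMatrix
from rescueseq.simdata import SimConfig, simulate_counts


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook step-up definition: adj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


def _two_arm_matrix(a: np.ndarray, b: np.ndarray) -> CountMatrix:
    n_a, n_b = a.shape[1], b.shape[1]
    cols = [f"A_{i}" for i in range(n_a)] + [f"B_{i}" for i in range(n_b)]
    counts = pd.DataFrame(
        np.hstack([a, b]),
        index=pd.Index([f"g{i}" for i in range(a.shape[0])], name="gene_id"),
        columns=cols,
    )
    arms = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
    return CountMatrix(counts=counts, arms=arms)


class TestContrast:
    def test_identical_arms_rejected(self):
        with pytest.raises(ValueError):
            Contrast("NC", "NC")

    def test_parse_roundtrip(self):
        c = Contrast.parse("W1CC:ADM")
        assert (c.numerator_arm, c.denominator_arm) == ("W1CC", "ADM")
        assert Contrast.parse(str(c)) == c


class TestEstimateDispersions:
    def test_constant_counts_raw_zero_reported_trend(self):
        a = np.full((5, 3), 50)
        b = np.full((5, 3), 50)
        cm = _two_arm_matrix(a, b)
        fit = estimate_dispersions(cm, Contrast("A", "B"))
        assert (fit.gene_estimates == 0).all()
        a0, a1 = fit.trend
        expected = max(a0 + a1 / 50.0, 1e-8)
        assert np.allclose(fit.dispersions, expected)
        assert (fit.dispersions > 0).all()

    def test_poisson_counts_median_at_most_trend(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(50, 500, 400)
        a = rng.poisson(mu[:, None], (400, 50))
        b = rng.poisson(mu[:, None], (400, 50))
        cm = _two_arm_matrix(a, b)
        fit = estimate_dispersions(cm, Contrast("A", "B"))
        a0, a1 = fit.trend
        trend_at = a0 + a1 / fit.dispersions.index.map(
            dict(zip(fit.dispersions.index, mu))
        ).to_numpy()
        assert np.median(fit.dispersions) <= np.median(trend_at) + 0.01

    def test_nb_mom_consistency(self):
        """True alpha = 0.2 at mean 100, n = 200: MoM within 20%."""
        rng = np.random.default_rng(6)
        alpha, mu, n = 0.2, 100.0, 200
        size = 1.0 / alpha
        p = size / (size + mu)
        a = rng.negative_binomial(size, p, (300, n))
        b = rng.negative_binomial(size, p, (300, n))
        cm = _two_arm_matrix(a, b)
        fit = estimate_dispersions(cm, Contrast("A", "B"))
        assert np.median(fit.gene_estimates) == pytest.approx(alpha, rel=0.2)

    def test_single_replicate_arm_rejected(self):
        cm = _two_arm_matrix(np.full((3, 1), 10), np.full((3, 3), 10))
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersions(cm, Contrast("A", "B"))


class TestNbTest:
    def test_identical_arms_null_identity(self):
        counts = np.full((4, 3), 80)
        cm = _two_arm_matrix(counts, counts)
        de = nb_test(cm, Contrast("A", "B"))
        assert np.allclose(de["log2fc"], 0.0)
        assert np.allclose(de["p_value"], 1.0)

    def test_all_zero_genes_excluded_from_fdr(self):
        a = np.vstack([np.full((3, 3), 100), np.zeros((1, 3), dtype=int)])
        cm = _two_arm_matrix(a, a)
        de = nb_test(cm, Contrast("A", "B"))
        assert np.isnan(de.loc["g3", "p_value"])
        assert np.isnan(de.loc["g3", "fdr"])
        assert de.loc[["g0", "g1", "g2"], "fdr"].notna().all()

    def test_swap_contrast_flips_lfc_keeps_p(self):
        rng = np.random.default_rng(7)
        a = rng.poisson(100, (50, 3))
        b = rng.poisson(150, (50, 3))
        cm = _two_arm_matrix(a, b)
        de_ab = nb_test(cm, Contrast("A", "B"))
        de_ba = nb_test(cm, Contrast("B", "A"))
        np.testing.assert_allclose(de_ab["log2fc"], -de_ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(de_ab["p_value"], de_ba["p_value"], atol=1e-12)

    def test_strong_effect_detected_at_three_replicates(self):
        """True log2fc = 3 at mean 500, alpha = 0.05 -> p < 1e-4."""
        rng = np.random.default_rng(8)
        size = 1.0 / 0.05

        def draw(mu, shape):
            return rng.negative_binomial(size, size / (size + mu), shape)

        n_genes = 100
        a = draw(500.0, (n_genes, 3))
        b = draw(500.0, (n_genes, 3))
        a[0] = draw(500.0 * 8, (1, 3))  # one strong-effect gene
        cm = _two_arm_matrix(a, b)
        de = nb_test(cm, Contrast("A", "B"))
        assert de.loc["g0", "p_value"] < 1e-4
        assert de.loc["g0", "log2fc"] == pytest.approx(3.0, abs=0.6)

    def test_lfc_sign_matches_mean_difference(self):
        rng = np.random.default_rng(9)
        a = rng.poisson(rng.uniform(5, 500, 100)[:, None], (100, 3))
        b = rng.poisson(rng.uniform(5, 500, 100)[:, None], (100, 3))
        cm = _two_arm_matrix(a, b)
        de = nb_test(cm, Contrast("A", "B"))
        from rescueseq.quantify import size_factors

        f = size_factors(cm, total_count_fallback=True)
        norm = cm.counts / f
        m_a = norm[[c for c in norm if c.startswith("A")]].mean(axis=1)
        m_b = norm[[c for c in norm if c.startswith("B")]].mean(axis=1)
        both = (m_a > 0) & (m_b > 0) & (m_a != m_b)
        assert (np.sign(de["log2fc"][both]) == np.sign((m_a - m_b)[both])).all()

    def test_unknown_arm_errors(self, toy_counts):
        with pytest.raises(ValueError, match="arm"):
            nb_test(toy_counts, Contrast("A", "Z"))


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        assert (bh_adjust(np.ones(5)) == 1.0).all()

    def test_missing_stays_missing(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(out.iloc[1])
        assert out.iloc[0] == pytest.approx(0.02)  # m = 2 non-missing

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_step_up_oracle(self, values):
        p = np.asarray(values)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_in_rank(self, seed):
        p = np.random.default_rng(seed).uniform(size=30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,fdr,is_deg,direction",
        [
            (0.5, 0.049, True, "up"),      # boundary: |log2FC| >= 0.5 counts
            (0.49, 0.001, False, None),
            (-2.0, 0.2, False, None),
            (-0.6, 0.01, True, "down"),
            (0.5, 0.05, False, None),      # FDR strictly < 0.05
        ],
    )
    def test_threshold_boundaries(self, lfc, fdr, is_deg, direction):
        table = pd.DataFrame(
            {"log2fc": [lfc], "fdr": [fdr]}, index=pd.Index(["g"], name="gene_id")
        )
        degs = call_degs(table)
        assert ("g" in degs.index) == is_deg
        if is_deg:
            assert degs.loc["g", "direction"] == direction


class TestTypeIError:
    def test_null_simulation_calibration(self):
        """No effects, alpha = 0.1, 3 vs 3: raw p < 0.05 near nominal."""
        fracs = []
        for seed in range(3):
            cfg = SimConfig(
                n_genes=2000,
                seed=seed,
                dispersion_model=(0.1, 0.0),
                archetype_fractions={"null": 1.0},
                treatments=(),
            )
            cm, _ = simulate_counts(cfg)
            p = nb_test(cm, Contrast("ADM", "NC"))["p_value"].dropna()
            fracs.append((p < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07
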