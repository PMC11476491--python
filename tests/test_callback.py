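"""Call-back classification: tier rules, direction, intersections."""

import numpy as np
import pandas as pd
import pytest

from rescueseq.callback import (
    CallbackThresholds,
    classify_callback,
    shared_callback,
    upset_counts,
)
from conftest import random_de_table


def straight_line_oracle(lm, fm, lt, ft):
    """Independent literal transcription of the three-tier text rules."""
    if (
        not np.isnan(fm) and not np.isnan(ft)
        and abs(lm) > 0.5 and fm < 0.05
        and abs(lt) > 0.5 and ft < 0.05
        and ((lm < 0 and lt > 0) or (lm > 0 and lt < 0))
    ):
        level = 1
    elif (
        not np.isnan(fm) and not np.isnan(ft)
        and abs(lm) > 0.1 and fm < 0.05
        and abs(lt) > 0.1 and ft < 0.05
        and ((lm < 0 and lt > 0) or (lm > 0 and lt < 0))
    ):
        level = 2
    elif (
        not np.isnan(fm) and fm > 0.05
        and not np.isnan(ft) and ft < 0.05 and abs(lt) > 0.1
    ):
        level = 3
    else:
        return 0, "none"
    if level in (1, 2):
        direction = "up-called-back" if lm < 0 else "down-called-back"
    else:
        direction = "treatment-up" if lt > 0 else "treatment-down"
    return level, direction


def _tables(rows):
    idx = pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id")
    model = pd.DataFrame(
        {"log2fc": [r[0] for r in rows], "fdr": [r[1] for r in rows]}, index=idx
    )
    treat = pd.DataFrame(
        {"log2fc": [r[2] for r in rows], "fdr": [r[3] for r in rows]}, index=idx
    )
    return model, treat


class TestClassifyCallback:
    @pytest.mark.parametrize(
        "lm,fm,lt,ft,level,direction",
        [
            (-0.8, 0.001, 0.6, 0.01, 1, "up-called-back"),
            (0.3, 0.01, -0.2, 0.02, 2, "down-called-back"),
            (0.05, 0.60, 0.4, 0.001, 3, "treatment-up"),
            (-0.8, 0.001, -0.6, 0.01, 0, "none"),  # same-direction change
            (0.6, 0.01, -0.5, 0.01, 2, "down-called-back"),  # |lt|=0.5 strict
            (0.6, 0.05, -0.6, 0.01, 0, "none"),  # fdr exactly at gate
        ],
    )
    def test_tier_rules(self, lm, fm, lt, ft, level, direction):
        model, treat = _tables([(lm, fm, lt, ft)])
        out = classify_callback(model, treat)
        assert out.loc["g0", "level"] == level
        assert out.loc["g0", "direction"] == direction

    def test_untested_gene_never_reaches_level3(self):
        model, treat = _tables([(0.0, np.nan, 0.8, 0.001)])
        out = classify_callback(model, treat)
        assert out.loc["g0", "level"] == 0

    def test_asymmetric_universe_rejected(self):
        model, treat = _tables([(0.1, 0.5, 0.1, 0.5), (0.1, 0.5, 0.1, 0.5)])
        with pytest.raises(ValueError, match="g1"):
            classify_callback(model, treat.drop("g1"))

    def test_partition(self):
        rng = np.random.default_rng(10)
        model = random_de_table(rng, 500)
        treat = random_de_table(rng, 500)
        out = classify_callback(model, treat)
        assert len(out) == 500
        assert set(out["level"]).issubset({0, 1, 2, 3})
        called = out["level"].isin((1, 2))
        assert out.loc[called, "direction"].isin(
            ["up-called-back", "down-called-back"]
        ).all()
        # sign rule on called-back genes
        assert (
            np.sign(out.loc[called, "lfc_model"])
            == -np.sign(out.loc[called, "lfc_treat"])
        ).all()

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            model = random_de_table(rng, 50)
            treat = random_de_table(rng, 50)
            out = classify_callback(model, treat)
            for g in model.index:
                level, direction = straight_line_oracle(
                    model.loc[g, "log2fc"],
                    model.loc[g, "fdr"],
                    treat.loc[g, "log2fc"],
                    treat.loc[g, "fdr"],
                )
                assert out.loc[g, "level"] == level, g
                assert out.loc[g, "direction"] == direction, g

    def test_threshold_monotonicity(self):
        """Raising level2_lfc never moves a gene from none into level 2."""
        rng = np.random.default_rng(12)
        model = random_de_table(rng, 400)
        treat = random_de_table(rng, 400)
        low = classify_callback(model, treat, CallbackThresholds(level2_lfc=0.1))
        high = classify_callback(model, treat, CallbackThresholds(level2_lfc=0.3))
        was_none = low["level"] == 0
        assert not (high.loc[was_none, "level"] == 2).any()

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            CallbackThresholds(level1_lfc=0.1, level2_lfc=0.5)


class TestSharedCallback:
    @staticmethod
    def _assignment(genes_by_level_dir):
        rows = []
        for (level, direction), genes in genes_by_level_dir.items():
            for g in genes:
                rows.append((g, level, direction))
        idx = pd.Index([r[0] for r in rows], name="gene_id")
        return pd.DataFrame(
            {"level": [r[1] for r in rows], "direction": [r[2] for r in rows]},
            index=idx,
        )

    def test_set_identities(self):
        a1 = self._assignment({(1, "up-called-back"): ["a", "b", "c"]})
        a2 = self._assignment({(1, "up-called-back"): ["b", "c", "d"]})
        out = shared_callback({"T1": a1, "T2": a2}, "up-called-back")
        assert out[1]["shared"] == {"b", "c"}
        assert out[1]["T1_unique"] == {"a"}
        assert out[1]["T2_unique"] == {"d"}

    def test_identical_assignments_full_shared(self):
        a = self._assignment({(2, "down-called-back"): ["x", "y"]})
        out = shared_callback({"T1": a, "T2": a.copy()}, "down-called-back")
        assert out[2]["shared"] == {"x", "y"}
        assert out[2]["T1_unique"] == set()

    def test_level3_uses_treatment_direction(self):
        a1 = self._assignment({(3, "treatment-up"): ["p"]})
        a2 = self._assignment({(3, "treatment-up"): ["p", "q"]})
        out = shared_callback({"T1": a1, "T2": a2}, "up-called-back")
        assert out[3]["shared"] == {"p"}

    def test_unknown_direction_rejected(self):
        a = self._assignment({(1, "up-called-back"): ["a"]})
        with pytest.raises(ValueError, match="direction_class"):
            shared_callback({"T1": a, "T2": a}, "sideways")

    def test_single_treatment_rejected(self):
        a = self._assignment({(1, "up-called-back"): ["a"]})
        with pytest.raises(ValueError, match="2 treatments"):
            shared_callback({"T1": a}, "up-called-back")


class TestUpsetCounts:
    def test_two_list_example(self):
        out = upset_counts({"L1": ["a", "b"], "L2": ["b", "c"]})
        sizes = out.set_index("combination")["size"]
        assert sizes["L1"] == 1 and sizes["L2"] == 1 and sizes["L1&L2"] == 1
        assert sizes.sum() == 3  # |union|

    def test_disjoint_lists(self):
        out = upset_counts({"L1": ["a"], "L2": ["b"], "L3": ["c"]})
        sizes = out.set_index("combination")["size"]
        assert sizes["L1&L2"] == 0 and sizes["L1&L2&L3"] == 0
        assert sizes.sum() == 3

    def test_matches_membership_enumeration(self):
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(60)]
        lists = {
            name: list(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for name in ("A", "B", "C")
        }
        out = upset_counts(lists).set_index("combination")["size"]
        # brute force: classify every union member by its exact membership
        sets = {k: set(v) for k, v in lists.items()}
        brute: dict[str, int] = {}
        for g in set().union(*sets.values()):
            combo = "&".join(n for n in ("A", "B", "C") if g in sets[n])
            brute[combo] = brute.get(combo, 0) + 1
        for combo, size in out.items():
            assert size == brute.get(combo, 0)
        assert out.sum() == len(set().union(*sets.values()))
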