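import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohesion_screen.interactome import PhenotypeCounts, ValidationError
from cohesion_screen.rnai import (
    PhenotypeScreen,
    counts_from_percent,
    fisher_normal_vs_control,
    percent_table,
    screen_summary,
)
from cohesion_screen.synth import SynthScreenConfig, make_screen


class TestCountsFromPercent:
    def test_whole_percent_no_repair(self):
        rec = counts_from_percent([100, 0, 0, 0, 0], 102)
        assert rec.categories == (102, 0, 0, 0, 0)

    def test_rounding_without_residual(self):
        # 0.99*102 = 100.98 -> 101; 0.01*102 = 1.02 -> 1; sums exactly
        rec = counts_from_percent([99, 0, 1, 0, 0], 102)
        assert rec.categories == (101, 0, 1, 0, 0)
        assert rec.n == 102

    def test_strong_defect_row_sums(self):
        rec = counts_from_percent([25, 13, 11, 46, 4], 114)
        assert sum(rec.categories) == 114
        assert rec.normal in (28, 29)

    def test_residual_repaired_largest_fraction_first(self):
        # 33.(3)% of 10 is 3.33 each -> provisional (3,3,3,0,0), residual +1
        # all fractions tie at 0.33 -> first column (normal) gets the unit
        rec = counts_from_percent([33.33, 33.33, 33.33, 0, 0.01], 10)
        assert sum(rec.categories) == 10
        assert rec.normal == 4

    def test_inconsistent_percents_error(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            counts_from_percent([50, 0, 0, 0, 0], 100)

    def test_all_zero_with_positive_n_error(self):
        with pytest.raises(ValidationError):
            counts_from_percent([0, 0, 0, 0, 0], 10)

    @given(
        n=st.integers(min_value=60, max_value=200),
        weights=st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_percent_round_trip(self, n, weights):
        """A printed percent row (integer percents derived from real
        counts) regenerates itself after count reconstruction."""
        if sum(weights) == 0:
            weights[0] = 1
        counts = [n * w // sum(weights) for w in weights]
        counts[0] += n - sum(counts)
        true = PhenotypeCounts("t", *counts, n)
        printed = [int(math.floor(p + 0.5)) for p in percent_table(true)]
        rec = counts_from_percent(printed, n)
        back = [int(math.floor(p + 0.5)) for p in percent_table(rec)]
        assert back == printed


def fisher_p_brute(table) -> float:
    """Independent oracle: full hypergeometric enumeration in exact
    rational arithmetic, two-sided by summing tables with probability
    <= the observed one (with a tiny relative slack for ties)."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        return (
            Fraction(math.comb(row1, x) * math.comb(row2, col1 - x), math.comb(n, col1))
        )

    lo, hi = max(0, col1 - row2), min(col1, row1)
    p_obs = prob(a)
    cutoff = p_obs * Fraction(1 + 10**-7)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= cutoff))


class TestFisher:
    def make(self, treatment, normal, defective):
        return PhenotypeCounts(treatment, normal, defective, 0, 0, 0, normal + defective)

    def test_identical_tables_p_one(self):
        t = self.make("t1", 50, 50)
        c = self.make("control", 50, 50)
        r = fisher_normal_vs_control(t, c)
        assert r.p_two_sided == 1.0 and r.tier == "ns"

    def test_small_table_exact_value(self):
        # [[3,1],[1,3]]: support C(8,4)=70 tables; two-sided p = 34/70
        r = fisher_normal_vs_control(self.make("t1", 3, 1), self.make("control", 1, 3))
        assert r.p_two_sided == pytest.approx(34 / 70, abs=1e-12)

    def test_invariant_to_group_and_outcome_swap(self):
        t, c = self.make("t1", 12, 7), self.make("control", 20, 2)
        p = fisher_normal_vs_control(t, c).p_two_sided
        p_swap_groups = fisher_normal_vs_control(
            self.make("t1", 20, 2), self.make("control", 12, 7)
        ).p_two_sided
        p_swap_outcomes = fisher_normal_vs_control(
            self.make("t1", 7, 12), self.make("control", 2, 20)
        ).p_two_sided
        assert p == pytest.approx(p_swap_groups, rel=1e-12)
        assert p == pytest.approx(p_swap_outcomes, rel=1e-12)

    def test_unscored_treatment_rejected(self):
        un = PhenotypeCounts("prp-8", None, None, None, None, None, None)
        with pytest.raises(ValidationError):
            fisher_normal_vs_control(un, self.make("control", 10, 0))

    def test_exhaustive_oracle_small_tables(self):
        """All 2x2 tables with positive margins and total <= 16."""
        for total in range(2, 17):
            for a, b, c in itertools.product(range(total + 1), repeat=3):
                d = total - a - b - c
                if d < 0 or a + b == 0 or c + d == 0:
                    continue
                r = fisher_normal_vs_control(
                    self.make("t1", a, b), self.make("control", c, d)
                )
                assert r.p_two_sided == pytest.approx(
                    fisher_p_brute(((a, b), (c, d))), abs=1e-9
                ), ((a, b), (c, d))

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_random_tables_up_to_40(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            total = int(rng.integers(4, 41))
            a = int(rng.integers(0, total + 1))
            b = int(rng.integers(0, total - a + 1))
            c = int(rng.integers(0, total - a - b + 1))
            d = total - a - b - c
            if a + b == 0 or c + d == 0:
                continue
            r = fisher_normal_vs_control(self.make("t1", a, b), self.make("control", c, d))
            assert r.p_two_sided == pytest.approx(
                fisher_p_brute(((a, b), (c, d))), abs=1e-9
            )

    def test_tier_thresholds(self):
        strong = fisher_normal_vs_control(self.make("t1", 10, 90), self.make("control", 99, 1))
        assert strong.tier == "four_star" and strong.p_two_sided < 0.0005
        none = fisher_normal_vs_control(self.make("t1", 50, 50), self.make("control", 52, 48))
        assert none.tier == "ns"


class TestScreen:
    def test_all_identical_no_significance(self):
        ctrl = PhenotypeCounts("control", 95, 1, 2, 1, 1, 100)
        treatments = [
            PhenotypeCounts(f"t{i}", 95, 1, 2, 1, 1, 100) for i in range(5)
        ]
        res = screen_summary([ctrl, *treatments])
        assert res.n_significant == 0

    def test_id_collision_errors(self):
        ctrl = PhenotypeCounts("control", 10, 0, 0, 0, 0, 10)
        t = PhenotypeCounts("t1", 10, 0, 0, 0, 0, 10)
        with pytest.raises(ValidationError, match="collision"):
            PhenotypeScreen([ctrl, t, t])

    def test_unscored_excluded_not_counted(self):
        ctrl = PhenotypeCounts("control", 99, 0, 1, 0, 0, 100)
        hit = PhenotypeCounts("hit", 40, 10, 10, 30, 10, 100)
        un = PhenotypeCounts("prp-8", None, None, None, None, None, None)
        res = screen_summary([ctrl, hit, un], interactor_ids={"hit", "prp-8"})
        assert res.n_significant == 1
        assert res.unscored == ["prp-8"]
        assert res.total_screened == 2

    def test_power_recovers_planted_hits(self):
        """Halving the normal-probability at n=100 is a large effect; the
        screen should recover exactly the planted hits nearly always."""
        k = 4
        recovered = 0
        for seed in range(200):
            cfg = SynthScreenConfig(
                hit_probs=(0.495, 0.2, 0.2, 0.1, 0.005),  # normal prob halved
                n_treatments=12,
                n_hits=k,
                animals_per_treatment=100,
                rng_seed=seed,
            )
            screen = make_screen(cfg)
            res = screen_summary(screen.records)
            called = {t for t, r in res.results.items() if r.significant}
            if called == screen.hit_treatments:
                recovered += 1
        assert recovered >= 180  # >= 90% of simulations

    def test_summary_and_frame(self):
        ctrl = PhenotypeCounts("control", 99, 0, 1, 0, 0, 100)
        hit = PhenotypeCounts("hit", 40, 10, 10, 30, 10, 100)
        res = screen_summary([ctrl, hit])
        df = res.to_frame()
        assert set(df.columns) >= {"treatment", "p_two_sided", "tier", "q_bh"}
        assert "Fisher" in res.summary()
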