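"""Poisson-Gamma posterior inference, p-values, BH correction, driver calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmburden.catalog import ProteinInfo, PTMSite, build_partition
from ptmburden.model import (
    GammaPosterior,
    GammaPrior,
    MCSettings,
    ProteinTestResult,
    bh_adjust,
    call_drivers,
    p_value_exact,
    p_value_mc,
    posterior_update,
    test_protein as run_protein_test,
)
from ptmburden.mutations import CountVector

PHOS = "Phosphorylation"


def bh_step_up(p):
    """Independent textbook BH: q_(i) = min_{j>=i} p_(j) * m / j, clipped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "prior, counts, expected",
        [
            ((1, 1), [2, 0, 1], (4, 4)),
            ((0.001, 0.001), [0] * 10, (0.001, 10.001)),
            ((2, 3), [5], (7, 4)),
        ],
    )
    def test_conjugate_closed_form(self, prior, counts, expected):
        post = posterior_update(GammaPrior(*prior), counts)
        assert post.shape == pytest.approx(expected[0])
        assert post.rate == pytest.approx(expected[1])

    def test_empty_counts_untestable(self):
        with pytest.raises(ValueError, match="untestable"):
            posterior_update(GammaPrior(), [])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            posterior_update(GammaPrior(), [1, -1])

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            GammaPrior(shape=0.0)
        with pytest.raises(ValueError):
            GammaPrior(rate=-1.0)


class TestExactPValue:
    def test_symmetric_posteriors_give_half(self):
        post = GammaPosterior(1, 1)
        assert p_value_exact(post, post) == pytest.approx(0.5)
        post = GammaPosterior(4, 4)
        assert p_value_exact(post, post) == pytest.approx(0.5)

    def test_beta_2_1_closed_form(self):
        # P(lambda1 <= lambda2) = CDF of Beta(2,1) at 1/2 = (1/2)^2
        assert p_value_exact(GammaPosterior(2, 1), GammaPosterior(1, 1)) == pytest.approx(0.25)

    def test_strong_enrichment_vanishing_p(self):
        assert p_value_exact(GammaPosterior(50, 1), GammaPosterior(1, 1)) < 1e-6

    def test_brute_force_sampling_oracle(self):
        """Exact incomplete-beta value agrees with naive paired Gamma sampling."""
        rng = np.random.default_rng(42)
        n = 200_000
        for (a1, b1), (a2, b2) in [((3, 2), (2, 5)), ((1.5, 0.7), (4, 1.2))]:
            lam1 = rng.gamma(a1, 1 / b1, n)
            lam2 = rng.gamma(a2, 1 / b2, n)
            brute = np.mean(lam1 <= lam2)
            exact = p_value_exact(GammaPosterior(a1, b1), GammaPosterior(a2, b2))
            se = np.sqrt(exact * (1 - exact) / n)
            assert abs(brute - exact) <= 4 * se


class TestMCPValue:
    def test_symmetry_within_mc_error(self):
        post = GammaPosterior(4, 4)
        p = p_value_mc(post, post, iterations=20_000, burn_in=0, seed=7)
        assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / 20_000)

    def test_against_exact_oracle(self):
        p = p_value_mc(
            GammaPosterior(2, 1), GammaPosterior(1, 1), iterations=20_000, burn_in=0, seed=3
        )
        se = np.sqrt(0.25 * 0.75 / 20_000)
        assert abs(p - 0.25) <= 3 * se

    def test_overwhelming_enrichment(self):
        p = p_value_mc(
            GammaPosterior(50, 1), GammaPosterior(1, 1), iterations=50_000, burn_in=0, seed=1
        )
        assert p < 1e-3  # exact value < 1e-6; MC floor is 1/draws

    def test_reproducible_for_fixed_seed(self):
        args = (GammaPosterior(3, 2), GammaPosterior(2, 5))
        assert p_value_mc(*args, seed=11) == p_value_mc(*args, seed=11)

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            p_value_mc(GammaPosterior(1, 1), GammaPosterior(1, 1), iterations=10, burn_in=10)

    @settings(deadline=None, max_examples=20)
    @given(
        a1=st.floats(0.5, 30),
        b1=st.floats(0.5, 10),
        a2=st.floats(0.5, 30),
        b2=st.floats(0.5, 10),
        seed=st.integers(0, 2**20),
    )
    def test_mc_tracks_exact_over_random_posteriors(self, a1, b1, a2, b2, seed):
        post1, post2 = GammaPosterior(a1, b1), GammaPosterior(a2, b2)
        exact = p_value_exact(post1, post2)
        draws = 50_000
        mc = p_value_mc(post1, post2, iterations=draws, burn_in=0, seed=seed)
        se = max(np.sqrt(exact * (1 - exact) / draws), 1 / draws)
        assert abs(mc - exact) <= 4 * se


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_test_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_boundary_preservation(self):
        assert bh_adjust([0.0, 1.0]) == pytest.approx([0.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_textbook_step_up_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_step_up(p).tolist())


def make_counts(n=100, site=30, mod_positions_counts=None, bg_positions_counts=None):
    part = build_partition(ProteinInfo("P1", n), [PTMSite("P1", site, PHOS)], window=7)
    mod = [0] * part.k
    bg = [0] * (part.n - part.k)
    for i, c in (mod_positions_counts or {}).items():
        mod[i] = c
    for i, c in (bg_positions_counts or {}).items():
        bg[i] = c
    return part, CountVector(part, tuple(mod), tuple(bg))


class TestProteinLevelTest:
    def test_depletion_gives_large_p(self):
        part, cv = make_counts(bg_positions_counts={i: 1 for i in range(10)})
        res = run_protein_test(part, cv, mc_settings=MCSettings(seed=0))
        assert res.p_value > 0.5

    def test_enrichment_gives_small_p(self):
        part, cv = make_counts(mod_positions_counts={i: 1 for i in range(10)})
        res = run_protein_test(part, cv, mc_settings=MCSettings(seed=0))
        assert res.p_value < 0.01

    def test_symmetric_counts_near_half(self):
        # equal-size regions with identical counts: exchangeable rates
        part = build_partition(ProteinInfo("P1", 30), [PTMSite("P1", 8, PHOS)], window=7)
        assert part.k == 15 and part.n - part.k == 15
        cv = CountVector(part, tuple([1] * 15), tuple([1] * 15))
        res = run_protein_test(part, cv)
        assert res.p_value == pytest.approx(0.5, abs=1e-9)

    def test_no_background_untestable(self):
        part = build_partition(ProteinInfo("P1", 15), [PTMSite("P1", 8, PHOS)], window=7)
        cv = CountVector(part, tuple([0] * 15), ())
        with pytest.raises(ValueError, match="no background"):
            run_protein_test(part, cv)

    def test_result_carries_totals_and_r_estimate(self):
        part, cv = make_counts(mod_positions_counts={0: 3}, bg_positions_counts={0: 1})
        res = run_protein_test(part, cv, mc_settings=MCSettings(seed=5))
        assert res.mod_total == 3 and res.bg_total == 1
        assert res.posterior_R_mean > 1

    def test_prior_washout_with_dense_counts(self):
        """With >= 100 total counts the default and unit priors agree closely."""
        rng = np.random.default_rng(8)
        part = build_partition(ProteinInfo("P1", 200), [PTMSite("P1", 50, PHOS)], window=7)
        mod = tuple(int(c) for c in rng.poisson(2.0, part.k))
        bg = tuple(int(c) for c in rng.poisson(1.0, part.n - part.k))
        cv = CountVector(part, mod, bg)
        p_default = run_protein_test(part, cv).p_value
        p_unit = run_protein_test(
            part, cv, prior_mod=GammaPrior(1, 1), prior_bg=GammaPrior(1, 1)
        ).p_value
        assert abs(p_default - p_unit) < 0.01


class TestCallDrivers:
    def mk(self, acc, p):
        return ProteinTestResult(acc, PHOS, 15, 100, 1, 1, 1.0, p)

    def test_single_protein_identity(self):
        (res,) = call_drivers([self.mk("P1", 0.01)])
        assert res.q_value == pytest.approx(0.01) and res.is_driver

    def test_two_protein_bh_by_hand(self):
        out = call_drivers([self.mk("P1", 0.03), self.mk("P2", 0.9)])
        assert [r.q_value for r in out] == pytest.approx([0.06, 0.9])
        assert not any(r.is_driver for r in out)

    def test_threshold_one_flags_everything(self):
        out = call_drivers([self.mk("P1", 0.4), self.mk("P2", 0.99)], q_threshold=1.0)
        assert all(r.is_driver for r in out)

    def test_sorted_by_q_then_p_then_accession(self):
        out = call_drivers([self.mk("B", 0.02), self.mk("A", 0.02), self.mk("C", 0.001)])
        assert [r.accession for r in out] == ["C", "A", "B"]

    def test_empty_input(self):
        assert call_drivers([]) == []
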