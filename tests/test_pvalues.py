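"""P-value tests: worked orderings, exact tail identities, validity."""

import numpy as np
import pytest
from scipy.stats import binom

from simon2stage import (
    TrialOutcome,
    conditional_pvalue,
    design_operating_chars,
    koyama_chen_pvalue,
    mle_order_pvalue,
    naive_pvalue,
    outcome_distribution,
    outcome_pmf,
    outcome_space,
    stagewise_pvalue,
    umvue,
)
from simon2stage.pvalues import conditional_pmf, pvalues_all

from conftest import DESIGN_SCENARIOS


def _stage2(x1, x2, n2p):
    return TrialOutcome(m=2, x1=x1, x2=x2, n2_actual=n2p)


class TestNaive:
    def test_all_zero_early_stop(self):
        assert naive_pvalue(TrialOutcome(m=1, x1=0), 21, 20, 0.05) == 1.0

    @pytest.mark.parametrize("s", [3, 10, 25])
    def test_continuation_is_pooled_binomial_tail(self, s):
        # summing over all x1 from 0 reconstitutes the Bin(n1+n2', pi0) tail
        x1 = min(21, max(2, s - 18))
        o = _stage2(x1, s - x1, 18)
        assert naive_pvalue(o, 21, 18, 0.05) == pytest.approx(
            float(binom.sf(s - 1, 39, 0.05)), abs=1e-12
        )

    def test_not_smaller_than_stagewise(self, optimal_mid):
        d = optimal_mid
        for s in range(9, 40, 5):
            o = _stage2(9, s - 9, 39)
            assert naive_pvalue(o, 24, 39, 0.3) >= stagewise_pvalue(o, 24, 8, 39, 0.3) - 1e-12


class TestMleOrdering:
    def test_most_extreme_outcome(self, toy):
        o = _stage2(2, 2, 2)
        assert mle_order_pvalue(o, 2, 0, 2, 0.5) == pytest.approx(
            outcome_pmf(2, 0, 2, 2, 4, 0.5), abs=1e-12
        )

    def test_worked_ordering_disagreement(self, optimal_mid):
        """18/63 after continuing vs 7/24 after stopping: the MLE ordering
        ranks the early stop as more extreme, the stage-wise ordering does
        not."""
        cont = _stage2(9, 9, 39)
        stop = TrialOutcome(m=1, x1=7)
        pm_cont = mle_order_pvalue(cont, 24, 8, 39, 0.3)
        pm_stop = mle_order_pvalue(stop, 24, 8, 39, 0.3)
        # the continuation's rejection set includes the stop's mass
        assert pm_cont >= outcome_pmf(24, 8, 39, 1, 7, 0.3)
        # stage-wise ordering reverses the comparison
        assert stagewise_pvalue(cont, 24, 8, 39, 0.3) < stagewise_pvalue(stop, 24, 8, 39, 0.3)

    def test_equals_bruteforce_sum(self, optimal_small):
        n1, r1, n2p, pi0 = 21, 1, 20, 0.05
        space, probs = outcome_distribution(n1, r1, n2p, pi0)
        for m, s in [(1, 1), (2, 5), (2, 12)]:
            obs = s / n1 if m == 1 else s / (n1 + n2p)
            expected = sum(
                p
                for (mm, ss), p in zip(space, probs)
                if (ss / n1 if mm == 1 else ss / (n1 + n2p)) >= obs - 1e-12
            )
            o = TrialOutcome(m=1, x1=s) if m == 1 else _stage2(2, s - 2, n2p)
            assert mle_order_pvalue(o, n1, r1, n2p, pi0) == pytest.approx(expected, abs=1e-12)


class TestStagewise:
    def test_equals_umvue_ordering_sum(self, optimal_small):
        """Eq-10-style ordering sum and the closed-form tail agree."""
        n1, r1, n2p, pi0 = 21, 1, 18, 0.05
        space, probs = outcome_distribution(n1, r1, n2p, pi0)
        uvals = {}
        for m, s in space:
            if m == 1:
                uvals[(m, s)] = umvue(TrialOutcome(m=1, x1=s), n1, r1, n2p)
            else:
                x1 = min(max(r1 + 1, s - n2p), n1)
                uvals[(m, s)] = umvue(_stage2(x1, s - x1, n2p), n1, r1, n2p)
        for m, s in space:
            if m == 1:
                expected = 1.0 - sum(
                    p for o, p in zip(space, probs) if uvals[o] < uvals[(m, s)] - 1e-12
                )
                o = TrialOutcome(m=1, x1=s)
            else:
                expected = sum(
                    p for o, p in zip(space, probs) if uvals[o] >= uvals[(m, s)] - 1e-12
                )
                x1 = min(max(r1 + 1, s - n2p), n1)
                o = _stage2(x1, s - x1, n2p)
            assert stagewise_pvalue(o, n1, r1, n2p, pi0) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("design,pi0,pi1", DESIGN_SCENARIOS)
    def test_rejects_exactly_when_design_rejects(self, design, pi0, pi1):
        n1, r1, n2, rt = design.n1, design.r1, design.n2, design.rt
        for m, s in outcome_space(n1, r1, n2):
            o = TrialOutcome(m=1, x1=s) if m == 1 else _stage2(
                min(max(r1 + 1, s - n2), n1), s - min(max(r1 + 1, s - n2), n1), n2
            )
            p = stagewise_pvalue(o, n1, r1, n2, pi0)
            assert (p <= 0.05) == (m == 2 and s > rt), (m, s, p)

    @pytest.mark.parametrize("design,pi0,pi1", DESIGN_SCENARIOS)
    def test_stochastic_ordering_of_tails(self, design, pi0, pi1):
        """Pr_pi(outcome >= fixed) is nondecreasing in pi for every outcome."""
        n1, r1, n2 = design.n1, design.r1, design.n2
        grid = np.arange(0.05, 1.0, 0.05)
        for m, s in list(outcome_space(n1, r1, n2))[::7]:
            o = TrialOutcome(m=1, x1=s) if m == 1 else _stage2(
                min(max(r1 + 1, s - n2), n1), s - min(max(r1 + 1, s - n2), n1), n2
            )
            tails = [stagewise_pvalue(o, n1, r1, n2, float(pi)) for pi in grid]
            assert all(b >= a - 1e-12 for a, b in zip(tails, tails[1:]))


class TestConditional:
    def test_minimal_continuation_covers_whole_support(self, optimal_small):
        assert conditional_pvalue(_stage2(2, 0, 20), 21, 1, 20, 0.05) == pytest.approx(1.0)

    def test_conditional_pmf_normalized(self, minimax_mid):
        _, probs = conditional_pmf(29, 12, 23, 0.4)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_not_smaller_than_stagewise(self, optimal_small):
        for s in range(3, 40, 4):
            x1 = min(max(2, s - 20), 21)
            o = _stage2(x1, s - x1, 20)
            assert conditional_pvalue(o, 21, 1, 20, 0.05) >= stagewise_pvalue(
                o, 21, 1, 20, 0.05
            ) - 1e-12


class TestKoyamaChen:
    @pytest.mark.parametrize("design,pi0,pi1", DESIGN_SCENARIOS)
    def test_planned_size_equals_stagewise(self, design, pi0, pi1):
        n1, r1, n2 = design.n1, design.r1, design.n2
        for x1 in range(r1 + 1, n1 + 1, 4):
            for x2 in range(0, n2 + 1, 5):
                o = _stage2(x1, x2, n2)
                assert koyama_chen_pvalue(x1, x2, design, n2, pi0) == pytest.approx(
                    stagewise_pvalue(o, n1, r1, n2, pi0), abs=1e-12
                )

    def test_zero_stage2_responses_limit(self, optimal_small):
        d = optimal_small
        assert koyama_chen_pvalue(3, 0, d, 18, 0.05) == pytest.approx(
            float(binom.sf(1, 21, 0.05)), abs=1e-12
        )

    def test_monotone_in_stage2_responses(self, optimal_small):
        d = optimal_small
        for x1 in (2, 3, 4):
            vals = [koyama_chen_pvalue(x1, x2, d, 18, 0.05) for x2 in range(19)]
            assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_interim_rejection_is_maximal_evidence(self, optimal_small):
        d = optimal_small
        assert koyama_chen_pvalue(7, 3, d, 18, 0.05) == pytest.approx(
            float(binom.sf(d.rt, d.n1, 0.05)), abs=1e-12
        )


class TestValidity:
    @pytest.mark.parametrize("design,pi0,pi1", DESIGN_SCENARIOS)
    def test_exact_pvalues_are_superuniform(self, design, pi0, pi1):
        """Pr_pi0(p <= u) <= u for the stage-wise and conditional p-values."""
        n1, r1, n2 = design.n1, design.r1, design.n2
        space, probs = outcome_distribution(n1, r1, n2, pi0)
        denom = sum(p for (m, _), p in zip(space, probs) if m == 2)
        ps, pc, w, is2 = [], [], [], []
        for (m, s), p in zip(space, probs):
            o = TrialOutcome(m=1, x1=s) if m == 1 else _stage2(
                min(max(r1 + 1, s - n2), n1), s - min(max(r1 + 1, s - n2), n1), n2
            )
            ps.append(stagewise_pvalue(o, n1, r1, n2, pi0))
            pc.append(conditional_pvalue(o, n1, r1, n2, pi0))
            w.append(p)
            is2.append(m == 2)
        ps, pc, w, is2 = map(np.array, (ps, pc, w, is2))
        for u in np.arange(0.01, 1.0, 0.07):
            assert w[ps <= u].sum() <= u + 1e-12
            assert w[is2 & (pc <= u)].sum() / denom <= u + 1e-12

    def test_all_pvalues_in_unit_interval(self, optimal_small):
        d = optimal_small
        for o in (TrialOutcome(m=1, x1=0), _stage2(2, 0, 18), _stage2(21, 18, 18)):
            for name, v in pvalues_all(o, d, 0.05, 18).as_dict().items():
                assert 0.0 <= v <= 1.0, name

    def test_early_stop_tail_shared_by_exact_methods(self, optimal_small):
        o = TrialOutcome(m=1, x1=1)
        pv = pvalues_all(o, optimal_small, 0.05)
        expected = float(binom.sf(0, 21, 0.05))
        assert pv.stagewise == pytest.approx(expected)
        assert pv.conditional == pytest.approx(expected)
        assert pv.koyama_chen == pytest.approx(expected)
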