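import math

import numpy as np
import pytest

from metofs.eto import EtoParams, EtoState
from metofs.gls import ExperienceBuffer, GlsParams
from metofs.meto import (
    MetoParams,
    SelectionState,
    hybrid_update,
    meto_run,
    meto_step,
    selection_probabilities,
    selection_threshold,
)
from metofs.optim_core import (
    Population,
    SearchSpace,
    StubRng,
    evaluate_and_update_best,
)
from metofs.eto import eto_run


def _no_gls(n=20, tmax=10_000):
    # experience cap the run can never exceed: guidance gate stays closed
    return GlsParams(cmax=n * (tmax + 2))


class TestSelection:
    def test_shares_normalize(self):
        p = selection_probabilities(np.array([0.2, 0.3, 0.5]))
        assert np.allclose(p, [0.2, 0.3, 0.5])
        p = selection_probabilities(np.array([2.0, 3.0, 5.0]))
        assert p.sum() == pytest.approx(1.0)

    def test_equal_fitness_gives_uniform(self):
        p = selection_probabilities(np.full(4, 0.25))
        assert np.allclose(p, 0.25)

    def test_zero_sum_fallback(self):
        p = selection_probabilities(np.zeros(5))
        assert np.allclose(p, 0.2)

    def test_threshold_interpolates_between_extreme_shares(self):
        p = np.array([0.2, 0.3, 0.5])
        assert selection_threshold(p, StubRng([0.0])) == pytest.approx(0.2)
        assert selection_threshold(p, StubRng([1.0])) == pytest.approx(0.5)
        assert selection_threshold(p, StubRng([0.5])) == pytest.approx(0.35)


class TestHybridUpdate:
    def _setup(self, sphere):
        space = SearchSpace.unit(2)
        pop = Population(x=np.array([[0.2, 0.7], [0.9, 0.1], [0.5, 0.5]]))
        evaluate_and_update_best(pop, sphere)
        params = MetoParams(eto=EtoParams(tmax=100), gls=_no_gls(3))
        state = EtoState.initial(params.eto, space)
        state.cm = 0.5  # phase-2 rules
        return space, pop, params, state

    def test_rp_below_all_shares_reduces_to_pure_eto(self, sphere):
        """rp forced below every P_i: the hybrid row loop consumes the same
        draws and produces the same rows as the ETO-only update."""
        space, pop, params, state = self._setup(sphere)
        sel = SelectionState(p=selection_probabilities(pop.fit), lp=0, up=0, rp=-1.0)
        draws = [0.6, 0.3] + [0.4, 0.5, 0.2, 0.8, 0.9, 0.1, 0.3, 0.6, 0.7]
        xa, counts_a = hybrid_update(pop, state, sel, params, "explore", 0.5,
                                     StubRng(draws))
        params.injection = "eto-only"
        xb, counts_b = hybrid_update(pop, state, None, params, "explore", 0.5,
                                     StubRng(draws))
        assert np.array_equal(xa, xb)
        assert counts_a == {"aoa": 0, "eto": 3} == counts_b

    def test_rp_above_all_shares_forces_aoa(self, sphere):
        space, pop, params, state = self._setup(sphere)
        sel = SelectionState(p=selection_probabilities(pop.fit), lp=0, up=0, rp=2.0)
        draws = [0.6, 0.3] + [0.4, 0.5, 0.2, 0.8, 0.9, 0.1]
        x, counts = hybrid_update(pop, state, sel, params, "exploit", 0.5,
                                  StubRng(draws))
        assert counts == {"aoa": 3, "eto": 0}
        # every row is Xb -/+ MOP((UB-LB) mu + LB) elementwise around the best
        step = 0.5 * (1.0 * 0.5 + 0.0)
        signs = np.where(np.array([[0.4, 0.5], [0.2, 0.8], [0.9, 0.1]]) < 0.5, -1, 1)
        assert np.allclose(x, pop.xb + signs * step)

    def test_mixed_branches_sum_to_population(self, sphere):
        space, pop, params, state = self._setup(sphere)
        p = selection_probabilities(pop.fit)  # 0.53/1.85, 0.82/1.85, 0.50/1.85
        rp = float(np.median(p))
        sel = SelectionState(p=p, lp=p.min(), up=p.max(), rp=rp)
        x, counts = hybrid_update(pop, state, sel, params, "explore", 0.5,
                                  StubRng([0.5] * 30))
        assert counts["aoa"] + counts["eto"] == pop.n
        assert counts["aoa"] == int((p < rp).sum())


class TestRun:
    def test_reproducible_and_monotone(self, sphere):
        space = SearchSpace.unit(8)
        r1 = meto_run(space, sphere, n=12, tmax=60, rng=9)
        r2 = meto_run(space, sphere, n=12, tmax=60, rng=9)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.all(np.diff(r1.trace) <= 0)

    def test_branch_counts_sum_to_population_each_iteration(self, sphere):
        space = SearchSpace.unit(5)
        res = meto_run(space, sphere, n=10, tmax=40, rng=3)
        totals = np.array(res.history["aoa"]) + np.array(res.history["eto"])
        assert np.all(totals == 10)

    def test_guidance_only_fires_on_period_multiples(self, sphere):
        space = SearchSpace.unit(5)
        params = MetoParams(gls=GlsParams(cmax=10))  # cap = N: fires at each gate
        res = meto_run(space, sphere, n=10, tmax=40, rng=3, params=params)
        events = np.flatnonzero(res.history["gls_event"]) + 1  # iterations
        assert len(events) > 0
        assert np.all(events % 10 == 0)

    def test_degenerate_hybrid_is_bitwise_eto(self, sphere):
        """AOA branch disabled: METO and ETO produce identical runs."""
        space = SearchSpace.unit(6)
        params = MetoParams(injection="eto-only", gls=_no_gls(15, 50))
        a = meto_run(space, sphere, n=15, tmax=50, rng=21, params=params)
        b = eto_run(space, sphere, n=15, tmax=50, rng=21)
        assert np.array_equal(a.trace, b.trace)
        assert np.array_equal(a.xb, b.xb)

    def test_forced_aoa_mode_never_takes_eto_branch(self, sphere):
        space = SearchSpace.unit(6)
        params = MetoParams(injection="aoa-only", gls=_no_gls(10, 30))
        res = meto_run(space, sphere, n=10, tmax=30, rng=2, params=params)
        assert sum(res.history["eto"]) == 0
        assert sum(res.history["aoa"]) == 10 * 30


class TestStepOracle:
    def test_two_iterations_match_straight_line_oracle(self, sphere):
        """Two full hybrid iterations on a 4 x 3 population with an injected
        draw sequence, against independent scalar arithmetic."""
        space = SearchSpace.unit(3)
        x0 = np.array([
            [0.1, 0.2, 0.3],
            [0.9, 0.8, 0.7],
            [0.5, 0.5, 0.5],
            [0.2, 0.9, 0.4],
        ])
        pop = Population(x=x0.copy())
        evaluate_and_update_best(pop, sphere)
        params = MetoParams(eto=EtoParams(tmax=100), gls=_no_gls(4, 100))
        state = EtoState.initial(params.eto, space)
        buffer = ExperienceBuffer()

        # iteration 1 (t=1, explore, cm = 13.02*0.5 > 1 -> alpha1 rule):
        draws_t1 = [
            0.5,            # cm
            0.4,            # rp
            0.7,            # alpha1
            0.3, 0.6, 0.1,  # row0 (AOA explore: r2 per dim)
            0.4, 0.2, 0.8, 0.5,  # row1 (ETO phase1: q1 + u per dim)
            0.9, 0.2, 0.5,  # row2 (AOA)
            0.8, 0.1, 0.3, 0.9,  # row3 (ETO)
        ]
        # iteration 2 (t=2, explore, cm = 0.005*(0.02)^tan(-1) * u):
        draws_t2 = [
            1e-5,           # cm -> far below 1: alpha2 rule
            0.2,            # rp
            0.6, 0.3,       # alpha2 (two draws)
            0.5, 0.5, 0.5,  # row draws, roles depend on shares (below)
            0.5, 0.5, 0.5, 0.5,
            0.5, 0.5, 0.5, 0.5,
            0.5, 0.5, 0.5, 0.5,
        ]
        stub = StubRng(draws_t1 + draws_t2)
        pop, state, buffer, _ = meto_step(pop, state, buffer, params, space, sphere, stub)

        # ---------- oracle, iteration 1 ----------
        fit0 = [0.14, 1.94, 0.75, 1.01]
        total = sum(fit0)
        p = [f / total for f in fit0]
        rp = min(p) + 0.4 * (max(p) - min(p))
        assert [pi < rp for pi in p] == [True, False, True, False]
        cm = 0.01 * 0.5 * (0.01) ** math.tan(-1.0)
        assert cm > 1.0
        alpha1 = 3 * 0.7 * (0.01 - 0.85) * math.exp(-1.0 - 1.0)
        mop = 1.0 - (1.0 / 100.0) ** 0.2
        eps = 1e-12
        xb = [0.1, 0.2, 0.3]
        exp_rows = []
        # row0: AOA explore, r2 = (0.3, 0.6, 0.1)
        exp_rows.append([
            xb[0] / (mop + eps), xb[1] * mop, xb[2] / (mop + eps),
        ])
        # row1: ETO phase1, q1 = 0.4 <= 0.5 (+), u = (0.2, 0.8, 0.5)
        exp_rows.append([
            xb[j] + u * alpha1 * abs(xb[j] - x0[1][j])
            for j, u in enumerate((0.2, 0.8, 0.5))
        ])
        # row2: AOA explore, r2 = (0.9, 0.2, 0.5)
        exp_rows.append([xb[0] * mop, xb[1] / (mop + eps), xb[2] * mop])
        # row3: ETO phase1, q1 = 0.8 > 0.5 (-), u = (0.1, 0.3, 0.9)
        exp_rows.append([
            xb[j] - u * alpha1 * abs(xb[j] - x0[3][j])
            for j, u in enumerate((0.1, 0.3, 0.9))
        ])
        exp_rows = [[min(max(v, 0.0), 1.0) for v in row] for row in exp_rows]
        assert np.max(np.abs(pop.x - np.array(exp_rows))) < 1e-12
        fits1 = [sum(v * v for v in row) for row in exp_rows]
        fitb1 = min(0.14, min(fits1))
        assert abs(pop.fitb - fitb1) < 1e-12
        assert buffer.c == 4  # experience recorded, no guidance at t=1

        # ---------- iteration 2 ----------
        pop, state, buffer, _ = meto_step(pop, state, buffer, params, space, sphere, stub)
        p2 = [f / sum(fits1) for f in fits1]
        rp2 = min(p2) + 0.2 * (max(p2) - min(p2))
        cm2 = 0.01 * 1e-5 * (0.02) ** math.tan(-1.0)
        assert cm2 < 1.0
        alpha2 = 0.6 * math.exp(math.tanh(1.5 * (-2 / 100 - 0.75) - 0.3))
        xb1_idx = int(np.argmin(fits1)) if min(fits1) < 0.14 else 0
        xb2 = exp_rows[xb1_idx] if min(fits1) < 0.14 else [0.1, 0.2, 0.3]
        draws_iter = iter([0.5] * 19)
        exp2 = []
        for i in range(4):
            if p2[i] < rp2:  # AOA explore row: 3 draws (r2 per dim)
                row = []
                for j in range(3):
                    r2 = next(draws_iter)
                    row.append(xb2[j] / (mop2(eps) + eps) if r2 < 0.5
                               else xb2[j] * mop2(eps))
                exp2.append(row)
            else:  # ETO phase-2 explore: q2 + u per dim
                q2 = next(draws_iter)
                row = []
                for j in range(3):
                    u = next(draws_iter)
                    step = 3.0 * u * alpha2 * abs(xb2[j] - exp_rows[i][j])
                    row.append(exp_rows[i][j] + step if q2 <= 0.5
                               else exp_rows[i][j] - step)
                exp2.append(row)
        exp2 = [[min(max(v, 0.0), 1.0) for v in row] for row in exp2]
        assert np.max(np.abs(pop.x - np.array(exp2))) < 1e-12


def mop2(eps):
    return 1.0 - (2.0 / 100.0) ** 0.2
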