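"""T-cell rules: recruitment, kill/exhaustion probabilities, stepping."""
import math

import numpy as np
import pytest

from spatialqsp.cytokines import Field
from spatialqsp.lattice import init_grid
from spatialqsp.registry import default_registry
from spatialqsp.synapse import SynapseParams
from spatialqsp.tcells import (
    SynapseCache,
    TcellParams,
    _VoxelIndex,
    expected_recruitment,
    kill_phase,
    prob_exhaust_pdl1,
    prob_exhaust_treg,
    prob_kill,
    recruit_at_entry_points,
    step_tcell,
)


@pytest.fixture
def tparams(reg):
    return TcellParams.from_registry(reg)


def _fields(dims, reg):
    il2 = Field("IL2", dims, reg["voxel_size"], reg["D_IL2"], reg["gamma_IL2"])
    ifng = Field("IFNg", dims, reg["voxel_size"], reg["D_IFNg"], reg["gamma_IFNg"])
    return il2, ifng


class TestProbabilities:
    def test_kill_boundary_cases(self):
        assert prob_kill(1.0, 2.0, H=0.3, q_teff=0.0) == 0.0
        assert prob_kill(1.0, 2.0, H=1.0, q_teff=1.0) == 0.0
        assert prob_kill(1e6, 2.0, H=0.0, q_teff=1.0) == pytest.approx(1.0)

    def test_kill_formula(self):
        dt, k, H, q = 0.5, 1.3, 0.4, 0.7
        expected = 1.0 - math.exp(-dt * k) ** ((1 - H) * q)
        assert prob_kill(dt, k, H, q) == pytest.approx(expected)

    def test_kill_monotone_in_H_and_q(self):
        grid = np.linspace(0, 1, 11)
        ps_h = [prob_kill(1.0, 1.0, h, 0.5) for h in grid]
        ps_q = [prob_kill(1.0, 1.0, 0.5, q) for q in grid]
        assert all(b <= a for a, b in zip(ps_h, ps_h[1:]))
        assert all(a <= b for a, b in zip(ps_q, ps_q[1:]))

    def test_exhaust_pdl1_formula(self):
        assert prob_exhaust_pdl1(1.0, 0.5, H=0.0) == 0.0
        assert prob_exhaust_pdl1(2.0, 0.5, H=1.0) == pytest.approx(1 - math.exp(-1.0))
        hs = np.linspace(0, 1, 11)
        ps = [prob_exhaust_pdl1(1.0, 0.5, h) for h in hs]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_exhaust_treg_formula_and_amplification(self):
        assert prob_exhaust_treg(1.0, 0.5, H=0.3, q_treg=0.0) == 0.0
        base = prob_exhaust_treg(1.0, 0.5, H=0.0, q_treg=1.0)
        assert base == pytest.approx(1 - math.exp(-0.5))
        amplified = prob_exhaust_treg(1.0, 0.5, H=1.0, q_treg=1.0)
        # (1 + H) doubles the exponent at H = 1
        assert 1 - amplified == pytest.approx((1 - base) ** 2)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            prob_kill(1.0, 1.0, H=1.5, q_teff=0.5)
        with pytest.raises(ValueError):
            prob_exhaust_treg(1.0, 1.0, H=0.5, q_treg=-0.1)


class TestRecruitment:
    def test_expectation_is_bilinear(self):
        n = expected_recruitment(1e8, 1e9, 1e-20)
        assert n == pytest.approx(1e-3)
        assert expected_recruitment(2e8, 1e9, 1e-20) == pytest.approx(2 * n)
        assert expected_recruitment(0.0, 1e9, 1e-20) == 0.0

    def test_warning_when_expectation_reaches_one(self, caplog):
        with caplog.at_level("WARNING"):
            expected_recruitment(1e10, 1e10, 1e-19)
        assert any("recruitment" in r.message for r in caplog.records)

    def test_zero_probability_recruits_nothing(self, rng):
        g = init_grid((5, 5, 5), seed=0)
        g.entry_points = np.array([[2, 2, 2]])
        assert recruit_at_entry_points(g, 0.0, 0.0, rng) == []

    def test_bernoulli_mean(self, rng):
        g = init_grid((25, 25, 25), seed=0)
        g.entry_points = np.column_stack([rng.integers(0, 25, 1000) for _ in range(3)])
        total = 0
        n_rep = 30
        for _ in range(n_rep):
            recruits = recruit_at_entry_points(g, 0.5, 0.0, rng)
            total += len(recruits)
            for a in recruits:
                g.remove_agent(a)
        mean = total / n_rep
        sigma = np.sqrt(1000 * 0.25 / n_rep)
        assert abs(mean - 500.0) < 3 * sigma

    def test_recruits_reported_equal_agents_placed(self, rng):
        g = init_grid((8, 8, 8), seed=0)
        g.entry_points = np.array([[1, 1, 1], [5, 5, 5], [2, 6, 3]])
        before = len(g.agents)
        recruits = recruit_at_entry_points(g, 1.0, 1.0, rng)
        assert len(g.agents) - before == len(recruits)


class TestStepping:
    def test_lone_effector_never_activates_and_dies_exponentially(self, reg, tparams, rng):
        lifetimes = []
        for seed in range(300):
            g = init_grid((6, 6, 6), seed=seed)
            il2, ifng = _fields(g.dims, reg)
            cache = SynapseCache(SynapseParams.from_registry(reg), 0.0)
            cell = g.add_agent("CD8", "effector", (3, 3, 3))
            local_rng = np.random.default_rng(seed)
            t = 0.0
            while cell.id in g.agents and t < 60.0:
                index = _VoxelIndex(g)
                step_tcell(cell, g, index, il2, ifng, tparams, cache, 0.5, local_rng)
                assert cell.state != "cytotoxic"
                t += 0.5
            lifetimes.append(t)
        mean = np.mean(lifetimes)
        sem = np.std(lifetimes, ddof=1) / np.sqrt(len(lifetimes))
        # discrete-step survival mean ~ lifespan (+half-step bias allowance)
        assert abs(mean - tparams.lifespan) < 3 * sem + 0.5

    def test_effector_activates_next_to_cancer(self, reg, tparams, rng):
        g = init_grid((5, 5, 5), seed=0)
        il2, ifng = _fields(g.dims, reg)
        cache = SynapseCache(SynapseParams.from_registry(reg), 0.0)
        g.add_agent("cancer", "csc", (2, 2, 2))
        cell = g.add_agent("CD8", "effector", (2, 2, 3))
        params = TcellParams(**{**tparams.__dict__, "lifespan": 1e9, "move_prob": 0.0})
        step_tcell(cell, g, _VoxelIndex(g), il2, ifng, params, cache, 0.5, rng)
        assert cell.state in ("cytotoxic", "exhausted")

    def test_certain_kill_frees_cancer_slot(self, reg, rng):
        g = init_grid((5, 5, 5), seed=0)
        il2, ifng = _fields(g.dims, reg)
        cache = SynapseCache(SynapseParams.from_registry(reg), 1e-6)  # H ~ 0
        target = g.add_agent("cancer", "senescent", (2, 2, 2))
        killer = g.add_agent("CD8", "cytotoxic", (2, 2, 3))
        params = TcellParams.from_registry(reg)
        kills = kill_phase(g, _VoxelIndex(g), params, cache, ifng, dt=1e6, rng=rng)
        assert kills == 1
        assert target.id not in g.agents
        assert g.cancer_id[2, 2, 2] == -1
        assert killer.id in g.agents

    def test_mean_kills_match_formula(self, reg):
        """Monte-Carlo kill counts agree with prob_kill x exposure."""
        g0 = init_grid((5, 5, 5), seed=0)
        dt = 0.5
        params = TcellParams.from_registry(reg)
        cache = SynapseCache(SynapseParams.from_registry(reg), 1e-6)
        H = cache.H(0.0)
        kills = 0
        n_rep = 2000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            g = init_grid((5, 5, 5), seed=seed)
            _, ifng = _fields(g.dims, reg)
            g.add_agent("cancer", "csc", (2, 2, 2))
            g.add_agent("CD8", "cytotoxic", (2, 2, 3))
            kills += kill_phase(g, _VoxelIndex(g), params, cache, ifng, dt, rng)
        # q_teff = 1 attacker / 1 total neighbor
        p = prob_kill(dt, params.k_C_death_by_T, H, 1.0)
        sigma = math.sqrt(n_rep * p * (1 - p))
        assert abs(kills - n_rep * p) < 3 * sigma

    def test_treg_adjacent_exhaustion_uses_moore_fraction(self, reg, rng):
        g = init_grid((5, 5, 5), seed=0)
        il2, ifng = _fields(g.dims, reg)
        cache = SynapseCache(SynapseParams.from_registry(reg), 0.0)
        # surround a CD8 with Tregs only -> q_treg = 1
        cd8 = g.add_agent("CD8", "effector", (2, 2, 2))
        for v in [(2, 2, 3), (2, 3, 2), (3, 2, 2)]:
            g.add_agent("Treg", "treg", v)
        params = TcellParams(
            **{**TcellParams.from_registry(reg).__dict__,
               "k_Teff_inhibBy_Treg": 1e6, "lifespan": 1e9, "move_prob": 0.0,
               "k_Teff_death_by_C": 0.0}
        )
        step_tcell(cd8, g, _VoxelIndex(g), il2, ifng, params, cache, 1.0, rng)
        assert cd8.state == "exhausted"
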