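"""Semi-complete likelihood: pi table, closed forms, invariances, priors."""

import math

import numpy as np
import pytest

from flankscr.encounter_data import TrapArray, ObservedEncounterData, MatchState
from flankscr.state_space import HabitatGrid
from flankscr.detection import DetectionParams, ModelSpec, p_detect, pstar
from flankscr.likelihood import (
    PriorSpec, ChainState, log_pi, log_semicomplete, log_posterior,
    record_loglik_by_cell, enumerate_match_posterior,
)


class TestLogPi:
    def test_ghost_record_contributes_nothing(self):
        assert log_pi(0, m=1, z=0, p=0.7, delta1=0.3, delta2=0.3, alpha=0.5) == 0.0

    def test_nonsimultaneous_both_flank_probability(self):
        got = log_pi(3, m=1, z=1, p=0.4, delta1=0.3, delta2=0.3, alpha=0.5)
        assert got == pytest.approx(math.log(0.4 * 0.4 * 0.5))

    def test_detection_at_dark_trap_impossible(self):
        assert log_pi(1, m=0, z=1, p=0.5, delta1=0.3, delta2=0.3, alpha=0.5) == -math.inf

    @pytest.mark.parametrize("p,d1,d2,a", [
        (0.4, 0.3, 0.3, 0.5), (0.9, 0.1, 0.2, 0.8), (0.05, 0.45, 0.45, 0.0),
    ])
    def test_normalization_over_codes(self, p, d1, d2, a):
        total = sum(math.exp(log_pi(y, 1, 1, p, d1, d2, a)) for y in range(5))
        assert total == pytest.approx(1.0)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            log_pi(7, 1, 1, 0.5, 0.3, 0.3, 0.5)


def _one_cell_setup():
    traps = TrapArray(ids=["A"], xy=[[0.0, 0.0]], elevation=[0.0],
                      operation=np.ones((1, 1), dtype=np.int8))
    grid = HabitatGrid(centroids=np.array([[0.0, 0.0]]), cell_size=1000.0,
                       h=np.ones(1, dtype=np.int8), nrow=1, ncol=1,
                       xll=-500.0, yll=-500.0)
    return traps, grid


class TestSemicomplete:
    def test_single_simultaneous_event_closed_form(self):
        traps, grid = _one_cell_setup()
        params = DetectionParams(beta=[0.0], sigma=500.0)
        model = ModelSpec("M0")
        data = ObservedEncounterData(known=[np.array([[4]], dtype=np.int8)])
        d1 = d2 = 0.25
        alpha = 0.6
        N = 5
        state = ChainState(match=MatchState(), s=np.array([0]), params=params,
                           delta1=d1, delta2=d2, alpha=alpha, psi=0.5, N=N)
        got = log_semicomplete(state, data, grid, traps, model)
        p = p_detect(np.array([1.0]), params, 0.0)
        ps = pstar(params, model, grid, traps)
        expected = (math.log(p * (1 - d1 - d2) * alpha)
                    + math.lgamma(N + 1) - math.lgamma(N)  # n = 1
                    + (N - 1) * math.log1p(-ps))
        assert got == pytest.approx(expected)

    def test_population_at_observed_size_drops_pstar_factor(self):
        traps, grid = _one_cell_setup()
        params = DetectionParams(beta=[0.0], sigma=500.0)
        data = ObservedEncounterData(known=[np.array([[4]], dtype=np.int8)])
        state = ChainState(match=MatchState(), s=np.array([0]), params=params,
                           delta1=0.25, delta2=0.25, alpha=0.6, psi=0.5, N=1)
        got = log_semicomplete(state, data, grid, traps, ModelSpec("M0"))
        p = p_detect(np.array([1.0]), params, 0.0)
        assert got == pytest.approx(math.log(p * 0.5 * 0.6) + math.lgamma(2))

    def test_record_relabeling_invariance(self, micro_instance):
        m = micro_instance
        data = m["data"]
        swapped = ObservedEncounterData(left=list(data.left), right=list(data.right))
        state = ChainState(match=MatchState(), s=np.array([0, 3]),
                           params=m["params"], delta1=0.3, delta2=0.3,
                           alpha=0.4, psi=0.5, N=4)
        a = log_semicomplete(state, data, m["grid"], m["traps"], m["model"])
        b = log_semicomplete(state, swapped, m["grid"], m["traps"], m["model"])
        assert a == pytest.approx(b)

    def test_population_below_observed_impossible(self, micro_instance):
        m = micro_instance
        state = ChainState(match=MatchState(), s=np.array([0, 3]),
                           params=m["params"], delta1=0.3, delta2=0.3,
                           alpha=0.4, psi=0.5, N=1)
        assert log_semicomplete(state, m["data"], m["grid"], m["traps"],
                                m["model"]) == -math.inf


class TestPosteriorSupport:
    def test_sigma_outside_prior_bounds(self, micro_instance):
        m = micro_instance
        params = DetectionParams(beta=[-0.5], sigma=5.0)  # below 10 m bound
        state = ChainState(match=MatchState(), s=np.array([0, 3]), params=params,
                           delta1=0.3, delta2=0.3, alpha=0.4, psi=0.5, N=3)
        assert log_posterior(state, m["data"], m["grid"], m["traps"],
                             m["model"], m["priors"]) == -math.inf

    def test_unsuitable_center_impossible(self, micro_instance):
        m = micro_instance
        grid = HabitatGrid(centroids=m["grid"].centroids.copy(), cell_size=1000.0,
                           h=np.array([1, 1, 1, 0], dtype=np.int8), nrow=2,
                           ncol=2, xll=-750.0, yll=-750.0)
        state = ChainState(match=MatchState(), s=np.array([0, 3]),
                           params=m["params"], delta1=0.3, delta2=0.3,
                           alpha=0.4, psi=0.5, N=3)
        assert log_semicomplete(state, m["data"], grid, m["traps"],
                                m["model"]) == -math.inf


class TestEnumerationOracle:
    def test_weights_normalize_and_link_raises_population_evidence(self, micro_instance):
        m = micro_instance
        res = enumerate_match_posterior(m["data"], m["grid"], m["traps"],
                                        m["model"], m["params"], 0.3, 0.3, 0.4,
                                        m["priors"])
        assert res["probs"].sum() == pytest.approx(1.0)
        assert len(res["matchings"]) == 2  # unlinked + the single link
        assert 0.0 < res["p_linked"] < 1.0

    def test_far_apart_records_rarely_link(self, micro_instance):
        """Records detected far apart (relative to sigma) should be
        attributed to distinct individuals with high probability."""
        m = micro_instance
        traps = TrapArray(ids=["A", "B"], xy=[[0.0, 0.0], [6000.0, 0.0]],
                          elevation=[0.0, 0.0],
                          operation=np.ones((2, 2), dtype=np.int8))
        cent = np.array([[-1500.0, -1500.0], [7500.0, -1500.0],
                         [-1500.0, 4500.0], [7500.0, 4500.0]])
        grid = HabitatGrid(centroids=cent, cell_size=6000.0,
                           h=np.ones(4, dtype=np.int8), nrow=2, ncol=2,
                           xll=-4500.0, yll=-4500.0)
        params = DetectionParams(beta=[-0.5], sigma=500.0)
        near = enumerate_match_posterior(m["data"], m["grid"], m["traps"],
                                         m["model"], m["params"], 0.3, 0.3, 0.4,
                                         m["priors"])["p_linked"]
        far = enumerate_match_posterior(m["data"], grid, traps, m["model"],
                                        params, 0.3, 0.3, 0.4,
                                        m["priors"])["p_linked"]
        assert far < near
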