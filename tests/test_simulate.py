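"""Individual-based sampling, contests, and reproduction."""

import io

import numpy as np
import pytest

import agonistic as ag
from conftest import make_table


class TestSamplePopulation:
    def test_recovers_the_honesty_covariance(self, runaway_G):
        n = 100_000
        males = ag.sample_population(n, ag.PopulationState(), runaway_G, seed=5)
        cov = np.cov(males.breeding[:, 0], males.breeding[:, 1])[0, 1]
        se = np.sqrt((1.0 * 1.0 + 0.8**2) / n)
        assert abs(cov - 0.8) < 3 * se

    def test_zero_variance_gives_identical_males(self):
        G = ag.GeneticArchitecture(GSS=0, GBB=0, GAA=0, GSB=0)
        state = ag.PopulationState(meanS=1.0, meanB=2.0, meanA=3.0)
        males = ag.sample_population(10, state, G, seed=0)
        assert np.allclose(males.breeding, state.means())
        assert np.allclose(males.environment, 0.0)

    def test_population_size_must_be_even(self, stable_G):
        with pytest.raises(ValueError, match="even"):
            ag.sample_population(11, ag.PopulationState(), stable_G)
        with pytest.raises(ValueError, match="even"):
            ag.sample_population(0, ag.PopulationState(), stable_G)

    def test_male_view_matches_arrays(self, stable_G):
        males = ag.sample_population(4, ag.PopulationState(), stable_G, seed=1)
        m = males[2]
        assert m.zS == pytest.approx(males.zS[2])
        assert m.zB == pytest.approx(males.zB[2])


class TestRunContests:
    def test_fixed_seed_reproduces_table_byte_for_byte(self, stable_G):
        outputs = []
        for _ in range(2):
            table, *_ = make_table(n=200, seed=42, G=stable_G)
            buf = io.StringIO()
            table.data.to_csv(buf, index=False)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_every_male_is_focal_once_and_opponent_once(self, stable_G):
        table, *_ = make_table(n=300, seed=3, G=stable_G)
        focal = np.sort(table.data["focal_zS"].to_numpy())
        opp = np.sort(table.data["opp_zS"].to_numpy())
        assert np.array_equal(focal, opp)
        assert len(table) == 300

    def test_social_aggression_contribution_averages_to_zero(self, stable_G):
        table, males, params, _ = make_table(n=1000, seed=7, G=stable_G)
        social = table.data["focal_zA"].to_numpy() - males.intrinsic_aggression
        assert social.mean() == pytest.approx(0.0, abs=1e-12)
        # hence mean expressed aggression == mean intrinsic aggression
        assert table.data["focal_zA"].mean() == pytest.approx(
            males.intrinsic_aggression.mean(), abs=1e-12
        )

    def test_relative_fitness_has_mean_one(self, stable_G):
        table, *_ = make_table(n=500, seed=9, G=stable_G)
        assert table.data["w"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_benefit_term_is_zero_sum_across_the_table(self, stable_G):
        table, *_ = make_table(n=400, seed=11, G=stable_G)
        diff = table.data["focal_zA"] - table.data["opp_zA"]
        assert diff.mean() == pytest.approx(0.0, abs=1e-12)

    def test_no_responsiveness_no_aggression_signal_slope(self, stable_G):
        p = ag.ContestParams(deltaAS=0.0)
        table, *_ = make_table(n=4000, seed=13, G=stable_G, params=p)
        fit = ag.estimate_deltaAS(table)
        assert abs(fit.estimates["deltaAS"]) < 3 * fit.se["deltaAS"]

    def test_relabelling_focal_and_opponent_changes_nothing(self, stable_G):
        """Each dyad already contributes one row per orientation, so the
        relabelled table is the same multiset of rows."""
        table, *_ = make_table(n=200, seed=15, G=stable_G)
        a = table.data[["focal_zS", "focal_zB", "focal_zA"]].to_numpy()
        b = table.data[["opp_zS", "opp_zB", "opp_zA"]].to_numpy()
        order = lambda X: X[np.lexsort(X.T)]
        assert np.allclose(order(a), order(b))

    def test_negative_mean_fitness_demands_recalibration(self, stable_G):
        state = ag.PopulationState(meanS=0.0, meanB=10.0, meanA=4.0)
        males = ag.sample_population(200, state, stable_G, seed=1)
        with pytest.raises(ValueError, match="intercept"):
            ag.run_contests(males, ag.ContestParams(), seed=1)

    def test_csv_round_trip(self, stable_G, tmp_path):
        table, *_ = make_table(n=100, seed=21, G=stable_G)
        table.metadata["generation"] = 0
        csv = tmp_path / "contests.csv"
        sidecar = tmp_path / "contests.json"
        table.to_csv(csv, sidecar=sidecar)
        back = ag.ContestTable.from_csv(csv, sidecar=sidecar)
        assert np.allclose(back.data.to_numpy(), table.data.to_numpy())
        assert back.metadata["params"]["bA"] == 0.2

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("focal_zS,focal_zB,w\n1,2,1\n")
        with pytest.raises(ValueError, match="opp_zA"):
            ag.ContestTable.from_csv(path)


class TestNextGeneration:
    def test_zero_selection_leaves_means_unchanged(self, stable_G):
        p = ag.ContestParams(bA=0, cA=0, cB=0, cS=0, deltaAS=0.4)
        state = ag.PopulationState(meanS=1.0, meanB=2.0, meanA=3.0)
        deltas = []
        for rep in range(5):
            rngs = ag.spawn_rngs(100 + rep)
            males = ag.sample_population(20_000, state, stable_G, rngs["sampling"])
            table = ag.run_contests(
                males, p, rng_pairing=rngs["pairing"], rng_noise=rngs["noise"]
            )
            new = ag.next_generation_means(
                table, males, stable_G, state, rngs["reproduction"]
            )
            deltas.append(new.means() - state.means())
        mean_delta = np.mean(deltas, axis=0)
        se = np.std(deltas, axis=0, ddof=1) / np.sqrt(len(deltas))
        assert np.all(np.abs(mean_delta) < 3 * se + 1e-12)

    def test_one_generation_response_tracks_the_recursion(self, params, stable_G):
        """Replicate-averaged individual-based response approximates the
        deterministic prediction (coarse check; the dedicated acceptance
        test runs the full-size version)."""
        state = ag.PopulationState()
        predicted = ag.response_mechanistic(state, params, stable_G)
        deltas = []
        for rep in range(8):
            rngs = ag.spawn_rngs(300 + rep)
            males = ag.sample_population(50_000, state, stable_G, rngs["sampling"])
            table = ag.run_contests(
                males, params, rng_pairing=rngs["pairing"], rng_noise=rngs["noise"]
            )
            new = ag.next_generation_means(
                table, males, stable_G, state, rngs["reproduction"]
            )
            deltas.append(new.means() - state.means())
        mean_delta = np.mean(deltas, axis=0)
        assert np.allclose(mean_delta, predicted, atol=0.01)
        # stochastic version of the coupling invariant
        assert mean_delta[1] / mean_delta[0] == pytest.approx(
            stable_G.GSB / stable_G.GSS, abs=0.15
        )

    def test_truncation_is_counted(self, stable_G):
        state = ag.PopulationState()
        rngs = ag.spawn_rngs(4)
        males = ag.sample_population(10_000, state, stable_G, rngs["sampling"])
        table = ag.run_contests(
            males,
            ag.ContestParams(),
            rng_pairing=rngs["pairing"],
            rng_noise=rngs["noise"],
        )
        ag.next_generation_means(table, males, stable_G, state, rngs["reproduction"])
        assert table.metadata["truncation_count"] >= 0

    def test_degenerate_selection_is_an_error(self, stable_G):
        state = ag.PopulationState()
        males = ag.sample_population(100, state, stable_G, seed=2)
        p = ag.ContestParams(w0=-100.0)
        table = ag.run_contests(males, p, seed=2, normalize=False)
        with pytest.raises(ValueError, match="degenerate"):
            ag.next_generation_means(table, males, stable_G, state, 0)

    def test_multi_generation_runaway_phenomenology(self, params, runaway_G, stable_G):
        """Strong honesty elaborates signal and body size further than weak
        honesty over the same horizon, growth continues late, and
        aggression tracks its self-limiting approach to bA/cA."""
        out = {}
        for key, G in (("weak", stable_G), ("strong", runaway_G)):
            states, _ = ag.simulate_generations(
                ag.PopulationState(), params, G, n=20_000, generations=60, seed=6
            )
            out[key] = np.array([s.means() for s in states])
        S, B, A = out["strong"][:, 0], out["strong"][:, 1], out["strong"][:, 2]
        assert S[-1] > out["weak"][-1, 0]
        assert B[-1] > 2.0 * out["weak"][-1, 1]
        # elaboration has not stalled late in the run
        assert S[-1] - S[-21] > 0.3 * (S[20] - S[0])
        # aggression follows its autonomous, self-limiting recursion
        det = ag.iterate(
            ag.PopulationState(), params, runaway_G, max_generations=60, tol=0.0
        )
        assert abs(A[-1] - det.final_state.meanA) < 0.5
        assert np.all(np.diff(A) > -0.2) and A[-1] < 4.2
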