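"""Task generator: SOC pair maps, session streams, agent simulation."""

import numpy as np
import pandas as pd
import pytest

from cathgf import (
    SEQUENCE_A,
    SEQUENCE_B,
    HGFParameters,
    ResponseParameters,
    SequenceSpec,
    build_pair_map,
    generate_experiment,
    generate_session,
    simulate_agent,
)


class TestBuildPairMap:
    @pytest.mark.parametrize(
        "sequence, pair, successor",
        [
            (SEQUENCE_A, (1, 2), 1),  # "...1-2-1..."
            (SEQUENCE_B, (1, 2), 4),  # "...1-2-4..."
            (SEQUENCE_A, (2, 3), 1),  # cyclic wrap of the printed sequence
        ],
    )
    def test_printed_sequence_pairs(self, sequence, pair, successor):
        assert build_pair_map(sequence)[pair] == successor

    def test_all_twelve_distinct_pairs_covered(self):
        for seq in (SEQUENCE_A, SEQUENCE_B):
            pairs = set(build_pair_map(seq))
            assert len(pairs) == 12
            assert all(a != b for a, b in pairs)
        assert set(build_pair_map(SEQUENCE_A)) == set(build_pair_map(SEQUENCE_B))

    def test_conflicting_pair_raises(self):
        with pytest.raises(ValueError, match="maps to both"):
            build_pair_map([1, 2, 3, 1, 2, 4])  # (1,2) -> 3 and -> 4

    def test_immediate_repetition_raises(self):
        with pytest.raises(ValueError, match="repetition"):
            build_pair_map([1, 2, 2, 4, 1, 3])


class TestSequenceSpec:
    def test_defaults_valid(self, spec):
        assert spec.p_high == 0.85
        assert spec.trials_per_session == 960
        assert spec.n_sessions == 2

    @pytest.mark.parametrize("p_high", [0.0, -0.1, 1.5])
    def test_invalid_p_high(self, p_high):
        with pytest.raises(ValueError, match="p_high"):
            SequenceSpec(p_high=p_high)

    def test_json_round_trip(self, spec):
        assert SequenceSpec.from_json(spec.to_json()) == spec


class TestGenerateSession:
    def test_high_source_fraction_near_085(self, spec):
        df = generate_session(spec, "pre", seed=123)
        frac = (df["source"] == "high").sum() / (len(df) - 2)
        se = np.sqrt(0.85 * 0.15 / (len(df) - 2))
        assert abs(frac - 0.85) <= 3 * se

    def test_long_run_frequency_converges(self):
        spec = SequenceSpec(trials_per_session=10_000)
        df = generate_session(spec, "pre", seed=7)
        frac = (df["source"] == "high").sum() / (len(df) - 2)
        se = np.sqrt(0.85 * 0.15 / (len(df) - 2))
        assert abs(frac - 0.85) <= 3 * se

    def test_degenerate_p_high_cycles_through_sequence_a(self):
        spec = SequenceSpec(p_high=1.0, trials_per_session=60)
        df = generate_session(spec, "pre", seed=5)
        stim = df["stimulus"].tolist()
        # after any starting pair the stream must track the 12-cycle of A
        cycle = list(SEQUENCE_A[:12])
        start = next(
            k for k in range(12)
            if (cycle[k], cycle[(k + 1) % 12]) == (stim[0], stim[1])
        )
        expected = [cycle[(start + i) % 12] for i in range(60)]
        assert stim == expected

    def test_no_immediate_repetitions(self, spec):
        df = generate_session(spec, "pre", seed=42)
        stim = df["stimulus"].to_numpy()
        assert np.all(stim[1:] != stim[:-1])

    def test_every_triple_is_a_sequence_continuation(self, spec):
        map_a, map_b = spec.pair_map_a, spec.pair_map_b
        df = generate_session(spec, "post", seed=9)
        stim = df["stimulus"].tolist()
        for t in range(2, len(stim)):
            pair = (stim[t - 2], stim[t - 1])
            assert stim[t] in (map_a[pair], map_b[pair])

    def test_post_session_swaps_sequence_roles(self, spec):
        df = generate_session(spec, "post", seed=11)
        stim = df["stimulus"].tolist()
        map_b = spec.pair_map_b
        for t in range(2, len(stim)):
            if df["source"].iloc[t] == "high":
                assert stim[t] == map_b[(stim[t - 2], stim[t - 1])]

    def test_seed_determinism(self, spec):
        a = generate_session(spec, "pre", seed=3)
        b = generate_session(spec, "pre", seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_experiment_layout(self, spec):
        df = generate_experiment(spec, seed=1)
        assert len(df) == 1920
        assert df["session"].tolist() == ["pre"] * 960 + ["post"] * 960
        assert df["trial"].tolist() == list(range(1, 1921))


class TestSimulateAgent:
    def test_intercept_only_noise_free(self, short_spec):
        stimuli = generate_experiment(short_spec, seed=2)
        resp = ResponseParameters(beta0=5.0, sigma=1e-12)
        out = simulate_agent(stimuli, HGFParameters(-4.0), resp, seed=4)
        assert np.allclose(out["rt_ms"], np.exp(5.0))

    def test_post_error_slowing_matches_beta4(self, spec):
        resp = ResponseParameters(beta0=5.8, beta4=0.10, sigma=0.01)
        stimuli = generate_experiment(spec, seed=6)
        out = simulate_agent(
            stimuli, HGFParameters(-4.0), resp, error_rate=0.1, seed=8
        )
        log_rt = np.log(out["rt_ms"].to_numpy())
        correct = out["correct"].to_numpy(dtype=bool)
        post_err = np.zeros(len(out), dtype=bool)
        post_err[1:] = ~correct[:-1]
        post_err[[0, 960]] = False  # session-initial trials
        gap = log_rt[post_err].mean() - log_rt[~post_err].mean()
        assert gap == pytest.approx(0.10, abs=0.01)

    def test_seed_determinism(self, short_spec):
        stimuli = generate_experiment(short_spec, seed=2)
        resp = ResponseParameters(beta0=5.8, beta4=0.1)
        a = simulate_agent(stimuli, HGFParameters(-4.0), resp, seed=5)
        b = simulate_agent(stimuli, HGFParameters(-4.0), resp, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_accuracy_matches_error_rate(self, spec):
        stimuli = generate_experiment(spec, seed=2)
        resp = ResponseParameters(beta0=5.8)
        out = simulate_agent(
            stimuli, HGFParameters(-4.0), resp, error_rate=0.08, seed=5
        )
        acc = out["correct"].to_numpy(dtype=bool).mean()
        assert acc == pytest.approx(0.92, abs=3 * np.sqrt(0.08 * 0.92 / len(out)))

    def test_invalid_error_rate(self, short_spec):
        stimuli = generate_experiment(short_spec, seed=2)
        with pytest.raises(ValueError, match="error_rate"):
            simulate_agent(
                stimuli, HGFParameters(-4.0), ResponseParameters(beta0=5.8),
                error_rate=1.0, seed=0,
            )
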