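import numpy as np
import pandas as pd
import pytest

from syncoh.coherence import CoherenceSpectrum, SpectralConfig
from syncoh.pairstats import (LOWER_THRESHOLD, UPPER_THRESHOLD,
                              assemble_observations, classify_pairs,
                              fit_pair_lmm, normalize_weights,
                              per_bin_analysis, per_layer_analysis)

CENTERS = SpectralConfig().bin_centers()


class TestNormalizeWeights:
    def test_three_four_five_triangle(self):
        W = normalize_weights(np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(W, [[0.6, 0.8]])

    def test_one_hot_row_unchanged(self):
        W = normalize_weights(np.array([[0.0, 1.0, 0.0]]))
        np.testing.assert_allclose(W, [[0.0, 1.0, 0.0]])

    def test_squared_sums_are_one(self):
        rng = np.random.default_rng(0)
        W = normalize_weights(rng.uniform(0.01, 1.0, (12, 5)))
        np.testing.assert_allclose(np.sum(W ** 2, axis=1), 1.0, atol=1e-9)

    def test_zero_row_rejected_with_muscle_name(self):
        W = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="index 1"):
            normalize_weights(W)


def _brute_force_label(wi, wj):
    """Independent re-statement of the pair rules, evaluated literally."""
    for s in range(len(wi)):
        if wi[s] > 0.75 and wj[s] > 0.75:
            return "synergistic"
        if (wi[s] > 0.75 and wj[s] < 0.25) or (wj[s] > 0.75 and wi[s] < 0.25):
            return "non_synergistic"
    return "excluded"


class TestClassifyPairs:
    def test_both_dominant_in_one_synergy(self):
        W = normalize_weights(np.array([[0.9, 0.1], [0.9, 0.2]]))
        out = classify_pairs(W)
        assert out[0].label == "synergistic" and out[0].synergy == 0

    def test_dominant_versus_weak_is_non_synergistic(self):
        W = normalize_weights(np.array([[0.95, 0.1], [0.1, 0.95]]))
        out = classify_pairs(W)
        assert out[0].label == "non_synergistic"

    def test_dominant_versus_intermediate_excluded(self):
        W = np.array([[0.8, 0.6], [0.5, 0.866]])
        W = W / np.linalg.norm(W, axis=1, keepdims=True)
        assert W[0, 0] > 0.75 and LOWER_THRESHOLD < W[1, 0] < UPPER_THRESHOLD
        out = classify_pairs(W)
        assert out[0].label == "excluded"

    def test_matches_brute_force_on_random_weights(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            W = normalize_weights(rng.uniform(0.01, 1.0, (8, 3)))
            out = {c.pair: c.label for c in classify_pairs(W)}
            for i in range(8):
                for j in range(i + 1, 8):
                    assert out[(i, j)] == _brute_force_label(W[i], W[j])

    def test_every_pair_labelled_exactly_once(self):
        rng = np.random.default_rng(1)
        W = normalize_weights(rng.uniform(0.01, 1.0, (10, 4)))
        out = classify_pairs(W)
        assert len(out) == 45
        assert len({c.pair for c in out}) == 45

    def test_no_muscle_dominant_in_two_synergies(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            W = normalize_weights(rng.uniform(0.01, 1.0, (6, 4)))
            assert np.all((W > UPPER_THRESHOLD).sum(axis=1) <= 1)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            classify_pairs(np.array([[2.0, 1.0]]))


def _spec(Z, trial=0, pair=(0, 1)):
    Z = np.asarray(Z, float)
    return CoherenceSpectrum(pair=pair, trial_id=trial, C=np.tanh(Z / 58.0),
                             Z=Z, significant=Z > 0, n_segments=29,
                             bin_centers=CENTERS)


class TestAssembleObservations:
    def _classes(self):
        W = normalize_weights(np.array([[1.0, 0.05], [1.0, 0.1], [0.05, 1.0]]))
        return classify_pairs(W)

    def test_row_count_trials_times_layers(self):
        classes = self._classes()
        bounds = [(1.0, 10.0), (10.0, 20.0), (20.0, 30.0),
                  (30.0, 40.0), (40.0, 50.0), (50.0, 60.0)]
        spectra = {t: [_spec(np.ones(15), trial=t, pair=(0, 1))] for t in (0, 1)}
        meta = {0: (0, 1), 1: (0, 2)}
        df = assemble_observations(classes, spectra, bounds, meta, 7)
        assert len(df) == 2 * 1 * 6
        assert set(df.layer) == {1, 2, 3, 4, 5, 6}

    def test_all_zero_pair_spectra_dropped(self):
        classes = self._classes()
        spectra = {0: [_spec(np.zeros(15), pair=(0, 1)),
                       _spec(np.ones(15), pair=(0, 2))]}
        df = assemble_observations(classes, spectra, [(1.0, 60.0)], {0: (0, 1)}, 0)
        assert set(zip(df.muscle_i, df.muscle_j)) == {(0, 2)}

    def test_missing_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            assemble_observations(self._classes(), {}, [], {}, 0)


def _null_obs(rng, n_participants=6, n_directions=6, n_pairs=8, effect=0.0,
              sigma=1.0, tau=0.5):
    rows = []
    for p in range(n_participants):
        u = tau * rng.standard_normal()
        for d in range(n_directions):
            for q in range(n_pairs):
                syn = q % 2
                rows.append({
                    "participant": p, "direction": d,
                    "repetition": int(rng.integers(1, 4)),
                    "synergistic": syn,
                    "iz": 5.0 + u + effect * syn + sigma * rng.standard_normal(),
                    "layer": 1,
                })
    return pd.DataFrame(rows)


class TestPairLmm:
    def test_type_one_error_rate_near_alpha(self):
        """Under a null with participant random effects, ~5% of fits reject."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            res = fit_pair_lmm(_null_obs(rng))
            rejections += res.pvalue < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03

    def test_recovers_large_additive_effect(self):
        rng = np.random.default_rng(5)
        res = fit_pair_lmm(_null_obs(rng, effect=5.0, sigma=1.0))
        assert abs(res.estimate - 5.0) / 5.0 < 0.10
        assert res.pvalue < 0.01

    def test_constant_pair_type_rejected(self):
        df = _null_obs(np.random.default_rng(1))
        df["synergistic"] = 1
        with pytest.raises(ValueError, match="both pair types"):
            fit_pair_lmm(df)

    def test_single_participant_rejected(self):
        df = _null_obs(np.random.default_rng(2), n_participants=1)
        with pytest.raises(ValueError, match="2 participants"):
            fit_pair_lmm(df)

    def test_per_layer_returns_one_result_per_layer(self):
        rng = np.random.default_rng(3)
        df = pd.concat([_null_obs(rng).assign(layer=k) for k in (1, 2)],
                       ignore_index=True)
        results = per_layer_analysis(df)
        assert [r.unit for r in results] == [1, 2]

    def test_per_bin_single_bin_gives_one_row(self):
        rng = np.random.default_rng(4)
        df = _null_obs(rng).rename(columns={"iz": "z"})
        df["bin_center"] = 3.90625
        out = per_bin_analysis(df)
        assert len(out) == 1 and out[0].unit == pytest.approx(3.90625)


@pytest.mark.parametrize("seed", [0])
def test_classification_matches_brute_force_under_hypothesis(seed):
    from hypothesis import given, settings, strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (5, 3),
                      elements=st.floats(0.01, 1.0, allow_nan=False)))
    def check(raw):
        W = normalize_weights(raw)
        out = {c.pair: c.label for c in classify_pairs(W)}
        for i in range(5):
            for j in range(i + 1, 5):
                assert out[(i, j)] == _brute_force_label(W[i], W[j])
        labels = [c.label for c in classify_pairs(W)]
        assert set(labels) <= {"synergistic", "non_synergistic", "excluded"}

    check()
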