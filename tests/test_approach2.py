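import numpy as np
import pytest

from cspselect import (
    CVConfig,
    NoCandidatesError,
    SelectionConfig,
    SimConfig,
    ValidationError,
    approach2_best,
    baseline_bfull,
    extract_combination,
    generate_session,
    select_electrodes_from_pattern,
)
from cspselect.csp import CSPModel


def model_from_patterns(patterns, ch_names):
    patterns = np.asarray(patterns, dtype=float)
    return CSPModel(
        filters=np.zeros_like(patterns),
        patterns=patterns,
        eigvals=np.linspace(0.9, 0.1, patterns.shape[0]),
        ch_names=tuple(ch_names),
        n_components=patterns.shape[0],
        class_order=("left", "right"),
    )


class TestPatternSelection:
    def test_constant_pattern_selects_nothing(self):
        assert select_electrodes_from_pattern(
            [3.0, 3.0, 3.0, 3.0], ("A", "B", "C", "D")
        ) == set()

    def test_single_outlier_oracle(self):
        # mean 2.5, population sd 4.3301, threshold 6.4952; only the
        # deviation |10 - 2.5| = 7.5 exceeds it
        got = select_electrodes_from_pattern(
            [0.0, 0.0, 0.0, 10.0], ("A", "B", "C", "D"), theta=1.5
        )
        assert got == {"D"}

    def test_symmetric_pattern_below_threshold(self):
        # sd = 4.0825, threshold 6.1237, max deviation 5 -> empty
        assert select_electrodes_from_pattern(
            [-5.0, 0.0, 5.0], ("A", "B", "C"), theta=1.5
        ) == set()

    @pytest.mark.parametrize("sample_sd", [False, True])
    def test_matches_brute_force_recomputation(self, rng, sample_sd):
        for _ in range(200):
            n = int(rng.integers(3, 65))
            p = rng.standard_normal(n) * rng.uniform(0.1, 10)
            names = tuple(f"E{i}" for i in range(n))
            got = select_electrodes_from_pattern(p, names, 1.5, sample_sd)
            mu = sum(p) / n
            var = sum((v - mu) ** 2 for v in p) / (n - 1 if sample_sd else n)
            expected = {
                names[i] for i, v in enumerate(p) if abs(v - mu) > 1.5 * var**0.5
            }
            assert got == expected

    @pytest.mark.parametrize("a, b", [(2.0, 0.0), (-3.0, 1.5), (0.1, -7.0)])
    def test_affine_invariance(self, rng, a, b):
        p = rng.standard_normal(12)
        names = tuple(f"E{i}" for i in range(12))
        assert select_electrodes_from_pattern(
            p, names
        ) == select_electrodes_from_pattern(a * p + b, names)

    def test_short_pattern_rejected(self):
        with pytest.raises(ValidationError):
            select_electrodes_from_pattern([1.0], ("A",))


class TestExtractCombination:
    def test_all_constant_patterns_give_none(self):
        model = model_from_patterns(np.ones((3, 4)), ("A", "B", "C", "D"))
        assert extract_combination(model) is None

    def test_union_in_channel_order(self):
        patterns = np.array([
            [0.0, 0.0, 0.0, 10.0],   # selects D
            [10.0, 0.0, 0.0, 0.0],   # selects A
            [1.0, 1.0, 1.0, 1.0],    # selects nothing
        ])
        combo = extract_combination(
            model_from_patterns(patterns, ("A", "B", "C", "D"))
        )
        assert combo.names == ("A", "D")

    def test_respects_n_patterns_limit(self):
        patterns = np.array([
            [0.0, 0.0, 0.0, 10.0],
            [10.0, 0.0, 0.0, 0.0],
        ])
        combo = extract_combination(
            model_from_patterns(patterns, ("A", "B", "C", "D")),
            SelectionConfig(n_patterns=1),
        )
        assert combo.names == ("D",)

    def test_recovers_planted_channels(self):
        from cspselect.csp import class_covariances, fit_csp
        from cspselect.preprocess import bandpass

        hits = 0
        for seed in range(10):
            s = generate_session(
                SimConfig(seed=1000 + seed, effect=8.0, n_trials_per_class=100,
                          disc_channels=("C3", "C4"), mixing_strength=0.0)
            )
            model = fit_csp(class_covariances(bandpass(s)), 8)
            combo = extract_combination(model)
            names = set(combo.names) if combo else set()
            hits += {"C3", "C4"} <= names
        assert hits >= 9


class TestApproach2Best:
    def test_deterministic_and_deduplicated(self, strong_session):
        cv = CVConfig(5, seed=4)
        b1, r1, c1 = approach2_best(strong_session, cv)
        b2, r2, c2 = approach2_best(strong_session, cv)
        assert b1 == b2 and r1 == r2 and c1 == c2
        names = [c.names for c in c1]
        assert len(names) == len(set(names))
        assert len(names) <= cv.n_splits
        assert all(len(c) >= 3 for c in c1)

    def test_best_close_to_full_baseline(self, strong_session):
        _, result, _ = approach2_best(strong_session)
        bfull = baseline_bfull(strong_session)
        assert result.mean_accuracy >= bfull.mean_accuracy - 0.05

    def test_min_electrode_filter_raises_empty_signal(self, strong_session):
        with pytest.raises(NoCandidatesError):
            approach2_best(
                strong_session,
                cfg=SelectionConfig(min_electrodes=17),
            )

    def test_restricting_base_limits_candidates(self, strong_session):
        from cspselect import ChannelSubset

        base = ChannelSubset(("C3", "C1", "Cz", "C2", "C4", "CP3", "CPz", "CP4"))
        _, _, candidates = approach2_best(strong_session, base=base)
        for c in candidates:
            assert set(c.names) <= set(base.names)
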