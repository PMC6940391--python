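"""Stimulus design: enumeration, irregularity metrics, rendering, family."""

import itertools

import numpy as np
import pytest

from phasescramble.stimulus_design import (
    DEFAULT_CORRELATION_GRID,
    DEFAULT_S6_STEPS,
    PhaseSequence,
    StimulusSpec,
    best_aligned_correlation,
    build_family,
    canonicalize,
    enumerate_sequences,
    forward_sequence,
    backward_sequence,
    irregularity_table,
    load_family,
    motion_energy,
    motion_energy_of_movie,
    render_movie,
    save_family,
    select_scrambled_sequences,
    smooth_motion_metrics,
    summed_phase_interval,
)


def brute_force_unique_count(n):
    """Oracle: dedup all n! permutations by circular rotation."""
    seen = set()
    for perm in itertools.permutations(range(1, n + 1)):
        rots = {perm[k:] + perm[:k] for k in range(n)}
        seen.add(min(rots))
    return len(seen)


def brute_force_correlation(a, b, normalize=True):
    """Oracle: explicit double loop over offsets and frames, no vectorization."""
    x = DEFAULT_CORRELATION_GRID
    n = len(a)

    def frame(step):
        return np.sin(2 * np.pi * (x + (step - 1) / n))

    def product(sa, sb):
        total = 0.0
        for i in range(n):
            total += float(np.sum(frame(sa[i]) * frame(sb[i])))
        return total

    best = -np.inf
    for k in range(n):
        rotated = list(b[k:]) + list(b[:k])
        best = max(best, product(list(a), rotated))
    if not normalize:
        return best
    return best / np.sqrt(product(list(a), list(a)) * product(list(b), list(b)))


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(3, 2), (4, 6), (5, 24), (8, 5040)])
    def test_counts(self, n, expected):
        seqs = enumerate_sequences(n)
        assert len(seqs) == expected
        # every representative is canonical and they are pairwise distinct
        assert all(s.steps[0] == 1 for s in seqs)
        assert len({s.steps for s in seqs}) == expected

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_dedup(self, n):
        assert len(enumerate_sequences(n)) == brute_force_unique_count(n)

    def test_contains_forward_and_backward(self):
        steps = {s.steps for s in enumerate_sequences(8)}
        assert forward_sequence(8).steps in steps
        assert backward_sequence(8).canonical().steps in steps

    def test_no_two_are_rotations(self):
        seqs = enumerate_sequences(5)
        canon = {min(s.steps[k:] + s.steps[:k] for k in range(5)) for s in seqs}
        assert len(canon) == len(seqs)

    @pytest.mark.parametrize("n", [1, 11])
    def test_bounds(self, n):
        with pytest.raises(ValueError):
            enumerate_sequences(n)


class TestCanonicalize:
    def test_rotation_example(self):
        assert canonicalize([2, 3, 4, 5, 6, 7, 8, 1]).steps == tuple(range(1, 9))

    def test_backward(self):
        assert canonicalize([8, 7, 6, 5, 4, 3, 2, 1]).steps == (
            1, 8, 7, 6, 5, 4, 3, 2)

    def test_idempotent(self):
        seq = canonicalize([3, 2, 4, 5, 6, 7, 8, 1])
        assert canonicalize(seq).steps == seq.steps

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            PhaseSequence((1, 2, 2, 4))


class TestBestAlignedCorrelation:
    def test_self_correlation_is_one(self):
        for steps in [tuple(range(1, 9)), DEFAULT_S6_STEPS]:
            assert best_aligned_correlation(steps, steps) == pytest.approx(1.0)

    def test_symmetric_and_rotation_invariant(self):
        a = PhaseSequence((3, 2, 4, 5, 6, 7, 8, 1))
        b = PhaseSequence(DEFAULT_S6_STEPS)
        ref = best_aligned_correlation(a, b)
        assert best_aligned_correlation(b, a) == pytest.approx(ref)
        for k in range(8):
            assert best_aligned_correlation(a.rotated(k), b.rotated(-k)) == (
                pytest.approx(ref))

    def test_matches_brute_force_oracle(self):
        f = tuple(range(1, 9))
        b = tuple(range(8, 0, -1))
        for pair in [(f, b), (f, DEFAULT_S6_STEPS), (b, DEFAULT_S6_STEPS)]:
            assert best_aligned_correlation(*pair) == pytest.approx(
                brute_force_correlation(*pair), abs=1e-12)

    def test_alignment_uses_best_rotation(self):
        # [3 2 4 5 6 7 8 1] rotates to [1 3 2 4 5 6 7 8] against smooth
        # forward motion; that leading-1 alignment attains the maximum.
        a = (3, 2, 4, 5, 6, 7, 8, 1)
        aligned = (1, 3, 2, 4, 5, 6, 7, 8)
        x = DEFAULT_CORRELATION_GRID
        frames = [np.sin(2 * np.pi * (x + (s - 1) / 8)) for s in range(1, 9)]
        raw = sum(
            float(np.sum(frames[sa - 1] * frames[sf - 1]))
            for sa, sf in zip(aligned, range(1, 9))
        )
        self_a = sum(float(np.sum(frames[s - 1] ** 2)) for s in a)
        self_f = sum(float(np.sum(frames[s - 1] ** 2)) for s in range(1, 9))
        assert best_aligned_correlation(a, forward_sequence(8)) == (
            pytest.approx(raw / np.sqrt(self_a * self_f)))

    def test_values_bounded(self):
        rng = np.random.default_rng(0)
        f = forward_sequence(8)
        for _ in range(20):
            steps = tuple(rng.permutation(np.arange(1, 9)))
            c = best_aligned_correlation(steps, f)
            assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12

    def test_as_printed_mode_differs(self):
        # the literal product kernel makes phase step 1 identically zero,
        # so the two modes disagree in general
        f, s6 = tuple(range(1, 9)), DEFAULT_S6_STEPS
        sensible = best_aligned_correlation(f, s6, mode="sensible")
        printed = best_aligned_correlation(f, s6, mode="as_printed")
        assert printed != pytest.approx(sensible)
        x = DEFAULT_CORRELATION_GRID
        assert np.allclose(np.sin(2 * np.pi * ((1 - 1) / 8) * x), 0.0)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            best_aligned_correlation((1, 2, 3), (1, 2, 3, 4))


class TestSmoothMotionMetrics:
    def test_forward_and_backward_self(self):
        cf, _, _ = smooth_motion_metrics(forward_sequence(8))
        assert cf == pytest.approx(1.0)
        _, cb, _ = smooth_motion_metrics(backward_sequence(8))
        assert cb == pytest.approx(1.0)

    def test_average_is_mean(self):
        cf, cb, avg = smooth_motion_metrics(DEFAULT_S6_STEPS)
        assert avg == pytest.approx((cf + cb) / 2)

    def test_s6_uncorrelated_with_smooth_motion(self):
        cf, cb, _ = smooth_motion_metrics(DEFAULT_S6_STEPS)
        assert abs(cf) < 1e-10 and abs(cb) < 1e-10
        # oracle agreement
        assert cf == pytest.approx(
            brute_force_correlation(DEFAULT_S6_STEPS, tuple(range(1, 9))),
            abs=1e-12)


class TestSummedPhaseInterval:
    def test_forward_is_two_pi(self):
        assert summed_phase_interval(forward_sequence(8)) == pytest.approx(
            2 * np.pi)

    def test_s6_hand_summation(self):
        # circular step distances of [8 3 6 2 7 4 1 5]:
        # 3+3+4+3+3+3+4+3 = 26 steps of 2*pi/8 each
        assert summed_phase_interval(DEFAULT_S6_STEPS) == pytest.approx(
            26 * 2 * np.pi / 8)

    def test_rotation_and_reversal_invariance(self):
        seq = PhaseSequence(DEFAULT_S6_STEPS)
        ref = summed_phase_interval(seq)
        for k in range(8):
            assert summed_phase_interval(seq.rotated(k)) == pytest.approx(ref)
        assert summed_phase_interval(seq.reversed()) == pytest.approx(ref)

    def test_smooth_attains_minimum_over_full_enumeration(self):
        table = irregularity_table(8)
        assert table["summed_phase_interval"].min() == pytest.approx(2 * np.pi)
        argmin = table.loc[
            table["summed_phase_interval"].idxmin(), "sequence"]
        assert argmin == "[1 2 3 4 5 6 7 8]"


class TestMotionEnergy:
    def test_constant_movie_has_zero_energy(self):
        frames = np.ones((8, 16)) * 0.3
        assert motion_energy_of_movie(frames) == pytest.approx(0.0)

    def test_scrambled_exceeds_smooth(self):
        assert motion_energy(DEFAULT_S6_STEPS) > motion_energy(
            forward_sequence(8))

    def test_naive_dft_oracle(self):
        # O(N^2) DFT by definition on the forward movie at 8x16 sampling
        seq = forward_sequence(8)
        x = np.arange(16) / 16
        frames = np.stack(
            [np.sin(2 * np.pi * (x + (s - 1) / 8)) for s in seq.steps])
        T, S = frames.shape
        total = 0.0
        for ft in range(T):
            for fx in range(S):
                coeff = 0.0 + 0.0j
                for t in range(T):
                    for s in range(S):
                        coeff += frames[t, s] * np.exp(
                            -2j * np.pi * (ft * t / T + fx * s / S))
                if ft != 0:
                    total += abs(coeff)
        assert motion_energy(seq) == pytest.approx(total, abs=1e-8)

    def test_smooth_is_minimal_over_enumeration(self):
        table = irregularity_table(8)
        e_forward = table.loc[
            table["sequence"] == "[1 2 3 4 5 6 7 8]", "motion_energy"
        ].item()
        violations = table[table["motion_energy"] < e_forward - 1e-9]
        assert violations.empty, violations.to_string()

    def test_too_few_spatial_samples(self):
        with pytest.raises(ValueError):
            motion_energy(forward_sequence(8), spatial_samples_per_cycle=1)


class TestRenderMovie:
    def test_forward_timing(self):
        spec = StimulusSpec(label="F", sequence=forward_sequence(8))
        movie = render_movie(spec)
        assert movie.n_frames == 80
        assert movie.frame_duration == pytest.approx(0.0625)
        assert movie.n_frames * movie.frame_duration == pytest.approx(5.0)

    def test_counterphase_is_mean_of_forward_and_backward(self, family):
        by_label = {s.label: s for s in family}
        for cp_label in ("CP1", "CP2"):
            cp = by_label[cp_label]
            f = StimulusSpec(
                label="F", sequence=forward_sequence(8),
                spatial_phase_offset=cp.spatial_phase_offset)
            b = StimulusSpec(
                label="B", sequence=backward_sequence(8),
                spatial_phase_offset=cp.spatial_phase_offset)
            mean = (render_movie(f).frames + render_movie(b).frames) / 2
            np.testing.assert_allclose(
                render_movie(cp).frames, mean, atol=1e-12)

    def test_sequence_frames_are_unit_amplitude_sinusoids(self):
        movie = render_movie(
            StimulusSpec(label="S6", sequence=PhaseSequence(DEFAULT_S6_STEPS)))
        for frame in movie.frames:
            spectrum = np.fft.rfft(frame)
            # all power in the first harmonic, amplitude exactly 1
            assert 2 * np.abs(spectrum[1]) / frame.size == pytest.approx(1.0)
            assert np.abs(frame).max() <= 1.0 + 1e-12

    def test_values_in_range(self, family):
        for spec in family:
            frames = render_movie(spec).frames
            assert frames.min() >= -1.0 - 1e-12
            assert frames.max() <= 1.0 + 1e-12


class TestBuildFamily:
    def test_default_family_composition(self, family):
        assert [s.label for s in family] == [
            "F", "B", "S1", "S2", "S3", "S4", "S5", "S6", "CP1", "CP2"]
        by_label = {s.label: s for s in family}
        assert by_label["F"].sequence.steps == tuple(range(1, 9))
        assert by_label["B"].sequence.steps == tuple(range(8, 0, -1))
        assert by_label["S6"].sequence.steps == DEFAULT_S6_STEPS

    def test_step_duration(self, family):
        for s in family:
            assert s.step_duration == 1.0 / (2.0 * 8)

    def test_selection_respects_correlation_ceiling(self, family):
        for s in family:
            if s.label.startswith("S") and s.label != "S6":
                _, _, avg = smooth_motion_metrics(s.sequence)
                assert avg <= 0.5 + 1e-12

    def test_selection_mutual_dissimilarity(self, family):
        scrambled = [s.sequence for s in family if s.label.startswith("S")]
        for i, a in enumerate(scrambled):
            for b in scrambled[i + 1:]:
                assert best_aligned_correlation(a, b) <= 0.6 + 1e-12

    def test_overrides_are_honored(self):
        fam = build_family(sequences={"S1": [1, 3, 2, 4, 5, 6, 7, 8]})
        by_label = {s.label: s for s in fam}
        assert by_label["S1"].sequence.steps == (1, 3, 2, 4, 5, 6, 7, 8)
        assert by_label["S6"].sequence.steps == DEFAULT_S6_STEPS

    def test_too_strict_ceiling_errors(self):
        with pytest.raises(ValueError):
            select_scrambled_sequences(n_select=5, corr_ceiling=-1.0)

    def test_config_round_trip(self, family, tmp_path):
        path = tmp_path / "family.yaml"
        save_family(family, path)
        reloaded = load_family(path)
        assert [s.label for s in reloaded] == [s.label for s in family]
        for a, b in zip(reloaded, family):
            if a.kind == "sequence":
                assert a.sequence.steps == b.sequence.steps
            else:
                assert a.spatial_phase_offset == pytest.approx(
                    b.spatial_phase_offset)
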