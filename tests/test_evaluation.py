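import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from prftone.evaluation import (cents_error, generate_foils, identification,
                                residual_bias_test, adjust_pvalues, rrmse,
                                rrmse_report, evaluate_reconstruction)
from prftone.stimulus import ParameterError


class TestCentsError:
    @pytest.mark.parametrize("f_est,f_true,expected", [
        (880.0, 880.0, 0.0),
        (1760.0, 880.0, 1200.0),       # one octave = 1200 cents
        (932.33, 880.0, 100.0),        # one equal-tempered semitone
    ])
    def test_reference_values(self, f_est, f_true, expected):
        assert cents_error(f_est, f_true) == pytest.approx(expected, abs=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(50, 9000), b=st.floats(50, 9000))
    def test_antisymmetry(self, a, b):
        assert cents_error(a, b) == pytest.approx(-cents_error(b, a),
                                                  abs=1e-6)

    def test_octave_stacking_additive(self):
        assert cents_error(880 * 4, 880) == pytest.approx(2 * 1200.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            cents_error(0.0, 880.0)


class TestFoils:
    def test_foil_shape_and_note_set(self):
        song = [880.0, 987.77, 880.0, 1174.66, 880.0]
        foils = generate_foils(song, n_foils=50, rng_seed=1)
        assert len(foils) == 50
        for seq in foils.sequences:
            assert len(seq) == len(song)
            assert set(seq) <= set(song)

    def test_transition_frequencies_converge(self):
        # toy song [A, A, B, A]: from A, half the transitions go to B
        A, B = 880.0, 987.77
        song = [A, A, B, A]
        foils = generate_foils(song, n_foils=4000, rng_seed=2)
        a_to_b = a_total = 0
        for seq in foils.sequences:
            for x, y in zip(seq[:-1], seq[1:]):
                if x == A:
                    a_total += 1
                    a_to_b += y == B
        assert a_to_b / a_total == pytest.approx(0.5, abs=0.03)

    def test_single_unique_note_degenerates(self):
        foils = generate_foils([880.0, 880.0, 880.0], n_foils=5, rng_seed=0)
        assert all(seq == [880.0] * 3 for seq in foils.sequences)

    def test_short_song_rejected(self):
        with pytest.raises(ParameterError):
            generate_foils([880.0], n_foils=2)

    def test_seed_determinism(self):
        song = [880.0, 987.77, 1108.73, 880.0, 987.77]
        a = generate_foils(song, 20, rng_seed=9).sequences
        b = generate_foils(song, 20, rng_seed=9).sequences
        assert a == b


class TestIdentification:
    def test_perfect_reconstruction_beats_all_foils(self):
        song = [880.0, 987.77, 1108.73, 1318.51, 880.0, 987.77]
        foils = generate_foils(song, 200, rng_seed=3)
        correct, r = identification(song, song, foils)
        assert r == pytest.approx(1.0)
        beaten = sum(seq != song for seq in foils.sequences)
        assert correct == beaten  # identical foils tie and are not beaten

    def test_identical_foil_ties_against(self):
        song = [880.0, 987.77, 880.0, 1108.73]
        foils = generate_foils(song, 10, rng_seed=4)
        foils.sequences[0] = list(song)
        correct, _ = identification(song, song, foils)
        assert correct <= 9

    def test_independent_reconstruction_is_near_uniform_rank(self, rng):
        song = list(rng.choice([880.0, 987.77, 1108.73, 1318.51], size=30))
        foils = generate_foils(song, 400, rng_seed=5)
        ranks = []
        for seed in range(20):
            fake = rng.choice([880.0, 987.77, 1108.73, 1318.51], size=30)
            correct, _ = identification(fake, song, foils)
            ranks.append(correct / 400)
        assert 0.1 < np.mean(ranks) < 0.9  # far from systematically perfect

    def test_zero_variance_reconstruction_flagged(self):
        song = [880.0, 987.77, 880.0, 1108.73]
        foils = generate_foils(song, 5, rng_seed=6)
        correct, r = identification([880.0] * 4, song, foils)
        assert correct == 0 and np.isnan(r)

    def test_length_mismatch_rejected(self):
        foils = generate_foils([880.0, 987.77], 2, rng_seed=0)
        with pytest.raises(ParameterError):
            identification([880.0], [880.0, 987.77], foils)


class TestBiasTest:
    def test_symmetric_pair(self):
        mean, sd, t, p = residual_bias_test([100.0, -100.0])
        assert mean == 0.0 and t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_three_sample(self):
        mean, sd, t, p = residual_bias_test([10.0, 20.0, 30.0])
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(10.0)
        assert t == pytest.approx(20.0 / (10.0 / np.sqrt(3)), rel=1e-12)

    def test_zero_variance_flagged(self):
        mean, sd, t, p = residual_bias_test([5.0, 5.0, 5.0])
        assert np.isnan(t) and np.isnan(p)

    def test_single_residual_rejected(self):
        with pytest.raises(ParameterError):
            residual_bias_test([1.0])


class TestPValueAdjustment:
    def test_bonferroni_with_external_m(self):
        # one test of six (3 subjects x 2 songs): 6 * 0.0173 = 0.1038,
        # non-significant after correction
        adj = adjust_pvalues([0.0173], method="bonferroni", m=6)
        assert adj[0] == pytest.approx(0.1038)
        assert adj[0] > 0.05

    def test_holm_step_down_by_hand(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "holm") == pytest.approx(
            [0.03, 0.04, 0.04])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_holm_dominated_by_bonferroni(self, ps):
        holm = adjust_pvalues(ps, "holm")
        bonf = adjust_pvalues(ps, "bonferroni")
        assert all(h <= b + 1e-12 for h, b in zip(holm, bonf))

    @pytest.mark.parametrize("method", ["bonferroni", "holm"])
    def test_matches_statsmodels(self, method, rng):
        ps = rng.uniform(0, 1, size=7)
        ours = adjust_pvalues(ps, method)
        theirs = multipletests(ps, method={"bonferroni": "bonferroni",
                                           "holm": "holm"}[method])[1]
        assert np.allclose(ours, theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            adjust_pvalues([1.5], "holm")


class TestRRMSE:
    def test_prediction_equal_to_one_scan_gives_half(self, rng):
        signal = rng.normal(size=500)
        scan2 = signal + rng.normal(0, 1, 500)
        # RMSE(pred, scan1) = 0, so rRMSE = D / (2 D) = 0.5
        assert rrmse(signal, signal, scan2) == pytest.approx(0.5)

    def test_perfect_model_iid_noise_near_inv_sqrt2(self, rng):
        vals = []
        for _ in range(50):
            signal = rng.normal(size=800)
            s1 = signal + rng.normal(0, 1, 800)
            s2 = signal + rng.normal(0, 1, 800)
            vals.append(rrmse(signal, s1, s2))
        assert np.mean(vals) == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_identical_scans_flagged(self):
        s = np.arange(10.0)
        assert np.isnan(rrmse(np.zeros(10), s, s))

    def test_shift_and_scale_invariance(self, rng):
        pred = rng.normal(size=100)
        s1 = rng.normal(size=100)
        s2 = rng.normal(size=100)
        base = rrmse(pred, s1, s2)
        assert rrmse(pred + 5, s1 + 5, s2 + 5) == pytest.approx(base)
        assert rrmse(3 * pred, 3 * s1, 3 * s2) == pytest.approx(base)

    def test_report_summaries(self, rng):
        signal = rng.normal(size=(30, 400))
        s1 = signal + rng.normal(0, 1, signal.shape)
        s2 = signal + rng.normal(0, 1, signal.shape)
        values, median, frac = rrmse_report(signal, s1, s2)
        assert values.size == 30
        assert median == pytest.approx(1 / np.sqrt(2), abs=0.03)
        assert frac == 0.0

    def test_report_single_voxel_median(self, rng):
        pred, s1, s2 = rng.normal(size=(3, 1, 50))
        values, median, _ = rrmse_report(pred, s1, s2)
        assert median == pytest.approx(values[0])


def test_evaluate_reconstruction_bundles_all_metrics(rng):
    # short songs can draw foils nearly identical to the actual sequence,
    # so near-perfect identification (not necessarily 100%) is expected
    song = [880.0, 987.77, 1108.73, 1318.51, 880.0, 987.77, 1174.66,
            1318.51, 1174.66, 987.77, 880.0, 1108.73]
    rec = [f * 2 ** (rng.normal(0, 0.02)) for f in song]
    foils = generate_foils(song, 100, rng_seed=8)
    signal = rng.normal(size=(5, 60))
    report = evaluate_reconstruction(
        rec, song, foils, pred_matrix=signal,
        scan1_matrix=signal + rng.normal(0, 1, signal.shape),
        scan2_matrix=signal + rng.normal(0, 1, signal.shape))
    assert report.identification_correct >= 90
    assert report.actual_r > 0.98
    assert abs(report.mean_cents) < 40
    assert len(report.rrmse_per_voxel) == 5
    assert "identification_correct" in report.to_json()


def test_rrmse_histogram_marks_reference_lines(rng, tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from prftone.evaluation import plot_rrmse_hist
    ax = plot_rrmse_hist(rng.uniform(0.5, 1.2, 200))
    xs = sorted(line.get_xdata()[0] for line in ax.lines)
    assert xs == pytest.approx([1 / np.sqrt(2), 1.0])
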