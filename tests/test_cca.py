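"""CCA solver: oracle equivalence, invariances, decoding behaviour."""

import numpy as np
import pytest

import ffsmvep as fm
from ffsmvep.cca import DegenerateInputError

from conftest import decode_session


def brute_force_cca(X, Y):
    """Independent oracle: explicit generalized-eigenvalue solve.

    First canonical correlation = sqrt of the largest eigenvalue of
    Cxx^-1 Cxy Cyy^-1 Cyx on centred data.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    cxx = Xc @ Xc.T
    cyy = Yc @ Yc.T
    cxy = Xc @ Yc.T
    m = np.linalg.inv(cxx) @ cxy @ np.linalg.inv(cyy) @ cxy.T
    return float(np.sqrt(max(np.linalg.eigvals(m).real.max(), 0.0)))


def test_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(200):
        nx = rng.integers(2, 6)
        ny = rng.integers(2, 5)
        n = int(rng.integers(50, 400))
        X = rng.standard_normal((nx, n))
        Y = rng.standard_normal((ny, n))
        rho, _, _ = fm.canonical_correlation(X, Y)
        assert abs(rho - brute_force_cca(X, Y)) < 1e-8
        worst = max(worst, abs(rho - brute_force_cca(X, Y)))
    assert worst < 1e-8


def test_perfect_linear_dependence_gives_rho_one():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((2, 500))
    mix = np.array([[1.0, 2.0], [3.0, -1.0]])
    rho, _, _ = fm.canonical_correlation(X, mix @ X)
    assert rho == pytest.approx(1.0, abs=1e-9)


def test_white_noise_vs_sinusoids_stays_low():
    """Uncorrelated noise cannot reach a high canonical correlation."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        X = rng.standard_normal((6, 1000))
        ref = fm.build_reference(11.0, 1200.0, 1000, n_harmonics=1)
        rho, _, _ = fm.canonical_correlation(X, ref.matrix)
        assert rho < 0.35


def test_rho_invariant_under_channel_scaling_and_mixing():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((4, 600))
    ref = fm.build_reference(9.0, 1200.0, 600, n_harmonics=2)
    rho0, _, _ = fm.canonical_correlation(X, ref.matrix)
    scaled = np.diag([0.1, 10.0, 3.0, 0.5]) @ X
    rho1, _, _ = fm.canonical_correlation(scaled, ref.matrix)
    mixed = rng.standard_normal((4, 4)) @ X  # invertible w.h.p.
    rho2, _, _ = fm.canonical_correlation(mixed, ref.matrix)
    assert rho1 == pytest.approx(rho0, abs=1e-9)
    assert rho2 == pytest.approx(rho0, abs=1e-8)


def test_reference_matrix_follows_sin_cos_construction():
    ref = fm.build_reference(10.0, 1200.0, 6000, n_harmonics=1)
    assert ref.matrix.shape == (2, 6000)
    assert ref.matrix[0, 0] == pytest.approx(np.sin(2 * np.pi * 10.0 / 1200.0))
    assert ref.matrix[1, 0] == pytest.approx(np.cos(2 * np.pi * 10.0 / 1200.0))
    ref3 = fm.build_reference(10.0, 1200.0, 100, n_harmonics=3)
    assert ref3.matrix.shape == (6, 100)
    n = np.arange(1, 101) / 1200.0
    np.testing.assert_allclose(ref3.matrix[4], np.sin(2 * np.pi * 30.0 * n), atol=1e-12)


def test_reference_harmonic_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        fm.build_reference(100.0, 1200.0, 100, n_harmonics=7)


def test_classify_noise_free_epoch_recovers_frequency(noise_free_config, speller_freqs):
    rec = fm.generate_epoch(noise_free_config, 9.8, seed=0)
    (epoch, _), = fm.extract_epochs(rec, 2.0, 0.150)
    out = fm.classify_epoch(epoch, speller_freqs, 1200.0)
    assert out.predicted_hz == pytest.approx(9.8)
    assert out.rho[np.argmin(np.abs(speller_freqs - 9.8))] == out.rho.max()


def test_duplicate_candidates_tie_breaks_to_first():
    rng = np.random.default_rng(5)
    epoch = rng.standard_normal((500, 3))
    out = fm.classify_epoch(epoch, [8.0, 8.0, 12.0], 1200.0)
    # identical references at indices 0 and 1: argmax must take index 0
    assert out.rho[0] == pytest.approx(out.rho[1], abs=1e-12)
    if out.rho[0] >= out.rho[2]:
        assert out.predicted_hz == 8.0


def test_all_zero_epoch_is_degenerate():
    with pytest.raises(DegenerateInputError):
        fm.classify_epoch(np.zeros((400, 4)), [8.0, 9.0], 1200.0)


def test_coefficient_spectrum_peaks_on_diagonal(noise_free_config):
    stim = [8.0, 10.0, 12.0]
    session = []
    for f in stim:
        rec = fm.generate_epoch(noise_free_config, f, seed=1)
        (epoch, _), = fm.extract_epochs(rec, 2.0, 0.150)
        session.append((epoch, f))
    grid = np.arange(4.0, 30.0, 0.4)
    spec = fm.cca_coefficient_spectrum(session, grid, 1200.0)
    assert spec.rho_matrix.shape == (grid.size, len(stim))
    assert np.all(spec.rho_matrix >= 0) and np.all(spec.rho_matrix <= 1 + 1e-12)
    for j, f in enumerate(stim):
        peak = grid[np.argmax(spec.rho_matrix[:, j])]
        assert peak == pytest.approx(f, abs=0.2)


def test_motion_profile_concentrates_energy_at_fundamental(default_config):
    """Harmonic-to-fundamental rho ratio: motion profile below flicker profile."""
    import dataclasses

    freqs = np.arange(8.0, 14.1, 1.0)
    ratios = {}
    for name, profile in (("ssmvep", fm.SSMVEP_PROFILE), ("ssvep", fm.SSVEP_PROFILE)):
        cfg = dataclasses.replace(default_config, profile=profile)
        session = []
        for i, f in enumerate(freqs):
            rec = fm.generate_epoch(cfg, f, seed=100 + i)
            (epoch, _), = fm.extract_epochs(rec, 2.0, 0.150)
            session.append((epoch, f))
        fund = fm.harmonic_response(session, 1200.0, harmonic=1)
        second = fm.harmonic_response(session, 1200.0, harmonic=2)
        ratios[name] = (second / fund).mean()
    assert ratios["ssmvep"] < ratios["ssvep"]


def test_accuracy_improves_with_snr_and_duration(speller_freqs):
    """Reduced-size monotonicity smoke check (full sweep in acceptance)."""
    freqs = speller_freqs[::8]  # 5-class subproblem
    accs_snr = []
    for scale in (3.0, 1.0, 0.3):
        cfg = fm.SyntheticSessionConfig(
            noise=fm.NoiseModel().scaled(scale), trial_duration_s=1.5
        )
        session = fm.generate_session(cfg, freqs, trials_per_freq=4, seed=11)
        accs_snr.append(decode_session(session, freqs, 1200.0, 1.2))
    assert accs_snr == sorted(accs_snr)
    accs_dur = []
    cfg = fm.SyntheticSessionConfig(noise=fm.NoiseModel().scaled(2.0), trial_duration_s=3.2)
    session = fm.generate_session(cfg, freqs, trials_per_freq=4, seed=12)
    for dur in (0.5, 1.5, 3.0):
        accs_dur.append(decode_session(session, freqs, 1200.0, dur))
    assert accs_dur == sorted(accs_dur)
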