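"""Training-free CCA frequency recognition.

Canonical correlation analysis finds weight vectors ``wx`` and ``wy`` that
maximize the correlation between a linear combination of the multichannel
EEG ``X`` and a linear combination of sinusoidal reference signals ``Y_i``
built at a candidate stimulation frequency ``f_i``:

    rho(f_i) = max_{wx, wy} corr(wx' X, wy' Y_i).

The candidate with the largest canonical correlation is the recognized
frequency.  For motion (SSMVEP) stimulation the references are a single
sin/cos pair at the stimulus frequency, because the evoked response
concentrates at the fundamental; harmonic pairs can be added for
harmonic-rich (flicker SSVEP) responses.

The solver uses the SVD-subspace formulation: with centred, sample-major
matrices X' = U_x S_x V_x' and Y' = U_y S_y V_y', the canonical
correlations are the singular values of U_x' U_y restricted to the
significant singular subspaces.  This is numerically stabler than
inverting covariance blocks and absorbs rank-deficient (collinear-channel)
inputs without explicit regularization; only zero-variance inputs are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
__all__ = [
    "ReferenceSet",
    "CCAOutcome",
    "CCASpectrum",
    "build_reference",
    "canonical_correlation",
    "classify_epoch",
    "cca_coefficient_spectrum",
    "harmonic_response",
]


class DegenerateInputError(ValueError):
    """Raised when an input set has no variance (e.g. an all-zero epoch)."""


@dataclass
class ReferenceSet:
    """Sin/cos reference matrix for one candidate frequency.

    Rows alternate sin/cos per harmonic: row ``2h-2`` is
    ``sin(2 pi h f n)`` and row ``2h-1`` is ``cos(2 pi h f n)`` for
    ``n = 1/Fs, 2/Fs, ..., K/Fs``.
    """

    f_hz: float
    fs_hz: float
    n_samples: int
    n_harmonics: int
    matrix: np.ndarray  # (2 * n_harmonics, n_samples)


@dataclass
class CCAOutcome:
    """Decoding result for one epoch over a candidate-frequency grid."""

    candidate_freqs_hz: np.ndarray
    rho: np.ndarray  # canonical correlation per candidate
    predicted_hz: float
    wx: np.ndarray  # channel weights at the winning candidate
    wy: np.ndarray  # reference weights at the winning candidate


@dataclass
class CCASpectrum:
    """rho at every (stimulation frequency, response frequency) pair."""

    stim_freqs_hz: np.ndarray
    response_freqs_hz: np.ndarray
    rho_matrix: np.ndarray  # (n_response, n_stim)


def build_reference(
    f_hz: float, fs_hz: float, n_samples: int, n_harmonics: int = 1
) -> ReferenceSet:
    """Sin/cos pairs at ``f_hz`` and its harmonics, sampled at n = k/Fs.

    The time base starts at ``1/Fs`` (not 0).  Single-harmonic references
    (the default) are the motion-stimulation contract: the evoked response
    carries no usable harmonics, so none are modelled.
    """
    if f_hz <= 0:
        raise ValueError("f_hz must be > 0")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if f_hz * n_harmonics >= fs_hz / 2:
        raise ValueError(
            f"harmonic {n_harmonics} of {f_hz} Hz is at or above Nyquist ({fs_hz / 2} Hz)"
        )
    n = np.arange(1, n_samples + 1) / fs_hz
    rows = []
    for h in range(1, n_harmonics + 1):
        arg = 2.0 * np.pi * h * f_hz * n
        rows.append(np.sin(arg))
        rows.append(np.cos(arg))
    return ReferenceSet(f_hz, fs_hz, n_samples, n_harmonics, np.vstack(rows))


def _center_rows(a: np.ndarray, name: str) -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    ac = a - a.mean(axis=1, keepdims=True)
    if not np.any(ac):
        raise DegenerateInputError(f"{name} has zero variance")
    return ac


def canonical_correlation(X, Y) -> tuple[float, np.ndarray, np.ndarray]:
    """First canonical correlation between two multivariate signal sets.

    Parameters
    ----------
    X, Y : arrays of shape (n_dims, n_samples)
        Variable sets with samples along the second axis (channels x
        samples for EEG, reference rows x samples for the templates).
        Rows are centred internally.

    Returns
    -------
    rho : float in [0, 1]
    wx, wy : weight vectors achieving the maximum correlation.
    """
    Xc = _center_rows(X, "X")
    Yc = _center_rows(Y, "Y")
    if Xc.shape[1] != Yc.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    n = Xc.shape[1]
    if n < Xc.shape[0] + Yc.shape[0]:
        raise ValueError("need at least as many samples as combined dimensions")

    ux, sx, vxt = np.linalg.svd(Xc.T, full_matrices=False)
    uy, sy, vyt = np.linalg.svd(Yc.T, full_matrices=False)
    # canonical correlations depend only on the column spaces: project onto
    # the significant left-singular subspaces, which absorbs rank-deficient
    # (collinear-channel) inputs without explicit regularization
    keep_x = sx > max(Xc.shape) * np.finfo(float).eps * sx[0]
    keep_y = sy > max(Yc.shape) * np.finfo(float).eps * sy[0]
    u, s, vt = np.linalg.svd(ux[:, keep_x].T @ uy[:, keep_y])
    rho = float(np.clip(s[0], 0.0, 1.0))
    wx = vxt.T[:, keep_x] @ (u[:, 0] / sx[keep_x])
    wy = vyt.T[:, keep_y] @ (vt[0, :] / sy[keep_y])
    return rho, wx, wy


def classify_epoch(
    epoch: np.ndarray,
    candidate_freqs,
    fs_hz: float,
    n_harmonics: int = 1,
) -> CCAOutcome:
    """Recognize the stimulation frequency of one epoch.

    Parameters
    ----------
    epoch : array (n_samples, n_channels)
        Time-major multichannel epoch (the layout produced by
        :func:`ffsmvep.preprocessing.extract_epochs`).
    candidate_freqs : iterable of float
        Candidate stimulation frequencies; ties in rho resolve to the
        earliest (lowest, when sorted ascending) candidate.
    """
    freqs = np.asarray(list(candidate_freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("candidate_freqs must be non-empty")
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    X = epoch.T  # channels x samples
    if not np.any(X - X.mean(axis=1, keepdims=True)):
        raise DegenerateInputError("epoch has zero variance")
    n_samples = X.shape[1]
    rhos = np.empty(freqs.size)
    weights: list[tuple[np.ndarray, np.ndarray]] = []
    for i, f in enumerate(freqs):
        ref = build_reference(f, fs_hz, n_samples, n_harmonics)
        rho, wx, wy = canonical_correlation(X, ref.matrix)
        rhos[i] = rho
        weights.append((wx, wy))
    best = int(np.argmax(rhos))  # first occurrence wins ties
    return CCAOutcome(freqs, rhos, float(freqs[best]), *weights[best])


def cca_coefficient_spectrum(
    session,
    response_freq_grid,
    fs_hz: float,
) -> CCASpectrum:
    """rho between each stimulation epoch and single-harmonic references
    over a grid of response frequencies.

    ``session`` is an iterable of ``(epoch, stim_freq_hz)`` pairs with one
    epoch (samples x channels) per stimulation frequency.  Columns follow
    the stimulation axis, rows the response axis.
    """
    pairs = [(np.atleast_2d(np.asarray(e, dtype=float)), float(f)) for e, f in session]
    stim = np.array([f for _, f in pairs])
    grid = np.asarray(list(response_freq_grid), dtype=float)
    rho = np.empty((grid.size, stim.size))
    for j, (epoch, _) in enumerate(pairs):
        X = epoch.T
        n_samples = X.shape[1]
        for i, f in enumerate(grid):
            ref = build_reference(f, fs_hz, n_samples, n_harmonics=1)
            rho[i, j] = canonical_correlation(X, ref.matrix)[0]
    return CCASpectrum(stim, grid, rho)


def harmonic_response(session, fs_hz: float, harmonic: int = 1) -> np.ndarray:
    """rho at ``harmonic x f_stim`` for each epoch of a session.

    Evaluating the references directly at each harmonic of the true
    stimulation frequency gives the frequency-response curves from which
    the harmonic-to-fundamental contrast between motion and flicker
    stimulation is measured.
    """
    out = []
    for epoch, f in session:
        X = np.atleast_2d(np.asarray(epoch, dtype=float)).T
        ref = build_reference(harmonic * float(f), fs_hz, X.shape[1], n_harmonics=1)
        out.append(canonical_correlation(X, ref.matrix)[0])
    return np.asarray(out)
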