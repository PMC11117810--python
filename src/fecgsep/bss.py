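"""Blind source separation of two-channel ECG by whitening + fixed-point ICA.

The observation model is instantaneous and linear, ``x(k) = H s(k)`` with
two sensors and two sources; separation estimates an unmixing matrix ``W``
such that ``y(k) = W x(k)`` recovers the sources up to permutation and
scale.  Preprocessing centers each channel and whitens the pair (zero mean,
identity covariance), after which the remaining indeterminacy is a rotation
found by maximizing non-Gaussianity with a symmetric (parallel) fixed-point
update: every iteration updates both rows and re-orthonormalizes them
jointly via ``B <- (B B^T)^{-1/2} B``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm
from scipy.signal import find_peaks

from .errors import DegenerateInputError, InvalidArgumentError, NotWhitenedError

__all__ = [
    "EcgRecord",
    "WhiteningTransform",
    "IcaOptions",
    "SeparationResult",
    "center",
    "whiten",
    "ica_symmetric",
    "resolve_labels",
    "separate",
]


@dataclass
class EcgRecord:
    """A two-channel sampled voltage record (row 0 thorax, row 1 abdomen)."""

    channels: np.ndarray  # 2 x T, mV
    fs: float  # Hz
    labels: tuple[str, str] = ("thorax", "abdomen")

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 2:
            raise InvalidArgumentError("record must have exactly 2 channel rows")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be > 0")
        if not np.all(np.isfinite(self.channels)):
            raise InvalidArgumentError("record contains non-finite samples")
        self.labels = tuple(self.labels)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map taking raw channels to zero-mean, identity-covariance
    coordinates: ``z = V (x - mean)``."""

    mean: np.ndarray  # per-channel, mV
    V: np.ndarray  # 2x2
    V_inv: np.ndarray  # 2x2


@dataclass(frozen=True)
class IcaOptions:
    """Knobs of the symmetric fixed-point ICA stage."""

    contrast: str = "tanh"  # "tanh" or "kurtosis"
    tol: float = 1e-8
    max_iter: int = 500
    seed: int | None = None  # None -> deterministic identity start


@dataclass
class SeparationResult:
    """Separation output: ``y = W (x - mean)`` with labelled rows."""

    W: np.ndarray  # 2x2 unmixing, original (unwhitened) coordinates
    mean: np.ndarray  # per-channel means removed before unmixing
    sources: np.ndarray  # 2 x T estimated y(k)
    labels: tuple[str, str]  # per-row, permutation of ("mECG", "fECG")
    H_est: np.ndarray  # 2x2 estimated mixing = W^{-1}
    iterations: int
    converged: bool

    def source(self, label: str) -> np.ndarray:
        """Row of ``sources`` carrying the given label ("mECG" or "fECG")."""
        return self.sources[self.labels.index(label)]


def center(record: EcgRecord) -> tuple[EcgRecord, np.ndarray]:
    """Remove each channel's mean; returns the centered record and means."""
    if not np.all(np.isfinite(record.channels)):
        raise InvalidArgumentError("record contains non-finite samples")
    means = record.channels.mean(axis=1)
    centered = record.channels - means[:, None]
    return EcgRecord(centered, record.fs, record.labels), means


def whiten(record: EcgRecord) -> tuple[np.ndarray, WhiteningTransform]:
    """Whiten a centered record via eigendecomposition of the sample
    covariance: ``V = D^{-1/2} E^T`` so ``cov(V x) = I``.

    Raises :class:`DegenerateInputError` when the channels are (close to)
    proportional and the covariance is numerically rank-deficient.
    """
    x = record.channels
    means = x.mean(axis=1)
    x = x - means[:, None]
    T = x.shape[1]
    cov = (x @ x.T) / T
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-300):
        raise DegenerateInputError(
            f"channels {record.labels} are proportional or constant: "
            f"covariance eigenvalues {evals.tolist()}"
        )
    V = np.diag(evals**-0.5) @ evecs.T
    V_inv = evecs @ np.diag(evals**0.5)
    z = V @ x
    return z, WhiteningTransform(mean=means, V=V, V_inv=V_inv)


def _contrast_funcs(name: str):
    if name == "tanh":
        return np.tanh, lambda u: 1.0 - np.tanh(u) ** 2
    if name == "kurtosis":
        return lambda u: u**3, lambda u: 3.0 * u**2
    raise InvalidArgumentError(f"unknown contrast {name!r} (use 'tanh' or 'kurtosis')")


def _sym_decorrelate(B: np.ndarray) -> np.ndarray:
    # B <- (B B^T)^{-1/2} B ; sqrtm of a 2x2 SPD matrix is exact enough here
    M = np.real(sqrtm(B @ B.T))
    return np.linalg.solve(M, B)


def ica_symmetric(
    whitened: np.ndarray,
    contrast: str = "tanh",
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Estimate the 2x2 orthogonal unmixing rotation of whitened data.

    Fixed-point update per row ``b``: ``b <- E[z g(b.z)] - E[g'(b.z)] b``
    with ``g`` the chosen contrast nonlinearity, followed every iteration by
    symmetric decorrelation of the whole matrix.  Convergence is declared
    when ``max_i |1 - |<b_i_new, b_i_old>||`` drops below ``tol``.

    Returns ``(B, iterations, converged)``; non-convergence warns rather
    than raises (short records may oscillate near the optimum).
    """
    z = np.asarray(whitened, dtype=float)
    if z.ndim != 2 or z.shape[0] != 2:
        raise InvalidArgumentError("whitened data must be 2 x T")
    if tol <= 0 or max_iter < 1:
        raise InvalidArgumentError("tol must be > 0 and max_iter >= 1")
    T = z.shape[1]
    cov = (z @ z.T) / T
    if np.max(np.abs(cov - np.eye(2))) > 1e-4:
        raise NotWhitenedError(
            "input covariance deviates from identity by "
            f"{np.max(np.abs(cov - np.eye(2))):.3g} (> 1e-4); whiten first"
        )
    g, g_prime = _contrast_funcs(contrast)

    if seed is None:
        B = np.eye(2)
    else:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        B = q
    B = _sym_decorrelate(B)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = B @ z  # projections, 2 x T
        B_new = (g(u) @ z.T) / T - np.diag(g_prime(u).mean(axis=1)) @ B
        B_new = _sym_decorrelate(B_new)
        delta = np.max(np.abs(1.0 - np.abs(np.sum(B_new * B, axis=1))))
        B = B_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"symmetric ICA did not converge in {max_iter} iterations "
            f"(last delta {delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return B, it, converged


def _approx_beat_rate(x: np.ndarray, fs: float) -> float:
    """Crude beats-per-minute estimate used only for label tie-breaking."""
    r = np.abs(x)
    thr = r.mean() + 0.6 * (r.max() - r.mean())
    peaks, _ = find_peaks(r, height=thr, distance=max(1, int(0.2 * fs)))
    return len(peaks) * 60.0 * fs / len(x)


def resolve_labels(
    sources: np.ndarray, record: EcgRecord
) -> tuple[tuple[str, str], np.ndarray]:
    """Resolve ICA's permutation and sign ambiguity.

    Each estimated source is sign-flipped so its largest-magnitude sample is
    positive (R-peak up).  The source more correlated in magnitude with the
    thorax channel — which is maternal-dominant — is labelled ``mECG``, the
    other ``fECG``; near-ties (correlation gap < 0.01) fall back to beat
    rate, the faster train being fetal.
    """
    y = np.array(sources, dtype=float, copy=True)
    if y.ndim != 2 or y.shape[0] != 2:
        raise InvalidArgumentError("expected 2 estimated sources")
    stds = y.std(axis=1)
    if np.any(stds == 0):
        raise DegenerateInputError("zero-variance estimated source")
    for i in range(2):
        if y[i, np.argmax(np.abs(y[i]))] < 0:
            y[i] = -y[i]

    thorax = record.channels[0]
    rho = np.array(
        [abs(np.corrcoef(y[i], thorax)[0, 1]) for i in range(2)]
    )
    if abs(rho[0] - rho[1]) < 0.01:
        rates = [_approx_beat_rate(y[i], record.fs) for i in range(2)]
        fetal_row = int(np.argmax(rates))
    else:
        fetal_row = int(np.argmin(rho))
    labels = tuple("fECG" if i == fetal_row else "mECG" for i in range(2))
    return labels, y


def separate(record: EcgRecord, options: IcaOptions | None = None) -> SeparationResult:
    """Full separation chain: center -> whiten -> symmetric ICA -> labels.

    ``W = B V`` maps centered observations to estimated sources;
    ``H_est = W^{-1}`` estimates the mixing.  Deterministic for a given
    record and options.
    """
    options = options or IcaOptions()
    centered, means = center(record)
    z, wt = whiten(centered)
    B, iterations, converged = ica_symmetric(
        z,
        contrast=options.contrast,
        tol=options.tol,
        max_iter=options.max_iter,
        seed=options.seed,
    )
    W = B @ wt.V
    y = W @ centered.channels
    labels, y_fixed = resolve_labels(y, record)
    # propagate the sign fixes into W so y = W (x - mean) stays exact
    signs = np.array(
        [1.0 if np.allclose(y_fixed[i], y[i]) else -1.0 for i in range(2)]
    )
    W = signs[:, None] * W
    H_est = np.linalg.inv(W)
    return SeparationResult(
        W=W,
        mean=means,
        sources=y_fixed,
        labels=labels,
        H_est=H_est,
        iterations=iterations,
        converged=converged,
    )
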