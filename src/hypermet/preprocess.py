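"""Multicoil preprocessing: noise covariance, prewhitening, combination, phasing.

The raw data are per-coil complex dynamic images.  Signal-free samples
(end-of-scan pyruvate frames, or appended pure-noise frames in the
phantom) give the coil noise covariance; prewhitening by its inverse
Cholesky factor makes coil noise i.i.d. unit-variance; an SVD-based
combination with sensitivities estimated from the highest-SNR (pyruvate)
channel then collapses the coil axis; finally a per-voxel zeroth-order
phase rotation yields a real-valued, magnitude-like series whose noise
floor stays zero-mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import CHANNELS, AcquisitionProtocol

__all__ = [
    "CoilStack",
    "DynamicSeries",
    "NoiseCovariance",
    "estimate_noise_covariance",
    "prewhiten",
    "coil_combine",
    "phase_correct",
]


@dataclass
class CoilStack:
    """Per-coil complex dynamic images plus signal-free noise samples.

    ``data`` is indexed ``(coil, row, col, slice, frame, channel)``;
    ``noise_samples`` is ``(coil, sample)`` drawn from signalless frames.
    """

    data: np.ndarray
    noise_samples: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.data.ndim != 6:
            raise ValueError("data must be (coil, row, col, slice, frame, channel)")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one coil")
        if self.noise_samples.ndim != 2 or self.noise_samples.shape[0] != self.data.shape[0]:
            raise ValueError("noise_samples must be (coil, sample)")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class DynamicSeries:
    """Coil-combined per-channel space-time data.

    ``data`` is ``(row, col, slice, frame, channel)``; complex after
    combination, real after phasing.  Synthetic series carry their
    ground truth in ``truth``.
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS
    protocol: AcquisitionProtocol | None = None
    truth: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("data must be (row, col, slice, frame, channel)")

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channel_names.index(name)]


@dataclass(frozen=True)
class NoiseCovariance:
    """Sample coil noise covariance (Hermitian PSD) and its sample count."""

    matrix: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.conj().T, atol=1e-10 * max(1.0, float(np.abs(m).max()))):
            raise ValueError("covariance must be Hermitian")


def estimate_noise_covariance(noise_samples: np.ndarray) -> NoiseCovariance:
    """Sample covariance of complex coil noise across signal-free samples."""
    x = np.asarray(noise_samples)
    if x.ndim != 2:
        raise ValueError("noise samples must be (coil, sample)")
    ncoil, nsamp = x.shape
    if nsamp < 2:
        raise ValueError("need at least 2 noise samples per coil")
    if nsamp < ncoil:
        warnings.warn(
            f"only {nsamp} noise samples for {ncoil} coils: covariance is rank-deficient",
            stacklevel=2,
        )
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.conj().T / (nsamp - 1)
    cov = 0.5 * (cov + cov.conj().T)  # Hermitian by construction
    return NoiseCovariance(cov, nsamp)


def _whitener(cov: NoiseCovariance, diagonal_loading: float = 1e-6) -> np.ndarray:
    m = cov.matrix.astype(complex)
    n = m.shape[0]
    load = diagonal_loading * np.trace(m).real / n
    m = m + load * np.eye(n)
    try:
        chol = np.linalg.cholesky(m)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "noise covariance is singular; provide more noise samples or "
            "increase diagonal loading"
        ) from err
    return np.linalg.inv(chol)


def prewhiten(
    stack: CoilStack, cov: NoiseCovariance, diagonal_loading: float = 1e-6
) -> CoilStack:
    """Decorrelate coil noise: multiply the coil axis by inv(chol(cov)).

    After whitening, the re-estimated covariance of the transformed noise
    samples is approximately the identity.  ``diagonal_loading`` (times
    ``trace/n``) stabilizes the Cholesky factorization.
    """
    w = _whitener(cov, diagonal_loading)
    data = np.einsum("ij,j...->i...", w, stack.data)
    noise = w @ stack.noise_samples
    return CoilStack(data=data, noise_samples=noise, channel_names=stack.channel_names)


def coil_combine(
    stack: CoilStack,
    weight_channel: str = "pyruvate",
    protocol: AcquisitionProtocol | None = None,
) -> DynamicSeries:
    """SVD-based combination of the (prewhitened) coil stack.

    Per voxel, the sensitivity direction is the dominant eigenvector of
    the coil x coil outer-product of the highest-SNR channel's coil x
    frame matrix; the unit-norm conjugate weights are applied to every
    channel, so the low-SNR metabolite channels inherit pyruvate-derived
    sensitivities.  All-zero voxels combine to exactly zero.
    """
    ci = stack.channel_index(weight_channel)
    d = stack.data  # (coil, R, C, S, F, ch)
    ref = np.moveaxis(d[..., ci], 0, -2)  # (R, C, S, coil, F)
    # coil x coil outer product per voxel; Hermitian, batched eigh
    outer = ref @ ref.conj().swapaxes(-1, -2)
    vals, vecs = np.linalg.eigh(outer)
    w = vecs[..., -1]  # dominant eigenvector, unit norm, (R, C, S, coil)
    # voxels with no reference signal: deterministic uniform weights
    # (keeps the combination coil-permutation invariant there)
    energy = np.einsum("...ii->...", outer).real
    ncoil = d.shape[0]
    w = np.where(energy[..., None] > 0, w, 1.0 / np.sqrt(ncoil))
    # deterministic phase convention: largest-|.| component real positive
    idx = np.argmax(np.abs(w), axis=-1, keepdims=True)
    piv = np.take_along_axis(w, idx, axis=-1)
    phase = np.where(np.abs(piv) > 0, piv / np.where(np.abs(piv) > 0, np.abs(piv), 1.0), 1.0)
    w = w * phase.conj()
    combined = np.einsum("xyzc,cxyzfk->xyzfk", w.conj(), d)
    return DynamicSeries(
        data=combined,
        channel_names=stack.channel_names,
        protocol=protocol,
        meta={"combine_weights": w},
    )


def phase_correct(series: DynamicSeries) -> DynamicSeries:
    """Per-voxel, per-channel zeroth-order phasing; returns the real channel.

    The phase is chosen to make the temporal-peak frame real positive;
    zero voxels pass through unchanged, and the noise floor in signal-free
    regions remains zero-mean (the rotation is unitary).
    """
    d = series.data
    if not np.iscomplexobj(d):
        return DynamicSeries(
            data=d.astype(float),
            channel_names=series.channel_names,
            protocol=series.protocol,
            truth=series.truth,
            meta=dict(series.meta),
        )
    peak = np.argmax(np.abs(d), axis=3)  # over frames, (R, C, S, ch)
    pv = np.take_along_axis(d, peak[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    mag = np.abs(pv)
    rot = np.where(mag > 0, np.conj(pv) / np.where(mag > 0, mag, 1.0), 1.0)
    out = (d * rot[:, :, :, None, :]).real
    return DynamicSeries(
        data=out,
        channel_names=series.channel_names,
        protocol=series.protocol,
        truth=series.truth,
        meta=dict(series.meta),
    )
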