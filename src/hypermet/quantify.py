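"""Signal maps, AUC ratios, doublet QC metrics, SNR filters and masking.

Area-under-curve (AUC) images are per-voxel sums of the dynamic signal
over the timeframes; metabolite-to-pyruvate AUC ratios act as surrogate
conversion measures.  The separately acquired lactate doublet peaks are
summed into a total lactate image after agreement QC (Pearson r and SSIM
between the downfield and upfield AUC images).  Brain voxels enter the
whole-volume statistics only if their gray+white-matter fraction exceeds
0.40, and ratio/rate voxels additionally require SNR of the AUC above 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from skimage.metrics import structural_similarity

__all__ = [
    "AUCMaps",
    "BrainMask",
    "auc_map",
    "normalize_to_peak_pyruvate",
    "sum_lactate_doublet",
    "doublet_agreement",
    "snr_auc_map",
    "make_brain_mask",
    "apply_brain_mask",
    "zero_fill",
]

GM_WM_MIN_FRACTION = 0.40
SNR_AUC_MIN = 3.0


@dataclass(frozen=True)
class BrainMask:
    include: np.ndarray  # boolean, (row, col, slice)
    gm_wm_fraction: np.ndarray


@dataclass
class AUCMaps:
    """Per-channel AUC images, voxelwise ratios and SNR_AUC maps."""

    auc: dict[str, np.ndarray]
    snr_auc: dict[str, np.ndarray] = field(default_factory=dict)
    ratios: dict[str, np.ndarray] = field(default_factory=dict)


def auc_map(series: np.ndarray) -> np.ndarray:
    """Sum the dynamic series through time: (..., frame) -> (...)."""
    series = np.asarray(series)
    if series.shape[-1] < 1:
        raise ValueError("need at least one frame")
    return series.sum(axis=-1)


def normalize_to_peak_pyruvate(series_by_channel: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Divide every channel by the global (all voxels, frames) pyruvate peak."""
    if "pyruvate" not in series_by_channel:
        raise ValueError("pyruvate channel required for normalization")
    peak = float(np.max(series_by_channel["pyruvate"]))
    if peak <= 0:
        raise ValueError("pyruvate channel is all zero; cannot normalize")
    return {k: np.asarray(v) / peak for k, v in series_by_channel.items()}


def sum_lactate_doublet(down: np.ndarray, up: np.ndarray) -> np.ndarray:
    """Total lactate: voxelwise sum of the two separately acquired peaks."""
    down = np.asarray(down)
    up = np.asarray(up)
    if down.shape != up.shape:
        raise ValueError("doublet images must share shape")
    return down + up


def doublet_agreement(
    down_auc: np.ndarray, up_auc: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """(Pearson r, SSIM) between the downfield and upfield AUC images.

    r is computed over the masked voxels pooled across slices.  SSIM uses
    the standard constants (K1=0.01, K2=0.03, 11x11 Gaussian window of
    sigma 1.5, dynamic range = joint maximum), evaluated per slice and
    averaged over masked pixels.  A constant image makes r undefined; it
    is returned as NaN with a warning while SSIM is still reported.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 masked voxels")
    d = np.asarray(down_auc, dtype=float)
    u = np.asarray(up_auc, dtype=float)
    dv, uv = d[mask], u[mask]
    if np.ptp(dv) == 0 or np.ptp(uv) == 0:
        warnings.warn("constant image: Pearson r undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(pearsonr(dv, uv)[0])
    rng_val = float(max(d.max(), u.max()) - min(d.min(), u.min()))
    if rng_val == 0:
        return r, 1.0
    # 11x11 Gaussian window (sigma 1.5, truncated at 3.5 sigma), shrunk to
    # the largest odd size that fits small fixtures
    win = min(11, d.shape[0], d.shape[1])
    win -= 1 - win % 2
    vals = []
    wts = []
    for s in range(d.shape[2]):
        if not mask[:, :, s].any():
            continue
        _, ssim_map = structural_similarity(
            d[:, :, s],
            u[:, :, s],
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=rng_val,
            win_size=win,
            full=True,
        )
        vals.append(float(ssim_map[mask[:, :, s]].mean()))
        wts.append(int(mask[:, :, s].sum()))
    ssim = float(np.average(vals, weights=wts))
    return r, ssim


def snr_auc_map(auc: np.ndarray, noise_sigma: float, n_frames: int) -> np.ndarray:
    """SNR of the AUC image: AUC / (sigma * sqrt(n_frames)).

    The AUC of white noise with per-frame std sigma has std
    sigma*sqrt(n); ``noise_sigma == 0`` (noiseless data) yields +inf
    wherever the AUC is nonzero.
    """
    auc = np.asarray(auc, dtype=float)
    if noise_sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    denom = noise_sigma * np.sqrt(n_frames)
    if denom == 0:
        out = np.where(auc != 0, np.inf, 0.0)
        return out
    return auc / denom


def make_brain_mask(gm_wm_fraction: np.ndarray, threshold: float = GM_WM_MIN_FRACTION) -> BrainMask:
    f = np.asarray(gm_wm_fraction, dtype=float)
    return BrainMask(include=f > threshold, gm_wm_fraction=f)


def apply_brain_mask(maps: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Zero (or ``fill``) voxels outside the gray+white-matter mask."""
    m = np.asarray(maps, dtype=float)
    return np.where(mask.include, m, fill)


def zero_fill(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Fourier zero-padding interpolation for display only.

    Upsamples the two in-plane axes by ``factor``; never used in
    quantification.
    """
    im = np.asarray(image, dtype=float)
    nr, nc = im.shape[:2]
    k = np.fft.fftshift(np.fft.fft2(im, axes=(0, 1)), axes=(0, 1))
    pr = (factor - 1) * nr
    pc = (factor - 1) * nc
    pad = [(pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)] + [(0, 0)] * (im.ndim - 2)
    kz = np.pad(k, pad)
    out = np.fft.ifft2(np.fft.ifftshift(kz, axes=(0, 1)), axes=(0, 1)).real
    return out * factor**2
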