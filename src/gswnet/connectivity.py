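"""Imaginary part of coherency between source (ROI) time courses.

Complex coherency ``C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f))`` is estimated
with Welch-averaged cross-spectra (1-s Hann segments, 50% overlap, giving
1 Hz resolution so the analysis frequencies 1–12 Hz map to integer bins).
Cross-spectra are pooled over all segments of all epochs of a state before
the division.

The imaginary part of coherency vanishes for any zero-lag (instantaneous)
mixture of sources, which makes it insensitive to volume conduction; only
phase-lagged interactions survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ConnectivityTensor",
    "coherency",
    "imaginary_coherence_matrix",
    "DEFAULT_FREQS",
]

DEFAULT_FREQS = tuple(range(1, 13))


@dataclass
class ConnectivityTensor:
    """Signed ImCoh, subjects x frequencies x nodes x nodes.

    Antisymmetric in the node indices (ImCoh_ij = -ImCoh_ji), zero diagonal,
    all magnitudes <= 1.  ``state`` is "GSW" or "RS".
    """

    values: np.ndarray
    freqs: tuple[int, ...]
    state: str
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (subjects, freqs, nodes, nodes)")
        if np.max(np.abs(self.values), initial=0.0) > 1 + 1e-9:
            raise ValueError("|ImCoh| must not exceed 1")
        if not self.node_labels:
            self.node_labels = [f"n{i}" for i in range(self.values.shape[-1])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def magnitude(self, subject: int, freq: int) -> np.ndarray:
        """|ImCoh| matrix for one subject at one analysis frequency (Hz)."""
        return np.abs(self.values[subject, self.freqs.index(freq)])


def _segment_fft(data: np.ndarray, fs: float, nperseg: int,
                 noverlap: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered segment FFTs.

    ``data`` is (..., samples); returns (freqs, X) with X shaped
    (..., n_segments, n_freqs).
    """
    n = data.shape[-1]
    if nperseg > n:
        raise ValueError("segment longer than the data")
    step = nperseg - noverlap
    n_seg = 1 + (n - nperseg) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = data[..., idx]                       # (..., n_seg, nperseg)
    win = signal.windows.hann(nperseg, sym=False)
    segs = (segs - segs.mean(axis=-1, keepdims=True)) * win
    X = np.fft.rfft(segs, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    return freqs, X


def coherency(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    freqs: tuple[float, ...] = DEFAULT_FREQS,
    seg_len: float = 1.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Complex coherency of two equal-length series at the given frequencies.

    Welch cross- and auto-spectra with Hann segments of ``seg_len`` seconds
    and fractional ``overlap``; zero-power bins yield 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if max(freqs) >= fs / 2:
        raise ValueError("requested frequency at/above Nyquist")
    stacked = np.stack([x, y])
    tensor = imaginary_coherence_matrix(
        stacked[None], fs, freqs=tuple(freqs), seg_len=seg_len,
        overlap=overlap, return_complex=True)
    return tensor[:, 0, 1]


def imaginary_coherence_matrix(
    roi_activity: np.ndarray,
    fs: float,
    freqs: tuple[int, ...] = DEFAULT_FREQS,
    seg_len: float = 1.0,
    overlap: float = 0.5,
    return_complex: bool = False,
) -> np.ndarray:
    """All-pairs ImCoh from epoched node signals.

    ``roi_activity`` is epochs x nodes x samples.  Cross-spectra are averaged
    over every segment of every epoch before forming coherency, then the
    imaginary part is taken; the diagonal is forced to zero.  Returns an
    array of shape (n_freqs, nodes, nodes) — the per-subject slice of a
    :class:`ConnectivityTensor` — or complex coherency when
    ``return_complex`` is set.
    """
    act = np.asarray(roi_activity, dtype=float)
    if act.ndim != 3:
        raise ValueError("roi_activity must be epochs x nodes x samples")
    if act.shape[0] < 1 or act.shape[1] < 2:
        raise ValueError("need >= 1 epoch and >= 2 nodes")
    if act.shape[2] < 2:
        raise ValueError("epochs of a single sample carry no spectrum")

    nperseg = int(round(seg_len * fs))
    noverlap = int(round(nperseg * overlap))
    fgrid, X = _segment_fft(act, fs, nperseg, noverlap)
    # pool epoch and segment axes: (nodes, pooled_segments, n_freqs)
    X = np.moveaxis(X, 1, 0).reshape(act.shape[1], -1, fgrid.size)

    bins = np.array([int(np.argmin(np.abs(fgrid - f))) for f in freqs])
    Xb = X[:, :, bins]                               # (nodes, segs, nf)
    S = np.einsum("isf,jsf->fij", Xb, np.conj(Xb)) / Xb.shape[1]
    power = np.real(np.einsum("fii->fi", S))
    denom = np.sqrt(power[:, :, None] * power[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(denom == 0):
        import warnings
        warnings.warn("zero-power bin: coherency set to 0", stacklevel=2)
    n = act.shape[1]
    C[:, np.arange(n), np.arange(n)] = 1.0 if return_complex else 0.0
    if return_complex:
        return C
    out = np.imag(C)
    out[:, np.arange(n), np.arange(n)] = 0.0
    return out


def subject_tensor(
    per_subject_slices: list[np.ndarray],
    freqs: tuple[int, ...],
    state: str,
    node_labels: list[str] | None = None,
) -> ConnectivityTensor:
    """Stack per-subject (n_freqs, n, n) ImCoh slices into a tensor."""
    values = np.stack(per_subject_slices)
    return ConnectivityTensor(values, tuple(freqs), state,
                              node_labels or [])
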