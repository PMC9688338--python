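"""Distributed source estimation with sLORETA and max-energy ROI selection.

The inverse operator is the classical standardized minimum-norm solution:
with gain matrix ``G`` (sensors x sources) and noise covariance ``C``, the
minimum-norm kernel is ``K = G' (G G' + λ C)^-1`` and the current estimate
``ĵ = K d``.  sLORETA standardizes each source by the square root of the
corresponding diagonal element of the resolution matrix ``K G``, which gives
the method its zero-localization-error property for a single noiseless
source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LeadField",
    "NoiseCovariance",
    "SourceEstimate",
    "RoiSet",
    "estimate_noise_covariance",
    "average_reference_gain",
    "sloreta_solve",
    "select_rois",
]


@dataclass
class LeadField:
    """Sensors x sources gain matrix (µV per unit dipole moment)."""

    gain: np.ndarray
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D (sensors x sources)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")
        if not self.source_ids:
            self.source_ids = [f"src{i}" for i in range(self.gain.shape[1])]
        if len(self.source_ids) != self.gain.shape[1]:
            raise ValueError("source id count must equal source count")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class NoiseCovariance:
    """Symmetric positive semi-definite sensor covariance (µV²)."""

    cov: np.ndarray

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim != 2 or self.cov.shape[0] != self.cov.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass
class SourceEstimate:
    """Standardized current density, sources x samples (dimensionless)."""

    activity: np.ndarray
    fs: float
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("source activity must be finite")


@dataclass
class RoiSet:
    """Winning source per event plus region labels.

    ``rois`` maps the winning source index to (region label, multiplicity —
    how many events that source won).
    """

    rois: dict[int, tuple[str, int]]
    label_map: dict[int, str]

    @property
    def indices(self) -> list[int]:
        return sorted(self.rois)

    @property
    def labels(self) -> list[str]:
        return [self.rois[i][0] for i in self.indices]


def average_reference_gain(lf: LeadField) -> LeadField:
    """Re-reference the lead field to the common average.

    When the sensor data have been average-referenced, the effective forward
    model is the gain matrix with its per-source sensor mean removed; using
    the unreferenced gain instead introduces substantial source crosstalk in
    the inverse.
    """
    g = lf.gain - lf.gain.mean(axis=0, keepdims=True)
    return LeadField(g, list(lf.source_ids))


def estimate_noise_covariance(
    rs_data: np.ndarray,
    loading: float = 1e-6,
) -> NoiseCovariance:
    """Sample covariance across time of a resting epoch, diagonally loaded.

    ``rs_data`` is channels x samples (or epochs x channels x samples, in
    which case covariances are averaged over epochs).  Diagonal loading of
    ``loading * trace / n_channels`` guarantees positive definiteness, which
    matters because average-referenced data are rank deficient.
    """
    data = np.asarray(rs_data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.shape[-1] < 2:
        raise ValueError("need at least 2 samples to estimate covariance")
    covs = [np.cov(ep) for ep in data]
    cov = np.mean(covs, axis=0)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        warnings.warn("zero-variance channel in noise covariance", stacklevel=2)
    cov = cov + loading * (np.trace(cov) / cov.shape[0]) * np.eye(cov.shape[0])
    return NoiseCovariance(0.5 * (cov + cov.T))


def sloreta_solve(
    lf: LeadField,
    ncov: NoiseCovariance,
    epoch: np.ndarray,
    snr: float = 3.0,
    lam: float | None = None,
) -> SourceEstimate:
    """Standardized minimum-norm inverse of one epoch (channels x samples).

    ``λ`` defaults to ``trace(GG') / (trace(C) · snr²)`` — a fixed-SNR
    regularization heuristic.  Each source is standardized by
    ``sqrt([K G]_ii)``, the diagonal of the resolution matrix.
    """
    G = lf.gain
    data = np.asarray(epoch, dtype=float)
    if data.ndim == 1:
        data = data[None]
    if data.shape[0] != lf.n_sensors:
        raise ValueError(
            f"epoch has {data.shape[0]} channels, lead field expects "
            f"{lf.n_sensors}")
    C = ncov.cov
    if C.shape[0] != lf.n_sensors:
        raise ValueError("noise covariance does not match sensor count")

    GGt = G @ G.T
    if lam is None:
        tr_c = np.trace(C)
        lam = np.trace(GGt) / (tr_c * snr**2) if tr_c > 0 else 0.0
    M = GGt + lam * C
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular sensor-space system: increase regularization (snr/lam)"
        ) from err
    K = G.T @ Minv
    j = K @ data
    res_diag = np.einsum("ij,ji->i", K, G)
    res_diag = np.maximum(res_diag, np.finfo(float).tiny)
    activity = j / np.sqrt(res_diag)[:, None]
    return SourceEstimate(activity, fs=0.0, source_ids=list(lf.source_ids))


def select_rois(
    src: SourceEstimate,
    events: np.ndarray,
    label_map: dict[int, str],
    window: int = 0,
) -> RoiSet:
    """For each event, pick the source with maximal energy at the event.

    Energy is squared standardized activity summed over ``event ± window``
    samples.  Ties break to the lower source index (logged).  The union of
    winners over events defines the node set of the network.
    """
    act = src.activity
    n_src, n_samp = act.shape
    rois: dict[int, tuple[str, int]] = {}
    for e in np.asarray(events, dtype=int):
        if not 0 <= e < n_samp:
            raise ValueError(f"event sample {e} outside epoch range")
        lo, hi = max(0, e - window), min(n_samp, e + window + 1)
        energy = np.sum(act[:, lo:hi] ** 2, axis=1)
        best = int(np.argmax(energy))  # argmax returns the lowest tied index
        if np.sum(energy == energy[best]) > 1:
            warnings.warn(
                f"energy tie at event {e}: lowest source index {best} wins",
                stacklevel=2)
        if best not in label_map:
            raise KeyError(f"no region label for winning source {best}")
        label = label_map[best]
        mult = rois.get(best, (label, 0))[1] + 1
        rois[best] = (label, mult)
    return RoiSet(rois, dict(label_map))
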