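"""Transmit (fT) and receive (fR) bias-field handling.

fT is the multiplicative deviation of the local flip angle from nominal
(1 = nominal internally, 100 p.u. on disk); it biases R1, PD and MT maps.
fR is the spatial receive-sensitivity modulation; it only biases PD (absent
motion).  B1 mapping here covers the actual-flip-angle (AFI) two-TR method
and ingestion of pre-computed maps; data-driven (segmentation-based)
estimation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import GridError, ImageVolume, MultiEchoSeries, read_volume

__all__ = [
    "TransmitField",
    "ReceiveField",
    "AfiPair",
    "afi_to_ft",
    "simulate_afi",
    "load_precomputed_ft",
    "receive_from_pair",
    "apply_receive_correction",
    "smooth_mm",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_mm(data: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in millimetres."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return np.asarray(data, dtype=float).copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (data.ndim,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vs
    return gaussian_filter(np.asarray(data, dtype=float), sigma=sigma_vox, mode="constant")


@dataclass
class TransmitField:
    """B1+ field as a fraction of the nominal flip angle (1 = nominal)."""

    ft: np.ndarray
    affine: np.ndarray
    valid: np.ndarray
    source: str = "unity"  # AFI | precomputed | unity

    @property
    def as_pu(self) -> np.ndarray:
        """Export scale: percent units (100 = nominal)."""
        return self.ft * 100.0

    @classmethod
    def from_pu(cls, pu: np.ndarray, affine: np.ndarray, source: str = "precomputed") -> "TransmitField":
        ft = np.asarray(pu, dtype=float) / 100.0
        return cls(ft=ft, affine=affine, valid=ft > 0, source=source)

    @classmethod
    def unity(cls, shape, affine) -> "TransmitField":
        return cls(ft=np.ones(shape), affine=affine, valid=np.ones(shape, dtype=bool), source="unity")


@dataclass
class ReceiveField:
    """Per-contrast receive sensitivity maps (arbitrary positive scale)."""

    fr: dict[str, np.ndarray]
    affine: np.ndarray
    fwhm_mm: float = 0.0
    source: str = "per_contrast"  # single | per_contrast | unity

    def for_contrast(self, contrast: str) -> np.ndarray:
        if self.source == "single":
            return next(iter(self.fr.values()))
        if contrast not in self.fr:
            raise KeyError(f"no receive map for contrast {contrast!r}")
        return self.fr[contrast]


@dataclass
class AfiPair:
    """Two interleaved-TR volumes of the actual-flip-angle B1 sequence."""

    s1: ImageVolume
    s2: ImageVolume
    tr1_ms: float
    tr2_ms: float
    alpha_nominal_deg: float

    def __post_init__(self) -> None:
        if self.tr1_ms <= 0 or self.tr2_ms <= 0:
            raise ValueError("repetition times must be positive")
        if self.tr2_ms / self.tr1_ms <= 1:
            raise ValueError("AFI requires TR2/TR1 > 1")
        if self.alpha_nominal_deg <= 0:
            raise ValueError("nominal flip angle must be positive")
        if self.s1.shape != self.s2.shape or not np.allclose(self.s1.affine, self.s2.affine, atol=1e-4):
            raise GridError("AFI volumes are not on a common grid")

    @property
    def n(self) -> float:
        return self.tr2_ms / self.tr1_ms


def simulate_afi(
    alpha_actual_rad: np.ndarray | float,
    tr1_ms: float,
    tr2_ms: float,
    alpha_nominal_deg: float,
    scale: float = 1000.0,
    affine: np.ndarray | None = None,
) -> AfiPair:
    """Ideal-spoiling AFI signal pair in the short-TR regime.

    In the short-TR limit the interleaved steady state gives signals with
    ratio S2/S1 = (TR1 + TR2 cos a)/(TR2 + TR1 cos a); the arccos relation
    used by :func:`afi_to_ft` is the exact algebraic inverse of this pair.
    """
    a = np.atleast_3d(np.asarray(alpha_actual_rad, dtype=float))
    c = np.cos(a)
    denom = tr1_ms + tr2_ms
    s1 = scale * np.sin(a) * (tr2_ms + tr1_ms * c) / denom
    s2 = scale * np.sin(a) * (tr1_ms + tr2_ms * c) / denom
    if affine is None:
        affine = np.eye(4)
    return AfiPair(
        s1=ImageVolume(data=s1, affine=affine),
        s2=ImageVolume(data=s2, affine=affine),
        tr1_ms=tr1_ms,
        tr2_ms=tr2_ms,
        alpha_nominal_deg=alpha_nominal_deg,
    )


def afi_to_ft(pair: AfiPair, fwhm_mm: float = 8.0) -> TransmitField:
    """Invert the AFI signal ratio to the transmit-field map.

    cos(a_actual) = (r n - 1)/(n - r) with r = S2/S1 and n = TR2/TR1;
    fT = a_actual / a_nominal.  Voxels whose cosine argument falls outside
    [-1, 1] (noise, background) are masked invalid; the field is smoothed
    with a configurable kernel (default 8 mm FWHM) before export, invalid
    voxels excluded via normalised convolution.
    """
    s1 = pair.s1.data
    s2 = pair.s2.data
    n = pair.n
    ok = s1 > 0
    r = np.divide(s2, s1, out=np.zeros_like(s2), where=ok)
    denom = n - r
    cosarg = np.divide(r * n - 1.0, denom, out=np.full_like(r, 2.0), where=np.abs(denom) > 1e-12)
    valid = ok & (cosarg >= -1.0) & (cosarg <= 1.0)
    alpha = np.where(valid, np.arccos(np.clip(cosarg, -1.0, 1.0)), 0.0)
    ft = alpha / np.deg2rad(pair.alpha_nominal_deg)
    valid = valid & (alpha > 0)  # a vanishing recovered angle is implausible

    if fwhm_mm > 0:
        vs = pair.s1.voxel_size
        w = valid.astype(float)
        num = smooth_mm(ft * w, fwhm_mm, vs)
        den = smooth_mm(w, fwhm_mm, vs)
        ft = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-6)
    return TransmitField(ft=ft, affine=pair.s1.affine, valid=valid, source="AFI")


def load_precomputed_ft(path: str | Path) -> TransmitField:
    """Ingest a pre-computed B1+ map, auto-detecting p.u. versus fraction.

    A map whose median (over positive voxels) lies in [0.3, 3] is read as a
    fraction; in [30, 300] as percent units; anything else is rejected as
    unit-ambiguous.
    """
    vol, _ = read_volume(path)
    pos = vol.data[vol.data > 0]
    if pos.size == 0:
        raise ValueError(f"{path}: empty B1 map")
    med = float(np.median(pos))
    if 0.3 <= med <= 3.0:
        ft = vol.data.copy()
    elif 30.0 <= med <= 300.0:
        ft = vol.data / 100.0
    else:
        raise ValueError(
            f"{path}: median {med:g} is neither a plausible fraction nor p.u.; "
            "cannot determine units"
        )
    return TransmitField(ft=ft, affine=vol.affine, valid=ft > 0, source="precomputed")


def receive_from_pair(
    head: ImageVolume,
    body: ImageVolume,
    fwhm_mm: float = 12.0,
    threshold: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Receive-sensitivity field from a head-coil / body-coil image pair.

    fR = smooth(head) / smooth(body), masked where the smoothed body-coil
    reference falls below ``threshold`` times its maximum.  The body coil is
    used as measured; its own (unmodelled) receive profile is a known
    residual limitation recorded in provenance by the pipeline.
    """
    if head.shape != body.shape or not np.allclose(head.affine, body.affine, atol=1e-4):
        raise GridError("head/body volumes are not on a common grid")
    if not np.any(body.data != 0):
        raise ValueError("body-coil reference is identically zero")
    vs = head.voxel_size
    sh = smooth_mm(head.data, fwhm_mm, vs)
    sb = smooth_mm(body.data, fwhm_mm, vs)
    cut = threshold * np.abs(sb).max()
    mask = sb > cut
    fr = np.divide(sh, sb, out=np.ones_like(sh), where=mask)
    return fr, mask


def apply_receive_correction(
    series: dict[str, MultiEchoSeries],
    field: ReceiveField,
    mode: str,
) -> dict[str, MultiEchoSeries]:
    """Divide each contrast's echoes by its receive-sensitivity map.

    ``mode='single'`` applies one map to every contrast (valid only when
    between-contrast motion is negligible); ``mode='per_contrast'`` uses one
    map per contrast and is robust to inter-contrast motion.
    """
    if mode not in ("single", "per_contrast"):
        raise ValueError(f"unknown receive-correction mode {mode!r}")
    out = {}
    for contrast, ser in series.items():
        if mode == "single":
            fr = next(iter(field.fr.values()))
        else:
            if contrast not in field.fr:
                raise KeyError(
                    f"per-contrast receive correction requested but no map for {contrast!r}"
                )
            fr = field.fr[contrast]
        if fr.shape != ser.shape:
            raise GridError(f"receive map for {contrast!r} not on the series grid")
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(fr > 0, 1.0 / fr, 0.0)
        out[contrast] = ser.scaled(inv)
    return out
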