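"""Digital multi-parameter-mapping phantom.

Forward-simulates multi-echo PDw/T1w/MTw spoiled gradient-echo (FLASH)
signals from ground-truth R1, R2*, amplitude and MT-saturation maps under
the Ernst steady state, with multiplicative transmit (fT) and per-contrast
receive (fR) bias fields and optional Gaussian or Rician noise.  The MTw
steady state uses the small-angle rational form with an explicit saturation
term, which is the exact algebraic inverse of the map-computation formulas,
so a noiseless simulate-then-fit round trip closes in the approximation
regime.

Units: TR and TE in milliseconds throughout the signal functions (converted
internally where a formula wants seconds), flip angles in radians, rates in
s^-1, MT saturation in percent units (p.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np

from .core_io import (
    AcquisitionMetadata,
    ImageVolume,
    MultiEchoSeries,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "make_layered_phantom",
    "ernst_signal",
    "mt_flash_signal",
    "simulate_contrast",
    "simulate_protocol",
    "default_protocol",
    "write_phantom_dataset",
]

#: per-compartment tissue-like truth values: (R1 s^-1, R2* s^-1, A a.u., MTsat p.u.)
DEFAULT_COMPARTMENTS = (
    ("cortex", 0.65, 17.0, 850.0, 1.0),
    ("white_matter", 1.05, 21.0, 690.0, 1.9),
    ("deep_grey", 0.90, 30.0, 800.0, 1.3),
)


@dataclass
class PhantomSpec:
    """Ground truth plus instrumental conditions for one simulation."""

    voxel_size: tuple[float, float, float]
    r1: np.ndarray          # s^-1
    r2s: np.ndarray         # s^-1
    a: np.ndarray           # a.u., proportional to PD; 0 marks background
    mtsat: np.ndarray       # p.u.
    ft: np.ndarray          # dimensionless, 1 = nominal flip angle
    fr: dict[str, np.ndarray] = field(default_factory=dict)  # per-contrast, a.u.
    labels: np.ndarray | None = None
    noise: str = "none"     # none | gaussian | rician
    sigma: float = 0.0      # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        maps = [self.r1, self.r2s, self.a, self.mtsat, self.ft, *self.fr.values()]
        shapes = {m.shape for m in maps}
        if len(shapes) != 1:
            raise ValueError("all phantom maps must share one lattice")
        for name, m in (("R1", self.r1), ("R2*", self.r2s), ("A", self.a), ("MTsat", self.mtsat)):
            if np.any(m < 0):
                raise ValueError(f"{name} must be nonnegative")
        if np.any(self.ft <= 0):
            raise ValueError("fT must be strictly positive")
        for c, m in self.fr.items():
            if np.any(m <= 0):
                raise ValueError(f"fR[{c}] must be strictly positive")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.sigma <= 0:
            raise ValueError("gaussian/rician noise requires sigma > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.r1.shape  # type: ignore[return-value]

    @property
    def foreground(self) -> np.ndarray:
        return self.a > 0

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size, 1.0])

    def fr_for(self, contrast: str) -> np.ndarray:
        return self.fr.get(contrast, np.ones(self.shape))

    def with_noise(self, noise: str, sigma: float) -> "PhantomSpec":
        return replace(self, noise=noise, sigma=sigma)


def _smooth_poly_field(
    rng: np.random.Generator, shape, amplitude: float, norm_mask: np.ndarray | None = None
) -> np.ndarray:
    """Smooth low-order polynomial field 1 + amplitude * p(x).

    p is a random quadratic in the normalised coordinates, scaled so
    max|p| = 1 over ``norm_mask`` (default: whole grid); the field then
    attains the full +-amplitude range inside the mask.
    """
    if amplitude == 0:
        return np.ones(shape)
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    c = rng.uniform(-1.0, 1.0, size=9)
    x, y, z = coords
    p = (
        c[0] * x + c[1] * y + c[2] * z
        + c[3] * x * y + c[4] * x * z + c[5] * y * z
        + c[6] * x ** 2 + c[7] * y ** 2 + c[8] * z ** 2
    )
    peak = np.abs(p[norm_mask]).max() if norm_mask is not None else np.abs(p).max()
    if peak > 0:
        p = p / peak
    return 1.0 + amplitude * p


def make_layered_phantom(
    dimensions: int | Sequence[int] = 48,
    seed: int = 0,
    *,
    voxel_size: float = 1.0,
    ft_range: float = 0.2,
    fr_range: float = 0.15,
    fr_contrast_dev: float = 0.05,
    noise: str = "none",
    sigma: float = 0.0,
    compartments=DEFAULT_COMPARTMENTS,
) -> PhantomSpec:
    """Deterministic concentric-shell phantom with brain-like tissue values.

    Three ellipsoidal shells emulate cortex, white matter and an iron-rich
    deep-grey core; the transmit field is a smooth low-order polynomial with
    default range +-20% of nominal, the per-contrast receive fields share a
    common +-15% profile plus a small (+-5%) contrast-specific deviation
    emulating between-contrast head motion.

    Parameters are ground truth: the same arrays are returned to tests and
    written to the ``truth/`` tree by :func:`write_phantom_dataset`.
    """
    if np.isscalar(dimensions):
        dims = (int(dimensions),) * 3
    else:
        dims = tuple(int(d) for d in dimensions)
    if min(dims) < 8:
        raise ValueError("phantom needs at least 8 voxels per axis")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E37]))
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in dims], indexing="ij")
    r = np.sqrt(sum(c ** 2 for c in coords))

    # concentric radial shells; outermost boundary at r=0.9 leaves background
    edges = np.linspace(0.9, 0.0, len(compartments) + 1)
    labels = np.zeros(dims, dtype=np.int16)
    r1 = np.zeros(dims)
    r2s = np.zeros(dims)
    a = np.zeros(dims)
    mt = np.zeros(dims)
    for k, (_, tr1, tr2s, ta, tmt) in enumerate(compartments):
        m = (r <= edges[k]) & (r > edges[k + 1]) if k + 1 < len(edges) else (r <= edges[k])
        labels[m] = k + 1
        r1[m], r2s[m], a[m], mt[m] = tr1, tr2s, ta, tmt

    fg = labels > 0
    ft = _smooth_poly_field(rng, dims, ft_range, norm_mask=fg)
    fr = {}
    base = _smooth_poly_field(rng, dims, fr_range, norm_mask=fg)
    for contrast in ("PDw", "T1w", "MTw"):
        dev = _smooth_poly_field(rng, dims, fr_contrast_dev, norm_mask=fg)
        fr[contrast] = base * dev

    return PhantomSpec(
        voxel_size=(float(voxel_size),) * 3,
        r1=r1, r2s=r2s, a=a, mtsat=mt,
        ft=ft, fr=fr, labels=labels,
        noise=noise, sigma=sigma, seed=int(seed),
    )


def ernst_signal(a, r1, alpha, tr_ms):
    """Steady-state spoiled gradient-echo signal (Ernst equation).

    S = A sin(alpha) (1 - E1) / (1 - cos(alpha) E1),  E1 = exp(-TR * R1)
    with ``alpha`` in radians, ``tr_ms`` in ms and ``r1`` in s^-1.
    """
    tr_ms = np.asarray(tr_ms, dtype=float)
    if np.any(tr_ms <= 0):
        raise ValueError("TR must be positive")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha >= np.pi):
        raise ValueError("flip angle must be in [0, pi)")
    e1 = np.exp(-tr_ms * np.asarray(r1, dtype=float) / 1000.0)
    return np.asarray(a) * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def mt_flash_signal(a, r1, mtsat_pu, alpha, tr_ms):
    """MT-weighted FLASH steady state, small-angle rational form.

    S = A alpha R1 TR' / (alpha^2/2 + R1 TR' + delta/100), TR' in seconds.
    The per-excitation MT saturation ``delta`` (p.u.) acts as an extra
    partial-saturation term alongside incomplete T1 relaxation; the form is
    the exact algebraic inverse of the MT-saturation map formula.
    """
    tr_s = np.asarray(tr_ms, dtype=float) / 1000.0
    alpha = np.asarray(alpha, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    num = np.asarray(a) * alpha * r1 * tr_s
    den = alpha ** 2 / 2.0 + r1 * tr_s + np.asarray(mtsat_pu) / 100.0
    return np.divide(num, den, out=np.zeros(np.broadcast(num, den).shape), where=den > 0)


def _echo_rng(seed: int, contrast: str, echo_index: int) -> np.random.Generator:
    cidx = {"PDw": 1, "T1w": 2, "MTw": 3}[contrast]
    return np.random.default_rng(np.random.SeedSequence([int(seed), cidx, int(echo_index)]))


def simulate_contrast(phantom: PhantomSpec, meta: AcquisitionMetadata) -> MultiEchoSeries:
    """Forward-simulate one multi-echo contrast from the phantom.

    Per echo:  S(TE) = fR_c * S_ss(A, R1, fT*alpha_nom, TR) * exp(-TE R2*/1000)
    where the steady state S_ss is the Ernst equation for PDw/T1w and the
    MT-saturated small-angle form for MTw.  Noise is drawn independently per
    echo volume from the phantom's stored seed.
    """
    alpha_local = phantom.ft * meta.flip_angle_rad
    if meta.mt_pulse:
        s0 = mt_flash_signal(phantom.a, phantom.r1, phantom.mtsat, alpha_local, meta.tr_ms)
    else:
        s0 = ernst_signal(phantom.a, phantom.r1, alpha_local, meta.tr_ms)
    s0 = phantom.fr_for(meta.contrast_label) * s0

    volumes = []
    for j, te in enumerate(meta.te_ms):
        sig = s0 * np.exp(-te * phantom.r2s / 1000.0)
        if phantom.noise == "gaussian":
            rng = _echo_rng(phantom.seed, meta.contrast_label, j)
            sig = sig + rng.normal(0.0, phantom.sigma, size=sig.shape)
        elif phantom.noise == "rician":
            rng = _echo_rng(phantom.seed, meta.contrast_label, j)
            n1 = rng.normal(0.0, phantom.sigma, size=sig.shape)
            n2 = rng.normal(0.0, phantom.sigma, size=sig.shape)
            sig = np.sqrt((sig + n1) ** 2 + n2 ** 2)
        volumes.append(ImageVolume(data=sig, affine=phantom.affine))
    return MultiEchoSeries(meta=meta, volumes=volumes)


def default_protocol(
    contrasts: Sequence[str] = ("PDw", "T1w", "MTw"),
    n_echoes: int = 6,
) -> dict[str, AcquisitionMetadata]:
    """Representative MPM protocol: TR 25 ms, flip 6/21/6 deg, 6 echoes
    equally spaced 2.3-14.8 ms."""
    te = tuple(np.linspace(2.3, 14.8, n_echoes)) if n_echoes > 1 else (2.3,)
    angles = {"PDw": 6.0, "T1w": 21.0, "MTw": 6.0}
    out = {}
    for c in contrasts:
        out[c] = AcquisitionMetadata(
            contrast_label=c,
            flip_angle_deg=angles[c],
            tr_ms=25.0,
            te_ms=te,
            mt_pulse=(c == "MTw"),
        )
    return out


def simulate_protocol(
    phantom: PhantomSpec,
    protocol: Mapping[str, AcquisitionMetadata] | None = None,
) -> dict[str, MultiEchoSeries]:
    if protocol is None:
        protocol = default_protocol()
    return {c: simulate_contrast(phantom, meta) for c, meta in protocol.items()}


def write_phantom_dataset(
    phantom: PhantomSpec,
    out_dir: str | Path,
    protocol: Mapping[str, AcquisitionMetadata] | None = None,
) -> dict[str, list[Path]]:
    """Write the simulated input tree (NIfTI + BIDS-style sidecars) plus a
    ``truth/`` folder with the ground-truth maps and bias fields."""
    out_dir = Path(out_dir)
    if protocol is None:
        protocol = default_protocol()
    series = simulate_protocol(phantom, protocol)
    written: dict[str, list[Path]] = {}
    for contrast, ser in series.items():
        paths = []
        for j, vol in enumerate(ser.volumes):
            p = out_dir / contrast / f"sim_{contrast.lower()}_e{j + 1}.nii"
            write_volume(vol, p)
            sidecar = ser.meta.to_sidecar(j)
            (p.parent / (p.stem + ".json")).write_text(json.dumps(sidecar, indent=2))
            paths.append(p)
        written[contrast] = paths

    truth = out_dir / "truth"
    aff = phantom.affine
    for name, arr in (
        ("R1", phantom.r1), ("R2s", phantom.r2s), ("A", phantom.a),
        ("MTsat", phantom.mtsat), ("fT", phantom.ft),
    ):
        write_volume(ImageVolume(data=arr, affine=aff), truth / f"truth_{name}.nii")
    for c, arr in phantom.fr.items():
        write_volume(ImageVolume(data=arr, affine=aff), truth / f"truth_fR_{c}.nii")
    spec_json = {
        "voxel_size": list(phantom.voxel_size),
        "noise": phantom.noise,
        "sigma": phantom.sigma,
        "seed": phantom.seed,
    }
    (truth / "phantom_spec.json").write_text(json.dumps(spec_json, indent=2))
    return written
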