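"""NIfTI + JSON-sidecar I/O, grid checks, and output naming.

All volumes live on a common voxel grid; no resampling or registration is
performed anywhere in the package, so grid agreement is enforced up front by
:func:`assert_common_grid`.  Internal canonical units are milliseconds for
TR/TE and degrees for nominal flip angles; sidecars follow the BIDS
convention (``RepetitionTime``/``EchoTime`` in seconds, ``FlipAngle`` in
degrees) and are converted on read/write.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "AcquisitionMetadata",
    "MultiEchoSeries",
    "ProvenanceRecord",
    "GridError",
    "MetadataError",
    "read_volume",
    "load_series",
    "write_volume",
    "write_map",
    "map_output_path",
    "assert_common_grid",
    "validate_provenance_dict",
    "MAP_KINDS",
    "RESULTS_DIR",
    "SUPPLEMENTARY_DIR",
]

CONTRAST_LABELS = ("PDw", "T1w", "MTw")

RESULTS_DIR = "Results"
SUPPLEMENTARY_DIR = "Supplementary"

#: kind -> (file suffix, lives in Supplementary?)
MAP_KINDS = {
    "MTsat": ("_MTsat", False),
    "PD": ("_PD", False),
    "R1": ("_R1", False),
    "R2s_OLS": ("_R2s_OLS", False),
    "R2s": ("_R2s", True),
    "B1map": ("_B1map", True),
    "B1ref": ("_B1ref", True),
    "PDw_TEzero": ("_PDw_OLSfit_TEzero", True),
    "T1w_TEzero": ("_T1w_OLSfit_TEzero", True),
    "MTw_TEzero": ("_MTw_OLSfit_TEzero", True),
}


class GridError(ValueError):
    """Inputs do not share a common voxel grid."""


class MetadataError(ValueError):
    """Sidecar metadata missing or inconsistent."""


def _stem(path: Path | str) -> str:
    name = Path(path).name
    for ext in (".nii.gz", ".nii", ".json"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return Path(name).stem


@dataclass
class ImageVolume:
    """A 3-D scalar volume with its voxel-to-world affine.

    Non-finite voxels are replaced by zero at construction time and counted
    in :attr:`n_nonfinite`; downstream fits exclude them through their own
    validity masks.
    """

    data: np.ndarray
    affine: np.ndarray
    n_nonfinite: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        bad = ~np.isfinite(self.data)
        if bad.any():
            self.data = np.where(bad, 0.0, self.data)
            self.n_nonfinite = int(bad.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=np.asarray(data), affine=self.affine.copy())

    @classmethod
    def from_array(cls, data: np.ndarray, voxel_size: float | Sequence[float] = 1.0) -> "ImageVolume":
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        affine = np.diag([*vs, 1.0])
        return cls(data=np.asarray(data), affine=affine)


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition parameters of one weighted FLASH contrast.

    ``tr_ms`` and ``te_ms`` are in milliseconds, ``flip_angle_deg`` in
    degrees of the *nominal* flip angle.
    """

    contrast_label: str
    flip_angle_deg: float
    tr_ms: float
    te_ms: tuple[float, ...]
    mt_pulse: bool = False

    def __post_init__(self) -> None:
        if self.contrast_label not in CONTRAST_LABELS:
            raise MetadataError(f"contrast_label must be one of {CONTRAST_LABELS}")
        if not (0 < self.flip_angle_deg <= 90):
            raise MetadataError("flip angle must be in (0, 90] degrees")
        if self.tr_ms <= 0:
            raise MetadataError("repetition time must be positive")
        te = tuple(float(t) for t in self.te_ms)
        if len(te) == 0 or any(t <= 0 for t in te) or any(b <= a for a, b in zip(te, te[1:])):
            raise MetadataError("echo times must be positive and strictly increasing")
        object.__setattr__(self, "te_ms", te)
        if self.mt_pulse != (self.contrast_label == "MTw"):
            raise MetadataError("mt_pulse must be set iff contrast is MTw")

    @property
    def flip_angle_rad(self) -> float:
        return float(np.deg2rad(self.flip_angle_deg))

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    def to_sidecar(self, echo_index: int) -> dict:
        """BIDS-convention sidecar for one echo (seconds for times)."""
        return {
            "RepetitionTime": self.tr_ms / 1000.0,
            "EchoTime": self.te_ms[echo_index] / 1000.0,
            "FlipAngle": self.flip_angle_deg,
            "MTState": bool(self.mt_pulse),
            "ContrastLabel": self.contrast_label,
        }

    @classmethod
    def from_sidecars(cls, sidecars: Sequence[dict]) -> "AcquisitionMetadata":
        """Build series metadata from one sidecar dict per echo."""
        if not sidecars:
            raise MetadataError("no sidecars given")
        first = sidecars[0]
        for key in ("RepetitionTime", "EchoTime", "FlipAngle"):
            if key not in first:
                raise MetadataError(f"sidecar missing required field {key!r}")
        label = first.get("ContrastLabel")
        mt = bool(first.get("MTState", False))
        if label is None:
            label = "MTw" if mt else None
        if label is None:
            raise MetadataError("sidecar missing required field 'ContrastLabel'")
        te = []
        for sc in sidecars:
            if "EchoTime" not in sc:
                raise MetadataError("sidecar missing required field 'EchoTime'")
            te.append(float(sc["EchoTime"]) * 1000.0)
        return cls(
            contrast_label=label,
            flip_angle_deg=float(first["FlipAngle"]),
            tr_ms=float(first["RepetitionTime"]) * 1000.0,
            te_ms=tuple(te),
            mt_pulse=mt,
        )


@dataclass
class MultiEchoSeries:
    """Ordered echo volumes of one weighted contrast."""

    meta: AcquisitionMetadata
    volumes: list[ImageVolume]
    source_paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.volumes) != self.meta.n_echoes:
            raise ValueError(
                f"{len(self.volumes)} volumes but {self.meta.n_echoes} echo times"
            )
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if v.shape != ref.shape or not np.allclose(v.affine, ref.affine, atol=1e-4):
                raise GridError("echo volumes disagree in shape or affine")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def affine(self) -> np.ndarray:
        return self.volumes[0].affine

    def stack(self) -> np.ndarray:
        """Echo data as a (n_echo, nx, ny, nz) array."""
        return np.stack([v.data for v in self.volumes], axis=0)

    def scaled(self, factor: np.ndarray | float) -> "MultiEchoSeries":
        """Voxelwise-multiplied copy (used for receive-field correction)."""
        return MultiEchoSeries(
            meta=self.meta,
            volumes=[v.with_data(v.data * factor) for v in self.volumes],
            source_paths=list(self.source_paths),
        )


@dataclass
class ProvenanceRecord:
    """Ordered processing history serialised with every output map."""

    software: str = "mpmkit"
    version: str = "0.1.0"
    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, params: dict | None = None, inputs: Iterable[str] = ()) -> None:
        self.steps.append(
            {
                "step": step,
                "params": _jsonify(params or {}),
                "inputs": [str(p) for p in inputs],
                "timestamp": datetime.now(timezone.utc).isoformat(),
            }
        )

    def to_dict(self) -> dict:
        return {"software": self.software, "version": self.version, "steps": self.steps}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ProvenanceRecord":
        validate_provenance_dict(d)
        return cls(software=d["software"], version=d["version"], steps=list(d["steps"]))

    @classmethod
    def from_json(cls, text: str) -> "ProvenanceRecord":
        return cls.from_dict(json.loads(text))


def _jsonify(obj):
    """Coerce numpy scalars/arrays and paths into JSON-serialisable values."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def validate_provenance_dict(d: dict) -> None:
    """Structural validation of a provenance JSON object.

    The schema is deliberately small: top-level ``software``/``version``
    strings and a ``steps`` list whose entries carry ``step`` (str),
    ``params`` (object), ``inputs`` (list of str) and ``timestamp`` (str).
    """
    if not isinstance(d, dict):
        raise MetadataError("provenance must be a JSON object")
    for key, typ in (("software", str), ("version", str), ("steps", list)):
        if not isinstance(d.get(key), typ):
            raise MetadataError(f"provenance field {key!r} missing or wrong type")
    for entry in d["steps"]:
        if not isinstance(entry, dict):
            raise MetadataError("provenance step must be an object")
        if not isinstance(entry.get("step"), str):
            raise MetadataError("provenance step missing 'step' name")
        if not isinstance(entry.get("params"), dict):
            raise MetadataError("provenance step missing 'params' object")
        if not isinstance(entry.get("inputs"), list):
            raise MetadataError("provenance step missing 'inputs' list")
        if not isinstance(entry.get("timestamp"), str):
            raise MetadataError("provenance step missing 'timestamp'")


def read_volume(path: str | Path) -> tuple[ImageVolume, AcquisitionMetadata | None]:
    """Load a NIfTI volume and, if present, its JSON sidecar.

    The sidecar shares the volume's basename with extension ``.json``.  A
    sidecar describes a *single echo*; series-level metadata is assembled by
    :func:`load_series`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    vol = ImageVolume(data=np.asanyarray(img.dataobj), affine=img.affine)
    sidecar = path.parent / (_stem(path) + ".json")
    meta = None
    if sidecar.exists():
        sc = json.loads(sidecar.read_text())
        # a same-basename JSON may be a provenance record rather than an
        # acquisition sidecar; only parse it when acquisition keys appear
        if isinstance(sc, dict) and any(
            k in sc for k in ("RepetitionTime", "EchoTime", "FlipAngle")
        ):
            meta = AcquisitionMetadata.from_sidecars([sc])
    return vol, meta


def load_series(paths: Sequence[str | Path]) -> MultiEchoSeries:
    """Load a multi-echo contrast from per-echo NIfTI files with sidecars."""
    paths = [Path(p) for p in paths]
    vols, sidecars = [], []
    for p in paths:
        img = nib.load(str(p))
        vols.append(ImageVolume(data=np.asanyarray(img.dataobj), affine=img.affine))
        sc_path = p.parent / (_stem(p) + ".json")
        if not sc_path.exists():
            raise MetadataError(f"missing sidecar for {p}")
        sidecars.append(json.loads(sc_path.read_text()))
    order = np.argsort([sc["EchoTime"] for sc in sidecars])
    vols = [vols[i] for i in order]
    sidecars = [sidecars[i] for i in order]
    paths = [paths[i] for i in order]
    meta = AcquisitionMetadata.from_sidecars(sidecars)
    return MultiEchoSeries(meta=meta, volumes=vols, source_paths=paths)


def write_volume(volume: ImageVolume, path: str | Path, dtype=np.float32) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(dtype), volume.affine)
    nib.save(img, str(path))
    return path


def map_output_path(kind: str, out_dir: str | Path, basename_source: str | Path) -> Path:
    """Pure naming rule: where a map of ``kind`` derived from
    ``basename_source`` goes below ``out_dir`` (before run-collision
    handling)."""
    if kind not in MAP_KINDS:
        raise ValueError(f"unknown map kind {kind!r}; expected one of {sorted(MAP_KINDS)}")
    suffix, supplementary = MAP_KINDS[kind]
    base = _stem(basename_source)
    d = Path(out_dir) / RESULTS_DIR
    if supplementary:
        d = d / SUPPLEMENTARY_DIR
    return d / f"{base}{suffix}.nii"


def _bump_run_dir(out_dir: Path) -> Path:
    """Next unused ``run-NN`` subfolder below ``out_dir``."""
    n = 2
    while (out_dir / f"run-{n:02d}").exists():
        n += 1
    return out_dir / f"run-{n:02d}"


def write_map(
    volume: ImageVolume,
    kind: str,
    out_dir: str | Path,
    basename_source: str | Path,
    provenance: ProvenanceRecord,
) -> Path:
    """Write ``<basename><suffix>.nii`` plus a provenance ``.json``.

    Existing outputs are never overwritten: on collision the whole
    ``Results`` tree is redirected into a fresh ``run-NN`` subfolder.
    """
    out_dir = Path(out_dir)
    target = map_output_path(kind, out_dir, basename_source)
    if target.exists():
        rel = target.relative_to(out_dir)
        target = _bump_run_dir(out_dir) / rel
    write_volume(volume, target)
    json_path = target.with_suffix(".json")
    json_path.write_text(provenance.to_json())
    return target


def assert_common_grid(items: Sequence[MultiEchoSeries | ImageVolume]) -> tuple[tuple[int, int, int], np.ndarray]:
    """Check that all inputs share one lattice; return (shape, affine).

    Runs before any fit: inputs must be pre-aligned, resampling is out of
    scope for this package.
    """
    if len(items) == 0:
        raise ValueError("assert_common_grid needs at least one input")
    shapes, affines = [], []
    for it in items:
        if isinstance(it, MultiEchoSeries):
            shapes.append(it.shape)
            affines.append(it.affine)
        else:
            shapes.append(it.shape)
            affines.append(it.affine)
    ref_shape, ref_aff = shapes[0], affines[0]
    offenders = [
        i
        for i, (s, a) in enumerate(zip(shapes, affines))
        if s != ref_shape or not np.allclose(a, ref_aff, atol=1e-4)
    ]
    if offenders:
        raise GridError(f"inputs {offenders} are not on the common grid {ref_shape}")
    return ref_shape, ref_aff
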