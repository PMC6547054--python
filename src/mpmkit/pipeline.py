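"""Map-creation and spatial-processing workflows.

``run_map_creation`` is the in-memory engine: it takes loaded multi-echo
series plus optional bias fields and returns the parameter maps, the decay
fit and the QA report.  ``create_maps`` wraps it with file I/O driven by a
:class:`PipelineConfig` and writes the standard output tree
(``Results/`` + ``Results/Supplementary``).  The correction order is fixed
and recorded in provenance: receive correction on the raw echoes, joint
decay fit, transmit-dependent map computation, spoiling correction of R1,
MT saturation, residual MT B1 correction, PD calibration, QA.

Supported input subsets degrade gracefully: PDw alone yields only R2*;
PDw+T1w adds R1 and PD; the full triple adds MT saturation.  Single-echo
inputs skip the decay fit, use the first-echo signal directly and flag the
resulting T2* bias in provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from . import __version__
from .bias import (
    AfiPair,
    ReceiveField,
    TransmitField,
    afi_to_ft,
    apply_receive_correction,
    load_precomputed_ft,
)
from .core_io import (
    RESULTS_DIR,
    SUPPLEMENTARY_DIR,
    ImageVolume,
    MultiEchoSeries,
    ProvenanceRecord,
    assert_common_grid,
    load_series,
    read_volume,
    write_volume,
    _bump_run_dir,
)
from .estatics import EstaticsFit, extrapolate_te_zero, fit_estatics, fit_r2s_single
from .maps import (
    ParameterMapSet,
    SpoilingCoefficients,
    apply_spoiling_correction,
    b1_correct_mt,
    calibrate_pd,
    compute_amplitude,
    compute_mt_sat,
    compute_r1,
)
from .qa import QAReport, build_qa_report, write_qa
from .vbq import TissueWeightMap, vbq_smooth_per_tissue

__all__ = [
    "PipelineConfig",
    "ConfigurationError",
    "MapCreationResult",
    "run_map_creation",
    "create_maps",
    "process_maps",
    "rerun_from_provenance",
]

CONTRAST_ORDER = ("PDw", "T1w", "MTw")


class ConfigurationError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """JSON-serialisable configuration of one map-creation run."""

    series_paths: dict[str, list[str]]            # contrast -> echo NIfTI paths
    out_dir: str = "."
    b1: str = "none"                              # none | afi | precomputed
    b1_map_path: str | None = None                # for b1 = precomputed
    afi_paths: list[str] | None = None            # [S1, S2] for b1 = afi
    afi_tr_ms: tuple[float, float] | None = None
    afi_alpha_deg: float | None = None
    b1_smooth_fwhm_mm: float = 8.0
    rf_sens: str = "none"                         # none | single | per_contrast
    rf_map_paths: dict[str, str] = dfield(default_factory=dict)  # contrast -> fR NIfTI
    rf_smooth_fwhm_mm: float = 12.0
    spoiling_a_poly: list[float] | None = None
    spoiling_b_poly: list[float] | None = None
    pd_target_pu: float | None = None
    pd_mask_path: str | None = None
    mt_b1_constant: float = 0.4
    max_te_ms: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["afi_tr_ms"] = list(self.afi_tr_ms) if self.afi_tr_ms else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("afi_tr_ms"):
            d["afi_tr_ms"] = tuple(d["afi_tr_ms"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MapCreationResult:
    maps: ParameterMapSet
    fit: EstaticsFit | None
    qa: QAReport
    te_zero: dict[str, np.ndarray]
    single_echo: bool
    r2s_pdw: np.ndarray | None = None   # simple per-contrast fit of the PDw echoes


def _check_subset(series: dict[str, MultiEchoSeries]) -> list[str]:
    if "PDw" not in series:
        raise ConfigurationError("map creation requires at least a PDw series (stage: input)")
    if "MTw" in series and "T1w" not in series:
        raise ConfigurationError(
            "MT saturation requires both T1w and MTw series: missing dependency T1w (stage: input)"
        )
    return [c for c in CONTRAST_ORDER if c in series]


def run_map_creation(
    series: dict[str, MultiEchoSeries],
    ft: TransmitField | None = None,
    receive: ReceiveField | None = None,
    receive_mode: str | None = None,
    spoiling: SpoilingCoefficients | None = None,
    mt_b1_constant: float = 0.4,
    pd_target_pu: float | None = None,
    pd_mask: np.ndarray | None = None,
    max_te_ms: float | None = None,
    provenance: ProvenanceRecord | None = None,
) -> MapCreationResult:
    """Run the full map-creation chain on in-memory series."""
    order = _check_subset(series)
    prov = provenance if provenance is not None else ProvenanceRecord(version=__version__)

    items: list = [series[c] for c in order]
    if ft is not None:
        items.append(ImageVolume(data=ft.ft, affine=ft.affine))
    shape, _affine = assert_common_grid(items)
    prov.add("assert_common_grid", {"shape": list(shape), "n_series": len(order)})

    if receive is not None:
        mode = receive_mode or receive.source
        series = apply_receive_correction(series, receive, mode)
        prov.add(
            "receive_correction",
            {
                "mode": mode,
                "fwhm_mm": receive.fwhm_mm,
                "limitation": "body-coil receive profile not modelled; residual modulation possible",
            },
        )
    else:
        prov.add("receive_correction", {"mode": "none"})

    single_echo = any(series[c].meta.n_echoes < 2 for c in order)
    fit: EstaticsFit | None = None
    te_zero: dict[str, np.ndarray] = {}
    r2s_pdw = None

    if single_echo:
        stacked = np.stack([series[c].volumes[0].data for c in order], axis=0)
        valid = np.all(stacked > 0, axis=0)
        for c in order:
            te_zero[c] = np.where(valid, series[c].volumes[0].data, 0.0)
        prov.add(
            "single_echo_signals",
            {
                "t2s_bias": "single-echo input: no TE=0 extrapolation possible, "
                "PD (and mildly R1/MT) biased by exp(-TE1*R2*)",
                "te1_ms": {c: series[c].meta.te_ms[0] for c in order},
            },
        )
    else:
        fit = fit_estatics([series[c] for c in order], max_te_ms=max_te_ms)
        valid = fit.valid
        for c in order:
            te_zero[c] = extrapolate_te_zero(series[c], fit).data
        r2s_pdw = fit_r2s_single(series["PDw"], max_te_ms=max_te_ms)[0].data
        prov.add(
            "estatics_fit",
            {
                "contrasts": order,
                "max_te_ms": max_te_ms,
                "n_invalid": int((~fit.valid).sum()),
                "n_clipped_r2s": fit.n_clipped,
            },
        )

    ft_arr = ft.ft if ft is not None else None
    prov.add("transmit_field", {"source": ft.source if ft is not None else "unity"})

    maps = ParameterMapSet(affine=series["PDw"].affine, provenance=prov)
    maps.r2s = fit.r2s if fit is not None else None
    mask = valid.copy()

    if "T1w" in series:
        meta_pd, meta_t1 = series["PDw"].meta, series["T1w"].meta
        r1, v1 = compute_r1(te_zero["PDw"], te_zero["T1w"], meta_pd, meta_t1, ft_arr)
        a_map, v2 = compute_amplitude(te_zero["PDw"], te_zero["T1w"], meta_pd, meta_t1, ft_arr)
        mask &= v1 & v2
        r1, v_sp = apply_spoiling_correction(r1, ft_arr, spoiling)
        if spoiling is not None:
            mask &= v_sp
        prov.add(
            "vfa_maps",
            {
                "formula": "small-TR/small-angle rational approximation",
                "spoiling_correction": "disabled" if spoiling is None else {
                    "a_poly": list(spoiling.a_poly),
                    "b_poly": list(spoiling.b_poly),
                },
            },
        )
        maps.r1 = np.where(mask, r1, 0.0)
        maps.a = np.where(mask, a_map, 0.0)

        if "MTw" in series:
            delta, v3 = compute_mt_sat(te_zero["MTw"], a_map, r1, series["MTw"].meta, ft_arr)
            mask &= v3
            delta, v4 = b1_correct_mt(delta, ft_arr, mt_b1_constant)
            mask &= v4
            maps.mtsat = np.where(mask, delta, 0.0)
            prov.add("mt_saturation", {"b1_correction_constant": mt_b1_constant})

        cal_mask = (pd_mask.astype(bool) & mask) if pd_mask is not None else mask
        target = pd_target_pu if pd_target_pu is not None else (69.0 if pd_mask is not None else 100.0)
        maps.pd = np.where(mask, calibrate_pd(np.where(mask, a_map, 0.0), cal_mask, target), 0.0)
        prov.add(
            "pd_calibration",
            {
                "target_pu": target,
                "mask": "user-supplied" if pd_mask is not None else "validity-mask",
                "note": None if pd_mask is not None else "uncalibrated-relative",
            },
        )

    maps.valid = mask
    qa = (
        build_qa_report(fit, mask)
        if fit is not None
        else QAReport(
            n_invalid_voxels=int((~mask).sum()),
            notes=["single-echo input: no decay fit, residual QA unavailable"],
        )
    )
    return MapCreationResult(
        maps=maps, fit=fit, qa=qa, te_zero=te_zero, single_echo=single_echo, r2s_pdw=r2s_pdw
    )


def _results_dir(out_dir: Path) -> Path:
    """Pick a fresh Results tree: never overwrite a previous run."""
    res = out_dir / RESULTS_DIR
    if res.exists() and any(res.iterdir()):
        return _bump_run_dir(res)
    return res


def create_maps(config: PipelineConfig) -> dict[str, Path]:
    """File-based map creation: load inputs, run, write the output tree.

    Returns a dict of logical output name -> written path.
    """
    series = {}
    for contrast, paths in config.series_paths.items():
        if not paths:
            raise ConfigurationError(f"no echo files for {contrast} (stage: input)")
        series[contrast] = load_series(paths)
    order = _check_subset(series)

    prov = ProvenanceRecord(version=__version__)
    prov.add("config", {"config": config.to_dict()})

    ft = None
    b1_outputs = {}
    if config.b1 == "precomputed":
        if not config.b1_map_path:
            raise ConfigurationError("b1=precomputed requires b1_map_path (stage: transmit-field)")
        ft = load_precomputed_ft(config.b1_map_path)
    elif config.b1 == "afi":
        if not (config.afi_paths and config.afi_tr_ms and config.afi_alpha_deg):
            raise ConfigurationError(
                "b1=afi requires afi_paths, afi_tr_ms and afi_alpha_deg (stage: transmit-field)"
            )
        v1, _ = read_volume(config.afi_paths[0])
        v2, _ = read_volume(config.afi_paths[1])
        pair = AfiPair(
            s1=v1, s2=v2,
            tr1_ms=config.afi_tr_ms[0], tr2_ms=config.afi_tr_ms[1],
            alpha_nominal_deg=config.afi_alpha_deg,
        )
        ft = afi_to_ft(pair, fwhm_mm=config.b1_smooth_fwhm_mm)
        b1_outputs["B1map"] = (
            ImageVolume(data=ft.as_pu, affine=ft.affine), config.afi_paths[0]
        )
        b1_outputs["B1ref"] = (
            ImageVolume(data=0.5 * (v1.data + v2.data), affine=v1.affine), config.afi_paths[0]
        )
    elif config.b1 != "none":
        raise ConfigurationError(f"unknown B1 option {config.b1!r} (stage: transmit-field)")

    receive = None
    if config.rf_sens in ("single", "per_contrast"):
        fr = {}
        for contrast, path in config.rf_map_paths.items():
            vol, _ = read_volume(path)
            fr[contrast] = vol.data
        if not fr:
            raise ConfigurationError("rf_sens requested but rf_map_paths empty (stage: receive-field)")
        if config.rf_sens == "per_contrast":
            missing = [c for c in order if c not in fr]
            if missing:
                raise ConfigurationError(
                    f"per-contrast receive correction missing maps for {missing} (stage: receive-field)"
                )
        receive = ReceiveField(
            fr=fr, affine=series["PDw"].affine,
            fwhm_mm=config.rf_smooth_fwhm_mm, source=config.rf_sens,
        )
    elif config.rf_sens != "none":
        raise ConfigurationError(f"unknown receive option {config.rf_sens!r} (stage: receive-field)")

    spoiling = None
    if config.spoiling_a_poly is not None or config.spoiling_b_poly is not None:
        spoiling = SpoilingCoefficients(
            a_poly=tuple(config.spoiling_a_poly or (0.0,)),
            b_poly=tuple(config.spoiling_b_poly or (1.0,)),
        )

    pd_mask = None
    if config.pd_mask_path:
        vol, _ = read_volume(config.pd_mask_path)
        pd_mask = vol.data > 0.5

    result = run_map_creation(
        series,
        ft=ft,
        receive=receive,
        receive_mode=config.rf_sens if receive is not None else None,
        spoiling=spoiling,
        mt_b1_constant=config.mt_b1_constant,
        pd_target_pu=config.pd_target_pu,
        pd_mask=pd_mask,
        max_te_ms=config.max_te_ms,
        provenance=prov,
    )

    # --- write the output tree ---------------------------------------
    out_dir = Path(config.out_dir)
    basename_source = Path(config.series_paths["PDw"][0])
    res_dir = _results_dir(out_dir)
    supp_dir = res_dir / SUPPLEMENTARY_DIR
    base = basename_source.name
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    affine = result.maps.affine

    written: dict[str, Path] = {}

    def _emit(arr: np.ndarray, kind: str) -> None:
        suffix_dir = supp_dir if kind in (
            "R2s", "B1map", "B1ref", "PDw_TEzero", "T1w_TEzero", "MTw_TEzero"
        ) else res_dir
        from .core_io import MAP_KINDS

        suffix, _supp = MAP_KINDS[kind]
        path = suffix_dir / f"{base}{suffix}.nii"
        write_volume(ImageVolume(data=arr, affine=affine), path)
        path.with_suffix(".json").write_text(prov.to_json())
        written[kind] = path

    if result.maps.r2s is not None:
        _emit(result.maps.r2s, "R2s_OLS")
        _emit(result.r2s_pdw, "R2s")
    if result.maps.r1 is not None:
        _emit(result.maps.r1, "R1")
        _emit(result.maps.pd, "PD")
    if result.maps.mtsat is not None:
        _emit(result.maps.mtsat, "MTsat")
    if not result.single_echo:
        for c in order:
            _emit(result.te_zero[c], f"{c}_TEzero")

    for kind, (vol, src) in b1_outputs.items():
        src_base = Path(src).name
        for ext in (".nii.gz", ".nii"):
            if src_base.endswith(ext):
                src_base = src_base[: -len(ext)]
        from .core_io import MAP_KINDS

        suffix, _supp = MAP_KINDS[kind]
        path = supp_dir / f"{src_base}{suffix}.nii"
        write_volume(vol, path)
        path.with_suffix(".json").write_text(prov.to_json())
        written[kind] = path

    qa_path = write_qa(result.qa, supp_dir)
    written["qa"] = qa_path

    job_json = {
        "job": "create_maps",
        "software": "mpmkit",
        "version": __version__,
        "config": config.to_dict(),
    }
    (supp_dir / "hMRI_map_creation_job_create_maps.json").write_text(json.dumps(job_json, indent=2))
    written["job"] = supp_dir / "hMRI_map_creation_job_create_maps.json"

    mpm_params = {
        "contrasts": {
            c: {
                "flip_angle_deg": series[c].meta.flip_angle_deg,
                "tr_ms": series[c].meta.tr_ms,
                "te_ms": list(series[c].meta.te_ms),
                "mt_pulse": series[c].meta.mt_pulse,
            }
            for c in order
        },
        "provenance": prov.to_dict(),
    }
    (supp_dir / "hMRI_map_creation_mpm_params.json").write_text(json.dumps(mpm_params, indent=2))
    written["mpm_params"] = supp_dir / "hMRI_map_creation_mpm_params.json"

    if config.b1 != "none":
        b1_params = {
            "method": config.b1,
            "smooth_fwhm_mm": config.b1_smooth_fwhm_mm,
            "afi_tr_ms": list(config.afi_tr_ms) if config.afi_tr_ms else None,
            "afi_alpha_deg": config.afi_alpha_deg,
        }
        (supp_dir / "hMRI_map_creation_b1map_params.json").write_text(json.dumps(b1_params, indent=2))
        written["b1_params"] = supp_dir / "hMRI_map_creation_b1map_params.json"
    if config.rf_sens != "none":
        rf_params = {
            "mode": config.rf_sens,
            "smooth_fwhm_mm": config.rf_smooth_fwhm_mm,
            "maps": {c: str(p) for c, p in config.rf_map_paths.items()},
        }
        (supp_dir / "hMRI_map_creation_rfsens_params.json").write_text(json.dumps(rf_params, indent=2))
        written["rfsens_params"] = supp_dir / "hMRI_map_creation_rfsens_params.json"

    return written


def rerun_from_provenance(provenance_json: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Re-execute a run from the config stored in any of its output JSONs."""
    d = json.loads(Path(provenance_json).read_text())
    if "config" in d:  # job JSON
        cfg = d["config"]
    else:  # provenance record: find the config step
        steps = [s for s in d.get("steps", []) if s["step"] == "config"]
        if not steps:
            raise ConfigurationError("no config step in provenance record")
        cfg = steps[0]["params"]["config"]
    config = PipelineConfig.from_dict(cfg)
    config.out_dir = str(out_dir)
    return create_maps(config)


def process_maps(
    qmaps: dict[str, ImageVolume],
    weight_maps: list[TissueWeightMap],
    fwhm_mm: float,
    mask_threshold: float = 0.05,
    out_dir: str | Path | None = None,
) -> dict[str, list]:
    """Tissue-weighted smoothing of a set of quantitative maps.

    Returns per map name the list of per-tissue :class:`SmoothedMap`; when
    ``out_dir`` is given, writes each smoothed map and its companion mask.
    """
    if not qmaps:
        raise ConfigurationError("no maps to process")
    ref = next(iter(qmaps.values()))
    for name, vol in qmaps.items():
        if vol.shape != ref.shape:
            raise ConfigurationError(f"map {name!r} not on the common grid")
        for wm in weight_maps:
            if wm.weights.shape != vol.shape:
                raise ConfigurationError("tissue weights not on the map grid")
    out: dict[str, list] = {}
    for name, vol in qmaps.items():
        smoothed = vbq_smooth_per_tissue(vol, weight_maps, fwhm_mm, mask_threshold=mask_threshold)
        out[name] = smoothed
        if out_dir is not None:
            for sm in smoothed:
                stem = f"{name}_{sm.tissue}_vbq{fwhm_mm:g}mm"
                write_volume(sm.as_volume(), Path(out_dir) / f"{stem}.nii")
                write_volume(sm.mask_volume(), Path(out_dir) / f"{stem}_mask.nii")
    return out
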