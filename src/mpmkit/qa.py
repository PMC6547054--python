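"""Quality-assessment summary measures.

Two descriptive indices are reported, both derived from the joint decay
fit: the pooled standard deviation of log-domain fit residuals per contrast
(a proxy for intra-scan degradation such as head motion, evaluated within a
tissue mask), and a robust pairwise dispersion of log-intercept differences
between contrasts (sensitive to spatially varying inconsistency such as
between-scan motion or receive-field changes, insensitive to global
scaling).  No pass/fail thresholds are applied: interpretation is left to
the user and the report labels the motion indices as proxies.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import RESULTS_DIR, SUPPLEMENTARY_DIR, MetadataError
from .estatics import EstaticsFit

__all__ = ["QAReport", "QA_FILENAME", "residual_sd", "inter_contrast_index", "write_qa", "build_qa_report"]

QA_FILENAME = "hMRI_map_creation_quality_assessment.json"


@dataclass
class QAReport:
    """Serialisable quality-assessment summary."""

    residual_sd: dict[str, float] = field(default_factory=dict)
    inter_contrast: dict[str, float] = field(default_factory=dict)  # "PDw/T1w" -> MAD
    n_invalid_voxels: int = 0
    n_clipped_r2s: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "residual_sd": {k: float(v) for k, v in self.residual_sd.items()},
            "inter_contrast_mad": {k: float(v) for k, v in self.inter_contrast.items()},
            "n_invalid_voxels": int(self.n_invalid_voxels),
            "n_clipped_r2s": int(self.n_clipped_r2s),
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QAReport":
        validate_qa_dict(d)
        return cls(
            residual_sd=dict(d["residual_sd"]),
            inter_contrast=dict(d["inter_contrast_mad"]),
            n_invalid_voxels=d["n_invalid_voxels"],
            n_clipped_r2s=d["n_clipped_r2s"],
            notes=list(d["notes"]),
        )


def validate_qa_dict(d: dict) -> None:
    if not isinstance(d, dict):
        raise MetadataError("QA report must be a JSON object")
    for key, typ in (
        ("residual_sd", dict),
        ("inter_contrast_mad", dict),
        ("n_invalid_voxels", int),
        ("n_clipped_r2s", int),
        ("notes", list),
    ):
        if not isinstance(d.get(key), typ):
            raise MetadataError(f"QA report field {key!r} missing or wrong type")
    for sd in d["residual_sd"].values():
        if not isinstance(sd, (int, float)) or sd < 0:
            raise MetadataError("residual SD must be a nonnegative number")


def residual_sd(fit: EstaticsFit, contrast: str, mask: np.ndarray) -> float:
    """SD of log-domain residuals pooled over mask voxels and echoes.

    Invariant under global scaling of the contrast's signals (a global
    factor only shifts the intercept) and zero for an exact fit.
    """
    mask = np.asarray(mask, dtype=bool) & fit.valid
    if not mask.any():
        raise ValueError("empty mask")
    if contrast not in fit.residuals:
        raise KeyError(f"no residuals for contrast {contrast!r}")
    res = fit.residuals[contrast][:, mask]
    return float(res.std())


def inter_contrast_index(fit: EstaticsFit, mask: np.ndarray) -> pd.DataFrame:
    """Pairwise robust dispersion of log-intercept differences.

    For each contrast pair the voxelwise difference of log intercepts has
    its mask-median removed (discarding global scale) and the median
    absolute deviation of the remainder is reported.  Spatially uniform
    inter-contrast differences therefore score zero; spatially varying
    inconsistency (e.g. differing receive fields after motion) scores
    positive.
    """
    contrasts = fit.contrasts
    if len(contrasts) < 2:
        return pd.DataFrame(columns=["pair", "mad"]).set_index("pair")
    mask = np.asarray(mask, dtype=bool) & fit.valid
    if not mask.any():
        raise ValueError("empty mask")
    rows = []
    for c1, c2 in itertools.combinations(contrasts, 2):
        d = fit.intercept_log[c1][mask] - fit.intercept_log[c2][mask]
        d = d - np.median(d)
        rows.append({"pair": f"{c1}/{c2}", "mad": float(np.median(np.abs(d)))})
    return pd.DataFrame(rows).set_index("pair")


def build_qa_report(fit: EstaticsFit, mask: np.ndarray) -> QAReport:
    report = QAReport(
        n_invalid_voxels=int((~fit.valid).sum()),
        n_clipped_r2s=fit.n_clipped,
        notes=[
            "residual_sd is a proxy for intra-scan degradation (e.g. motion), "
            "computed from log-domain decay-fit residuals within the supplied mask",
            "inter_contrast_mad is a proxy for between-scan inconsistency; "
            "no pass/fail thresholds are applied",
        ],
    )
    for c in fit.contrasts:
        report.residual_sd[c] = residual_sd(fit, c, mask)
    table = inter_contrast_index(fit, mask)
    for pair, row in table.iterrows():
        report.inter_contrast[str(pair)] = float(row["mad"])
    return report


def write_qa(report: QAReport, out_dir: str | Path) -> Path:
    """Write the QA JSON into ``Results/Supplementary``."""
    out_dir = Path(out_dir)
    target = out_dir
    if target.name != SUPPLEMENTARY_DIR:
        target = out_dir / RESULTS_DIR / SUPPLEMENTARY_DIR
    target.mkdir(parents=True, exist_ok=True)
    path = target / QA_FILENAME
    path.write_text(json.dumps(report.to_dict(), indent=2))
    return path
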