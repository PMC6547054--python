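"""R1, amplitude/PD and MT-saturation maps from TE=0 intercepts.

The variable-flip-angle pair (PDw, T1w) is inverted with the small-TR /
small-angle rational approximations of the Ernst equation; MT saturation is
the per-excitation saturation of the MTw steady state after removing the T1
and flip-angle dependence.  The transmit field fT scales the local flip
angles; receive-field correction happens upstream on the signals.

Unit regimes are deliberately explicit per formula to avoid silent 1000x
errors: the R1/A rational formulas work with TR in milliseconds (R1 then
converted to s^-1); the MT-saturation formula wants TR in seconds and R1 in
s^-1.  Angles are radians everywhere inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AcquisitionMetadata, ProvenanceRecord

__all__ = [
    "ParameterMapSet",
    "SpoilingCoefficients",
    "DegenerateProtocolError",
    "CalibrationError",
    "compute_r1",
    "compute_amplitude",
    "compute_mt_sat",
    "b1_correct_mt",
    "apply_spoiling_correction",
    "calibrate_pd",
]


class DegenerateProtocolError(ValueError):
    """The two flip-angle acquisitions do not span a solvable system."""


class CalibrationError(ValueError):
    """PD calibration mask empty or degenerate."""


@dataclass
class SpoilingCoefficients:
    """Imperfect-spoiling correction polynomials.

    The corrected longitudinal relaxation time is
    ``T1_corr = Acoef(fT) + Bcoef(fT) * T1_app`` (ms), with both
    coefficients low-order polynomials in the local transmit field fT.
    Coefficients are protocol-specific and supplied by the user; the
    identity is ``a_poly=(0,)``, ``b_poly=(1,)``.
    """

    a_poly: tuple[float, ...] = (0.0,)   # ms; lowest-order coefficient first
    b_poly: tuple[float, ...] = (1.0,)   # dimensionless; lowest-order first
    protocol_fingerprint: str = ""

    def acoef(self, ft: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(ft, self.a_poly)

    def bcoef(self, ft: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(ft, self.b_poly)


@dataclass
class ParameterMapSet:
    """Bundle of output maps on the common grid."""

    r2s: np.ndarray | None = None       # s^-1
    r1: np.ndarray | None = None        # s^-1
    a: np.ndarray | None = None         # a.u.
    pd: np.ndarray | None = None        # p.u.
    mtsat: np.ndarray | None = None     # p.u.
    valid: np.ndarray | None = None
    affine: np.ndarray | None = None
    provenance: ProvenanceRecord = field(default_factory=ProvenanceRecord)


def _local_angles(meta: AcquisitionMetadata, ft) -> np.ndarray:
    ft = 1.0 if ft is None else np.asarray(ft, dtype=float)
    return ft * meta.flip_angle_rad


def compute_r1(
    s_pd0: np.ndarray,
    s_t10: np.ndarray,
    meta_pd: AcquisitionMetadata,
    meta_t1: AcquisitionMetadata,
    ft: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal relaxation rate from the two-flip-angle intercepts.

    R1 = 1/2 (S_T1 a_T1/TR_T1 - S_PD a_PD/TR_PD) / (S_PD/a_PD - S_T1/a_T1)

    with local angles a_c = fT * a_nominal,c in radians and TR in ms;
    returned in s^-1 together with a validity mask (False where the
    denominator is non-positive or a signal is non-positive).
    """
    a_pd = _local_angles(meta_pd, ft)
    a_t1 = _local_angles(meta_t1, ft)
    if np.all(np.isclose(a_pd, a_t1)):
        raise DegenerateProtocolError(
            "identical effective flip angles: the variable-flip-angle system is unsolvable"
        )
    s_pd0 = np.asarray(s_pd0, dtype=float)
    s_t10 = np.asarray(s_t10, dtype=float)
    num = 0.5 * (s_t10 * a_t1 / meta_t1.tr_ms - s_pd0 * a_pd / meta_pd.tr_ms)
    den = s_pd0 / a_pd - s_t10 / a_t1
    # the formula is symmetric under swapping the two inputs (both numerator
    # and denominator change sign), so validity is judged on the recovered
    # rate, not on the sign convention of the denominator
    nonzero = np.abs(den) > 1e-300
    r1_per_ms = np.divide(num, den, out=np.zeros_like(num), where=nonzero)
    valid = nonzero & (s_pd0 > 0) & (s_t10 > 0) & (r1_per_ms > 0)
    r1_per_ms = np.where(valid, r1_per_ms, 0.0)
    return r1_per_ms * 1000.0, valid


def compute_amplitude(
    s_pd0: np.ndarray,
    s_t10: np.ndarray,
    meta_pd: AcquisitionMetadata,
    meta_t1: AcquisitionMetadata,
    ft: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apparent amplitude A (a.u., proportional to PD) from the intercept pair.

    A = S_PD S_T1 (TR_PD a_T1/a_PD - TR_T1 a_PD/a_T1)
        / (S_T1 TR_PD a_T1 - S_PD TR_T1 a_PD)
    """
    a_pd = _local_angles(meta_pd, ft)
    a_t1 = _local_angles(meta_t1, ft)
    if np.all(np.isclose(a_pd, a_t1)):
        raise DegenerateProtocolError(
            "identical effective flip angles: the variable-flip-angle system is unsolvable"
        )
    s_pd0 = np.asarray(s_pd0, dtype=float)
    s_t10 = np.asarray(s_t10, dtype=float)
    num = s_pd0 * s_t10 * (meta_pd.tr_ms * a_t1 / a_pd - meta_t1.tr_ms * a_pd / a_t1)
    den = s_t10 * meta_pd.tr_ms * a_t1 - s_pd0 * meta_t1.tr_ms * a_pd
    nonzero = np.abs(den) > 1e-12 * np.abs(num).max(initial=1.0)
    a_map = np.divide(num, den, out=np.zeros_like(num), where=nonzero)
    valid = nonzero & (s_pd0 > 0) & (s_t10 > 0) & (a_map > 0)
    a_map = np.where(valid, a_map, 0.0)
    return a_map, valid


def compute_mt_sat(
    s_mt0: np.ndarray,
    a_map: np.ndarray,
    r1: np.ndarray,
    meta_mt: AcquisitionMetadata,
    ft: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-excitation MT saturation delta in percent units.

    delta = 100 [ (A a_MT / S_MT - 1) R1 TR_MT - a_MT^2 / 2 ]

    with the local MT-pulse excitation angle a_MT in radians, TR in seconds
    and R1 in s^-1.  Removing the A, R1 and flip-angle dependence is what
    distinguishes this semi-quantitative measure from the plain MT ratio.
    """
    a_mt = _local_angles(meta_mt, ft)
    tr_s = meta_mt.tr_ms / 1000.0
    s_mt0 = np.asarray(s_mt0, dtype=float)
    valid = s_mt0 > 0
    ratio = np.divide(np.asarray(a_map) * a_mt, s_mt0, out=np.ones_like(s_mt0), where=valid)
    delta = 100.0 * ((ratio - 1.0) * np.asarray(r1) * tr_s - a_mt ** 2 / 2.0)
    return np.where(valid, delta, 0.0), valid


def b1_correct_mt(
    mtsat: np.ndarray,
    ft: np.ndarray | None,
    c: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual transmit-field correction of the MT-saturation map.

    delta_corr = delta (1 - C) / (1 - C fT); the small empirical constant C
    (default 0.4, configurable) captures the residual B1 dependence of the
    MT pulse's saturation efficiency.  fT absent or C=0 are identities.
    """
    if not 0 <= c < 1:
        raise ValueError("C must be in [0, 1)")
    if ft is None or c == 0:
        return np.asarray(mtsat, dtype=float).copy(), np.ones(np.shape(mtsat), dtype=bool)
    ft = np.asarray(ft, dtype=float)
    den = 1.0 - c * ft
    valid = den > 0
    corr = np.divide(np.asarray(mtsat) * (1.0 - c), den,
                     out=np.zeros(np.broadcast(mtsat, den).shape), where=valid)
    return corr, valid


def apply_spoiling_correction(
    r1: np.ndarray,
    ft: np.ndarray | None,
    coeffs: SpoilingCoefficients | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Imperfect-spoiling correction of the apparent R1 map.

    Disabled (identity) when ``coeffs`` is None — the default, since the
    correction polynomials are protocol-specific and must be supplied.
    Works on T1 = 1/R1 in ms: T1_corr = Acoef(fT) + Bcoef(fT) T1_app.
    """
    r1 = np.asarray(r1, dtype=float)
    if coeffs is None:
        return r1.copy(), np.ones(r1.shape, dtype=bool)
    ft_arr = np.ones(r1.shape) if ft is None else np.asarray(ft, dtype=float)
    pos = r1 > 0
    t1_app = np.divide(1000.0, r1, out=np.zeros_like(r1), where=pos)  # ms
    t1_corr = coeffs.acoef(ft_arr) + coeffs.bcoef(ft_arr) * t1_app
    valid = pos & (t1_corr > 0)
    r1_corr = np.divide(1000.0, t1_corr, out=np.zeros_like(r1), where=valid)
    return r1_corr, valid


def calibrate_pd(
    a_map: np.ndarray,
    calibration_mask: np.ndarray,
    target_pu: float = 100.0,
) -> np.ndarray:
    """Scale the amplitude map so its mean over the mask equals the target.

    PD = A * target / mean(A over mask).  The global scaling preserves all
    ratios; with a white-matter mask the conventional target is 69 p.u.,
    otherwise the map is relative with mean 100 p.u. over the validity mask.
    """
    mask = np.asarray(calibration_mask, dtype=bool)
    if not mask.any():
        raise CalibrationError("empty calibration mask")
    a_map = np.asarray(a_map, dtype=float)
    m = a_map[mask].mean()
    if m == 0:
        raise CalibrationError("zero mean amplitude over the calibration mask")
    return a_map * (target_pu / m)
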