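"""Joint R2* estimation across contrasts (ESTATICS).

All multi-echo contrasts share one effective transverse decay, so the
log-signals of every echo of every contrast obey

    ln S_c(TE) = ln S_c(0) - R2* TE

with a single slope and one intercept per contrast.  The joint ordinary
least-squares fit pools echoes from all contrasts, which raises the
effective SNR of the R2* estimate relative to fitting each contrast alone.

Voxels with any non-positive signal among the used echoes are excluded from
the fit (the logarithm is undefined there) and flagged in the validity
mask; no epsilon-clipping happens inside the estimator.  Negative R2*
estimates are kept raw for residual/QA purposes and clipped to zero only in
the exported map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ImageVolume, MultiEchoSeries, assert_common_grid

__all__ = ["EstaticsFit", "ModelError", "fit_estatics", "fit_r2s_single", "extrapolate_te_zero"]


class ModelError(ValueError):
    """The requested fit is not identifiable from the given data."""


@dataclass
class EstaticsFit:
    """Result of the joint log-linear decay fit.

    ``r2s_raw`` keeps negative estimates; ``r2s`` is the exported, clipped
    map.  ``intercept_log`` holds ln S_c(0) per contrast; ``residuals`` the
    log-domain residual volumes (echo-first axis) used for quality
    assessment.  Values at invalid voxels are zero and must be interpreted
    through ``valid``.
    """

    r2s_raw: np.ndarray
    intercept_log: dict[str, np.ndarray]
    residuals: dict[str, np.ndarray]
    valid: np.ndarray
    affine: np.ndarray
    te_ms: dict[str, tuple[float, ...]] = field(default_factory=dict)
    n_clipped: int = 0
    max_te_ms: float | None = None

    @property
    def r2s(self) -> np.ndarray:
        return np.clip(self.r2s_raw, 0.0, None)

    @property
    def contrasts(self) -> list[str]:
        return list(self.intercept_log)

    def residual_variance(self, contrast: str) -> np.ndarray:
        """Per-voxel residual variance (a.u.^2 in log domain) for one contrast."""
        res = self.residuals[contrast]
        return np.where(self.valid, (res ** 2).mean(axis=0), 0.0)


def _select_echoes(series: MultiEchoSeries, max_te_ms: float | None):
    te = np.asarray(series.meta.te_ms)
    keep = np.ones(len(te), dtype=bool) if max_te_ms is None else te <= max_te_ms
    if keep.sum() < 2:
        raise ModelError(
            f"{series.meta.contrast_label}: fewer than 2 echoes available "
            "(single-echo data must use the single-echo pipeline path)"
        )
    return te[keep], series.stack()[keep]


def fit_estatics(
    series_list: list[MultiEchoSeries],
    max_te_ms: float | None = None,
) -> EstaticsFit:
    """Joint OLS fit of one shared R2* and per-contrast TE=0 intercepts.

    Parameters
    ----------
    series_list:
        One to three multi-echo contrasts on a common grid, each with at
        least two echoes (after the optional ``max_te_ms`` cut).
    max_te_ms:
        Optional echo-selection cap: echoes with TE above it are dropped.
        Default uses all echoes.
    """
    if not 1 <= len(series_list) <= 3:
        raise ValueError("fit_estatics takes 1-3 contrasts")
    labels = [s.meta.contrast_label for s in series_list]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate contrast labels: {labels}")
    shape, affine = assert_common_grid(series_list)

    tes, stacks = [], []
    for s in series_list:
        te, stack = _select_echoes(s, max_te_ms)
        tes.append(te)
        stacks.append(stack)

    n_obs = sum(len(t) for t in tes)
    n_par = len(series_list) + 1
    if n_obs < n_par:
        raise ModelError(f"{n_obs} observations cannot identify {n_par} parameters")

    # design: one intercept column per contrast, shared -TE slope column
    X = np.zeros((n_obs, n_par))
    row = 0
    for ci, te in enumerate(tes):
        X[row: row + len(te), ci] = 1.0
        X[row: row + len(te), -1] = -te
        row += len(te)

    signals = np.concatenate(stacks, axis=0).reshape(n_obs, -1)
    valid = np.all(signals > 0, axis=0).reshape(shape)
    logs = np.zeros_like(signals)
    np.log(signals, out=logs, where=signals > 0)

    pinv = np.linalg.pinv(X)
    beta = pinv @ logs  # (n_par, nvox)
    resid = logs - X @ beta

    flat_valid = valid.reshape(-1)
    r2s_per_ms = np.where(flat_valid, beta[-1], 0.0).reshape(shape)
    r2s_raw = r2s_per_ms * 1000.0  # 1/ms -> s^-1
    n_clipped = int(((r2s_raw < 0) & valid).sum())

    intercept_log, residuals, te_used = {}, {}, {}
    row = 0
    for ci, (lab, te) in enumerate(zip(labels, tes)):
        intercept_log[lab] = np.where(flat_valid, beta[ci], 0.0).reshape(shape)
        residuals[lab] = np.where(
            flat_valid, resid[row: row + len(te)], 0.0
        ).reshape((len(te),) + shape)
        te_used[lab] = tuple(te)
        row += len(te)

    return EstaticsFit(
        r2s_raw=r2s_raw,
        intercept_log=intercept_log,
        residuals=residuals,
        valid=valid,
        affine=affine,
        te_ms=te_used,
        n_clipped=n_clipped,
        max_te_ms=max_te_ms,
    )


def fit_r2s_single(
    series: MultiEchoSeries, max_te_ms: float | None = None
) -> tuple[ImageVolume, ImageVolume]:
    """Per-contrast exponential-decay fit (same conventions as the joint fit).

    Returns the clipped R2* map (s^-1) and the TE=0 signal-domain intercept.
    """
    fit = fit_estatics([series], max_te_ms=max_te_ms)
    r2s = ImageVolume(data=fit.r2s, affine=fit.affine)
    s0 = extrapolate_te_zero(series, fit)
    return r2s, s0


def extrapolate_te_zero(series: MultiEchoSeries, fit: EstaticsFit) -> ImageVolume:
    """Fitted S(TE=0) volume for the series' contrast.

    Removes the T2* weighting from the contrast, which is what de-biases the
    PD map (and, to a lesser degree, the R1 and MT inputs) downstream.
    Invalid voxels carry 0.
    """
    label = series.meta.contrast_label
    if label not in fit.intercept_log:
        raise KeyError(f"contrast {label!r} absent from fit (has {fit.contrasts})")
    s0 = np.where(fit.valid, np.exp(fit.intercept_log[label]), 0.0)
    return ImageVolume(data=s0, affine=fit.affine)
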