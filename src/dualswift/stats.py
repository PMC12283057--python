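"""Functional statistics: voxelwise GLM with a gamma-variate response model,
cluster extraction, threshold-free cluster enhancement (TFCE), sign-flip
permutation group inference with family-wise-error control, and response
time-course / peak-latency analysis.

Subject-level maps are thresholded at z > 3.1 for cluster reporting; group
inference enhances the one-sample t map with TFCE and corrects p-values by
the max-statistic distribution over sign flips (exhaustive when the number
of subjects allows, 2^n <= 4096).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special
from scipy import stats as sps

from .phantom import IRFParams, Paradigm, response_curve
from .preprocess import prewhiten

__all__ = [
    "StatsParams",
    "GLMResult",
    "build_design",
    "fit_glm",
    "extract_clusters",
    "tfce",
    "group_inference",
    "extract_timecourse",
    "compare_peak_latencies",
]

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class StatsParams:
    """Inference settings (TFCE defaults E=0.5, H=2 as in common practice)."""

    z_threshold: float = 3.1
    alpha_fwe: float = 0.05
    n_permutations: int = 1000   # used only when sign flips are not exhaustive
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh: float = 0.01        # step as a fraction of the map maximum
    exhaustive_max_subjects: int = 12
    # modelled hemodynamic delay per FOV (s): spinal responses lag cortical
    design_latencies: tuple = (0.0, 9.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_fwe < 1.0:
            raise ValueError("alpha_fwe must lie in (0, 1)")
        if self.tfce_e <= 0 or self.tfce_h <= 0 or self.tfce_dh <= 0:
            raise ValueError("TFCE parameters must be positive")


@dataclass
class GLMResult:
    """Voxelwise GLM output on a 3D grid (values outside the mask are 0)."""

    beta: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    design: np.ndarray
    dof: float
    residuals: np.ndarray | None = None   # (T', n_mask_voxels)


def build_design(
    paradigm: Paradigm,
    irf: IRFParams,
    volume_tr: float,
    n_volumes: int,
    confounds: np.ndarray | None = None,
    response_latency: float = 0.0,
) -> np.ndarray:
    """Design matrix: unit-peak boxcar (x) gamma-IRF task regressor,
    optional confound columns, and an intercept (last column).

    ``response_latency`` delays the modelled response (s); spinal-cord
    hemodynamics lag the brain's, and a matched regressor preserves
    sensitivity there.
    """
    task = response_curve(paradigm, irf, volume_tr, latency_shift=response_latency)
    if len(task) < n_volumes:
        task = np.pad(task, (0, n_volumes - len(task)))
    task = task[:n_volumes]
    cols = [task]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_volumes:
            confounds = confounds.T
        cols.extend(confounds.T)
    cols.append(np.ones(n_volumes))
    return np.column_stack(cols)


def _t_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Map t statistics to z through matched tail probabilities (sign-safe,
    stable far into the tails via log survival functions)."""
    t = np.asarray(t, dtype=float)
    sign = np.sign(t)
    logp = sps.t.logsf(np.abs(t), dof)
    z = -special.ndtri_exp(logp)
    return sign * z


_Z_CAP = 38.0  # beyond double-precision tail resolution


def fit_glm(
    data: np.ndarray,
    design: np.ndarray,
    mask: np.ndarray | None = None,
    ar_order: int = 1,
    keep_residuals: bool = False,
) -> GLMResult:
    """Voxelwise least squares of a 4D series onto the design.

    With ``ar_order = 1`` an initial OLS fit estimates per-voxel AR(1)
    autocorrelation from its residuals and the fit is repeated on
    Cochrane-Orcutt-transformed data and design (single pass).  The z map
    converts the task-column t statistic through the t -> z quantile map;
    voxels with zero residual variance are capped at +/-38.
    """
    data = np.asarray(data, dtype=float)
    t_len = data.shape[0]
    shape3 = data.shape[1:]
    if mask is None:
        mask = np.ones(shape3, dtype=bool)
    mask = mask.astype(bool)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    y = data.reshape(t_len, -1)[:, mask.ravel()]

    beta, res0 = _ols(design, y)
    if ar_order >= 1:
        yw, xw, _phi = prewhiten(res0, y, design, ar_order)
        beta, tval, sigma2, dof, res = _per_voxel_gls(xw, yw)
    else:
        tval, sigma2, dof, res = _ols_stats(design, y, beta, res0)

    z = np.where(np.isfinite(tval), _t_to_z(np.clip(tval, -1e8, 1e8), dof), 0.0)
    z = np.clip(z, -_Z_CAP, _Z_CAP)

    out_beta = np.zeros(shape3)
    out_var = np.zeros(shape3)
    out_z = np.zeros(shape3)
    out_beta[mask] = beta
    out_var[mask] = sigma2
    out_z[mask] = z
    return GLMResult(
        beta=out_beta,
        variance=out_var,
        z=out_z,
        mask=mask,
        design=design,
        dof=dof,
        residuals=res if keep_residuals else None,
    )


def _ols(design: np.ndarray, y: np.ndarray):
    beta_all, *_ = np.linalg.lstsq(design, y, rcond=None)
    res = y - design @ beta_all
    return beta_all[0], res


def _ols_stats(design: np.ndarray, y: np.ndarray, beta_task: np.ndarray, res: np.ndarray):
    t_len, p = design.shape
    dof = t_len - p
    sigma2 = (res**2).sum(axis=0) / max(dof, 1)
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta_task / se, np.sign(beta_task) * np.inf)
    return tval, sigma2, dof, res


def _per_voxel_gls(xw: np.ndarray, yw: np.ndarray):
    """Least squares with a per-voxel design stack xw (V, T, P), yw (T, V)."""
    v = xw.shape[0]
    t_len, p = xw.shape[1], xw.shape[2]
    dof = t_len - p
    xtx = np.einsum("vtp,vtq->vpq", xw, xw)
    xty = np.einsum("vtp,tv->vp", xw, yw)
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]     # (V, P)
    fitted = np.einsum("vtp,vp->tv", xw, beta)
    res = yw - fitted
    sigma2 = (res**2).sum(axis=0) / max(dof, 1)
    xtx_inv00 = np.linalg.inv(xtx)[:, 0, 0]
    se = np.sqrt(np.maximum(sigma2 * xtx_inv00, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[:, 0] / se, np.sign(beta[:, 0]) * np.inf)
    return beta[:, 0], tval, sigma2, dof, res


def extract_clusters(
    zmap: np.ndarray,
    mask: np.ndarray | None = None,
    params: StatsParams | None = None,
) -> pd.DataFrame:
    """Connected components (6-connectivity) of {z > z_threshold}.

    One row per cluster: voxel count, peak z, mean z, centroid (voxel
    coordinates); sorted by size descending (peak z breaks ties).
    """
    params = params or StatsParams()
    zmap = np.asarray(zmap, dtype=float)
    if not np.all(np.isfinite(zmap)):
        raise ValueError("z map contains non-finite values")
    supra = zmap > params.z_threshold
    if mask is not None:
        supra &= mask.astype(bool)
    labels, n = ndimage.label(supra, structure=_SIX_CONN)
    rows = []
    for i in range(1, n + 1):
        sel = labels == i
        zs = zmap[sel]
        centroid = np.mean(np.argwhere(sel), axis=0)
        rows.append(
            {
                "cluster": i,
                "n_voxels": int(sel.sum()),
                "peak_z": float(zs.max()),
                "mean_z": float(zs.mean()),
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster", "n_voxels", "peak_z", "mean_z",
            "centroid_x", "centroid_y", "centroid_z",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["n_voxels", "peak_z"], ascending=False, kind="stable"
        ).reset_index(drop=True)
    return table


def cluster_mask(zmap: np.ndarray, table_row: pd.Series, params: StatsParams | None = None) -> np.ndarray:
    """Recover the binary mask of one cluster row from its z map."""
    params = params or StatsParams()
    labels, _ = ndimage.label(zmap > params.z_threshold, structure=_SIX_CONN)
    lab = labels[int(round(table_row["centroid_x"])), int(round(table_row["centroid_y"])), int(round(table_row["centroid_z"]))]
    if lab == 0:  # centroid may fall outside a concave cluster; pick nearest
        coords = np.argwhere(labels > 0)
        c = np.array([table_row["centroid_x"], table_row["centroid_y"], table_row["centroid_z"]])
        lab = labels[tuple(coords[np.argmin(((coords - c) ** 2).sum(axis=1))])]
    return labels == lab


def tfce(
    statmap: np.ndarray,
    mask: np.ndarray | None = None,
    params: StatsParams | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement by explicit threshold summation.

    TFCE(v) = sum_h e(h, v)^E * h^H * dh over thresholds h = dh_abs, 2*dh_abs,
    ..., max(stat), where e(h, v) is the 6-connected extent of the component
    containing v at height h and dh_abs = tfce_dh * max(stat).  Negative
    input values contribute nothing (enhance a sign-flipped map separately).
    """
    params = params or StatsParams()
    stat = np.asarray(statmap, dtype=float).copy()
    if mask is not None:
        stat = np.where(mask.astype(bool), stat, 0.0)
    peak = stat.max()
    out = np.zeros_like(stat)
    if peak <= 0:
        return out
    dh = params.tfce_dh * peak
    heights = np.arange(dh, peak + 0.5 * dh, dh)
    for h in heights:
        supra = stat >= h
        labels, n = ndimage.label(supra, structure=_SIX_CONN)
        if n == 0:
            continue
        extents = np.bincount(labels.ravel())
        extents[0] = 0
        out += np.where(
            supra, (extents[labels].astype(float) ** params.tfce_e) * h**params.tfce_h, 0.0
        )
    return out * dh


def _sign_flip_matrix(n_subjects: int, params: StatsParams, seed: int) -> np.ndarray:
    if n_subjects <= params.exhaustive_max_subjects:
        bits = np.arange(2**n_subjects)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n_subjects)[None, :]) & 1)
        return signs.astype(float)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(params.n_permutations, n_subjects))
    signs[0] = 1.0  # include the identity so p >= 1/n_perm
    return signs


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def group_inference(
    subject_maps: np.ndarray,
    mask: np.ndarray | None = None,
    params: StatsParams | None = None,
    seed: int = 0,
) -> dict:
    """One-sample group test by sign-flipping with TFCE and FWE correction.

    The statistic is the TFCE-enhanced one-sample t map of the subject
    effect maps; the FWE-corrected p-value at voxel v is the fraction of
    sign-flip permutations (exhaustive 2^n when n <= 12, else
    ``n_permutations`` random flips including the identity) whose maximum
    statistic reaches TFCE(v).  Voxels with p < alpha are significant.

    Returns dict with keys: t, tfce, p_fwe, significant, n_permutations.
    """
    params = params or StatsParams()
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim < 2 or maps.shape[0] < 2:
        raise ValueError("need at least two subject maps")
    signs = _sign_flip_matrix(maps.shape[0], params, seed)
    n_perm = signs.shape[0]
    t_obs = _one_sample_t(maps)
    tfce_obs = tfce(t_obs, mask, params)
    max_stats = np.empty(n_perm)
    flat = maps.reshape(maps.shape[0], -1)
    for i in range(n_perm):
        t_perm = _one_sample_t((signs[i][:, None] * flat)).reshape(maps.shape[1:])
        max_stats[i] = tfce(t_perm, mask, params).max()
    p_fwe = (max_stats >= tfce_obs[..., None]).mean(axis=-1)
    if mask is not None:
        p_fwe = np.where(mask.astype(bool), p_fwe, 1.0)
    return {
        "t": t_obs,
        "tfce": tfce_obs,
        "p_fwe": p_fwe,
        "significant": p_fwe < params.alpha_fwe,
        "n_permutations": n_perm,
    }


def extract_timecourse(
    data: np.ndarray,
    roi_mask: np.ndarray,
    paradigm: Paradigm,
    volume_tr: float,
    irf: IRFParams | None = None,
) -> dict:
    """ROI-mean percent-signal-change curve, block average, peak latency.

    Baseline is the mean over the initial rest period.  The block-triggered
    average spans one on+off cycle from each block onset.  Peak latency
    (volume-TR resolution, relative to block onset): when an ``irf`` is
    given, the block average is matched against integer-volume shifts of
    the modelled block response and the latency is the best-fit shift plus
    the template's own time to peak — robust because the plateau-shaped
    response makes a plain argmax noise-fragile.  Without an ``irf`` the
    time of first reaching 95% of the maximum is used.
    """
    roi_mask = roi_mask.astype(bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    data = np.asarray(data, dtype=float)
    roi = data.reshape(data.shape[0], -1)[:, roi_mask.ravel()].mean(axis=1)
    n_base = max(int(paradigm.initial_rest // volume_tr), 1)
    baseline = roi[:n_base].mean()
    if baseline == 0:
        raise ValueError("zero baseline signal in ROI")
    pct = 100.0 * (roi - baseline) / baseline

    block_len = int(round((paradigm.block_on + paradigm.block_off) / volume_tr))
    blocks = []
    for onset in paradigm.onsets:
        i0 = int(round(onset / volume_tr))
        seg = pct[i0 : i0 + block_len]
        if len(seg) == block_len:
            blocks.append(seg)
    block_avg = np.mean(blocks, axis=0) if blocks else np.empty(0)
    if len(block_avg):
        peak_value = float(block_avg.max())
        if irf is not None:
            peak_latency = _template_latency(block_avg, paradigm, irf, volume_tr)
        elif peak_value > 0:
            peak_latency = float(np.argmax(block_avg >= 0.95 * peak_value)) * volume_tr
        else:
            peak_latency = float(np.argmax(block_avg)) * volume_tr
    else:
        peak_latency, peak_value = np.nan, np.nan
    return {
        "percent_change": pct,
        "block_average": block_avg,
        "block_time": np.arange(len(block_avg)) * volume_tr,
        "peak_latency": peak_latency,
        "peak_value": peak_value,
        "baseline": baseline,
    }


def _template_latency(
    block_avg: np.ndarray, paradigm: Paradigm, irf: IRFParams, volume_tr: float
) -> float:
    """Best-fit integer-volume shift of the modelled block response, plus
    the template's own time to (95% of) peak."""
    single = Paradigm(
        initial_rest=0.0, block_on=paradigm.block_on,
        block_off=paradigm.block_off, n_blocks=1,
    )
    tpl = response_curve(single, irf, volume_tr)[: len(block_avg)]
    n = len(block_avg)
    centred = block_avg - block_avg.mean()
    best_lag, best_corr = 0, -np.inf
    for lag in range(0, n // 2 + 1):
        shifted = np.zeros(n)
        shifted[lag:] = tpl[: n - lag]
        shifted -= shifted.mean()
        denom = np.linalg.norm(shifted) * np.linalg.norm(centred)
        if denom == 0:
            continue
        c = float(np.dot(shifted, centred) / denom)
        if c > best_corr:
            best_corr, best_lag = c, lag
    ttp = float(np.argmax(tpl >= 0.95 * tpl.max())) * volume_tr
    return best_lag * volume_tr + ttp


def compare_peak_latencies(latencies_a, latencies_b) -> dict:
    """Paired t test on per-subject peak-latency differences (a - b)."""
    a = np.asarray(latencies_a, dtype=float)
    b = np.asarray(latencies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired latency vectors of equal length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        warnings.warn("zero variance of latency differences; p is a limit case")
        if np.allclose(diff.mean(), 0.0):
            return {"t": 0.0, "p": 1.0, "mean_difference": 0.0}
        return {"t": np.sign(diff.mean()) * np.inf, "p": 0.0, "mean_difference": float(diff.mean())}
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_difference": float(diff.mean())}
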