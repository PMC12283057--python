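"""fMRI preprocessing: motion estimation/correction, ICA-based motion
regression, high-pass filtering, and AR(1) prewhitening.

Motion is estimated from the signal center of mass in three dimensions and
corrected by translation-only registration to the first volume.  Residual
motion artefacts are removed by decomposing the series into spatial
independent components and regressing out those classified as motion by two
rules: time-course correlation with a motion parameter exceeding 0.75, or
more than 70% of the component's (|z| > 2) spatial-map voxels lying on the
object's edge shell or outside it.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import FastICA

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocParams",
    "MotionTrace",
    "ComponentSet",
    "center_of_mass_motion",
    "rigid_motion_correct",
    "decompose_components",
    "classify_motion_components",
    "regress_out",
    "highpass",
    "dct_highpass_basis",
    "prewhiten",
    "preprocess_series",
]


@dataclass(frozen=True)
class PreprocParams:
    """Thresholds and sizes of the preprocessing chain."""

    n_components: int = 15
    motion_corr_threshold: float = 0.75   # strict: |r| must exceed this
    edge_fraction_threshold: float = 0.70  # strict: fraction must exceed this
    highpass_cutoff: float = 0.01          # Hz
    edge_width: int = 1                    # voxels, edge-shell thickness
    map_z_threshold: float = 2.0           # |z| defining a component's voxels
    ar_order: int = 1

    def __post_init__(self) -> None:
        for name in ("motion_corr_threshold", "edge_fraction_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.highpass_cutoff <= 0:
            raise ValueError("highpass_cutoff must be positive")


@dataclass
class MotionTrace:
    """Per-volume displacement estimates, voxels; volume 0 is the reference."""

    com_displacement: np.ndarray        # (T, 3) center-of-mass displacement
    rigid_translations: np.ndarray | None = None  # (T, 3) from registration
    rigid_rotations: np.ndarray | None = None     # (T, 3), zeros here

    @property
    def parameters(self) -> np.ndarray:
        """(T, 3) motion parameters used for component classification."""
        return self.com_displacement

    @property
    def max_displacement(self) -> float:
        """Largest absolute single-axis displacement, voxels."""
        return float(np.max(np.abs(self.com_displacement)))

    def to_table(self) -> pd.DataFrame:
        t = np.arange(len(self.com_displacement))
        return pd.DataFrame(
            {
                "volume": t,
                "dx": self.com_displacement[:, 0],
                "dy": self.com_displacement[:, 1],
                "dz": self.com_displacement[:, 2],
            }
        )


@dataclass
class ComponentSet:
    """Spatial ICA decomposition of a 4D series."""

    maps: np.ndarray          # (n_components, x, y, z), z-scored spatial maps
    timecourses: np.ndarray   # (T, n_components), unit variance
    labels: list = field(default_factory=list)  # "signal" / "motion"

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def motion_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == "motion")

    def report(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_components):
            rows.append({"component": i, "label": self.labels[i] if self.labels else ""})
        return pd.DataFrame(rows)


def center_of_mass_motion(data: np.ndarray) -> MotionTrace:
    """Intensity-weighted centroid displacement of each volume vs volume 0."""
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError("expected a 4-D series (t, x, y, z)")
    coms = []
    for t in range(data.shape[0]):
        vol = data[t]
        total = vol.sum()
        if total == 0:
            raise ValueError(f"volume {t} is all-zero; center of mass undefined")
        coms.append(ndimage.center_of_mass(vol))
    coms = np.asarray(coms)
    return MotionTrace(com_displacement=coms - coms[0])


def _register_translation(ref: np.ndarray, mov: np.ndarray, upsample: int = 20):
    from skimage.registration import phase_cross_correlation

    shift, error, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample, normalization=None
    )
    return shift, error


def rigid_motion_correct(
    data: np.ndarray, upsample: int = 20
) -> tuple[np.ndarray, MotionTrace]:
    """Align every volume to volume 0 by subvoxel Fourier-shift registration.

    Translation-only: rotations are reported as zero.  Volumes whose
    normalised registration correlation falls below 0.2 are flagged and
    passed through uncorrected.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least two volumes to motion-correct")
    ref = data[0]
    out = np.empty_like(data)
    out[0] = ref
    shifts = np.zeros((data.shape[0], 3))
    ref_f = np.fft.fftn(ref)
    ref_norm = np.linalg.norm(ref)
    for t in range(1, data.shape[0]):
        shift, _ = _register_translation(ref, data[t], upsample)
        mov_f = np.fft.fftn(data[t])
        corrected = np.fft.ifftn(ndimage.fourier_shift(mov_f, shift)).real
        corr = float(
            np.dot(ref.ravel(), corrected.ravel())
            / max(ref_norm * np.linalg.norm(corrected), 1e-30)
        )
        if corr < 0.2:
            logger.warning("volume %d: registration failed (corr=%.2f); passed through", t, corr)
            out[t] = data[t]
            shifts[t] = 0.0
        else:
            out[t] = corrected
            shifts[t] = shift
    trace = MotionTrace(
        com_displacement=center_of_mass_motion(data).com_displacement,
        rigid_translations=shifts,
        rigid_rotations=np.zeros_like(shifts),
    )
    return out, trace


def decompose_components(
    data: np.ndarray,
    n_components: int = 15,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ComponentSet:
    """Spatial ICA of a 4D series (voxel maps independent, FastICA).

    The series is demeaned per voxel; components are ordered by explained
    variance of their time courses, time courses normalised to unit
    variance, spatial maps z-scored.  Deterministic for a fixed seed.
    """
    data = np.asarray(data, dtype=float)
    t_len = data.shape[0]
    shape3 = data.shape[1:]
    if mask is None:
        mask = np.ones(shape3, dtype=bool)
    mask = mask.astype(bool)
    x = data.reshape(t_len, -1)[:, mask.ravel()]
    x = x - x.mean(axis=0, keepdims=True)
    rank = min(t_len - 1, x.shape[1])
    if n_components > rank:
        warnings.warn(f"reducing n_components from {n_components} to rank {rank}")
        n_components = rank
    if t_len <= n_components:
        raise ValueError("need more volumes than components")
    ica = FastICA(
        n_components=n_components,
        random_state=np.random.RandomState(seed),
        whiten="unit-variance",
        max_iter=1000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence chatter
        sources = ica.fit_transform(x.T)          # (voxels, q) spatial sources
    mixing = ica.mixing_                           # (T, q) time courses
    # order by time-course variance (energy) descending, normalise
    tc = mixing.copy()
    sd = tc.std(axis=0)
    sd[sd == 0] = 1.0
    order = np.argsort(-(sd**2))
    tc = (tc / sd)[:, order]
    sources = (sources * sd)[:, order]
    maps = np.zeros((n_components,) + shape3)
    flat = maps.reshape(n_components, -1)
    src_sd = sources.std(axis=0)
    src_sd[src_sd == 0] = 1.0
    zmaps = (sources - sources.mean(axis=0)) / src_sd
    flat[:, mask.ravel()] = zmaps.T
    return ComponentSet(maps=maps, timecourses=tc)


def edge_shell(object_mask: np.ndarray, width: int = 1) -> np.ndarray:
    """Voxels within ``width`` voxels of the object boundary (inside or out)."""
    obj = object_mask.astype(bool)
    eroded = ndimage.binary_erosion(obj, iterations=width)
    dilated = ndimage.binary_dilation(obj, iterations=width)
    return dilated & ~eroded


def classify_motion_components(
    components: ComponentSet,
    motion: MotionTrace,
    object_mask: np.ndarray,
    params: PreprocParams | None = None,
) -> list:
    """Label each component "motion" or "signal" by the two strict rules.

    Rule 1: max over motion parameters of |Pearson r(time course, parameter)|
    strictly exceeds ``motion_corr_threshold``.  Rule 2: of the component's
    suprathreshold voxels (|map z| > ``map_z_threshold``), the fraction on
    the object's edge shell or outside the object strictly exceeds
    ``edge_fraction_threshold``.  A component with no suprathreshold voxels
    fails rule 2.
    """
    params = params or PreprocParams()
    mpars = motion.parameters
    if len(mpars) != components.timecourses.shape[0]:
        raise ValueError("motion trace and component time courses differ in length")
    shell = edge_shell(object_mask, params.edge_width)
    outside = ~object_mask.astype(bool)
    edge_or_out = shell | outside
    labels = []
    for i in range(components.n_components):
        tc = components.timecourses[:, i]
        rmax = 0.0
        for a in range(mpars.shape[1]):
            p = mpars[:, a]
            if p.std() > 0 and tc.std() > 0:
                rmax = max(rmax, abs(np.corrcoef(tc, p)[0, 1]))
        crit1 = rmax > params.motion_corr_threshold
        supra = np.abs(components.maps[i]) > params.map_z_threshold
        n_supra = supra.sum()
        crit2 = False
        if n_supra > 0:
            frac = (supra & edge_or_out).sum() / n_supra
            crit2 = frac > params.edge_fraction_threshold
        labels.append("motion" if (crit1 or crit2) else "signal")
    components.labels = labels
    return labels


def component_report(
    components: ComponentSet,
    motion: MotionTrace,
    object_mask: np.ndarray,
    params: PreprocParams | None = None,
) -> pd.DataFrame:
    """Per-component max |r| with motion, edge fraction, and label."""
    params = params or PreprocParams()
    shell = edge_shell(object_mask, params.edge_width) | ~object_mask.astype(bool)
    rows = []
    for i in range(components.n_components):
        tc = components.timecourses[:, i]
        rmax = max(
            (
                abs(np.corrcoef(tc, motion.parameters[:, a])[0, 1])
                for a in range(motion.parameters.shape[1])
                if motion.parameters[:, a].std() > 0
            ),
            default=0.0,
        )
        supra = np.abs(components.maps[i]) > params.map_z_threshold
        frac = float((supra & shell).sum() / supra.sum()) if supra.any() else np.nan
        rows.append(
            {
                "component": i,
                "max_abs_r": rmax,
                "edge_fraction": frac,
                "label": components.labels[i] if components.labels else "",
            }
        )
    return pd.DataFrame(rows)


def regress_out(data: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Remove nuisance time courses (plus intercept) from every voxel.

    Least-squares projection; with no regressors the series is returned
    unchanged.  The voxel means survive (the intercept column is refitted
    and added back), so fractional-change analyses remain meaningful.
    """
    data = np.asarray(data, dtype=float)
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.size == 0:
        return data.copy()
    if regressors.shape[0] != data.shape[0]:
        regressors = regressors.T
    t_len = data.shape[0]
    design = np.column_stack([np.ones(t_len), regressors])
    flat = data.reshape(t_len, -1)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design[:, 1:] @ beta[1:]
    return resid.reshape(data.shape)


def dct_highpass_basis(n_volumes: int, volume_tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis: columns with frequency below ``cutoff``.

    Basis k has frequency k / (2 * T * tr); the constant term is excluded
    (handled as an intercept by callers).
    """
    freqs = np.arange(1, n_volumes) / (2.0 * n_volumes * volume_tr)
    keep = np.flatnonzero(freqs < cutoff) + 1
    t = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in keep]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


def highpass(data: np.ndarray, volume_tr: float, cutoff: float = 0.01) -> np.ndarray:
    """Remove frequencies below ``cutoff`` (Hz) by DCT-basis regression.

    The per-voxel temporal mean is restored after filtering.  1-D inputs
    (a single regressor) are supported.
    """
    if cutoff >= 0.5 / volume_tr:
        raise ValueError(
            f"cutoff {cutoff} Hz is at or above Nyquist {0.5 / volume_tr:.4f} Hz"
        )
    data = np.asarray(data, dtype=float)
    one_d = data.ndim == 1
    flat = data.reshape(data.shape[0], -1)
    basis = dct_highpass_basis(flat.shape[0], volume_tr, cutoff)
    mean = flat.mean(axis=0, keepdims=True)
    centred = flat - mean
    if basis.shape[1]:
        beta, *_ = np.linalg.lstsq(basis, centred, rcond=None)
        centred = centred - basis @ beta
    out = (centred + mean).reshape(data.shape)
    return out[:, 0] if one_d and out.ndim > 1 else out


def prewhiten(
    residuals: np.ndarray, data: np.ndarray, design: np.ndarray, ar_order: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-pass Cochrane-Orcutt AR(1) prewhitening.

    ``residuals`` (T, V) from an initial OLS fit give per-voxel lag-1
    autocorrelation phi (clipped to |phi| <= 0.99 with a warning);
    ``data`` (T, V) and ``design`` (T, P) are transformed to
    y_t - phi * y_{t-1} (per voxel; the design becomes (V, T-1, P)).

    Returns (whitened_data (T-1, V), whitened_design (V, T-1, P), phi (V,)).
    """
    res = np.asarray(residuals, dtype=float)
    y = np.asarray(data, dtype=float)
    x = np.asarray(design, dtype=float)
    if res.shape[0] < 10:
        raise ValueError("need at least 10 volumes for AR estimation")
    num = (res[1:] * res[:-1]).sum(axis=0)
    den = (res[:-1] ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    if np.any(np.abs(phi) >= 1.0):
        warnings.warn("AR(1) coefficient at or beyond unit root; clipping to 0.99")
        phi = np.clip(phi, -0.99, 0.99)
    if ar_order == 0:
        phi = np.zeros_like(phi)
    yw = y[1:] - phi[None, :] * y[:-1]
    xw = x[None, 1:, :] - phi[:, None, None] * x[None, :-1, :]
    return yw, xw, phi


def preprocess_series(
    data: np.ndarray,
    object_mask: np.ndarray,
    volume_tr: float,
    params: PreprocParams | None = None,
    seed: int = 0,
    do_highpass: bool = True,
):
    """Motion-correct, decompose, classify, regress out motion components,
    and optionally high-pass filter a 4D series.

    Returns (cleaned series, MotionTrace, ComponentSet).  The returned
    series retains voxel means.
    """
    params = params or PreprocParams()
    corrected, trace = rigid_motion_correct(data)
    comps = decompose_components(
        corrected, params.n_components, seed=seed, mask=object_mask
    )
    classify_motion_components(comps, trace, object_mask, params)
    idx = comps.motion_indices()
    cleaned = regress_out(corrected, comps.timecourses[:, idx]) if len(idx) else corrected
    if do_highpass:
        cleaned = highpass(cleaned, volume_tr, params.highpass_cutoff)
    logger.info(
        "preprocess: %d/%d components labelled motion; max residual motion %.3f vox",
        len(idx), comps.n_components, trace.max_displacement,
    )
    return cleaned, trace, comps
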