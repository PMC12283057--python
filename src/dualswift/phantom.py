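"""Ground-truth dual-organ phantoms, stimulation paradigm, hemodynamic model.

Two numerical objects emulate the dual-FOV anatomy: an ellipsoidal
"head" with a lateralised cortical ROI and a midline cerebellar ROI, and a
cylindrical spinal-cord segment with a unilateral dorsal-quadrant ROI.
Functional contrast is injected phenomenologically as a fractional signal
change (the measured contrast originates from inflow of unsaturated blood;
no quantitative inflow model is available, so the peak fractional change is
a direct parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Paradigm",
    "IRFParams",
    "DualPhantom",
    "make_paradigm",
    "gamma_irf",
    "make_dual_phantom",
    "render_truth_series",
    "response_curve",
]


@dataclass(frozen=True)
class Paradigm:
    """Block electrical-stimulation paradigm.

    Default: 60 s rest, then 6 repetitions of 24 s stimulation + 90 s rest
    (744 s total).  Stimulus frequency/current are carried as metadata only.
    """

    initial_rest: float = 60.0   # s
    block_on: float = 24.0       # s
    block_off: float = 90.0      # s
    n_blocks: int = 6
    stim_frequency: float = 9.0  # Hz, metadata
    stim_current: float = 2.0    # mA, metadata

    @property
    def total_duration(self) -> float:
        return self.initial_rest + self.n_blocks * (self.block_on + self.block_off)

    @property
    def onsets(self) -> np.ndarray:
        """Stimulation-block onset times, s."""
        return self.initial_rest + np.arange(self.n_blocks) * (self.block_on + self.block_off)

    def boxcar(self, t: np.ndarray) -> np.ndarray:
        """1 where time t (s) falls inside an on-block, else 0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        for onset in self.onsets:
            out[(t >= onset) & (t < onset + self.block_on)] = 1.0
        return out

    def to_onsets_table(self) -> np.ndarray:
        """Three-column (onset, duration, amplitude) representation."""
        return np.column_stack(
            [self.onsets, np.full(self.n_blocks, self.block_on), np.ones(self.n_blocks)]
        )


@dataclass(frozen=True)
class IRFParams:
    """Gamma-variate impulse-response parameters: delay = mean (s),
    variation = standard deviation (s) of the kernel."""

    delay: float = 2.8
    variation: float = 1.4

    def __post_init__(self) -> None:
        if self.delay <= 0 or self.variation <= 0:
            raise ValueError("delay and variation must be positive")

    @property
    def shape(self) -> float:
        return (self.delay / self.variation) ** 2

    @property
    def scale(self) -> float:
        return self.variation**2 / self.delay


def make_paradigm(paradigm: Paradigm, volume_tr: float) -> np.ndarray:
    """Boxcar regressor sampled at volume-acquisition start times.

    Element v is 1 iff volume v's start time lies inside an on-block; the
    vector spans ceil(total_duration / volume_tr) volumes.
    """
    if volume_tr <= 0:
        raise ValueError("volume_tr must be positive")
    n = int(np.ceil(paradigm.total_duration / volume_tr))
    t = np.arange(n) * volume_tr
    return paradigm.boxcar(t)


def gamma_irf(t: np.ndarray, irf: IRFParams) -> np.ndarray:
    """Gamma-density impulse response on a uniform time grid (s).

    Moment-matched: shape k = (delay/variation)^2, scale = variation^2/delay,
    so the kernel's mean is `delay` and SD is `variation`.  Renormalised to
    unit area on the sampled grid (sum * dt = 1).
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t must be a 1-D grid with at least two points")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t must be non-negative and increasing")
    k = stats.gamma.pdf(t, a=irf.shape, scale=irf.scale)
    dt = t[1] - t[0]
    area = k.sum() * dt
    if area <= 0:
        raise ValueError("IRF has zero mass on the given grid")
    return k / area


def response_curve(
    paradigm: Paradigm,
    irf: IRFParams,
    volume_tr: float,
    latency_shift: float = 0.0,
    fine_dt: float = 0.05,
) -> np.ndarray:
    """Boxcar (x) IRF sampled at volume times, rescaled to unit peak.

    The convolution is evaluated on a fine grid (``fine_dt`` s) and then
    sampled at volume start times shifted by ``latency_shift`` (an extra
    response delay, e.g. for the spinal cord's slower hemodynamics).
    """
    n_vol = int(np.ceil(paradigm.total_duration / volume_tr))
    t_fine = np.arange(0.0, paradigm.total_duration + 4 * irf.delay, fine_dt)
    box = paradigm.boxcar(t_fine)
    kern = gamma_irf(np.arange(0.0, irf.delay + 8 * irf.variation + fine_dt, fine_dt), irf)
    conv = np.convolve(box, kern)[: len(t_fine)] * fine_dt
    peak = conv.max()
    if peak > 0:
        conv = conv / peak
    t_vol = np.arange(n_vol) * volume_tr - latency_shift
    return np.interp(t_vol, t_fine, conv, left=0.0, right=0.0)


@dataclass
class DualPhantom:
    """Ground truth for both FOVs on a common matrix size.

    ``volumes`` are the static baselines (arbitrary units, non-negative);
    ``activation_masks`` flag the voxels carrying the task response with
    per-FOV peak fractional amplitude ``effect_size``.  ``motion_events``
    are (volume_index, (dx, dy, dz)) integer-voxel translation steps that
    add cumulatively from their volume onward (both FOVs move together).
    """

    volumes: tuple[np.ndarray, np.ndarray]
    activation_masks: tuple[np.ndarray, np.ndarray]
    object_masks: tuple[np.ndarray, np.ndarray]
    effect_size: tuple[float, float] = (0.005, 0.010)
    noise_sd: float = 0.0
    motion_events: list[tuple[int, tuple[int, int, int]]] = field(default_factory=list)
    latency_shift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for f in range(2):
            act = self.activation_masks[f].astype(bool)
            obj = self.object_masks[f].astype(bool)
            if np.any(act & ~obj):
                raise ValueError(f"activation mask of FOV {f} exceeds the object mask")
            if np.any(self.volumes[f] < 0):
                raise ValueError("baseline intensities must be non-negative")
        if any(e < 0 for e in self.effect_size):
            raise ValueError("effect_size must be >= 0")

    def roi_voxel_counts(self) -> tuple[int, int]:
        return tuple(int(m.sum()) for m in self.activation_masks)

    def displacement_at(self, volume: int) -> np.ndarray:
        """Cumulative integer-voxel displacement active at a given volume."""
        d = np.zeros(3, dtype=int)
        for v0, shift in self.motion_events:
            if volume >= v0:
                d += np.asarray(shift, dtype=int)
        return d


def _ellipsoid(n: int, center, semiaxes) -> np.ndarray:
    idx = np.indices((n, n, n)).astype(float)
    u = [(idx[a] - center[a]) / semiaxes[a] for a in range(3)]
    return (u[0] ** 2 + u[1] ** 2 + u[2] ** 2) <= 1.0


def _smooth_texture(shape, seed: int, amplitude: float = 0.1, sigma: float = 2.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    tex /= max(np.abs(tex).max(), 1e-12)
    return 1.0 + amplitude * tex


def make_dual_phantom(
    matrix_size: int = 64,
    effect_size: tuple[float, float] = (0.005, 0.010),
    noise_sd: float = 0.0,
    motion_events: list[tuple[int, tuple[int, int, int]]] | None = None,
    latency_shift: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> DualPhantom:
    """Build the standard dual-organ phantom on an N^3 grid.

    FOV 0 (head): ellipsoid with a smooth intensity texture; a lateralised
    "cortical" spherical ROI in the left dorsal quadrant and a midline
    posterior "cerebellar" ROI.  FOV 1 (cord): cylinder along z with a
    right-dorsal-quadrant ROI over a limited z range.  Axis convention is
    (x: left->right, y: ventral->dorsal, z: caudal->rostral), 0-based.
    """
    n = matrix_size
    if n < 16:
        raise ValueError("matrix_size must be >= 16")
    s = n / 64.0  # geometry scales with the grid

    # --- FOV 0: head ---------------------------------------------------------
    c = (n - 1) / 2.0
    head = _ellipsoid(n, (c, c, c), (24 * s, 20 * s, 26 * s))
    brain = head.astype(float) * _smooth_texture((n, n, n), seed, 0.10, 2.0 * s)
    # ROI radius never below 2.5 voxels: smaller blobs are dominated by
    # partial-volume dilution at the reconstruction's resolution
    r_roi = max(3.2 * s, 2.5)
    cortex = _ellipsoid(n, (c - 12 * s, c + 12 * s, c + 8 * s), (r_roi,) * 3) & head
    cerebellum = _ellipsoid(n, (c, c + 8 * s, c - 16 * s), (r_roi,) * 3) & head
    brain_roi = cortex | cerebellum
    if not cortex.any() or not cerebellum.any():
        raise ValueError("brain ROI fell outside the head; matrix too small")

    # --- FOV 1: spinal cord segment -----------------------------------------
    idx = np.indices((n, n, n)).astype(float)
    radial = (idx[0] - c) ** 2 + (idx[1] - c) ** 2
    zmask = (idx[2] >= 6 * s) & (idx[2] < n - 6 * s)
    cord = (radial <= (10 * s) ** 2) & zmask
    cord_img = cord.astype(float) * _smooth_texture((n, n, n), seed + 1, 0.10, 2.0 * s)
    # unilateral dorsal-quadrant ROI: right (x > c) and dorsal (y > c)
    cord_roi = (
        cord
        & (radial <= (9 * s) ** 2)
        & (idx[0] > c + min(1.0 * s, 0.5))
        & (idx[1] > c + min(1.0 * s, 0.5))
        & (idx[2] >= c - max(6 * s, 4.0))
        & (idx[2] < c + max(6 * s, 4.0))
    )
    if not cord_roi.any():
        raise ValueError("cord ROI is empty; matrix too small")

    return DualPhantom(
        volumes=(brain, cord_img),
        activation_masks=(brain_roi, cord_roi),
        object_masks=(head, cord),
        effect_size=tuple(effect_size),
        noise_sd=noise_sd,
        motion_events=list(motion_events or []),
        latency_shift=tuple(latency_shift),
    )


def render_truth_series(
    phantom: DualPhantom,
    paradigm: Paradigm,
    irf: IRFParams,
    volume_tr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Render noiseless ground-truth 4D series (t, x, y, z) for both FOVs.

    Voxel value at volume t is baseline * (1 + effect_size * mask * r(t))
    with r the unit-peak boxcar (x) IRF response (per-FOV latency shift
    applied); cumulative integer-voxel motion translations are then applied
    volume-wise.
    """
    out = []
    for f in range(2):
        r = response_curve(paradigm, irf, volume_tr, phantom.latency_shift[f])
        base = phantom.volumes[f]
        mask = phantom.activation_masks[f].astype(float)
        series = base[None] * (1.0 + phantom.effect_size[f] * mask[None] * r[:, None, None, None])
        if phantom.motion_events:
            for t in range(series.shape[0]):
                d = phantom.displacement_at(t)
                if np.any(d):
                    series[t] = np.roll(series[t], tuple(d), axis=(0, 1, 2))
        out.append(series)
    return out[0], out[1]
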