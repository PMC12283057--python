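"""Forward model: interleaved dual-FOV radial sampling of ground-truth series.

Each excitation is modelled as an instantaneous center-out Fourier readout
of the truth volume current at that excitation's timestamp.  The gapped,
frequency-swept pulse fine structure is abstracted into (a) an optional
multiplicative per-spoke "pulse profile" along the readout, exercising the
deconvolution step of the reconstruction, and (b) an optional per-FOV
frequency-offset phase ramp across the readout duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nufft import ExactNUDFT, GriddingNUFFT, RadialTrajectory, make_operator
from .sequence import SequenceParams, SpokeSchedule

__all__ = ["KSpaceStream", "sample_spoke", "acquire_dual", "save_stream", "load_stream"]


@dataclass
class KSpaceStream:
    """Complex per-spoke samples for one FOV.

    ``samples`` has shape (n_spokes_total, n_samples) with spokes ordered in
    acquisition time; ``directions`` are the matching unit vectors.  k-space
    coordinates are generated on demand from the trajectory geometry
    (cycles/mm: normalised coords divided by the voxel size).
    """

    samples: np.ndarray          # (n_spokes_total, n_samples) complex
    directions: np.ndarray       # (n_spokes_total, 3)
    fov_index: int
    n_spokes_per_volume: int
    matrix_size: int
    voxel_size: float            # mm
    gradient_scale: float = 1.0
    volume_tr: float = 0.0       # s, metadata
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_volumes(self) -> int:
        return self.samples.shape[0] // self.n_spokes_per_volume

    @property
    def dc_reference(self) -> np.ndarray:
        """Complex DC (k = 0) value of every spoke."""
        return self.samples[:, 0]

    def trajectory(self) -> RadialTrajectory:
        """Trajectory of one volume (directions repeat every volume)."""
        return RadialTrajectory(
            self.directions[: self.n_spokes_per_volume],
            self.n_samples,
            self.gradient_scale,
        )

    @property
    def k_coords(self) -> np.ndarray:
        """(n_spokes_total, n_samples, 3) coordinates in cycles/mm."""
        traj = RadialTrajectory(self.directions, self.n_samples, self.gradient_scale)
        return traj.coords() / self.voxel_size

    @property
    def k_radii(self) -> np.ndarray:
        """|k| per sample index along a spoke, cycles/mm."""
        return self.trajectory().radii / self.voxel_size

    def volume_view(self, t: int) -> np.ndarray:
        ns = self.n_spokes_per_volume
        return self.samples[t * ns : (t + 1) * ns]


def sample_spoke(
    volume: np.ndarray,
    direction: np.ndarray,
    n_samples: int,
    gradient_scale: float = 1.0,
) -> np.ndarray:
    """Exact center-out radial Fourier samples of one volume along one spoke.

    Sample j sits at k_j = j * dk * direction with the last sample at the
    grid Nyquist radius; evaluated by exact type-II NUDFT.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("spoke direction must have unit norm")
    traj = RadialTrajectory(direction[None, :], n_samples, gradient_scale)
    op = ExactNUDFT(traj, volume.shape[0])
    return op.forward(volume.astype(complex))[0]


def _readout_times(params: SequenceParams) -> np.ndarray:
    """Sample times within one spoke readout, s (gaps treated as contiguous)."""
    total = params.readout_per_spoke * 1e-6
    n = params.samples_per_spoke
    return np.arange(n) * (total / n)


def acquire_dual(
    series0: np.ndarray,
    series1: np.ndarray,
    schedule: SpokeSchedule,
    params: SequenceParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    pulse_profile: np.ndarray | None = None,
    coupling: float = 0.0,
    exact_max_size: int = 0,
) -> tuple[KSpaceStream, KSpaceStream]:
    """Sample both truth series along the interleaved schedule.

    Each excitation reads the truth volume with index
    ``floor(timestamp / volume_time)``; since object motion is frozen per
    volume, all spokes of a volume see the same image and are evaluated in
    one batched operator call.  Complex Gaussian noise with standard
    deviation ``noise_sd * mean |DC|`` is added independently per sample;
    ``coupling`` adds a fraction of the other FOV's noiseless signal to
    emulate imperfect coil decoupling.

    Returns one :class:`KSpaceStream` per FOV.
    """
    series = (np.asarray(series0), np.asarray(series1))
    n = params.matrix_size
    for s in series:
        if s.ndim != 4 or s.shape[1:] != (n, n, n):
            raise ValueError("series must be (T, N, N, N) matching matrix_size")
    n_vol = schedule.n_volumes
    if n_vol > min(series[0].shape[0], series[1].shape[0]):
        raise ValueError(
            f"schedule spans {n_vol} volumes but truth series has only "
            f"{min(series[0].shape[0], series[1].shape[0])}"
        )

    rng = np.random.default_rng(seed)
    n_samp = params.samples_per_spoke
    ns = schedule.n_spokes_per_volume
    dirs0, _ = schedule.for_fov(0)
    per_vol_dirs = dirs0[:ns]
    streams_raw = []
    for f in range(2):
        traj = RadialTrajectory(per_vol_dirs, n_samp, schedule.gradient_scale[f])
        op = make_operator(traj, n, exact_max_size=exact_max_size)
        stack = series[f][:n_vol].reshape(n_vol, -1).T.astype(complex)
        samp = op.forward(stack)                     # (ns, n_samp, n_vol)
        samp = np.moveaxis(samp, -1, 0).reshape(n_vol * ns, n_samp)
        streams_raw.append(samp)

    out = []
    for f in range(2):
        samp = streams_raw[f].copy()
        if coupling:
            samp += coupling * streams_raw[1 - f]
        if pulse_profile is not None:
            prof = np.asarray(pulse_profile)
            if len(prof) < n_samp:
                raise ValueError("pulse_profile shorter than the spoke readout")
            samp *= prof[None, :n_samp]
        if params.fov_offsets[f]:
            t_ro = _readout_times(params)
            samp *= np.exp(2j * np.pi * params.fov_offsets[f] * t_ro)[None, :]
        if noise_sd > 0:
            scale = noise_sd * np.mean(np.abs(samp[:, 0]))
            noise = rng.standard_normal(samp.shape) + 1j * rng.standard_normal(samp.shape)
            samp = samp + scale * noise
        out.append(
            KSpaceStream(
                samples=samp,
                directions=np.tile(per_vol_dirs, (n_vol, 1)),
                fov_index=f,
                n_spokes_per_volume=ns,
                matrix_size=n,
                voxel_size=params.voxel_size(f),
                gradient_scale=schedule.gradient_scale[f],
                volume_tr=params.volume_tr,
                seed=seed,
            )
        )
    return out[0], out[1]


def save_stream(stream: KSpaceStream, path: str) -> None:
    """Persist a stream as an .npz container plus a plain-text sidecar."""
    np.savez(
        path,
        samples=stream.samples,
        directions=stream.directions,
    )
    meta = {
        "fov_index": stream.fov_index,
        "n_spokes_per_volume": stream.n_spokes_per_volume,
        "matrix_size": stream.matrix_size,
        "voxel_size": stream.voxel_size,
        "gradient_scale": stream.gradient_scale,
        "volume_tr": stream.volume_tr,
        "seed": stream.seed,
    }
    sidecar = str(path)
    sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_stream(path: str) -> KSpaceStream:
    p = str(path)
    if not p.endswith(".npz"):
        p = p + ".npz"
    arr = np.load(p)
    with open(p[:-4] + ".json") as fh:
        meta = json.load(fh)
    return KSpaceStream(samples=arr["samples"], directions=arr["directions"], **meta)
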