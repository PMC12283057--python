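"""Dual-FOV MB-SWIFT sequence timing and 3D-radial spoke scheduling.

The sequence excites two distant fields of view (e.g. brain and lumbar
spinal cord) in strict alternation: each repetition-time *pair* holds one
excitation/readout per FOV at the same readout-gradient orientation, with
the gradient amplitude rescaled between the two spokes when the FOVs have
different sizes.  A full image volume is one spherical-spiral sweep of
spoke orientations; consecutive volumes reuse the same orientation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "SequenceParams",
    "SpokeSchedule",
    "make_spoke_directions",
    "make_dual_schedule",
    "timing_summary",
]


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters for one dual-FOV MB-SWIFT run.

    Durations are in the units stated per field; defaults correspond to a
    9.4 T small-animal functional protocol (64^3 matrix, 625 um isotropic,
    3 s volume rate).
    """

    tr_pair: float = 1.94            # ms, repetition time covering both spokes
    n_spokes_per_volume: int = 1547  # spokes per image volume (per FOV)
    n_volumes: int = 248             # volumes per FOV
    bandwidth: float = 192.0         # kHz, FOV bandwidth
    oversampling: int = 2            # readout oversampling factor
    matrix_size: int = 64            # voxels per dimension
    fov_size: tuple[float, float] = (40.0, 40.0)  # mm, per FOV
    flip_angle: float = 6.0          # degrees
    n_gaps: int = 4                  # readout gaps per excitation
    samples_per_gap: int = 32        # points per gap, before oversampling
    gap_readout: float = 167.5       # us, readout time per gap
    pulse_element_width: float = 2.6   # us
    pre_excitation_delay: float = 0.1  # us
    post_excitation_delay: float = 2.5  # us
    gradient_switch_time: float = 292.5  # us, per spoke
    fov_offsets: tuple[float, float] = (0.0, 0.0)  # Hz, per-FOV transmit offset

    def __post_init__(self) -> None:
        if self.tr_pair <= 0:
            raise ValueError("tr_pair must be positive")
        if self.n_spokes_per_volume < 1:
            raise ValueError("n_spokes_per_volume must be >= 1")
        if self.matrix_size < 1:
            raise ValueError("matrix_size must be >= 1")
        if len(self.fov_size) != 2 or any(f <= 0 for f in self.fov_size):
            raise ValueError("fov_size must hold two positive lengths")

    # ---- derived quantities -------------------------------------------------

    @property
    def single_spoke_time(self) -> float:
        """ms; acquisition time of one spoke (one FOV)."""
        return self.tr_pair / 2.0

    @property
    def volume_time(self) -> float:
        """ms; duration of one dual-FOV image volume."""
        return self.n_spokes_per_volume * self.tr_pair

    @property
    def volume_tr(self) -> float:
        """s; volume repetition time (the fMRI sampling interval)."""
        return self.volume_time / 1000.0

    @property
    def total_scan_time(self) -> float:
        """ms; duration of the whole run."""
        return self.volume_time * self.n_volumes

    @property
    def sweep_range(self) -> float:
        """kHz; baseband frequency-sweep range BW / samples_per_gap."""
        return self.bandwidth / self.samples_per_gap

    @property
    def acquisition_bandwidth(self) -> float:
        """kHz; BW x oversampling."""
        return self.bandwidth * self.oversampling

    @property
    def samples_per_spoke(self) -> int:
        """complex samples acquired along one spoke (after oversampling)."""
        return self.samples_per_gap * self.oversampling

    @property
    def readout_per_spoke(self) -> float:
        """us; total readout time per spoke (all gaps)."""
        return self.n_gaps * self.gap_readout

    @property
    def linewidth_tolerance(self) -> float:
        """kHz; maximal tolerable water-line half-maximum width, BW / N."""
        return self.bandwidth / self.matrix_size

    def voxel_size(self, fov: int = 0) -> float:
        """mm; isotropic voxel size of the given FOV."""
        return self.fov_size[fov] / self.matrix_size

    @property
    def gradient_scale(self) -> tuple[float, float]:
        """Relative readout-gradient amplitude per FOV.

        Proportional to 1/fov_size, normalised so the largest FOV (and
        hence equal FOVs) gets scale 1.
        """
        ref = max(self.fov_size)
        return tuple(ref / f for f in self.fov_size)

    def replace(self, **kw) -> "SequenceParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpokeSchedule:
    """Interleaved excitation schedule for both FOVs.

    One row per excitation.  Within every TR pair the two FOVs are excited
    back-to-back at the same gradient orientation; the orientation advances
    along the spherical spiral once both have been served.
    """

    directions: np.ndarray        # (n_excitations, 3) unit vectors
    fov_index: np.ndarray         # (n_excitations,) in {0, 1}
    timestamps: np.ndarray        # (n_excitations,) ms from first excitation
    gradient_scale: tuple[float, float]
    n_spokes_per_volume: int
    volume_time: float            # ms

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_volumes(self) -> int:
        return len(self.timestamps) // (2 * self.n_spokes_per_volume)

    def for_fov(self, fov: int) -> tuple[np.ndarray, np.ndarray]:
        """(directions, timestamps) of the excitations addressing one FOV."""
        sel = self.fov_index == fov
        return self.directions[sel], self.timestamps[sel]

    def to_table(self) -> pd.DataFrame:
        """Plain-text exportable table, one row per excitation."""
        scale = np.asarray(self.gradient_scale)[self.fov_index]
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "time_ms": self.timestamps,
                "fov": self.fov_index,
                "dir_x": self.directions[:, 0],
                "dir_y": self.directions[:, 1],
                "dir_z": self.directions[:, 2],
                "gradient_scale": scale,
            }
        )

    def save(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def make_spoke_directions(n_spokes: int, ordering: str = "spherical_spiral") -> np.ndarray:
    """Unit readout directions tracing one pole-to-pole spherical spiral.

    The polar angle advances uniformly in cos(theta) from +z to -z (equal-area
    steps) while the azimuth advances so that consecutive points keep a
    near-constant arc distance, yielding near-uniform coverage of the sphere.

    Parameters
    ----------
    n_spokes : number of directions (>= 1).
    ordering : only ``"spherical_spiral"`` is implemented.

    Returns
    -------
    (n_spokes, 3) array of unit vectors; deterministic.
    """
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    if ordering != "spherical_spiral":
        raise ValueError(f"unknown ordering {ordering!r}")
    if n_spokes == 1:
        return np.array([[0.0, 0.0, 1.0]])

    i = np.arange(n_spokes)
    z = 1.0 - 2.0 * i / (n_spokes - 1)           # pole to pole
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    # azimuth increment ~ (step along spiral) / (local circle radius); the
    # 3.6/sqrt(n) constant gives near-constant nearest-neighbour arc length.
    phi = np.zeros(n_spokes)
    with np.errstate(divide="ignore"):
        dphi = np.where(r > 1e-12, 3.6 / (np.sqrt(n_spokes) * np.where(r > 1e-12, r, 1.0)), 0.0)
    phi[1:] = np.cumsum(dphi[1:])
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def make_dual_schedule(
    params: SequenceParams,
    directions: np.ndarray,
    n_volumes: int | None = None,
) -> SpokeSchedule:
    """Interleave one direction set across both FOVs for ``n_volumes`` volumes.

    Each orientation is used by FOV 0 then FOV 1 (one TR pair) before the
    orientation advances; the same spiral repeats every volume.  Timestamps
    start at 0 and step by ``tr_pair / 2``.
    """
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise ValueError("directions must be (n, 3)")
    if directions.shape[0] != params.n_spokes_per_volume:
        raise ValueError(
            f"got {directions.shape[0]} directions for "
            f"{params.n_spokes_per_volume} spokes per volume"
        )
    if n_volumes is None:
        n_volumes = params.n_volumes

    ns = params.n_spokes_per_volume
    per_vol_dirs = np.repeat(directions, 2, axis=0)      # d0,d0,d1,d1,...
    dirs = np.tile(per_vol_dirs, (n_volumes, 1))
    fov = np.tile(np.array([0, 1], dtype=np.int8), ns * n_volumes)
    t = np.arange(2 * ns * n_volumes) * (params.tr_pair / 2.0)
    return SpokeSchedule(
        directions=dirs,
        fov_index=fov,
        timestamps=t,
        gradient_scale=params.gradient_scale,
        n_spokes_per_volume=ns,
        volume_time=params.volume_time,
    )


def timing_summary(params: SequenceParams) -> dict[str, float]:
    """Derived protocol durations and rates, in the units noted per key."""
    return {
        "single_spoke_time_ms": params.single_spoke_time,
        "readout_per_spoke_us": params.readout_per_spoke,
        "volume_time_ms": params.volume_time,
        "volume_tr_s": params.volume_tr,
        "total_scan_time_s": params.total_scan_time / 1000.0,
        "voxel_size_mm_fov0": params.voxel_size(0),
        "voxel_size_mm_fov1": params.voxel_size(1),
        "sweep_range_khz": params.sweep_range,
        "acquisition_bandwidth_khz": params.acquisition_bandwidth,
        "linewidth_tolerance_khz": params.linewidth_tolerance,
    }


def load_schedule(path) -> pd.DataFrame:
    """Read back a schedule table written by :meth:`SpokeSchedule.save`."""
    return pd.read_csv(path, sep="\t")
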