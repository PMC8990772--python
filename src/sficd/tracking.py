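"""Deterministic streamline tractography for short-range fibers.

FACT-style tracking: at each step the principal direction of the current
(nearest) voxel is sign-aligned to the incoming direction (diffusion is
axial), checked against the turning-angle threshold, blended with the
previous step direction by a momentum factor, and the point is advanced by a
fixed step.  Propagation runs bidirectionally from each seed and halts on
low FA, a sharp turn, grid exit, or the safety cap.  Short-range fibers are
then selected by an inclusive length window (default 10-65 mm).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .field import DiffusionField


@dataclass
class TrackingParams:
    """Stopping rules and integration constants of the tracker.

    Defaults follow common deterministic-tracking practice for 2 mm
    isotropic data: FA threshold 0.14, turning angle 35 degrees, 0.5 mm
    steps, momentum 0.5, one seed per voxel, and a 10-65 mm short-range
    length window.
    """

    fa_threshold: float = 0.14
    angle_threshold: float = 35.0  # degrees, on the unblended voxel direction
    step_size: float = 0.5  # mm
    smoothing: float = 0.5  # fraction of the previous direction kept
    seeds_per_voxel: int = 1
    min_length: float = 10.0  # mm
    max_length: float = 65.0  # mm
    max_points: int = 2000  # per half-track safety cap
    interpolation: str = "nearest"  # FA sampling: "nearest" or "linear"

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0.0 <= self.smoothing <= 1.0:
            raise ValueError("smoothing must be in [0, 1]")
        if not 0 < self.min_length < self.max_length:
            raise ValueError("need 0 < min_length < max_length")


@dataclass
class Streamline:
    """Ordered world-mm points with derived length and mean sampled FA."""

    points: np.ndarray  # (N, 3), N >= 2
    length: float
    mean_fa: float

    @classmethod
    def from_points(cls, points: np.ndarray, field: DiffusionField,
                    interpolation: str = "nearest") -> "Streamline":
        points = np.asarray(points, float)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        fa = [field.fa_at(p, interpolation) for p in points]
        return cls(points=points, length=float(seg.sum()), mean_fa=float(np.mean(fa)))


@dataclass
class Tractogram:
    """A set of streamlines in world RAS mm plus the parameters that made them."""

    streamlines: list[Streamline]
    params: TrackingParams | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])

    @property
    def mean_fas(self) -> np.ndarray:
        return np.array([s.mean_fa for s in self.streamlines])

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) terminal points of every streamline."""
        return np.array([[s.points[0], s.points[-1]] for s in self.streamlines])


def _align(direction: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip `direction` so it makes an acute angle with `reference`."""
    return direction if direction @ reference >= 0 else -direction


def _propagate(field: DiffusionField, seed: np.ndarray, init_dir: np.ndarray,
               params: TrackingParams) -> list[np.ndarray]:
    """One half-track from `seed` along `init_dir`; returns points incl. seed."""
    cos_limit = np.cos(np.deg2rad(params.angle_threshold))
    pos = np.asarray(seed, float)
    prev = np.asarray(init_dir, float)
    points = [pos]
    for _ in range(params.max_points):
        vox_dir = field.direction_at(pos)
        if vox_dir is None:
            break
        vox_dir = _align(vox_dir, prev)
        if vox_dir @ prev < cos_limit:  # turn sharper than the threshold
            break
        step_dir = params.smoothing * prev + (1.0 - params.smoothing) * vox_dir
        nrm = np.linalg.norm(step_dir)
        if nrm < 1e-12:
            break
        step_dir /= nrm
        nxt = pos + params.step_size * step_dir
        if not field.contains(nxt):
            break
        if field.fa_at(nxt, params.interpolation) < params.fa_threshold:
            break
        points.append(nxt)
        pos, prev = nxt, step_dir
    return points


def track_from_seed(field: DiffusionField, seed: np.ndarray,
                    params: TrackingParams | None = None) -> Streamline | None:
    """Bidirectional streamline through `seed`, or None if the seed is untrackable.

    The seed voxel must be inside the grid with FA at or above the threshold;
    both half-tracks start along +/- the seed voxel's principal direction and
    are concatenated with the seed point shared once.
    """
    params = params or TrackingParams()
    seed = np.asarray(seed, float)
    if not field.contains(seed):
        raise ValueError("seed lies outside the field")
    if field.fa_at(seed, params.interpolation) < params.fa_threshold:
        return None
    d0 = field.direction_at(seed)
    fwd = _propagate(field, seed, d0, params)
    bwd = _propagate(field, seed, -d0, params)
    points = bwd[::-1] + fwd[1:]
    if len(points) < 2:
        return None
    return Streamline.from_points(np.asarray(points), field, params.interpolation)


def track_volume(field: DiffusionField, params: TrackingParams | None = None,
                 rng_seed: int = 0, jitter: bool = False) -> Tractogram:
    """Track from the center of every voxel with FA >= threshold.

    Deterministic by default; ``jitter`` adds uniform sub-voxel offsets when
    ``seeds_per_voxel > 1`` (reproducible from ``rng_seed``).
    """
    params = params or TrackingParams()
    seeds = field.seed_points(params.fa_threshold)
    if params.seeds_per_voxel > 1 or jitter:
        rng = np.random.default_rng(rng_seed)
        reps = params.seeds_per_voxel
        vox = np.abs(np.diag(field.affine[:3, :3]))
        seeds = np.repeat(seeds, reps, axis=0)
        if jitter:
            seeds = seeds + rng.uniform(-0.5, 0.5, seeds.shape) * vox
    lines = []
    for s in seeds:
        sl = track_from_seed(field, s, params)
        if sl is not None:
            lines.append(sl)
    return Tractogram(streamlines=lines, params=params)


def filter_by_length(t: Tractogram, min_mm: float | None = None,
                     max_mm: float | None = None) -> Tractogram:
    """Keep streamlines with min_mm <= length <= max_mm (inclusive), in order."""
    if min_mm is None:
        min_mm = t.params.min_length if t.params else 10.0
    if max_mm is None:
        max_mm = t.params.max_length if t.params else 65.0
    kept = [s for s in t.streamlines if min_mm <= s.length <= max_mm]
    return Tractogram(streamlines=kept, params=t.params, provenance=t.provenance)


def track_short_range(field: DiffusionField,
                      params: TrackingParams | None = None,
                      rng_seed: int = 0) -> Tractogram:
    """Full short-range pipeline: volume seeding then the length window."""
    params = params or TrackingParams()
    return filter_by_length(track_volume(field, params, rng_seed),
                            params.min_length, params.max_length)
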