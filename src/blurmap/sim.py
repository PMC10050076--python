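"""Forward model: Brownian trajectories, motion-blurred images, datasets.

The simulator emulates wide-field single-molecule recordings of 2-D
diffusion under typical single-molecule localization microscopy (SMLM)
conditions.  A molecule diffusing at coefficient D traces a trajectory
during the camera exposure (default 9 ms, resolved into 1000 micro-steps
of fixed length sqrt(4·D·t)); its image is the convolution of that
trajectory with the microscope point spread function (PSF), sampled at
the photon level, pixelized onto a 160 nm grid and corrupted with camera
background noise.  Stacks of such images from independent trajectories
at a common D form the training unit for the diffusivity regressor.

Units: positions in nm, time in s, D in µm²/s, photon rates in
photons/ms, pixel values in photon counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .fields import DiffusivityField

__all__ = [
    "SimConfig",
    "Trajectory",
    "MoleculeImage",
    "ImageStack",
    "TrainingDataset",
    "FrameSequence",
    "simulate_trajectory",
    "simulate_trajectory_in_field",
    "simulate_trajectories",
    "simulate_trajectories_in_field",
    "render_image",
    "render_images",
    "render_frame_sequence",
    "build_training_dataset",
    "default_label_grid",
    "default_augmentation_grid",
    "save_dataset",
    "load_dataset",
]

NM_PER_UM = 1000.0

# Default label grid of the regression problem: 0-6 µm²/s in 0.05 steps,
# 121 labels.
FULL_LABEL_GRID = np.round(np.arange(0, 121) * 0.05, 10)


@dataclass(frozen=True)
class SimConfig:
    """Physical and sampling parameters of the forward model.

    Parameters
    ----------
    exposure_time:
        Camera exposure per frame, seconds (default 9 ms).
    n_micro_steps:
        Number of Brownian micro-steps resolved within one exposure.
    pixel_size:
        Camera pixel size at the sample plane, nm.
    roi_size:
        Side of the square single-molecule region of interest, pixels (odd).
    photon_rate_range:
        Typical single-molecule brightness range, photons/ms.
    background_mean, background_sigma:
        Per-pixel background model: Poisson(mean) + Normal(0, sigma) counts.
    psf_sigma:
        Gaussian PSF standard deviation, nm.
    step_scheme:
        ``"fixed"``: every micro-step has length sqrt(4·D·t) in a uniformly
        random direction. ``"gaussian"``: per-axis Normal(0, sqrt(2·D·t))
        increments.  Both give MSD = 4·D·τ.
    """

    exposure_time: float = 0.009
    n_micro_steps: int = 1000
    pixel_size: float = 160.0
    roi_size: int = 7
    photon_rate_range: tuple[float, float] = (60.0, 120.0)
    background_mean: float = 10.0
    background_sigma: float = 3.0
    psf_sigma: float = 110.0
    step_scheme: str = "fixed"

    def __post_init__(self) -> None:
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        if self.n_micro_steps < 1:
            raise ValueError("n_micro_steps must be >= 1")
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("physical quantities must be positive")
        if self.roi_size < 1 or self.roi_size % 2 == 0:
            raise ValueError("roi_size must be a positive odd integer")
        lo, hi = self.photon_rate_range
        if not (0 < lo <= hi):
            raise ValueError("photon_rate_range must satisfy 0 < min <= max")
        if self.background_mean < 0 or self.background_sigma < 0:
            raise ValueError("background parameters must be non-negative")
        if self.step_scheme not in ("fixed", "gaussian"):
            raise ValueError("step_scheme must be 'fixed' or 'gaussian'")
        if self.roi_size * self.pixel_size < 4.0 * self.psf_sigma:
            raise ValueError("ROI too small to contain the PSF core")

    @property
    def micro_dt(self) -> float:
        """Micro-step interval t = exposure / n_micro_steps, seconds."""
        return self.exposure_time / self.n_micro_steps

    @property
    def exposure_ms(self) -> float:
        return self.exposure_time * 1e3

    def step_length_nm(self, D) -> np.ndarray:
        """Fixed micro-step length sqrt(4·D·t), nm, for D in µm²/s."""
        return np.sqrt(4.0 * np.asarray(D, dtype=float) * self.micro_dt) * NM_PER_UM

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "photon_rate_range" in d:
            d["photon_rate_range"] = tuple(d["photon_rate_range"])
        return cls(**d)


@dataclass(frozen=True)
class Trajectory:
    """One molecule's path over a single exposure."""

    positions: np.ndarray  # (n_micro_steps + 1, 2), nm
    true_D: float  # µm²/s (field value at the start position)
    start_position: tuple[float, float]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def end_to_end_sq_um2(self) -> float:
        d = (self.positions[-1] - self.positions[0]) / NM_PER_UM
        return float(d @ d)


@dataclass(frozen=True)
class MoleculeImage:
    """A single-molecule ROI of photon counts plus rendering metadata."""

    pixels: np.ndarray  # (roi, roi) counts, >= 0
    photon_rate: float | None = None
    background_level: float | None = None
    true_D: float | None = None
    source_frame: int | None = None
    centroid: tuple[float, float] | None = None  # nm, global coordinates


@dataclass(frozen=True)
class ImageStack:
    """n_ch mutually uncorrelated molecule images; the regressor's input unit."""

    images: np.ndarray  # (n_ch, roi, roi)
    label_D: float | None = None

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be (n_ch, roi, roi)")

    @property
    def n_ch(self) -> int:
        return self.images.shape[0]


@dataclass
class TrainingDataset:
    """Stacks + labels, with the generation parameters kept alongside."""

    stacks: np.ndarray  # (N, n_ch, roi, roi) float32
    labels: np.ndarray  # (N,) float
    config: SimConfig
    augmentation_grid: list[tuple[float, float]]  # (photon_rate, background_mean)
    stacks_per_label: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.stacks)

    @property
    def n_ch(self) -> int:
        return self.stacks.shape[1]

    @property
    def label_grid(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class FrameSequence:
    """Synthetic wide-field movie plus its ground-truth emitter table."""

    frames: np.ndarray  # (n_frames, H, W) uint16 counts
    truth: "pandas.DataFrame"  # columns: frame, x_nm, y_nm, true_D, photons
    config: SimConfig
    field: DiffusivityField


# ---------------------------------------------------------------------- #
# trajectories


def simulate_trajectories(D: float, n: int, config: SimConfig,
                          rng: np.random.Generator,
                          starts: np.ndarray | None = None) -> np.ndarray:
    """Simulate ``n`` trajectories at fixed D; returns (n, S+1, 2) nm."""
    if D < 0:
        raise ValueError("D must be non-negative")
    S = config.n_micro_steps
    if starts is None:
        starts = np.zeros((n, 2), dtype=np.float32)
    starts = np.asarray(starts, dtype=np.float32)
    # float32 throughout: step lengths are ~10 nm, positions ~µm, so
    # single precision keeps sub-0.01 nm accuracy at ~6x the speed
    steps = np.empty((n, S, 2), dtype=np.float32)
    if config.step_scheme == "fixed":
        L = np.float32(config.step_length_nm(D))
        theta = rng.random((n, S), dtype=np.float32) * np.float32(2.0 * np.pi)
        steps[:, :, 0] = np.cos(theta)
        steps[:, :, 1] = np.sin(theta)
        steps *= L
    else:
        sigma = np.float32(np.sqrt(2.0 * D * config.micro_dt) * NM_PER_UM)
        steps[:] = rng.standard_normal((n, S, 2), dtype=np.float32)
        steps *= sigma
    pos = np.empty((n, S + 1, 2), dtype=np.float32)
    pos[:, 0] = starts
    np.cumsum(steps, axis=1, out=pos[:, 1:])
    pos[:, 1:] += starts[:, None, :]
    return pos


def simulate_trajectory(D: float, config: SimConfig,
                        rng: np.random.Generator,
                        start: Sequence[float] = (0.0, 0.0)) -> Trajectory:
    """Simulate one Brownian trajectory over a single exposure.

    Under the default ``fixed`` scheme every micro-step has length
    sqrt(4·D·t) with t = exposure / n_micro_steps, in a uniformly random
    direction, so the end-to-end mean squared displacement is exactly
    4·D·exposure.
    """
    start = np.asarray(start, dtype=float)
    pos = simulate_trajectories(D, 1, config, rng, starts=start[None, :])[0]
    return Trajectory(pos, float(D), tuple(start))


def simulate_trajectories_in_field(field: DiffusivityField, starts: np.ndarray,
                                   config: SimConfig,
                                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Trajectories in a spatially varying D field.

    The local D at the current position sets the next micro-step length.
    Returns ``(positions (n, S+1, 2) nm, true_D (n,))`` where ``true_D``
    is the field value at each start position.
    """
    starts = np.asarray(starts, dtype=float)
    if not np.all(field.contains(starts)):
        raise ValueError("start position outside the field domain")
    n = len(starts)
    S = config.n_micro_steps
    dt = config.micro_dt
    pos = np.empty((n, S + 1, 2), dtype=np.float32)
    pos[:, 0] = starts
    cur = starts.astype(np.float32)
    gaussian = config.step_scheme == "gaussian"
    two_pi = np.float32(2.0 * np.pi)
    for s in range(S):
        D_loc = field.D_at(cur).astype(np.float32)
        if gaussian:
            sigma = np.sqrt(np.float32(2.0 * dt * NM_PER_UM**2) * D_loc)
            cur = cur + rng.standard_normal((n, 2), dtype=np.float32) * sigma[:, None]
        else:
            L = np.sqrt(np.float32(4.0 * dt * NM_PER_UM**2) * D_loc)
            theta = rng.random(n, dtype=np.float32) * two_pi
            cur = cur + np.stack([L * np.cos(theta), L * np.sin(theta)], axis=1)
        pos[:, s + 1] = cur
    return pos, field.D_at(starts)


def simulate_trajectory_in_field(field: DiffusivityField, start, config: SimConfig,
                                 rng: np.random.Generator) -> Trajectory:
    start = np.asarray(start, dtype=float)
    pos, true_D = simulate_trajectories_in_field(field, start[None, :], config, rng)
    return Trajectory(pos[0], float(true_D[0]), tuple(start))


# ---------------------------------------------------------------------- #
# rendering


def _emit_photons(trajectories: np.ndarray, photon_rates: np.ndarray,
                  config: SimConfig, rng: np.random.Generator):
    """Photon emission along trajectories.

    The expected photon budget photon_rate × exposure_ms is apportioned
    uniformly over the micro-steps; realised counts are Poisson.  Each
    photon is displaced from its emission position by a Gaussian PSF draw.
    Returns (traj_id, photon positions (M, 2) nm, counts-per-trajectory).
    """
    k, n_pos, _ = trajectories.shape
    lam = np.asarray(photon_rates, dtype=float) * config.exposure_ms
    counts = rng.poisson(lam)
    total = int(counts.sum())
    tid = np.repeat(np.arange(k), counts)
    sid = rng.integers(0, n_pos, size=total)
    pts = trajectories[tid, sid, :]
    pts = pts + rng.normal(0.0, config.psf_sigma, size=(total, 2))
    return tid, pts, counts


def _photon_centroids(tid, pts, counts, trajectories):
    """Intensity-weighted centroid of the emitted photons, per trajectory."""
    k = len(counts)
    cent = np.empty((k, 2))
    for ax in range(2):
        cent[:, ax] = np.bincount(tid, weights=pts[:, ax], minlength=k)
    nz = counts > 0
    cent[nz] /= counts[nz, None]
    # zero-photon images: fall back to the trajectory mean position
    if not np.all(nz):
        cent[~nz] = trajectories[~nz].mean(axis=1)
    return cent


def render_images(trajectories: np.ndarray, config: SimConfig,
                  photon_rates, rng: np.random.Generator,
                  background_mean=None, background_sigma=None,
                  add_background: bool = True):
    """Render many trajectories into centroid-centered ROIs (vectorized).

    Parameters
    ----------
    trajectories:
        (k, S+1, 2) positions in nm.
    photon_rates:
        scalar or (k,) photons/ms.

    Returns
    -------
    images : (k, roi, roi) float32 photon counts (clipped at 0)
    centroids : (k, 2) photon centroid in the trajectory's own frame, nm

    The ROI is centered on the camera pixel containing the photon
    centroid (mirroring downstream centroid localization), so sub-pixel
    phases are preserved.
    """
    k = trajectories.shape[0]
    r = config.roi_size
    px = config.pixel_size
    half = r // 2
    rates = np.broadcast_to(np.asarray(photon_rates, dtype=float), (k,))
    b_mean = config.background_mean if background_mean is None else background_mean
    b_sigma = config.background_sigma if background_sigma is None else background_sigma

    tid, pts, counts = _emit_photons(trajectories, rates, config, rng)
    cent = _photon_centroids(tid, pts, counts, trajectories)

    # pixel grid anchored to the camera lattice: ROI center pixel is the
    # pixel containing the centroid
    center_pix = np.floor(cent / px).astype(np.int64)
    origin = (center_pix - half) * px  # (k, 2) nm, ROI lower corner
    rel = pts - origin[tid]
    ij = np.floor(rel / px).astype(np.int64)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < r) & (ij[:, 1] >= 0) & (ij[:, 1] < r)
    flat = tid[ok] * (r * r) + ij[ok, 1] * r + ij[ok, 0]
    images = np.bincount(flat, minlength=k * r * r).astype(np.float64)
    images = images.reshape(k, r, r)  # [y, x]

    if add_background and (np.any(np.asarray(b_mean) > 0) or b_sigma > 0):
        lam = np.broadcast_to(np.asarray(b_mean, dtype=float)
                              .reshape(-1, 1, 1), (k, r, r))
        images += rng.poisson(lam)
        if b_sigma > 0:
            images += rng.normal(0.0, b_sigma, size=(k, r, r))
        np.clip(images, 0.0, None, out=images)
    return images.astype(np.float32), cent


def render_image(traj: Trajectory, config: SimConfig, photon_rate: float,
                 rng: np.random.Generator, background_mean=None,
                 background_sigma=None, add_background: bool = True) -> MoleculeImage:
    """Render one trajectory into a single-molecule ROI image."""
    if photon_rate < 0:
        raise ValueError("photon_rate must be non-negative")
    images, cents = render_images(traj.positions[None], config, photon_rate, rng,
                                  background_mean=background_mean,
                                  background_sigma=background_sigma,
                                  add_background=add_background)
    b = config.background_mean if background_mean is None else background_mean
    return MoleculeImage(pixels=images[0], photon_rate=float(photon_rate),
                         background_level=float(b), true_D=traj.true_D,
                         centroid=(float(cents[0, 0]), float(cents[0, 1])))


def render_frame_sequence(field: DiffusivityField, density: float, n_frames: int,
                          config: SimConfig, rng: np.random.Generator,
                          photon_rate: float | None = None) -> FrameSequence:
    """Synthesize a wide-field movie of molecules diffusing in ``field``.

    Each frame holds a Poisson number of non-interacting molecules
    (mean = density × area), each an independent trajectory started at a
    uniform position with D updated from the field at every micro-step.

    Parameters
    ----------
    density:
        molecules/µm²/frame (SMLM-typical ~0.1).
    photon_rate:
        photons/ms; drawn uniformly from ``config.photon_rate_range`` per
        molecule when None.

    Ground truth is reported at each molecule's photon centroid.
    """
    import pandas as pd

    if density < 0:
        raise ValueError("density must be non-negative")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    x0, y0, x1, y1 = field.domain_bounds
    area_um2 = (x1 - x0) * (y1 - y0) / NM_PER_UM**2
    W = int(np.ceil((x1 - x0) / config.pixel_size))
    H = int(np.ceil((y1 - y0) / config.pixel_size))
    frames = np.zeros((n_frames, H, W), dtype=np.float64)
    rows = []
    for f in range(n_frames):
        k = rng.poisson(density * area_um2)
        if k > 0:
            starts = field.sample_positions(k, rng)
            trajs, true_D = simulate_trajectories_in_field(field, starts, config, rng)
            if photon_rate is None:
                rates = rng.uniform(*config.photon_rate_range, size=k)
            else:
                rates = np.full(k, float(photon_rate))
            tid, pts, counts = _emit_photons(trajs, rates, config, rng)
            cent = _photon_centroids(tid, pts, counts, trajs)
            ij = np.floor((pts - (x0, y0)) / config.pixel_size).astype(np.int64)
            ok = (ij[:, 0] >= 0) & (ij[:, 0] < W) & (ij[:, 1] >= 0) & (ij[:, 1] < H)
            np.add.at(frames[f], (ij[ok, 1], ij[ok, 0]), 1.0)
            for i in range(k):
                rows.append((f, cent[i, 0], cent[i, 1], float(true_D[i]), int(counts[i])))
        # camera background over the whole frame
        frames[f] += rng.poisson(config.background_mean, size=(H, W))
        if config.background_sigma > 0:
            frames[f] += rng.normal(0.0, config.background_sigma, size=(H, W))
    np.clip(frames, 0.0, 65535.0, out=frames)
    truth = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "true_D", "photons"])
    return FrameSequence(np.round(frames).astype(np.uint16), truth, config, field)


# ---------------------------------------------------------------------- #
# datasets


def default_label_grid(step: float = 0.05, lo: float = 0.0, hi: float = 6.0) -> np.ndarray:
    """D label grid; the full-scale default is 0-6 µm²/s in 0.05 steps (121)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def default_augmentation_grid(config: SimConfig | None = None,
                              n_rates: int = 4, n_backgrounds: int = 5):
    """Brightness × background combinations for domain randomization.

    The default 4 × 5 = 20 grid spans the configured photon-rate range
    and background levels bracketing the camera default.
    """
    config = config or SimConfig()
    rates = np.linspace(*config.photon_rate_range, n_rates)
    bgs = np.linspace(2.0, 18.0, n_backgrounds)
    return [(float(r), float(b)) for r in rates for b in bgs]


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-derived stream so dataset content is order-independent."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def build_training_dataset(config: SimConfig, label_grid, augmentation_grid,
                           stacks_per_label: int, seed: int,
                           n_ch: int = 40,
                           mix_within_stack: bool = False) -> TrainingDataset:
    """Generate stacks of uncorrelated blurred images for every (label, combo).

    For each D label and each (photon_rate, background_mean) augmentation
    combination, ``stacks_per_label`` stacks of ``n_ch`` independently
    simulated and rendered molecules are produced.  By default all images
    within one stack share the combo's brightness and background; with
    ``mix_within_stack`` each image draws its own combo from the grid
    (matching bin pools, which mix molecules of different brightness) and
    the same total count is kept.  Total size is
    ``len(label_grid) × len(augmentation_grid) × stacks_per_label``.
    """
    label_grid = np.asarray(label_grid, dtype=float)
    if label_grid.size == 0 or len(augmentation_grid) == 0:
        raise ValueError("label and augmentation grids must be non-empty")
    if np.any(label_grid < 0) or np.any(label_grid > 6.0):
        raise ValueError("labels must lie within [0, 6] µm²/s")
    if np.any(np.diff(label_grid) <= 0):
        raise ValueError("label grid must be strictly increasing")
    r = config.roi_size
    n_labels = len(label_grid)
    n_combo = len(augmentation_grid)
    N = n_labels * n_combo * stacks_per_label
    stacks = np.empty((N, n_ch, r, r), dtype=np.float32)
    labels = np.empty(N, dtype=np.float64)
    combo_arr = np.asarray(augmentation_grid, dtype=float)
    idx = 0
    for li, D in enumerate(label_grid):
        for ci in range(n_combo):
            rng = _child_rng(seed, li, ci)
            k = stacks_per_label * n_ch
            trajs = simulate_trajectories(float(D), k, config, rng)
            if mix_within_stack:
                pick = combo_arr[rng.integers(0, n_combo, size=k)]
                rates, bgs = pick[:, 0], pick[:, 1]
            else:
                rates, bgs = combo_arr[ci, 0], combo_arr[ci, 1]
            imgs, _ = render_images(trajs, config, rates, rng,
                                    background_mean=bgs)
            stacks[idx:idx + stacks_per_label] = imgs.reshape(stacks_per_label, n_ch, r, r)
            labels[idx:idx + stacks_per_label] = D
            idx += stacks_per_label
    return TrainingDataset(stacks, labels, config, list(augmentation_grid),
                           stacks_per_label, seed)


def save_dataset(dataset: TrainingDataset, path) -> None:
    """Write a dataset to HDF5 (/stacks, /labels + JSON meta attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("stacks", data=dataset.stacks, compression="gzip")
        f.create_dataset("labels", data=dataset.labels)
        f.attrs["config"] = json.dumps(dataset.config.to_dict())
        f.attrs["augmentation_grid"] = json.dumps(dataset.augmentation_grid)
        f.attrs["stacks_per_label"] = dataset.stacks_per_label
        f.attrs["seed"] = -1 if dataset.seed is None else dataset.seed


def load_dataset(path) -> TrainingDataset:
    import h5py

    with h5py.File(path, "r") as f:
        stacks = f["stacks"][...]
        labels = f["labels"][...]
        config = SimConfig.from_dict(json.loads(f.attrs["config"]))
        aug = [tuple(c) for c in json.loads(f.attrs["augmentation_grid"])]
        spl = int(f.attrs["stacks_per_label"])
        seed = int(f.attrs["seed"])
    return TrainingDataset(stacks, labels, config, aug, spl,
                           None if seed < 0 else seed)
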