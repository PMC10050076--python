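"""Super-resolved spatial mapping of D.

Retained single-molecule localizations are binned onto a fine grid
(default 120 nm).  Each bin i accumulates a pool of p_i molecule images;
for every bin with p_i > 10, m (default 100) stacks of n_ch images are
drawn from the pool, each stack is evaluated by the trained regressor,
and the m outputs are averaged into the bin's D (negative averages are
clamped to zero for physical relevance).  When a pool is smaller than
the stack depth, images may repeat within a stack, but each at most j
times with j the minimum integer satisfying j·p_i > n_ch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpatialBin", "DMap", "bin_localizations", "repetition_bound",
           "sample_stack_indices", "evaluate_bin", "build_dmap",
           "render_map", "read_map_csv"]

MIN_POOL = 10  # bins need p_i > 10 images to be evaluated


@dataclass
class SpatialBin:
    """One grid cell: indices into the localization table plus its images."""

    i: int  # row (y) index
    j: int  # column (x) index
    edges: tuple[float, float, float, float]  # (x0, y0, x1, y1) nm, half-open
    indices: np.ndarray  # indices of member localizations
    images: np.ndarray | None = None  # (p_i, roi, roi)

    @property
    def p_i(self) -> int:
        return len(self.indices)


@dataclass
class DMap:
    """Evaluated D per grid cell; NaN marks bins left undefined (p_i <= 10)."""

    D: np.ndarray  # (ny, nx) µm²/s, NaN where undefined
    counts: np.ndarray  # (ny, nx) p_i
    grid_size: float  # nm
    origin: tuple[float, float] = (0.0, 0.0)
    m: int = 100
    n_ch: int = 40

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.D)

    def bin_centers(self):
        ny, nx = self.D.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.grid_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.grid_size
        return x, y


def bin_localizations(positions: np.ndarray, grid_size: float,
                      origin=(0.0, 0.0), images: np.ndarray | None = None,
                      shape: tuple[int, int] | None = None) -> list[SpatialBin]:
    """Partition localizations into half-open grid cells [k·g, (k+1)·g).

    A record exactly on a boundary goes to the higher-index bin.  The
    partition is exhaustive and disjoint: every record lands in exactly
    one bin, so Σ p_i equals the number of records.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        return []
    ox, oy = origin
    jx = np.floor((positions[:, 0] - ox) / grid_size).astype(int)
    iy = np.floor((positions[:, 1] - oy) / grid_size).astype(int)
    bins: list[SpatialBin] = []
    order = np.lexsort((jx, iy))
    key = iy[order].astype(np.int64) << 32 | (jx[order] & 0xFFFFFFFF)
    starts = np.flatnonzero(np.r_[True, np.diff(key) != 0])
    bounds = np.r_[starts, len(order)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        idx = order[s:e]
        i, j = int(iy[idx[0]]), int(jx[idx[0]])
        edges = (ox + j * grid_size, oy + i * grid_size,
                 ox + (j + 1) * grid_size, oy + (i + 1) * grid_size)
        bins.append(SpatialBin(i, j, edges, idx,
                               None if images is None else images[idx]))
    return bins


def repetition_bound(p_i: int, n_ch: int) -> int:
    """Minimum integer j with j · p_i > n_ch (per-image repeat cap)."""
    if p_i <= 0:
        raise ValueError("p_i must be positive")
    return n_ch // p_i + 1


def sample_stack_indices(p_i: int, n_ch: int, m: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Indices of the m sampled stacks, shape (m, n_ch).

    For p_i >= n_ch each stack is an n_ch-subset drawn without
    replacement (a permutation subset of the pool).  For smaller pools,
    each stack is drawn without replacement from a virtual pool holding
    every image j times, so no image repeats more than j times.
    """
    if p_i >= n_ch:
        base = np.arange(p_i)
    else:
        j = repetition_bound(p_i, n_ch)
        base = np.tile(np.arange(p_i), j)
    out = np.empty((m, n_ch), dtype=np.intp)
    for s in range(m):
        out[s] = rng.permutation(base)[:n_ch]
    return out


def evaluate_bin(model, images: np.ndarray, m: int = 100, n_ch: int = 40,
                 rng: np.random.Generator | None = None) -> float:
    """Ensemble-evaluate one bin's image pool; returns D >= 0 (µm²/s).

    Raises ``ValueError`` for pools with p_i <= 10 — such bins are left
    undefined by :func:`build_dmap`.
    """
    images = np.asarray(images)
    p_i = len(images)
    if p_i <= MIN_POOL:
        raise ValueError(f"bin pool too small (p_i={p_i} <= {MIN_POOL})")
    rng = rng or np.random.default_rng()
    sel = sample_stack_indices(p_i, n_ch, m, rng)
    stacks = images[sel]  # (m, n_ch, r, r)
    preds = model.predict(stacks)
    return max(float(np.mean(preds)), 0.0)


def build_dmap(model, positions: np.ndarray, images: np.ndarray,
               grid_size: float = 120.0, m: int = 100, n_ch: int = 40,
               seed: int = 0, origin=(0.0, 0.0),
               shape: tuple[int, int] | None = None) -> DMap:
    """Bin localizations and evaluate every eligible bin into a D map.

    Per-bin RNG streams are derived from (seed, i, j) so the map does
    not depend on bin evaluation order.
    """
    import warnings

    bins = bin_localizations(positions, grid_size, origin=origin, images=images)
    if shape is None:
        if not bins:
            warnings.warn("no localizations: empty map")
            return DMap(np.full((0, 0), np.nan), np.zeros((0, 0), dtype=int),
                        grid_size, tuple(origin), m, n_ch)
        ny = max(b.i for b in bins) + 1
        nx = max(b.j for b in bins) + 1
    else:
        ny, nx = shape
    D = np.full((ny, nx), np.nan)
    counts = np.zeros((ny, nx), dtype=int)
    any_eval = False
    for b in bins:
        if not (0 <= b.i < ny and 0 <= b.j < nx):
            continue
        counts[b.i, b.j] = b.p_i
        if b.p_i > MIN_POOL:
            rng = np.random.default_rng(np.random.SeedSequence([seed, b.i, b.j]))
            D[b.i, b.j] = evaluate_bin(model, b.images, m=m, n_ch=n_ch, rng=rng)
            any_eval = True
    if not any_eval:
        warnings.warn("no bins satisfied p_i > 10; map is empty")
    return DMap(D, counts, grid_size, tuple(origin), m, n_ch)


def render_map(dmap: DMap, png_path=None, csv_path=None,
               vmin: float = 0.0, vmax: float | None = None,
               cmap: str = "viridis") -> pd.DataFrame:
    """Color-coded raster (undefined bins transparent) + (i, j, D, p_i) table.

    The color range clamps the display only; stored values are untouched.
    """
    ii, jj = np.nonzero(dmap.counts > 0)
    table = pd.DataFrame({"i": ii, "j": jj, "D": dmap.D[ii, jj],
                          "p_i": dmap.counts[ii, jj]})
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6 * max(dmap.D.shape[0], 1)
                                        / max(dmap.D.shape[1], 1)))
        if dmap.D.size:
            masked = np.ma.masked_invalid(dmap.D)
            im = ax.imshow(masked, origin="lower", cmap=cmap, vmin=vmin,
                           vmax=vmax, interpolation="nearest")
            fig.colorbar(im, ax=ax, label="D (µm²/s)")
        ax.set_xlabel("bin j")
        ax.set_ylabel("bin i")
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return table


def read_map_csv(csv_path, shape: tuple[int, int] | None = None,
                 grid_size: float = 120.0, **kwargs) -> DMap:
    """Rebuild a :class:`DMap` from its companion CSV (exact round-trip)."""
    t = pd.read_csv(csv_path)
    if shape is None:
        ny = int(t["i"].max()) + 1 if len(t) else 0
        nx = int(t["j"].max()) + 1 if len(t) else 0
    else:
        ny, nx = shape
    D = np.full((ny, nx), np.nan)
    counts = np.zeros((ny, nx), dtype=int)
    for _, row in t.iterrows():
        D[int(row.i), int(row.j)] = row.D
        counts[int(row.i), int(row.j)] = int(row.p_i)
    return DMap(D, counts, grid_size, **kwargs)
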