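"""Quantitative assessment of the diffusivity regressor and of D maps.

Accuracy is reported as %Error = (E − T)/T × 100 with E the evaluated
and T the ground-truth D; labels at T = 0 are excluded (absolute error
is reported for them instead).  The module provides per-label error
reports, precision-versus-image-count curves with the step-distance MLE
trend overlaid, boundary transition widths of mapped patterns, and
bin-wise map error distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fields import DiffusivityField
from .mapping import DMap, evaluate_bin
from .mle import images_to_steps_accounting, relative_se
from .sim import SimConfig, simulate_trajectories, render_images

__all__ = ["percent_error", "error_report", "precision_curve",
           "transition_width", "transition_profile", "map_error_distribution",
           "simulate_bin_pools", "evaluation_sigma"]


def percent_error(E, T):
    """(E − T)/T × 100.  Undefined (NaN) where T <= 0."""
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    out = np.where(T > 0, (E - T) / np.where(T > 0, T, 1.0) * 100.0, np.nan)
    if out.ndim == 0:
        if T <= 0:
            raise ValueError("%Error is undefined for T <= 0")
        return float(out)
    return out


def error_report(predictions: np.ndarray, truths: np.ndarray) -> pd.DataFrame:
    """Per-label mean prediction and sd of %Error.

    The T = 0 label (if present) reports NaN %Error statistics and the
    sd of the absolute error instead.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    rows = []
    for T in np.unique(truths):
        sel = truths == T
        E = predictions[sel]
        if T > 0:
            pe = (E - T) / T * 100.0
            rows.append((T, E.mean(), pe.mean(), pe.std(ddof=1), np.nan, sel.sum()))
        else:
            rows.append((T, E.mean(), np.nan, np.nan, np.abs(E).std(ddof=1), sel.sum()))
    return pd.DataFrame(rows, columns=["true_D", "mean_E", "mean_pct_error",
                                       "sd_pct_error", "sd_abs_error", "n_eval"])


def simulate_bin_pools(D: float, p_i: int, reps: int, config: SimConfig,
                       rng: np.random.Generator,
                       photon_rate: float | None = None) -> np.ndarray:
    """Simulate ``reps`` independent pools of p_i blurred images at fixed D."""
    if photon_rate is None:
        photon_rate = float(np.mean(config.photon_rate_range))
    k = reps * p_i
    trajs = simulate_trajectories(D, k, config, rng)
    imgs, _ = render_images(trajs, config, photon_rate, rng)
    return imgs.reshape(reps, p_i, *imgs.shape[1:])


def evaluation_sigma(model, D: float, p_i: int, reps: int, config: SimConfig,
                     rng: np.random.Generator, m: int = 100,
                     n_ch: int = 40) -> tuple[float, np.ndarray]:
    """sd of %Error over ``reps`` ensemble-evaluated bins at fixed D.

    Returns (sd(%Error), the per-bin evaluated D values).
    """
    pools = simulate_bin_pools(D, p_i, reps, config, rng)
    est = np.array([evaluate_bin(model, pool, m=m, n_ch=n_ch, rng=rng)
                    for pool in pools])
    pe = percent_error(est, np.full(reps, D))
    return float(np.std(pe, ddof=1)), est


def precision_curve(model, p_i_list, config: SimConfig, rng: np.random.Generator,
                    D_list=(1.0, 2.0, 3.0, 4.0), reps: int = 100,
                    m: int = 100, n_ch: int = 40) -> pd.DataFrame:
    """sd(%Error) vs p_i per D, with the MLE 1/√(p_i/2) trend overlaid.

    The MLE column converts the image budget to steps (two images per
    step) before applying the 1/√N law, putting both estimators on the
    same per-image budget.
    """
    rows = []
    for p_i in p_i_list:
        n_steps = images_to_steps_accounting(p_i)
        mle_pct = relative_se(n_steps) * 100.0 if n_steps >= 1 else np.nan
        for D in D_list:
            sd, _ = evaluation_sigma(model, D, p_i, reps, config, rng,
                                     m=m, n_ch=n_ch)
            rows.append((D, p_i, sd, mle_pct))
    return pd.DataFrame(rows, columns=["true_D", "p_i", "sd_pct_error",
                                       "mle_rel_se_pct"])


def transition_width(profile: np.ndarray, low: float, high: float,
                     tol: float = 0.1):
    """Width (in bins) of a low→high transition along a 1-D profile.

    The width is the number of bins strictly between the last bin within
    ``tol``·low of the low plateau and the first subsequent bin within
    ``tol``·high of the high plateau.  Profiles running high→low are
    handled by symmetry (the result is invariant to reversing the line).
    Returns None when the profile does not cross between the plateaus.
    """
    v = np.asarray(profile, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return None
    near_low = np.abs(v - low) <= tol * low
    near_high = np.abs(v - high) <= tol * high
    if not (near_low.any() and near_high.any()):
        return None
    if np.flatnonzero(near_low)[0] > np.flatnonzero(near_high)[0]:
        return transition_width(v[::-1], low, high, tol)
    first_high = np.flatnonzero(near_high)[0]
    lows_before = np.flatnonzero(near_low[:first_high])
    if len(lows_before) == 0:
        return None
    last_low = lows_before[-1]
    return int(first_high - last_low - 1)


def transition_profile(dmap: DMap, row: int, low: float, high: float,
                       tol: float = 0.1) -> dict:
    """Transition widths along one map row crossing pattern boundaries.

    Scans the row for every low→high and high→low crossing and reports
    each width in bins and nm.  Raises ``ValueError`` when the row holds
    no transition between the plateaus.
    """
    v = dmap.D[row, :]
    widths = []
    # split the row at plateau membership changes and measure each crossing
    state = np.full(len(v), -1)
    state[np.abs(v - low) <= tol * low] = 0
    state[np.abs(v - high) <= tol * high] = 1
    plateau_idx = np.flatnonzero(state >= 0)
    for a, b in zip(plateau_idx[:-1], plateau_idx[1:]):
        if state[a] != state[b]:
            widths.append(int(b - a - 1))
    if not widths:
        raise ValueError("line does not cross a boundary between the plateaus")
    return {"widths_bins": widths,
            "widths_nm": [w * dmap.grid_size for w in widths],
            "max_width_bins": max(widths),
            "max_width_nm": max(widths) * dmap.grid_size}


def _boundary_bins(dmap: DMap, field: DiffusivityField) -> np.ndarray:
    """Bins whose cell is crossed by a region boundary of the true field.

    Detected by sampling the field on a 5×5 lattice inside each cell: a
    cell whose samples disagree straddles a boundary.
    """
    ny, nx = dmap.D.shape
    g = dmap.grid_size
    ox, oy = dmap.origin
    frac = np.linspace(0.02, 0.98, 5)
    X = ox + (np.arange(nx)[None, :, None, None] + frac[None, None, :, None]) * g
    Y = oy + (np.arange(ny)[:, None, None, None] + frac[None, None, None, :]) * g
    pts = np.stack(np.broadcast_arrays(X, Y), axis=-1)  # (ny, nx, 5, 5, 2)
    D = field.D_at(pts).reshape(ny, nx, 25)
    return np.ptp(D, axis=2) > 0


def map_error_distribution(dmap: DMap, field: DiffusivityField) -> pd.DataFrame:
    """Bin-wise %Error of a map against the true field.

    Bins intersected by the true region boundary are flagged
    ``is_boundary`` so interior statistics can exclude them.
    """
    x, y = dmap.bin_centers()
    xx, yy = np.meshgrid(x, y)
    T = field.D_at(np.stack([xx, yy], axis=-1))
    boundary = _boundary_bins(dmap, field)
    ii, jj = np.nonzero(dmap.defined)
    E = dmap.D[ii, jj]
    Tb = T[ii, jj]
    pe = np.where(Tb > 0, (E - Tb) / np.where(Tb > 0, Tb, 1.0) * 100.0, np.nan)
    return pd.DataFrame({"i": ii, "j": jj, "E": E, "T": Tb, "pct_error": pe,
                         "is_boundary": boundary[ii, jj]})


def map_error_summary(table: pd.DataFrame) -> dict:
    interior = table[~table.is_boundary & np.isfinite(table.pct_error)]
    return {
        "median_abs_pct_error_interior": float(np.median(np.abs(interior.pct_error)))
        if len(interior) else float("nan"),
        "frac_within_10pct_interior": float(np.mean(np.abs(interior.pct_error) < 10.0))
        if len(interior) else float("nan"),
        "n_interior": int(len(interior)),
        "n_boundary": int(table.is_boundary.sum()),
    }


__all__.append("map_error_summary")
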