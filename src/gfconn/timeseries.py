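"""Parcellated time-series processing and Pearson connectivity.

Cleaning follows the one-step confound-projection approach: censored frames
are deleted first, then each region's series is projected onto the orthogonal
complement of the nuisance regressors together with sine/cosine pairs at the
out-of-band Fourier frequencies evaluated on the kept frames' original time
grid. This removes nuisance variance, applies the band-pass and handles the
irregular sampling left by censoring in a single projection, so none of the
steps can reintroduce variance removed by another.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "ParcellatedScan",
    "ExclusionError",
    "build_nuisance_matrix",
    "build_task_regressor",
    "double_gamma_hrf",
    "clean_timeseries",
    "select_timepoints",
    "connectivity_matrix",
    "vectorize_edges",
    "unvectorize_edges",
    "n_edges",
]


class ExclusionError(RuntimeError):
    """A subject/scan cannot satisfy the requested analysis (insufficient
    frames or degrees of freedom after censoring) and must be excluded."""


@dataclass
class ParcellatedScan:
    """Frames x regions BOLD series with acquisition metadata.

    ``censored`` marks frames to drop (True = censored). Optional nuisance
    provenance: ``motion`` (frames x 6), ``tissue`` (frames x 5 CompCor-style
    components) and ``events`` as (onset_s, duration_s, condition) triples.
    """

    series: np.ndarray
    tr_seconds: float
    scan_type: str = "rest"
    session: int = 1
    phase_label: str = "NA"  # LR | RL | NA
    censored: np.ndarray | None = None
    motion: np.ndarray | None = None
    tissue: np.ndarray | None = None
    events: list[tuple[float, float, str]] = field(default_factory=list)
    #: acquisition time of each frame in seconds; cleaning preserves the
    #: original (possibly irregular) grid of the surviving frames
    frame_times: np.ndarray | None = None
    #: frame count defining the Fourier frequency grid k/(N*TR); stays at the
    #: acquisition length through cleaning
    grid_n_frames: int | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be frames x regions")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.censored is None:
            self.censored = np.zeros(self.n_frames, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.censored.shape != (self.n_frames,):
            raise ValueError("censor mask length must equal frame count")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) * self.tr_seconds
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.n_frames,):
            raise ValueError("frame_times length must equal frame count")
        if self.grid_n_frames is None:
            self.grid_n_frames = self.n_frames

    @property
    def n_frames(self) -> int:
        return self.series.shape[0]

    @property
    def n_regions(self) -> int:
        return self.series.shape[1]

    @property
    def n_kept(self) -> int:
        return int((~self.censored).sum())

    @property
    def minutes_kept(self) -> float:
        return self.n_kept * self.tr_seconds / 60.0


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak minus undershoot)."""
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, peak) - _gamma_dist.pdf(t, undershoot) / ratio
    return np.where(t >= 0, h, 0.0)


def build_task_regressor(
    events: list[tuple[float, float, str]],
    n_frames: int,
    tr_seconds: float,
    dt: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Boxcar-per-condition convolved with the canonical HRF.

    Events are (onset seconds, duration seconds, condition). Each condition
    yields one column, built on a fine grid (step ``dt``) and sampled at
    frame midpoints. Returns (n_frames x n_conditions, condition names); an
    empty event list yields a single zero column.
    """
    duration_s = n_frames * tr_seconds
    for onset, dur, _ in events:
        if onset < 0 or onset >= duration_s:
            raise ValueError(f"event onset {onset} outside scan [0, {duration_s})")
        if dur < 0:
            raise ValueError("event duration must be nonnegative")
    conditions = sorted({c for _, _, c in events})
    frame_mid = (np.arange(n_frames) + 0.5) * tr_seconds
    if not conditions:
        return np.zeros((n_frames, 1)), ["task"]
    n_fine = int(math.ceil((duration_s + 32.0) / dt))
    tgrid = np.arange(n_fine) * dt
    hrf = double_gamma_hrf(tgrid[tgrid <= 32.0])
    cols = np.zeros((n_frames, len(conditions)))
    for j, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        for onset, dur, c in events:
            if c != cond:
                continue
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            box[i0:max(i1, i0 + 1)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine] * dt
        cols[:, j] = np.interp(frame_mid, tgrid, conv)
    return cols, conditions


def build_nuisance_matrix(
    scan: ParcellatedScan,
    use_motion: bool = False,
    use_tissue: bool = False,
    use_global: bool = False,
    task_regressors: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the confound regressor matrix.

    Columns: intercept | 6 motion + 6 backward-difference derivatives |
    5 tissue components | global mean | task columns. Every column except the
    intercept is demeaned. Derivatives use the backward difference with first
    element 0. A rank-deficient result (e.g. a constant motion trace whose
    derivative is all zero) is retained but flagged with a warning.
    """
    n = scan.n_frames
    cols = [np.ones((n, 1))]
    if use_motion:
        if scan.motion is None:
            raise ValueError("motion regressors requested but scan has no motion series")
        m = np.asarray(scan.motion, dtype=float)
        if m.shape != (n, 6):
            raise ValueError("motion series must be frames x 6")
        d = np.diff(m, axis=0, prepend=m[:1])
        d[0] = 0.0
        cols.append(m)
        cols.append(d)
    if use_tissue:
        if scan.tissue is None:
            raise ValueError("tissue components requested but scan has none")
        t = np.asarray(scan.tissue, dtype=float)
        if t.shape != (n, 5):
            raise ValueError("tissue components must be frames x 5")
        cols.append(t)
    if use_global:
        cols.append(scan.series.mean(axis=1, keepdims=True))
    if task_regressors is not None:
        tr = np.atleast_2d(np.asarray(task_regressors, dtype=float))
        if tr.shape[0] != n:
            tr = tr.T
        if tr.shape[0] != n:
            raise ValueError("task regressors must have one row per frame")
        cols.append(tr)
    mat = np.hstack(cols)
    mat[:, 1:] -= mat[:, 1:].mean(axis=0)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        warnings.warn("nuisance matrix is rank deficient", RuntimeWarning, stacklevel=2)
    return mat


def _outofband_basis(grid_n: int, tr: float, times: np.ndarray,
                     band: tuple[float, float | None]) -> np.ndarray:
    """Sine/cosine pairs at Fourier frequencies k/(N*TR) outside the band,
    evaluated on the kept frames' original time grid."""
    f_lo, f_hi = band
    freqs = np.arange(1, grid_n // 2 + 1) / (grid_n * tr)
    out = freqs < f_lo - 1e-12
    if f_hi is not None:
        out |= freqs > f_hi + 1e-12
    freqs = freqs[out]
    if freqs.size == 0:
        return np.empty((times.size, 0))
    ang = 2.0 * np.pi * np.outer(times, freqs)
    return np.hstack([np.cos(ang), np.sin(ang)])


def clean_timeseries(
    scan: ParcellatedScan,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float | None] | None = None,
) -> ParcellatedScan:
    """One-step confound projection: censor, nuisance-regress and band-pass.

    Censored frames are dropped; the kept series is projected onto the
    orthogonal complement of [nuisance | out-of-band trig basis]. The
    returned scan holds residual series over the kept frames only (its censor
    mask is all-keep). Raises :class:`ExclusionError` when the kept frame
    count does not exceed the regressor count.
    """
    kept = ~scan.censored
    y = scan.series[kept]
    parts = []
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.shape[0] == scan.n_frames:
            nuis = nuis[kept]
        elif nuis.shape[0] != y.shape[0]:
            raise ValueError("nuisance rows must match total or kept frame count")
        parts.append(nuis)
    else:
        parts.append(np.ones((y.shape[0], 1)))
    if band is not None:
        parts.append(
            _outofband_basis(scan.grid_n_frames, scan.tr_seconds,
                             scan.frame_times[kept], band)
        )
    reg = np.hstack(parts)
    u, s, _ = np.linalg.svd(reg, full_matrices=False)
    rank = int((s > (s[0] if s.size else 0) * 1e-10).sum())
    if y.shape[0] <= rank:
        raise ExclusionError(
            f"insufficient degrees of freedom: {y.shape[0]} kept frames, "
            f"{rank} independent regressors"
        )
    q = u[:, :rank]
    resid = y - q @ (q.T @ y)
    return replace(
        scan,
        series=resid,
        censored=np.zeros(y.shape[0], dtype=bool),
        motion=None,
        tissue=None,
        frame_times=scan.frame_times[kept],
        grid_n_frames=scan.grid_n_frames,
    )


def _ordered_frame_pool(scans: list[ParcellatedScan], indices, lr_first: bool) -> np.ndarray:
    """Kept-frame identifiers as an (n, 2) array of (scan_index, frame_index)
    in acquisition order, scans ordered LR-labelled first (stable) when
    requested."""
    order = list(indices)
    if lr_first:
        rank = {"LR": 0, "RL": 1}
        order.sort(key=lambda i: rank.get(scans[i].phase_label, 2))
    parts = []
    for i in order:
        keep = np.flatnonzero(~scans[i].censored)
        parts.append(np.column_stack([np.full(keep.size, i), keep]))
    if not parts:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(parts)


def select_timepoints(
    scans: list[ParcellatedScan],
    budget_minutes: float,
    equal_split: bool = True,
    lr_first: bool = True,
    seed: int = 0,
):
    """Select exactly the budgeted number of post-censor frames.

    With ``equal_split``, every scan type contributes an equal share of the
    budget for as long as it has frames; within a type, frames are taken in
    acquisition order from LR-labelled scans first, then RL. Any shortfall
    once a type is exhausted (and the remainder of a budget not divisible by
    the type count) is drawn uniformly at random, seeded, from all remaining
    frames. Without ``equal_split`` the scans form a single LR-first pool
    consumed in acquisition order.

    Returns ``(series, composition)`` where ``series`` stacks the selected
    frames and ``composition`` is a pandas DataFrame with one row per scan
    actually contributing frames.
    """
    import pandas as pd

    if budget_minutes <= 0:
        raise ValueError("budget must be positive")
    if not scans:
        raise ValueError("no scans supplied")
    trs = {s.tr_seconds for s in scans}
    if len(trs) != 1:
        raise ValueError("scans must share a TR")
    tr = trs.pop()
    budget = int(round(budget_minutes * 60.0 / tr))
    total_kept = sum(s.n_kept for s in scans)
    if total_kept < budget:
        raise ExclusionError(f"insufficient frames: {total_kept} kept < budget {budget}")

    if equal_split:
        types = sorted({s.scan_type for s in scans})
        quota = budget // len(types)
        taken = []
        leftovers = []
        for t in types:
            idx = [i for i, s in enumerate(scans) if s.scan_type == t]
            pool = _ordered_frame_pool(scans, idx, lr_first)
            taken.append(pool[:quota])
            leftovers.append(pool[quota:])
        chosen = np.concatenate(taken)
        shortfall = budget - chosen.shape[0]
        if shortfall > 0:
            remaining = np.concatenate(leftovers)
            rng = np.random.default_rng(seed)
            pick = rng.choice(remaining.shape[0], size=shortfall, replace=False)
            chosen = np.concatenate([chosen, remaining[pick]])
    else:
        pool = _ordered_frame_pool(scans, range(len(scans)), lr_first)
        chosen = pool[:budget]

    rows = []
    blocks = []
    for i in np.unique(chosen[:, 0]):
        frames = np.sort(chosen[chosen[:, 0] == i, 1])
        blocks.append(scans[i].series[frames])
        rows.append(
            {
                "scan_index": int(i),
                "scan_type": scans[i].scan_type,
                "phase_label": scans[i].phase_label,
                "session": scans[i].session,
                "n_frames": int(frames.size),
            }
        )
    series = np.vstack(blocks)
    assert series.shape[0] == budget
    return series, pd.DataFrame(rows)


def connectivity_matrix(series: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix of a frames x regions series.

    Zero-variance regions trigger a warning; their edges are returned as NaN
    (the diagonal stays 1).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    sd = series.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(series.T)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance region(s); edges set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        mat[degenerate, :] = np.nan
        mat[:, degenerate] = np.nan
    np.fill_diagonal(mat, 1.0)
    return (mat + mat.T) / 2.0


def n_edges(n_regions: int) -> int:
    """Number of unique edges R*(R-1)/2 of an R-region parcellation."""
    return n_regions * (n_regions - 1) // 2


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    if n_regions not in _TRIU_CACHE:
        _TRIU_CACHE[n_regions] = np.triu_indices(n_regions, k=1)
    return _TRIU_CACHE[n_regions]


def vectorize_edges(matrix: np.ndarray) -> np.ndarray:
    """Canonical upper-triangle vectorization (row-major, i < j)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    return matrix[_triu(matrix.shape[0])]


def unvectorize_edges(vector: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; the diagonal is set to 1."""
    vector = np.asarray(vector)
    if vector.shape != (n_edges(n_regions),):
        raise ValueError(f"expected {n_edges(n_regions)} edges for R={n_regions}")
    mat = np.zeros((n_regions, n_regions), dtype=vector.dtype)
    mat[_triu(n_regions)] = vector
    mat = mat + mat.T
    np.fill_diagonal(mat, 1.0)
    return mat
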