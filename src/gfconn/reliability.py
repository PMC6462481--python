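"""Edge-wise test-retest reliability: ICC(3,1), bins, summaries, sweeps.

ICC(3,1) is the two-way mixed-effects, consistency, single-measurement
intraclass correlation: with k sessions and the two-way ANOVA without
interaction, ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error).
It indexes how well a single session's edge estimate ranks subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import connectivity_matrix, select_timepoints, vectorize_edges

__all__ = [
    "ICCMap",
    "icc_3_1",
    "classify_icc",
    "bin_fractions",
    "network_summary",
    "compare_icc_maps",
    "PairedComparison",
    "reliability_sweep",
    "predicted_mean_icc",
    "ICC_BINS",
]

#: Left-closed reliability bins: [0, .4) poor, [.4, .6) moderate,
#: [.6, .75) good, [.75, 1] excellent; negative values clamp to poor.
ICC_BINS = ("poor", "moderate", "good", "excellent")
_BIN_EDGES = (0.4, 0.6, 0.75)


@dataclass
class ICCMap:
    """Per-edge ICC values plus the design metadata they came from."""

    icc: np.ndarray
    n_subjects: int
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.icc.size

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.icc).sum())

    def bin_counts(self) -> dict[str, int]:
        labels = classify_icc(self.icc)
        return {b: int((labels == b).sum()) for b in ICC_BINS}


def _icc31_columns(y: np.ndarray) -> np.ndarray:
    """Vectorized ICC(3,1) over the last axis of (n, k, E) data."""
    n, k, _ = y.shape
    grand = y.mean(axis=(0, 1))
    rowm = y.mean(axis=1)
    colm = y.mean(axis=0)
    sst = ((y - grand) ** 2).sum(axis=(0, 1))
    ssr = k * ((rowm - grand) ** 2).sum(axis=0)
    ssc = n * ((colm - grand) ** 2).sum(axis=0)
    sse = np.clip(sst - ssr - ssc, 0.0, None)
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    icc[denom <= 0] = np.nan
    return icc


def icc_3_1(test: np.ndarray, retest: np.ndarray) -> ICCMap:
    """ICC(3,1) per edge between test and retest subject x edge tables.

    Edges with missing values in either session are handled by pairwise
    deletion (subjects with a NaN at that edge are dropped for that edge);
    edges left with fewer than 3 subjects, or with no variance at all, are
    returned as NaN.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape:
        raise ValueError("test and retest must have identical subjects x edges shape")
    n = test.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    y = np.stack([test, retest], axis=1)  # (n, 2, E)
    finite = np.isfinite(y).all(axis=1)  # (n, E)
    icc = np.full(test.shape[1], np.nan)
    clean_cols = finite.all(axis=0)
    if clean_cols.any():
        icc[clean_cols] = _icc31_columns(y[:, :, clean_cols])
    for e in np.flatnonzero(~clean_cols):
        rows = finite[:, e]
        if rows.sum() >= 3:
            icc[e] = _icc31_columns(y[rows][:, :, [e]])[0]
    return ICCMap(icc=icc, n_subjects=n)


def classify_icc(icc: np.ndarray) -> np.ndarray:
    """Assign each finite ICC to poor/moderate/good/excellent (left-closed
    bins; negatives clamp to poor). NaNs map to the empty string."""
    icc = np.asarray(icc, dtype=float)
    out = np.full(icc.shape, "", dtype=object)
    finite = np.isfinite(icc)
    v = np.clip(icc[finite], 0.0, 1.0)
    idx = np.searchsorted(_BIN_EDGES, v, side="right")
    out[finite] = np.array(ICC_BINS, dtype=object)[idx]
    return out


def bin_fractions(icc: np.ndarray) -> dict[str, float]:
    """Fraction of non-missing edges per reliability bin (sums to 1)."""
    labels = classify_icc(icc)
    m = int((labels != "").sum())
    if m == 0:
        return {b: np.nan for b in ICC_BINS}
    return {b: float((labels == b).sum()) / m for b in ICC_BINS}


def network_summary(
    icc: np.ndarray,
    node_labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ICC over within-network edges, per network, with a seeded
    bootstrap CI over edges. Networks with fewer than 2 nodes are reported as
    missing."""
    icc = np.asarray(icc, dtype=float)
    node_labels = np.asarray(node_labels)
    r = node_labels.size
    if icc.size != r * (r - 1) // 2:
        raise ValueError("labels must cover all nodes of the edge set")
    iu, ju = np.triu_indices(r, k=1)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    rows = []
    for net in sorted(set(node_labels.tolist())):
        in_net = node_labels == net
        if in_net.sum() < 2:
            rows.append({"network": net, "n_edges": 0, "mean_icc": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        edge_sel = in_net[iu] & in_net[ju]
        vals = icc[edge_sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append({"network": net, "n_edges": 0, "mean_icc": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        rows.append(
            {
                "network": net,
                "n_edges": int(vals.size),
                "mean_icc": float(vals.mean()),
                "ci_lo": float(np.quantile(boots, alpha)),
                "ci_hi": float(np.quantile(boots, 1.0 - alpha)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedComparison:
    t: float
    df: int
    p: float
    mean_diff: float


def compare_icc_maps(icc_a: np.ndarray, icc_b: np.ndarray) -> PairedComparison:
    """Paired t-test over the shared non-missing edges of two ICC maps."""
    a = np.asarray(getattr(icc_a, "icc", icc_a), dtype=float)
    b = np.asarray(getattr(icc_b, "icc", icc_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("ICC maps must share an edge set")
    ok = np.isfinite(a) & np.isfinite(b)
    m = int(ok.sum())
    if m < 3:
        raise ValueError("fewer than 3 shared edges")
    res = stats.ttest_rel(a[ok], b[ok])
    return PairedComparison(
        t=float(res.statistic), df=m - 1, p=float(res.pvalue),
        mean_diff=float(np.mean(a[ok] - b[ok])),
    )


def predicted_mean_icc(
    sigma2_between,
    session_noise_var: float,
    n_frames: int,
    scan_weights=None,
) -> float:
    """Closed-form attenuation prediction for the mean edge ICC.

    On the Fisher-z scale a session's edge estimate is the trait value plus a
    per-scan state fluctuation (variance ``session_noise_var``) plus sampling
    noise with variance 1/(T-3). When a budget of T frames spans several
    scans with frame shares w_s, the state fluctuations average and
    contribute sum(w_s^2) * session_noise_var. The ratio
    sigma2_B / (sigma2_B + sigma2_W) then predicts the ICC of each edge; the
    per-edge tanh scale factor (1 - rho^2)^2 multiplies numerator and
    denominator alike and cancels.
    """
    s2b = np.atleast_1d(np.asarray(sigma2_between, dtype=float))
    w2 = 1.0 if scan_weights is None else float(np.sum(np.square(scan_weights)))
    s2w = session_noise_var * w2 + 1.0 / (n_frames - 3)
    return float(np.mean(s2b / (s2b + s2w)))


_COMPOSITIONS = ("rest_only", "gfc_equal", "task_only")


def _composition_scans(scans, composition: str):
    if composition == "rest_only":
        return [s for s in scans if s.scan_type == "rest"], False
    if composition == "task_only":
        return [s for s in scans if s.scan_type != "rest"], True
    if composition == "gfc_equal":
        return list(scans), True
    raise ValueError(f"unknown composition {composition!r}; expected one of {_COMPOSITIONS}")


def reliability_sweep(
    scans_by_subject: dict[str, dict[int, list]],
    budgets_minutes,
    composition: str = "rest_only",
    seed: int = 0,
    node_labels=None,
    fisher_z: bool = False,
) -> tuple[pd.DataFrame, dict[float, ICCMap]]:
    """Scan-length sweep: per budget, build mirrored test/retest edge vectors
    under the requested composition and compute the edge-wise ICC map.

    Subjects that cannot satisfy the largest budget (insufficient post-censor
    frames in either session) are excluded from *all* cells so every row of
    the sweep describes the same subject set; the exclusion count is recorded
    in the table. ICCs are computed on raw Pearson r by default;
    ``fisher_z`` switches the edge values to the arctanh scale first.
    Returns ``(tidy table, {budget: ICCMap})``.
    """
    budgets = sorted(budgets_minutes)
    sessions = (1, 2)
    subjects = sorted(scans_by_subject)
    usable = []
    n_excluded = 0
    max_budget = budgets[-1]
    for sid in subjects:
        ok = True
        for sess in sessions:
            sel, _ = _composition_scans(scans_by_subject[sid][sess], composition)
            tr = sel[0].tr_seconds if sel else 1.0
            need = int(round(max_budget * 60.0 / tr))
            if not sel or sum(s.n_kept for s in sel) < need:
                ok = False
        if ok:
            usable.append(sid)
        else:
            n_excluded += 1
    if not usable:
        raise RuntimeError("no subject satisfies the largest budget")

    rows = []
    maps: dict[float, ICCMap] = {}
    for budget in budgets:
        vecs = {sess: [] for sess in sessions}
        for si, sid in enumerate(usable):
            for sess in sessions:
                sel, equal = _composition_scans(scans_by_subject[sid][sess], composition)
                series, _ = select_timepoints(
                    sel, budget, equal_split=equal, lr_first=True,
                    seed=int(np.random.default_rng([seed, si, sess, int(budget * 60)])
                             .integers(2**31)),
                )
                vec = vectorize_edges(connectivity_matrix(series))
                if fisher_z:
                    vec = np.arctanh(np.clip(vec, -1 + 1e-12, 1 - 1e-12))
                vecs[sess].append(vec)
        icc_map = icc_3_1(np.vstack(vecs[1]), np.vstack(vecs[2]))
        icc_map.meta.update({"budget_minutes": budget, "composition": composition})
        maps[budget] = icc_map
        row = {
            "budget_minutes": budget,
            "composition": composition,
            "n_subjects": len(usable),
            "n_excluded": n_excluded,
            "mean_icc": float(np.nanmean(icc_map.icc)),
        }
        row.update({f"frac_{k}": v for k, v in bin_fractions(icc_map.icc).items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    if node_labels is not None:
        net_tables = []
        for budget, m in maps.items():
            nt = network_summary(m.icc, node_labels, seed=seed)
            nt.insert(0, "budget_minutes", budget)
            net_tables.append(nt)
        table.attrs["network_summary"] = pd.concat(net_tables, ignore_index=True)
    return table, maps
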