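"""Config-driven synthetic experiments.

Three experiment families, each a scaled-down analogue of a full twin-imaging
study run end to end on the synthetic generator:

* reliability sweep — mirrored test/retest sessions, edge-wise ICC across
  scan-length budgets and data compositions;
* heritability vs scan length — ACTE fits of observed edges as the
  per-subject frame budget grows;
* prediction — CPM trained on one cohort and transferred to an independent
  cohort drawn from the same ground truth, comparing a short rest-only
  composition against aggregated task+rest (GFC) data.

Every experiment is a pure function of its config (all randomness flows from
the config seeds) and returns tidy tables plus a provenance block.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .heritability import build_design, fit_acte, heritable_fraction, significant_a
from .prediction import bootstrap_ci, fdr_bh, fit_cpm, loocv_cpm, steiger_z, transfer_cpm
from .reliability import _composition_scans, reliability_sweep
from .synthetic import (
    Cohort,
    ScanSpec,
    default_ground_truth,
    generate_behavior,
    generate_cohort,
    generate_scan,
    generate_trait_connectomes,
    simulate_behavior,
)
from .timeseries import connectivity_matrix, select_timepoints, vectorize_edges

__all__ = [
    "ExperimentConfig",
    "default_config",
    "default_scan_menu",
    "default_network_labels",
    "simulate_dataset",
    "run_reliability_experiment",
    "run_heritability_experiment",
    "run_prediction_experiment",
]

#: HCP-shaped scan menu at reduced scale (TR 2 s, quarter-length task scans):
#: 4 rest + 7 task scans per session, LR/RL alternating.
_DEFAULT_MENU = [
    ("rest", 330, "LR"),
    ("rest", 330, "RL"),
    ("rest", 330, "LR"),
    ("rest", 330, "RL"),
    ("wm", 203, "LR"),
    ("gambling", 127, "RL"),
    ("motor", 142, "LR"),
    ("language", 158, "RL"),
    ("social", 137, "LR"),
    ("relational", 116, "RL"),
    ("emotion", 88, "LR"),
]


def default_scan_menu() -> list[dict]:
    return [{"scan_type": t, "n_frames": n, "phase_label": p} for t, n, p in _DEFAULT_MENU]


def default_network_labels(n_regions: int = 44) -> np.ndarray:
    """Assign regions to 7 canonical networks (contiguous blocks)."""
    names = ["visual", "somatomotor", "dorsal_attention", "ventral_attention",
             "limbic", "frontoparietal", "default"]
    sizes = np.full(7, n_regions // 7)
    sizes[: n_regions % 7] += 1
    return np.repeat(names, sizes)


@dataclass
class ExperimentConfig:
    """Generator + analysis settings for one experiment run.

    ``budgets_minutes`` are post-censoring minutes (frames * TR / 60).
    """

    seed: int = 0
    n_regions: int = 44
    tr_seconds: float = 2.0
    censor_frac: float = 0.05
    # cohort
    n_mz: int = 40
    n_dz: int = 30
    n_sib: int = 50
    extra_sib_prob: float = 0.3
    age_range: tuple[float, float] = (25.0, 35.0)
    # analysis
    budgets_minutes: list[float] = field(default_factory=lambda: [5.0, 10.0, 20.0, 40.0])
    compositions: list[str] = field(default_factory=lambda: ["rest_only", "gfc_equal"])
    scan_menu: list[dict] = field(default_factory=default_scan_menu)
    n_fit_edges: int = 30
    gsr: bool = False
    task_regression: bool = False
    # behavior
    n_signal_edges: int = 3
    target_r2: float = 0.10
    # prediction experiment
    n_train: int = 400
    n_test: int = 600
    rest_minutes: float = 5.0
    gfc_minutes: float = 40.0
    ci_level: float = 0.95

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["age_range"] = [float(v) for v in d["age_range"]]
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        elif isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def default_config(**overrides) -> ExperimentConfig:
    return ExperimentConfig(**overrides)


def _provenance(config: ExperimentConfig, experiment: str) -> dict:
    return {
        "experiment": experiment,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "gfconn_version": __version__,
        "numpy_version": np.__version__,
    }


def _menu_specs(config: ExperimentConfig, session: int, types=None) -> list[ScanSpec]:
    specs = []
    for entry in config.scan_menu:
        if types is not None and entry["scan_type"] not in types:
            continue
        specs.append(
            ScanSpec(
                scan_type=entry["scan_type"],
                n_frames=entry["n_frames"],
                tr_seconds=config.tr_seconds,
                phase_label=entry.get("phase_label", "NA"),
                session=session,
            )
        )
    return specs


def simulate_dataset(
    cohort: Cohort,
    gt,
    config: ExperimentConfig,
    sessions=(1, 2),
    types=None,
    subjects=None,
    seed: int = 0,
):
    """Yield ``(subject_id, {session: [scans]})`` one subject at a time so
    callers can stream connectome computation without holding every series.
    ``subjects`` restricts scan generation to a subset of the cohort (traits
    are still drawn for everyone, keeping family structure intact)."""
    trait = generate_trait_connectomes(cohort, gt, seed=seed)
    wanted = None if subjects is None else set(subjects)
    for si, sid in enumerate(cohort.subject_ids):
        if wanted is not None and sid not in wanted:
            continue
        per_session = {}
        for sess in sessions:
            scans = []
            for k, spec in enumerate(_menu_specs(config, sess, types)):
                scan_seed = int(
                    np.random.default_rng([seed, 1 + si, sess, k]).integers(2**31)
                )
                scans.append(
                    generate_scan(sid, trait, spec, gt, seed=scan_seed,
                                  censor_frac=config.censor_frac)
                )
            per_session[sess] = scans
        yield sid, per_session


def _block_events(n_frames: int, tr: float, on_s: float = 20.0, period_s: float = 40.0):
    """Generic block task design: 20 s on / 20 s off from 10 s onward."""
    return [(float(t), on_s, "task")
            for t in np.arange(10.0, n_frames * tr - on_s, period_s)]


def _maybe_clean(scans, config: ExperimentConfig):
    """Apply the configured cleaning switches (global-signal regression,
    task-structure regression with a generic block design) to each scan."""
    if not (config.gsr or config.task_regression):
        return scans
    from .timeseries import build_nuisance_matrix, build_task_regressor, clean_timeseries

    out = []
    for s in scans:
        task_cols = None
        if config.task_regression and s.scan_type != "rest":
            task_cols, _ = build_task_regressor(
                _block_events(s.n_frames, s.tr_seconds), s.n_frames, s.tr_seconds
            )
        nuis = build_nuisance_matrix(s, use_global=config.gsr,
                                     task_regressors=task_cols)
        out.append(clean_timeseries(s, nuis))
    return out


def _unrelated_subjects(n_subjects: int, config: ExperimentConfig, seed: int):
    """A cohort of two-member sibling families plus the ids of one member per
    family — an unrelated analysis set of size ``n_subjects``."""
    cohort = generate_cohort(0, 0, n_subjects, extra_sib_prob=0.0,
                             age_range=config.age_range, seed=seed)
    keep = sorted(members[0].subject_id for members in cohort.families().values())
    return cohort, keep


def run_reliability_experiment(config: ExperimentConfig, n_subjects: int = 60):
    """Test-retest ICC across budgets and compositions on one subject set.

    Returns {"table", "network_summary", "provenance"}; the table carries a
    monotone-trend flag per composition.
    """
    gt = default_ground_truth(config.n_regions, seed=config.seed)
    cohort, keep_ids = _unrelated_subjects(n_subjects, config, config.seed)
    scans_by_subject = {
        sid: {sess: _maybe_clean(scans, config) for sess, scans in per_session.items()}
        for sid, per_session in simulate_dataset(cohort, gt, config,
                                                 subjects=keep_ids, seed=config.seed)
    }
    labels = default_network_labels(config.n_regions)
    tables = []
    networks = []
    for comp in config.compositions:
        table, _ = reliability_sweep(
            scans_by_subject, config.budgets_minutes, composition=comp,
            seed=config.seed, node_labels=labels,
        )
        table["monotone_nondecreasing"] = bool(
            np.all(np.diff(table.sort_values("budget_minutes")["mean_icc"]) >= -0.02)
        )
        net = table.attrs.pop("network_summary", None)
        if net is not None:
            net.insert(1, "composition", comp)
            networks.append(net)
        tables.append(table)
    out = pd.concat(tables, ignore_index=True)
    return {
        "table": out,
        "network_summary": pd.concat([n for n in networks if n is not None],
                                     ignore_index=True),
        "provenance": _provenance(config, "reliability"),
    }


def _edge_tables(cohort, gt, config, cells, edge_idx, seed, subjects=None):
    """Observed edge values (subjects x selected edges) for each requested
    ``(composition, budget_minutes)`` cell, streaming one subject at a time
    over a single simulated session shared by all cells."""
    cells = list(cells)
    ids = list(subjects) if subjects is not None else cohort.subject_ids
    out = {cell: np.empty((len(ids), len(edge_idx))) for cell in cells}
    need_all = any(comp != "rest_only" for comp, _ in cells)
    types = None if need_all else {"rest"}
    for i, (sid, per_session) in enumerate(
        simulate_dataset(cohort, gt, config, sessions=(1,), types=types,
                         subjects=ids, seed=seed)
    ):
        scans = _maybe_clean(per_session[1], config)
        for comp, b in cells:
            sel, equal = _composition_scans(scans, comp)
            series, _ = select_timepoints(
                sel, b, equal_split=equal, lr_first=True,
                seed=int(np.random.default_rng([seed, 2, i, int(b * 60)]).integers(2**31)),
            )
            out[(comp, b)][i] = vectorize_edges(connectivity_matrix(series))[edge_idx]
    return out, ids


def run_heritability_experiment(config: ExperimentConfig, compute_significance: bool = True):
    """ACTE components of observed edges per scan-length budget.

    Fits ``config.n_fit_edges`` randomly chosen edges (seeded) at each budget
    under the rest-only composition and summarizes mean standardized
    components plus the heritable-edge fraction.
    """
    gt = default_ground_truth(config.n_regions, seed=config.seed)
    cohort = generate_cohort(config.n_mz, config.n_dz, config.n_sib,
                             config.extra_sib_prob, config.age_range, seed=config.seed)
    if not any(s.role in ("MZ_twin", "DZ_twin") for s in cohort.subjects):
        raise ValueError("heritability experiment requires twins in the cohort")
    rng = np.random.default_rng(config.seed)
    edge_idx = np.sort(rng.choice(gt.n_edges, size=min(config.n_fit_edges, gt.n_edges),
                                  replace=False))
    cells = [("rest_only", b) for b in config.budgets_minutes]
    tables, _ = _edge_tables(cohort, gt, config, cells, edge_idx, seed=config.seed)
    design = build_design(cohort)
    rows = []
    for b in config.budgets_minutes:
        fits = []
        for j in range(len(edge_idx)):
            y = tables[("rest_only", b)][:, j]
            fit = fit_acte(y, design=design, seed=config.seed)
            if compute_significance and fit.converged:
                fit.significant_a = significant_a(fit, y, design, level=config.ci_level)
            fits.append(fit)
        conv = [f for f in fits if f.converged]
        frac = np.nan
        if compute_significance and conv:
            frac, _ = heritable_fraction(fits)
        rows.append(
            {
                "budget_minutes": b,
                "composition": "rest_only",
                "n_edges": len(edge_idx),
                "n_converged": len(conv),
                "mean_a2": float(np.mean([f.a2 for f in conv])) if conv else np.nan,
                "mean_c2": float(np.mean([f.c2 for f in conv])) if conv else np.nan,
                "mean_t2": float(np.mean([f.t2 for f in conv])) if conv else np.nan,
                "mean_e2": float(np.mean([f.e2 for f in conv])) if conv else np.nan,
                "heritable_fraction": frac,
            }
        )
    return {
        "table": pd.DataFrame(rows),
        "provenance": _provenance(config, "heritability"),
    }


def run_prediction_experiment(config: ExperimentConfig, full_metrics: bool = True):
    """Train CPMs on one cohort, transfer to an independent cohort.

    Compares a short rest-only composition against an aggregated task+rest
    (GFC) composition: LOO-CV in the training cohort, frozen-model transfer
    to the test cohort, Steiger's z on the transfer effect sizes, BH-FDR over
    the transfer p-values and bootstrap CIs. ``full_metrics=False`` skips the
    LOO-CV and bootstrap (for replicate loops that only need transfer
    effect sizes).
    """
    gt = default_ground_truth(config.n_regions, seed=config.seed)
    train, train_ids = _unrelated_subjects(config.n_train, config, config.seed + 1)
    test, test_ids = _unrelated_subjects(config.n_test, config, config.seed + 2)

    trait_a = generate_trait_connectomes(train, gt, seed=config.seed + 3)
    trait_b = generate_trait_connectomes(test, gt, seed=config.seed + 4)
    y_a_all, behavior = generate_behavior(train, trait_a, config.n_signal_edges,
                                          config.target_r2, seed=config.seed + 5)
    y_b_all = simulate_behavior(trait_b, behavior, seed=config.seed + 6)
    rows_a = [train.subject_ids.index(s) for s in train_ids]
    rows_b = [test.subject_ids.index(s) for s in test_ids]
    y_a = y_a_all[rows_a]
    y_b = y_b_all[rows_b]

    all_edges = np.arange(gt.n_edges)
    comps = {"rest_only": config.rest_minutes, "gfc_equal": config.gfc_minutes}
    cells = [(comp, minutes) for comp, minutes in comps.items()]
    xa_tables, _ = _edge_tables(train, gt, config, cells, all_edges,
                                seed=config.seed + 3, subjects=train_ids)
    xb_tables, _ = _edge_tables(test, gt, config, cells, all_edges,
                                seed=config.seed + 4, subjects=test_ids)
    rows = []
    transfer_preds = {}
    for comp, minutes in comps.items():
        x_a, x_b = xa_tables[(comp, minutes)], xb_tables[(comp, minutes)]
        model = fit_cpm(x_a, y_a)
        tr = transfer_cpm(model, x_b, y_b)
        transfer_preds[comp] = tr.predictions
        row = {
            "composition": comp,
            "budget_minutes": minutes,
            "transfer_rho": tr.rho,
            "transfer_rho2_pct": 100.0 * tr.rho2,
            "transfer_p": tr.p,
        }
        if full_metrics:
            loo = loocv_cpm(x_a, y_a)
            ci = bootstrap_ci(tr.predictions, y_b, n_boot=1000, level=config.ci_level,
                              seed=config.seed + 9)
            row.update(
                {
                    "loo_rho": loo.rho,
                    "loo_rho2_pct": 100.0 * loo.rho2,
                    "ci_rho2_lo_pct": 100.0 * ci["rho2"][0],
                    "ci_rho2_hi_pct": 100.0 * ci["rho2"][1],
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(table["transfer_p"].to_numpy(), q=0.05)
    table["transfer_q"] = p_adj
    table["fdr_significant"] = reject

    # Steiger comparison of the Spearman effect sizes (computed on ranks)
    from scipy.stats import pearsonr, rankdata

    ranks_y = rankdata(y_b)
    r1 = pearsonr(rankdata(transfer_preds["gfc_equal"]), ranks_y).statistic
    r2 = pearsonr(rankdata(transfer_preds["rest_only"]), ranks_y).statistic
    r12 = pearsonr(rankdata(transfer_preds["gfc_equal"]),
                   rankdata(transfer_preds["rest_only"])).statistic
    z, p = steiger_z(r1, r2, r12, len(ranks_y))
    comparison = pd.DataFrame(
        [{"contrast": "gfc_equal - rest_only", "steiger_z": z, "p": p}]
    )
    return {
        "table": table,
        "comparison": comparison,
        "provenance": _provenance(config, "prediction"),
    }
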