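"""Plain-text readers and writers.

Every artifact round-trips through tab-separated text: per-scan time series
(with a JSON metadata header line), pedigrees, phenotypes, connectivity
matrices, long-format edge vectors, and the ground-truth latent model (YAML).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import Cohort, GroundTruth, Subject
from .timeseries import ParcellatedScan, n_edges, vectorize_edges

__all__ = [
    "write_scan",
    "read_scan",
    "write_pedigree",
    "read_pedigree",
    "write_phenotype",
    "read_phenotype",
    "write_matrix",
    "read_matrix",
    "write_edge_vector",
    "read_edge_vector",
    "read_events",
    "write_events",
    "read_regressors",
    "write_ground_truth",
    "read_ground_truth",
]

_META_PREFIX = "# meta: "


def write_scan(scan: ParcellatedScan, path, region_labels=None) -> None:
    """Tab-separated series with one JSON header line of metadata
    (TR, scan type, session, phase, censor mask)."""
    path = Path(path)
    r = scan.n_regions
    labels = list(region_labels) if region_labels is not None else [f"R{i:03d}" for i in range(r)]
    meta = {
        "tr_seconds": scan.tr_seconds,
        "scan_type": scan.scan_type,
        "session": scan.session,
        "phase_label": scan.phase_label,
        "censored": np.flatnonzero(scan.censored).tolist(),
    }
    with path.open("w") as fh:
        fh.write(_META_PREFIX + json.dumps(meta) + "\n")
        fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, scan.series, fmt="%.10g", delimiter="\t")


def read_scan(path) -> ParcellatedScan:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith(_META_PREFIX):
            raise ValueError(f"{path} lacks the metadata header line")
        meta = json.loads(header[len(_META_PREFIX):])
        fh.readline()  # region labels
        series = np.loadtxt(fh, delimiter="\t", ndmin=2)
    censored = np.zeros(series.shape[0], dtype=bool)
    censored[meta["censored"]] = True
    return ParcellatedScan(
        series=series,
        tr_seconds=meta["tr_seconds"],
        scan_type=meta["scan_type"],
        session=meta["session"],
        phase_label=meta["phase_label"],
        censored=censored,
    )


def write_pedigree(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Cohort:
    df = pd.read_csv(path, sep="\t")
    subjects = [
        Subject(str(r.subject_id), str(r.family_id), str(r.role), float(r.age), int(r.sex))
        for r in df.itertuples()
    ]
    return Cohort(subjects)


def write_phenotype(subject_ids, values, path) -> None:
    pd.DataFrame({"subject_id": subject_ids, "value": values}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, path, region_labels=None) -> None:
    r = matrix.shape[0]
    labels = list(region_labels) if region_labels is not None else [f"R{i:03d}" for i in range(r)]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_edge_vector(vector: np.ndarray, n_regions: int, path) -> None:
    """Long format: node_i, node_j, value over the canonical upper triangle."""
    if vector.shape != (n_edges(n_regions),):
        raise ValueError("edge vector length does not match region count")
    iu, ju = np.triu_indices(n_regions, k=1)
    pd.DataFrame({"node_i": iu, "node_j": ju, "value": vector}).to_csv(
        path, sep="\t", index=False
    )


def read_edge_vector(path) -> tuple[np.ndarray, int]:
    df = pd.read_csv(path, sep="\t")
    n_regions = int(df[["node_i", "node_j"]].to_numpy().max()) + 1
    mat = np.zeros((n_regions, n_regions))
    mat[df.node_i, df.node_j] = df.value
    return vectorize_edges(mat + mat.T), n_regions


def read_events(path) -> list[tuple[float, float, str]]:
    """Three-column event table (onset_s, duration_s, condition), the common
    convention for task timing files."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    return [(float(r[cols[0]]), float(r[cols[1]]), str(r[cols[2]]))
            for _, r in df.iterrows()]


def write_events(events, path) -> None:
    pd.DataFrame(events, columns=["onset", "duration", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def read_regressors(path) -> np.ndarray:
    """Frames x columns regressor table (motion parameters, tissue
    components, ...), whitespace- or tab-delimited, optional header."""
    try:
        return np.loadtxt(path, ndmin=2)
    except ValueError:
        return pd.read_csv(path, sep=r"\s+", engine="python").to_numpy(dtype=float)


def write_ground_truth(gt: GroundTruth, path) -> None:
    d = {
        "n_regions": gt.n_regions,
        "mean_profile": gt.mean_profile.tolist(),
        "var_a": gt.var_a.tolist(),
        "var_c": gt.var_c.tolist(),
        "var_t": gt.var_t.tolist(),
        "var_e": gt.var_e.tolist(),
        "state_offsets": {k: v.tolist() for k, v in gt.state_offsets.items()},
        "session_noise_sd": float(gt.session_noise_sd),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return GroundTruth(
        n_regions=d["n_regions"],
        mean_profile=np.array(d["mean_profile"]),
        var_a=np.array(d["var_a"]),
        var_c=np.array(d["var_c"]),
        var_t=np.array(d["var_t"]),
        var_e=np.array(d["var_e"]),
        state_offsets={k: np.array(v) for k, v in d["state_offsets"].items()},
        session_noise_sd=d["session_noise_sd"],
    )
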