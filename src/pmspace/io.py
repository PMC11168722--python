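"""Plain-text file formats used across the pipeline.

Matrices (structural connectivity, BOLD) travel as headerless tab-delimited
text; tables (labels, PMS, test results, centroids) as headered CSV; run
metadata as JSON manifests.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .leida import PMS, BoldTimeSeries, ClusterModel

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_bold",
    "read_bold",
    "read_bold_glob",
    "write_labels",
    "read_labels",
    "write_centroids",
    "write_assignments",
    "write_pms",
    "write_manifest",
    "read_manifest",
]

_BOLD_NAME = re.compile(r"bold_(?P<subject>[^_]+)_(?P<condition>[^.]+)\.tsv$")


def write_matrix_tsv(path: str | Path, m: np.ndarray) -> None:
    np.savetxt(path, np.asarray(m, float), delimiter="\t", fmt="%.10g")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_bold(directory: str | Path, ts: BoldTimeSeries) -> Path:
    """One TSV per subject-condition: rows = parcels, columns = TRs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"bold_{ts.subject_id}_{ts.condition}.tsv"
    write_matrix_tsv(path, ts.data)
    return path


def read_bold(path: str | Path, tr: float) -> BoldTimeSeries:
    path = Path(path)
    m = _BOLD_NAME.search(path.name)
    subject, condition = (m.group("subject"), m.group("condition")) if m else ("", "")
    return BoldTimeSeries(read_matrix_tsv(path), tr, subject, condition)


def read_bold_glob(pattern: str, tr: float) -> dict[tuple[str, str], BoldTimeSeries]:
    paths = sorted(Path().glob(pattern)) if not Path(pattern).is_absolute() else sorted(
        Path(pattern).parent.glob(Path(pattern).name)
    )
    if not paths:
        raise FileNotFoundError(f"no BOLD files match {pattern!r}")
    out = {}
    for p in paths:
        ts = read_bold(p, tr)
        out[(ts.subject_id, ts.condition)] = ts
    return out


def write_labels(path: str | Path, labels: pd.DataFrame) -> None:
    labels.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label table not found: {path}")
    return pd.read_csv(path)


def write_centroids(path: str | Path, model: ClusterModel) -> None:
    pd.DataFrame(model.centroids).to_csv(path, index=False)


def write_assignments(path: str | Path, model: ClusterModel) -> None:
    model.assignments.to_csv(path, index=False)


def write_pms(path: str | Path, pms_list: Iterable[PMS]) -> None:
    rows = []
    for pms in pms_list:
        for i, p in enumerate(pms.probabilities):
            rows.append(
                {
                    "condition": pms.condition,
                    "cluster": i,
                    "probability": p,
                    "n_obs": pms.n_observations,
                    "kind": pms.kind,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
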