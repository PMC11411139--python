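"""Plain-text file formats: TSV time series, CSV matrices/masks, YAML config.

Conventions:

* regional time series — one TSV per subject-session, T rows x R columns,
  header row = region ids, filename ``{subject}_{session}.tsv`` with session
  in {full, test, retest}; an all-NaN column marks a missing ROI;
* square matrices (FC, ICC, identifiability) — CSV with region-id (or
  subject-id) header row and index column, full decimal precision so a
  write/read cycle is value-exact;
* boolean masks — same layout with 0/1 entries;
* configuration — YAML (JSON is valid YAML and therefore also accepted).

Files carry region ids, never bare indices; readers validate the header
against an expected ordering and either reorder or fail, per caller choice.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .connectome import Parcellation, QCTrace, RegionalTimeSeries

SESSIONS = ("full", "test", "retest")


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


def write_timeseries(path: str | Path, ts: RegionalTimeSeries) -> Path:
    path = Path(path)
    pd.DataFrame(ts.data, columns=list(ts.region_ids)).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_timeseries(
    path: str | Path,
    subject_id: str | None = None,
    session: str | None = None,
    sampling_interval: float = 2.0,
) -> RegionalTimeSeries:
    path = Path(path)
    if subject_id is None or session is None:
        stem_subject, stem_session = parse_timeseries_name(path)
        subject_id = subject_id or stem_subject
        session = session or stem_session
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.isna().any(axis=None):
        partial = frame.columns[frame.isna().any() & ~frame.isna().all()]
        if len(partial):
            raise ValueError(
                f"{path.name}: ragged/partially missing column(s) {list(partial)}"
            )
    return RegionalTimeSeries(
        subject_id=subject_id,
        session=session,
        data=frame.to_numpy(dtype=float),
        region_ids=tuple(frame.columns),
        sampling_interval=sampling_interval,
    )


def parse_timeseries_name(path: Path) -> tuple[str, str]:
    """``{subject}_{session}`` stem -> (subject, session)."""
    stem = path.stem
    if "_" not in stem:
        raise ValueError(f"cannot parse subject/session from {path.name!r}")
    subject, session = stem.rsplit("_", 1)
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r} in {path.name!r}")
    return subject, session


def read_timeseries_dir(
    directory: str | Path,
    parcellation: Parcellation | None = None,
    sampling_interval: float = 2.0,
) -> list[RegionalTimeSeries]:
    """All ``*_{full,test,retest}.tsv`` series in a directory, sorted by name.

    When a parcellation is given every file's header must match its region
    ids exactly (order included).
    """
    directory = Path(directory)
    out = []
    for path in sorted(directory.glob("*.tsv")):
        try:
            parse_timeseries_name(path)
        except ValueError:
            continue
        ts = read_timeseries(path, sampling_interval=sampling_interval)
        if parcellation is not None and ts.region_ids != parcellation.region_ids:
            raise ValueError(
                f"{path.name}: header does not match the parcellation's region ids"
            )
        out.append(ts)
    if not out:
        raise FileNotFoundError(f"no time-series TSVs found under {directory}")
    return out


# ---------------------------------------------------------------------------
# matrices and masks
# ---------------------------------------------------------------------------


def write_matrix(path: str | Path, matrix: np.ndarray, labels: Sequence[str]) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path
    )
    return path


def read_matrix(
    path: str | Path,
    expect_labels: Sequence[str] | None = None,
    reorder: bool = False,
    expect_symmetric: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square CSV matrix.

    With ``expect_labels`` the header must match; ``reorder=True`` permutes
    rows/columns into the expected order instead of failing on a permuted
    header.  ``expect_symmetric=True`` validates symmetry to 1e-10.
    """
    frame = pd.read_csv(Path(path), index_col=0, float_precision="round_trip")
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    if expect_labels is not None and list(frame.columns) != list(expect_labels):
        if reorder and set(frame.columns) == set(expect_labels):
            frame = frame.loc[list(expect_labels), list(expect_labels)]
        else:
            raise ValueError(f"{path}: labels do not match the expected ordering")
    m = frame.to_numpy(dtype=float)
    if expect_symmetric and not np.allclose(
        np.nan_to_num(m), np.nan_to_num(m.T), atol=1e-10, rtol=0.0
    ):
        raise ValueError(f"{path}: matrix declared symmetric but is not")
    return m, list(frame.columns)


def write_mask(path: str | Path, mask: np.ndarray, labels: Sequence[str]) -> Path:
    return write_matrix(path, np.asarray(mask, dtype=int), labels)


def read_mask(path: str | Path, **kwargs) -> tuple[np.ndarray, list[str]]:
    m, labels = read_matrix(path, **kwargs)
    return m.astype(bool), labels


# ---------------------------------------------------------------------------
# parcellation, metadata, QC traces
# ---------------------------------------------------------------------------


def write_parcellation(path: str | Path, parcellation: Parcellation) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"region_id": parcellation.region_ids, "network": parcellation.networks}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_parcellation(path: str | Path) -> Parcellation:
    frame = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"region_id", "network"} <= set(frame.columns):
        raise ValueError("parcellation TSV needs 'region_id' and 'network' columns")
    return Parcellation(
        region_ids=tuple(frame["region_id"]), networks=tuple(frame["network"])
    )


def write_metadata(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", float_precision="round_trip")


def write_qc_trace(path: str | Path, trace: QCTrace) -> Path:
    path = Path(path)
    pd.DataFrame({"fd": trace.fd, "dvars": trace.dvars, "sd": trace.sd}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_qc_trace(path: str | Path, subject_id: str | None = None) -> QCTrace:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return QCTrace(
        subject_id=subject_id or path.stem.removesuffix("_qc"),
        fd=frame["fd"].to_numpy(),
        dvars=frame["dvars"].to_numpy(),
        sd=frame["sd"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# config / results
# ---------------------------------------------------------------------------


def write_yaml(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
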