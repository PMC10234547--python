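"""Event-record dataset I/O (NONMEM-convention CSV) and YAML model configs.

The on-disk format is a comma-separated table with mandatory columns
``ID, TIME, AMT, DV, EVID, MDV`` plus the covariates
``WT, SEX, AGE, ALT, AST, SCR, INF``.  Dose rows have ``EVID=1`` and carry
``AMT`` (ug); observation rows have ``EVID=0`` and carry ``DV`` (ng/mL).
Rows with ``MDV=1`` (e.g. pre-dose samples of treatment-naive subjects) are
parsed and preserved but excluded from fitting.  Amounts are in micrograms
and volumes in litres throughout, so amount/volume is ng/mL with no
conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .population import PopulationModel, model_from_dict, model_to_dict

MANDATORY_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV")
COVARIATE_COLUMNS = ("WT", "SEX", "AGE", "ALT", "AST", "SCR", "INF")

#: Decimal places used when writing datasets; the read/write round trip is
#: exact for values stored at this precision.
_WRITE_PRECISION = 6


class DatasetFormatError(ValueError):
    """The file does not conform to the event-record dialect."""


class DatasetValidationError(ValueError):
    """The parsed dataset violates a structural invariant."""


@dataclass
class SubjectRecord:
    """One subject: dose events, fit-eligible observations, covariates.

    ``excluded`` holds (time, DV) pairs of parsed MDV=1 rows (pre-dose
    anchors, below-LLOQ flags); they are carried for round-trip fidelity but
    never fitted.
    """

    subject_id: str
    dose_events: List[Tuple[float, float]]
    observations: List[Tuple[float, float]]
    covariates: dict
    excluded: List[Tuple[float, float]] = field(default_factory=list)

    @property
    def obs_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.observations], dtype=float)

    @property
    def obs_values(self) -> np.ndarray:
        return np.array([v for _, v in self.observations], dtype=float)


@dataclass
class Dataset:
    subjects: List[SubjectRecord]
    lloq: float = 0.1
    name: str = ""

    @property
    def n_observations(self) -> int:
        """Fit-eligible observations (EVID=0, MDV=0 rows)."""
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_samples(self) -> int:
        """All parsed sample rows, including MDV=1 (e.g. pre-dose) records."""
        return sum(len(s.observations) + len(s.excluded) for s in self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def validate_dataset(ds: Dataset) -> List[str]:
    """Invariant check; returns one human-readable finding per violation."""
    findings: List[str] = []
    seen = set()
    if ds.lloq <= 0.0:
        findings.append(f"dataset: LLOQ must be positive, got {ds.lloq}")
    for s in ds.subjects:
        sid = s.subject_id
        if sid in seen:
            findings.append(f"subject {sid}: duplicate subject_id")
        seen.add(sid)
        for label, events in (("dose", s.dose_events), ("observation", s.observations)):
            times = [t for t, _ in events]
            if any(t < 0 for t in times):
                findings.append(f"subject {sid}: negative {label} time")
            if times != sorted(times):
                findings.append(f"subject {sid}: {label} times not non-decreasing")
        if not s.dose_events:
            if s.observations:
                findings.append(f"subject {sid}: observations but no dose event")
        else:
            first_dose = min(t for t, _ in s.dose_events)
            post = [t for t, _ in s.observations if t > first_dose]
            if s.observations and not post:
                findings.append(f"subject {sid}: no post-dose observation")
        for t, a in s.dose_events:
            if a <= 0:
                findings.append(f"subject {sid}: non-positive dose amount {a} at t={t}")
        for t, dv in s.observations:
            if dv < ds.lloq:
                findings.append(
                    f"subject {sid}: observation {dv} ng/mL at t={t} h below LLOQ {ds.lloq}"
                )
        cov = s.covariates
        if "WT" in cov and not cov["WT"] > 0:
            findings.append(f"subject {sid}: WT must be positive, got {cov['WT']}")
        for cat in ("SEX", "INF"):
            if cat in cov and cov[cat] not in (0, 1, 0.0, 1.0):
                findings.append(f"subject {sid}: {cat} must be 0 or 1, got {cov[cat]}")
    return findings


def read_dataset(
    path, column_map: Optional[Mapping[str, str]] = None, lloq: float = 0.1, name: str = ""
) -> Dataset:
    """Parse an event-record CSV into a validated :class:`Dataset`.

    ``column_map`` maps canonical names (e.g. ``"DV"``) to the file's actual
    header names when they differ.
    """
    try:
        raw = pd.read_csv(path, dtype=str, sep=",", skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise DatasetFormatError(f"could not parse {path}: {exc}") from exc

    column_map = dict(column_map or {})
    # file header name -> canonical name
    rename = {
        column_map.get(c, c): c
        for c in MANDATORY_COLUMNS + COVARIATE_COLUMNS
        if column_map.get(c, c) in raw.columns
    }
    raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise DatasetFormatError(f"missing mandatory column {col!r}")

    def to_float(col: str, allow_blank: bool = False) -> np.ndarray:
        vals = []
        for i, cell in enumerate(raw[col]):
            if (cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == ""):
                if allow_blank:
                    vals.append(np.nan)
                    continue
                raise DatasetFormatError(f"blank cell in column {col!r} at data row {i}")
            try:
                vals.append(float(cell))
            except ValueError:
                raise DatasetFormatError(
                    f"non-numeric value {cell!r} in column {col!r} at data row {i}"
                ) from None
        return np.array(vals, dtype=float)

    ids = [str(v).strip() for v in raw["ID"]]
    time = to_float("TIME")
    amt = to_float("AMT", allow_blank=True)
    dv = to_float("DV", allow_blank=True)
    evid = to_float("EVID").astype(int)
    mdv = to_float("MDV").astype(int)
    covs = {c: to_float(c, allow_blank=True) for c in COVARIATE_COLUMNS if c in raw.columns}

    subjects: List[SubjectRecord] = []
    order: List[str] = []
    by_id = {}
    for i, sid in enumerate(ids):
        if sid not in by_id:
            cov = {c: float(covs[c][i]) for c in covs if np.isfinite(covs[c][i])}
            by_id[sid] = SubjectRecord(
                subject_id=sid, dose_events=[], observations=[], covariates=cov
            )
            order.append(sid)
        rec = by_id[sid]
        if evid[i] == 1:
            if np.isnan(amt[i]):
                raise DatasetFormatError(f"dose row without AMT at data row {i}")
            rec.dose_events.append((float(time[i]), float(amt[i])))
        elif evid[i] == 0:
            if mdv[i] == 1:
                rec.excluded.append((float(time[i]), float(0.0 if np.isnan(dv[i]) else dv[i])))
            else:
                if np.isnan(dv[i]):
                    raise DatasetFormatError(f"observation row without DV at data row {i}")
                rec.observations.append((float(time[i]), float(dv[i])))
        else:
            raise DatasetFormatError(f"unsupported EVID {evid[i]} at data row {i}")
    subjects = [by_id[sid] for sid in order]

    ds = Dataset(subjects=subjects, lloq=lloq, name=name or str(path))
    findings = validate_dataset(ds)
    if findings:
        raise DatasetValidationError("; ".join(findings))
    return ds


def dataset_to_frame(ds: Dataset) -> pd.DataFrame:
    """Flatten a Dataset to the event-record table (doses first per subject)."""
    rows = []
    for s in ds.subjects:
        cov = {c: s.covariates.get(c, np.nan) for c in COVARIATE_COLUMNS}
        for t, a in s.dose_events:
            rows.append({"ID": s.subject_id, "TIME": t, "AMT": a, "DV": np.nan,
                         "EVID": 1, "MDV": 1, **cov})
        records = [(t, v, 1) for t, v in s.excluded] + [(t, v, 0) for t, v in s.observations]
        for t, v, m in sorted(records, key=lambda r: (r[0], r[2])):
            rows.append({"ID": s.subject_id, "TIME": t, "AMT": np.nan, "DV": v,
                         "EVID": 0, "MDV": m, **cov})
    return pd.DataFrame(rows, columns=["ID", "TIME", "AMT", "DV", "EVID", "MDV", *COVARIATE_COLUMNS])


def write_dataset(ds: Dataset, path) -> None:
    """Write the event-record CSV; ``read_dataset`` round-trips it exactly."""
    frame = dataset_to_frame(ds)
    frame.to_csv(path, index=False, float_format=f"%.{_WRITE_PRECISION}f")


# -- YAML config -------------------------------------------------------------

def load_config(path) -> dict:
    """Load an analysis config; the ``model`` block parses to a PopulationModel."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "model" in cfg:
        cfg["model"] = model_from_dict(cfg["model"])
    return cfg


def save_config(cfg: Mapping, path) -> None:
    out = dict(cfg)
    if isinstance(out.get("model"), PopulationModel):
        out["model"] = model_to_dict(out["model"])
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
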