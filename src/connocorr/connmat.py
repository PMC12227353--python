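"""Intra- and inter-individual correlation matrices from longitudinal regional measures.

The central exchange object is :class:`RegionalMeasureTable`, a long-format
table of (subject, session, age, modality) records with one column per ROI.
From it this module builds the four families of region-by-region correlation
matrices used throughout the package:

* within-subject across-session correlations (``intra``), which isolate
  within-person variability (aging plus session-to-session state);
* across-subject correlations at fixed integer age (``inter``), which isolate
  between-person trait variability while controlling for age;
* element-wise averages of either family over subjects or age bins;
* resting-state functional connectivity from ROI time-series matrices.

All constructors return :class:`ConnMatrix`, a labelled symmetric correlation
matrix carrying provenance (mode, modality, sample sizes, flagged ROIs).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalMeasureTable",
    "ConnMatrix",
    "corr_across_sessions",
    "intra_individual_mean",
    "inter_individual_mean",
    "timeseries_fc",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

class RegionalMeasureTable:
    """Long-format table of per-session regional measures.

    Wraps a :class:`pandas.DataFrame` with metadata columns
    ``subject_id, session_id, age_years, modality`` followed by one column per
    ROI. Invariants: no duplicate (subject, session) pair; ages finite.
    Missing ROI values are carried as NaN (flagged), never silently zero.
    """

    META_COLUMNS = ("subject_id", "session_id", "age_years", "modality")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        roi = [c for c in df.columns if c not in self.META_COLUMNS]
        if not roi:
            raise ValueError("table has no ROI columns")
        dup = df.duplicated(subset=["subject_id", "session_id"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "session_id"]].to_records(index=False)
            raise ValueError(f"duplicate (subject, session) records: {list(pairs)[:5]}")
        ages = df["age_years"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)):
            raise ValueError("non-finite ages in table")
        # (subject, session) identifies a record, so row order carries no
        # meaning; canonical order makes every downstream matrix bitwise
        # invariant under input permutations
        df = df.sort_values(["subject_id", "session_id"], kind="stable")
        self.df = df.reset_index(drop=True)
        self.roi_names: list[str] = roi

    # -- accessors ---------------------------------------------------------

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    def subjects(self) -> list:
        return list(pd.unique(self.df["subject_id"]))

    def n_sessions(self, subject) -> int:
        return int((self.df["subject_id"] == subject).sum())

    def for_subject(self, subject) -> "RegionalMeasureTable":
        sub = self.df[self.df["subject_id"] == subject]
        if sub.empty:
            raise KeyError(f"subject {subject!r} not in table")
        return RegionalMeasureTable(sub.copy())

    def values(self, subject=None) -> np.ndarray:
        """Sessions x ROI value matrix (optionally for one subject)."""
        df = self.df if subject is None else self.df[self.df["subject_id"] == subject]
        if df.empty:
            raise KeyError(f"subject {subject!r} not in table")
        return df[self.roi_names].to_numpy(dtype=float)

    def ages(self, subject=None) -> np.ndarray:
        df = self.df if subject is None else self.df[self.df["subject_id"] == subject]
        return df["age_years"].to_numpy(dtype=float)

    def modality(self) -> str | None:
        mods = pd.unique(self.df["modality"])
        return str(mods[0]) if len(mods) == 1 else None

    # -- construction / I/O ------------------------------------------------

    @classmethod
    def from_arrays(cls, subject_ids, session_ids, ages, modality, values,
                    roi_names) -> "RegionalMeasureTable":
        values = np.asarray(values, dtype=float)
        meta = pd.DataFrame({
            "subject_id": subject_ids,
            "session_id": session_ids,
            "age_years": np.asarray(ages, dtype=float),
            "modality": modality,
        })
        roi = pd.DataFrame(values, columns=list(roi_names), index=meta.index)
        return cls(pd.concat([meta, roi], axis=1))

    def with_values(self, values: np.ndarray) -> "RegionalMeasureTable":
        """Same metadata rows, replaced ROI values (session-aligned)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.df), self.n_roi):
            raise ValueError(f"values shape {values.shape} != "
                             f"{(len(self.df), self.n_roi)}")
        meta = self.df[list(self.META_COLUMNS)].copy()
        roi = pd.DataFrame(values, columns=self.roi_names, index=meta.index)
        return RegionalMeasureTable(pd.concat([meta, roi], axis=1))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegionalMeasureTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ConnMatrix:
    """Symmetric ROI x ROI correlation matrix with labels and provenance.

    ``provenance`` records at least ``mode`` (one of intra / inter /
    timeseries / raw / age-fitted / residual), plus modality, sample sizes and
    flagged ROIs. Rows/columns of degenerate (zero-variance) ROIs are NaN.
    """

    values: np.ndarray
    roi_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        p = len(self.roi_names)
        if v.shape != (p, p):
            raise ValueError(f"matrix shape {v.shape} does not match {p} ROI labels")
        both = np.isfinite(v) & np.isfinite(v.T)
        if not np.allclose(v[both], v.T[both], atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(v[np.isfinite(v)]) > 1 + 1e-8):
            raise ValueError("correlation entries outside [-1, 1]")
        d = np.diag(v)
        ok = np.isfinite(d)
        if not np.allclose(d[ok], 1.0, atol=1e-8):
            raise ValueError("diagonal of a correlation matrix must be 1")
        np.clip(v, -1.0, 1.0, out=v)
        self.values = v

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    def flagged_rois(self) -> list[str]:
        """ROIs whose whole row is undefined (degenerate variance upstream)."""
        bad = ~np.isfinite(np.diag(self.values))
        return [n for n, b in zip(self.roi_names, bad) if b]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_names,
                            columns=self.roi_names)

    def to_tsv(self, path, sidecar: bool = True) -> None:
        """Write the labelled matrix as TSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t")
        if sidecar:
            side = path.with_suffix(path.suffix + ".json")
            side.write_text(json.dumps(self.provenance, sort_keys=True,
                                       indent=2, default=str) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ConnMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        prov = {}
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            prov = json.loads(side.read_text())
        return cls(df.to_numpy(dtype=float), list(df.columns), prov)


# ---------------------------------------------------------------------------
# Correlation constructors
# ---------------------------------------------------------------------------

def _pearson_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation across rows of X (samples x variables).

    Returns (matrix, degenerate-column mask); degenerate columns give NaN
    rows/columns rather than propagating a divide-by-zero.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    bad = ~(sd > 0) | ~np.isfinite(sd)
    p = X.shape[1]
    C = np.full((p, p), np.nan)
    good = ~bad
    if good.sum() >= 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sub = np.corrcoef(X[:, good], rowvar=False)
        sub = np.atleast_2d(sub)
        C[np.ix_(good, good)] = sub
    np.clip(C, -1.0, 1.0, out=C)
    return C, bad


def _average_corr(stack: np.ndarray, fisher_z: bool = False) -> np.ndarray:
    """Element-wise mean of a stack of correlation matrices.

    The default is the plain mean of r. ``fisher_z=True`` averages
    arctanh-transformed values instead (and back-transforms); this variant is
    provided for sensitivity analyses but is off by default. NaN entries are
    excluded pairwise (missing ROIs never count as zero).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if fisher_z:
            z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
            out = np.tanh(np.nanmean(z, axis=0))
        else:
            out = np.nanmean(stack, axis=0)
    # restore the exact unit diagonal where any input defined it
    d = np.diag(out)
    np.fill_diagonal(out, np.where(np.isfinite(d), 1.0, np.nan))
    return out


def corr_across_sessions(table: RegionalMeasureTable, subject,
                         min_sessions: int = 3) -> ConnMatrix:
    """Within-individual correlation matrix for one subject.

    Entry (i, j) is the Pearson correlation between ROI i's and ROI j's value
    series across the subject's sessions. Requires at least ``min_sessions``
    (default 3; below that r is degenerate). Constant-valued ROIs are flagged
    as NaN rows/columns and logged; the rest of the matrix is unaffected.
    """
    X = table.values(subject)
    n = X.shape[0]
    if n < min_sessions:
        raise ValueError(
            f"subject {subject!r} has {n} sessions; need >= {min_sessions} "
            "for an across-session correlation")
    C, bad = _pearson_columns(X)
    if bad.any():
        logger.info("corr_across_sessions(%r): flagged zero-variance ROIs %s",
                    subject, [table.roi_names[i] for i in np.where(bad)[0]])
    prov = {
        "mode": "intra",
        "modality": table.modality(),
        "subject": subject,
        "n_sessions": n,
        "flagged_rois": [table.roi_names[i] for i in np.where(bad)[0]],
    }
    return ConnMatrix(C, list(table.roi_names), prov)


def intra_individual_mean(table: RegionalMeasureTable, min_sessions: int = 5,
                          fisher_z: bool = False) -> ConnMatrix:
    """Average within-individual correlation matrix across qualifying subjects.

    Each subject with at least ``min_sessions`` sessions contributes one
    across-session correlation matrix; the matrices are averaged element-wise
    (unweighted mean of r; see :func:`_average_corr`).
    """
    included = [s for s in table.subjects() if table.n_sessions(s) >= min_sessions]
    if not included:
        census = {s: table.n_sessions(s) for s in table.subjects()}
        raise ValueError(
            f"no subject has >= {min_sessions} sessions; census: {census}")
    mats = [corr_across_sessions(table, s, min_sessions=min(3, min_sessions)).values
            for s in included]
    avg = _average_corr(np.stack(mats), fisher_z=fisher_z)
    prov = {
        "mode": "intra",
        "modality": table.modality(),
        "subjects": included,
        "n_subjects": len(included),
        "min_sessions": min_sessions,
        "fisher_z": fisher_z,
    }
    return ConnMatrix(avg, list(table.roi_names), prov)


def inter_individual_mean(table: RegionalMeasureTable, age_min: float = 70,
                          age_max: float = 89, min_n: int = 10,
                          fisher_z: bool = False) -> ConnMatrix:
    """Age-controlled between-individual correlation matrix.

    Sessions are binned to integer age (floor of age in years). Within a bin
    each subject contributes one record (multiple sessions falling in the same
    bin are averaged first); Pearson correlations are then computed across
    subjects for every bin with at least ``min_n`` subjects, and the
    qualifying bins' matrices are averaged element-wise.

    Raises with the full per-bin subject census if no bin qualifies.
    """
    df = table.df
    bins = np.floor(df["age_years"].to_numpy(dtype=float)).astype(int)
    mats, used_bins, census = [], {}, {}
    for b in range(int(age_min), int(age_max) + 1):
        sub = df[bins == b]
        if sub.empty:
            census[b] = 0
            continue
        per_subject = sub.groupby("subject_id", sort=True)[table.roi_names].mean()
        census[b] = len(per_subject)
        if len(per_subject) < min_n:
            continue
        C, bad = _pearson_columns(per_subject.to_numpy(dtype=float))
        mats.append(C)
        used_bins[b] = len(per_subject)
    if not mats:
        raise ValueError(
            f"no integer age bin in [{age_min}, {age_max}] reaches "
            f"min_n={min_n} subjects; per-bin census: {census}")
    avg = _average_corr(np.stack(mats), fisher_z=fisher_z)
    prov = {
        "mode": "inter",
        "modality": table.modality(),
        "age_bins": used_bins,
        "n_bins": len(used_bins),
        "min_n": min_n,
        "binning": "floor(session age), same-bin sessions per subject averaged",
        "fisher_z": fisher_z,
    }
    return ConnMatrix(avg, list(table.roi_names), prov)


def timeseries_fc(sessions, roi_names=None, fisher_z: bool = False) -> ConnMatrix:
    """Average resting-state functional connectivity over sessions.

    Each element of ``sessions`` is a ROI x timepoint matrix; a Pearson
    correlation matrix is computed per session over timepoints and the
    per-session matrices are averaged element-wise.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("timeseries_fc requires at least one session")
    mats = []
    p = None
    for k, ts in enumerate(sessions):
        ts = np.asarray(ts, dtype=float)
        if ts.ndim != 2 or ts.shape[1] < 3:
            raise ValueError(
                f"session {k}: need a 2-D ROI x time matrix with >= 3 "
                f"timepoints, got shape {ts.shape}")
        if p is None:
            p = ts.shape[0]
        elif ts.shape[0] != p:
            raise ValueError(f"session {k} has {ts.shape[0]} ROIs, expected {p}")
        C, _ = _pearson_columns(ts.T)
        mats.append(C)
    if roi_names is None:
        roi_names = [f"ROI_{i + 1}" for i in range(p)]
    avg = _average_corr(np.stack(mats), fisher_z=fisher_z)
    prov = {"mode": "timeseries", "n_sessions": len(mats),
            "n_timepoints": [int(np.asarray(s).shape[1]) for s in sessions],
            "fisher_z": fisher_z}
    return ConnMatrix(avg, list(roi_names), prov)
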