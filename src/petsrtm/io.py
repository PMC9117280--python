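"""Delimited-text formats for TAC and BP_ND tables, plus packaged fixtures.

The pipeline begins at regional time-activity curves, after image-space ROI
extraction; everything on disk is plain delimited text (comma by default,
tab accepted).

TAC tables: ``subject_id, scan, region, frame_start_min, frame_duration_min,
activity`` — one row per frame.  BP tables: ``subject_id, dose_group, scan,
region, bp_nd``.  The package ships the clinical study's per-subject BP_ND
values as a fixture, integrity-checked by SHA-256 on load.
"""
from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .frames import FrameSchedule, TimeActivityCurve
from .challenge import BPTable

__all__ = [
    "ParseError",
    "read_tac_table",
    "write_tac_table",
    "read_bp_table",
    "write_bp_table",
    "load_clinical_bp_table",
    "load_clinical_group_summary",
    "tacs_to_frame",
]

TAC_COLUMNS = [
    "subject_id",
    "scan",
    "region",
    "frame_start_min",
    "frame_duration_min",
    "activity",
]

_CLINICAL_BP_SHA256 = "315fefcd86642e84a7b8e46c9447467d3a1b0df03d5bc6c2a5d61a6b99762fa1"
_CLINICAL_SUMMARY_SHA256 = "e59bc0f26a3e06cfa41b1775ba644d5f0112a3b3a7e73cd1001bce9eff339101"


class ParseError(ValueError):
    """A table file violates the schema; the message names the offence."""


def _read_delimited(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        # sniff comma vs tab from the header line
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def tacs_to_frame(tacs: dict) -> pd.DataFrame:
    """Long-format frame table from {(subject, scan): {region: TAC}}."""
    rows = []
    for (subject, scan), curves in tacs.items():
        for region, tac in curves.items():
            sched = tac.schedule
            for s, d, a in zip(sched.start, sched.duration, tac.activity):
                rows.append((subject, scan, region, s, d, a))
    return pd.DataFrame(rows, columns=TAC_COLUMNS)


def write_tac_table(tacs: dict, path, sep: str = ",") -> None:
    """Write {(subject, scan): {region: TimeActivityCurve}} to delimited text."""
    tacs_to_frame(tacs).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_tac_table(path, sep: str | None = None) -> dict:
    """Read a TAC table into {(subject, scan): {region: TimeActivityCurve}}.

    Frames of each (subject, scan, region) are sorted canonically by start
    time, so row order in the file is immaterial.  Duplicate frames and
    non-monotone schedules raise :class:`ParseError` naming the rows.
    """
    df = _read_delimited(path, sep)
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("frame_start_min", "frame_duration_min", "activity"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in {col!r}: {exc}") from None
    out: dict = {}
    for (subject, scan, region), grp in df.groupby(
        ["subject_id", "scan", "region"], sort=False
    ):
        grp = grp.sort_values("frame_start_min")
        dup = grp["frame_start_min"].duplicated()
        if dup.any():
            rows = list(grp.index[dup] + 2)  # +2: header + 1-based
            raise ParseError(
                f"{path}: duplicate frame(s) for ({subject}, {scan}, {region}) "
                f"at file row(s) {rows}"
            )
        try:
            schedule = FrameSchedule(
                grp["frame_start_min"].to_numpy(), grp["frame_duration_min"].to_numpy()
            )
        except ValueError as exc:
            raise ParseError(
                f"{path}: invalid schedule for ({subject}, {scan}, {region}): {exc}"
            ) from None
        tac = TimeActivityCurve(schedule, grp["activity"].to_numpy(), str(region))
        out.setdefault((subject, scan), {})[region] = tac
    return out


def write_bp_table(table: BPTable, path, sep: str = ",") -> None:
    table.frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_bp_table(path, sep: str | None = None) -> BPTable:
    df = _read_delimited(path, sep)
    try:
        return BPTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _packaged(name: str, expected_sha: str) -> bytes:
    raw = resources.files("petsrtm").joinpath("data", name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise RuntimeError(
            f"packaged fixture {name} failed its integrity check "
            f"(sha256 {digest}, expected {expected_sha})"
        )
    return raw


def load_clinical_bp_table() -> BPTable:
    """The clinical study's per-subject BP_ND table (10 subjects x 3 scans
    x 5 regions; subjects 1-5 in the 20 mg group, 6-10 in the 40 mg group)."""
    import io as _io

    raw = _packaged("clinical_bpnd.csv", _CLINICAL_BP_SHA256)
    return BPTable(pd.read_csv(_io.BytesIO(raw)))


def load_clinical_group_summary() -> pd.DataFrame:
    """The published group means/SDs of dBP and ddBP per region and group,
    used for side-by-side comparison with recomputed values."""
    import io as _io

    raw = _packaged("clinical_group_summary.csv", _CLINICAL_SUMMARY_SHA256)
    return pd.read_csv(_io.BytesIO(raw))
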