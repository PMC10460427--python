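"""Event-log and results-table I/O.

The canonical on-disk dialect is TSV with a ``ego  alter  timestamp`` header
and ``#``-prefixed comment lines (CSV is accepted on input; the delimiter is
sniffed unless given).  Ego and alter identifiers are opaque strings;
timestamps are integers or ISO-8601 strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["EventLog", "ReadReport", "read_event_log", "write_event_log", "write_fit_table"]

REQUIRED_COLUMNS = ("ego", "alter", "timestamp")

#: fixed column order of the per-ego fit table
FIT_TABLE_COLUMNS = (
    "ego",
    "k",
    "a0",
    "a_m",
    "tau",
    "t",
    "beta",
    "alpha_r",
    "dispersion",
    "D",
    "pvalue",
    "accepted",
    "status",
)


@dataclass
class ReadReport:
    """Per-file parse report: counts plus (line number, reason) pairs."""

    n_records: int = 0
    n_malformed: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class EventLog:
    """Ordered communication events: one row per (ego, alter, timestamp).

    ``params`` optionally carries per-ego ground-truth model parameters when
    the log was produced by the simulator.
    """

    frame: pd.DataFrame
    params: dict | None = None
    report: ReadReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"event log missing required columns: {missing}")

    @property
    def n_events(self) -> int:
        return len(self.frame)

    @property
    def egos(self) -> list[str]:
        return sorted(self.frame["ego"].unique())

    def sorted(self) -> "EventLog":
        """Stable sort by (ego, timestamp); ties keep input order."""
        df = self.frame.sort_values(["ego", "timestamp"], kind="stable").reset_index(drop=True)
        return EventLog(frame=df, params=self.params, report=self.report)

    def events_of(self, ego: str) -> pd.DataFrame:
        df = self.frame
        return df[df["ego"] == ego]


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_event_log(path, delimiter: str | None = None) -> EventLog:
    """Read and validate a TSV/CSV event log.

    Malformed records (empty ids, ego == alter, unparseable timestamps) are
    dropped and reported, with 1-based line numbers, in ``log.report``.
    Missing required columns are a hard error.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, comment="#", dtype={"ego": str, "alter": str}, skip_blank_lines=True
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (header found: {list(df.columns)})")
    report = ReadReport(n_records=len(df))
    if len(df) == 0:
        logger.warning("%s: header-only event log (no records)", path)
        df = df.astype({"timestamp": "int64"}, errors="ignore")
        return EventLog(frame=df, report=report)

    lineno = df.index.to_numpy() + 2  # header is line 1
    bad = pd.Series(False, index=df.index)

    for col, reason in (("ego", "empty ego id"), ("alter", "empty alter id")):
        mask = df[col].isna() | (df[col].astype(str).str.len() == 0)
        _collect(report, lineno, mask & ~bad, reason)
        bad |= mask
    mask = (~bad) & (df["ego"] == df["alter"])
    _collect(report, lineno, mask, "self-loop (ego == alter)")
    bad |= mask

    ts = pd.to_numeric(df["timestamp"], errors="coerce")
    not_numeric = ts.isna() & ~bad
    if not_numeric.any():
        iso = pd.to_datetime(df.loc[not_numeric, "timestamp"], errors="coerce", utc=True)
        valid = iso.notna()
        ts.loc[valid[valid].index] = iso[valid].astype("int64") // 10**9
        mask = ts.isna() & ~bad
        _collect(report, lineno, mask, "unparseable timestamp")
        bad |= mask

    df = df.loc[~bad].copy()
    df["timestamp"] = ts.loc[~bad].astype("int64")
    report.n_malformed = len(report.malformed)
    if report.n_malformed:
        logger.warning("%s: dropped %d malformed records", path, report.n_malformed)
    out = EventLog(frame=df.reset_index(drop=True), report=report)
    return out.sorted()


def _collect(report: ReadReport, lineno: np.ndarray, mask: pd.Series, reason: str) -> None:
    for ln in lineno[mask.to_numpy()]:
        report.malformed.append((int(ln), reason))


def _comment_header(config_hash: str | None, seed: int | None) -> str:
    lines = []
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}\n")
    if seed is not None:
        lines.append(f"# seed: {seed}\n")
    return "".join(lines)


def write_event_log(log: EventLog, path, config_hash: str | None = None, seed: int | None = None) -> None:
    """Write the canonical TSV dialect with optional provenance comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_comment_header(config_hash, seed))
        log.frame.to_csv(fh, sep="\t", index=False, columns=list(REQUIRED_COLUMNS))


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "nan"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_fit_table(fits, path, config_hash: str | None = None, seed: int | None = None) -> None:
    """Write per-ego fit records as a deterministic TSV.

    Column order is fixed (:data:`FIT_TABLE_COLUMNS`); floats carry six
    significant digits; rows are sorted by ego id.
    """
    path = Path(path)
    rows = sorted(fits, key=lambda f: str(getattr(f, "ego", "")))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_comment_header(config_hash, seed))
        fh.write("\t".join(FIT_TABLE_COLUMNS) + "\n")
        for f in rows:
            rec = {
                "ego": f.ego,
                "k": f.k,
                "a0": f.a0,
                "a_m": f.a_m,
                "tau": f.tau,
                "t": f.t,
                "beta": f.beta,
                "alpha_r": f.alpha_r,
                "dispersion": f.dispersion,
                "D": f.D,
                "pvalue": f.p_value,
                "accepted": f.accepted,
                "status": f.status,
            }
            fh.write("\t".join(_fmt(rec[c]) for c in FIT_TABLE_COLUMNS) + "\n")


def read_fit_table(path) -> pd.DataFrame:
    """Read a fit table written by :func:`write_fit_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
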