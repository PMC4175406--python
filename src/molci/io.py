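"""CSV readers and the serializable result record.

Dialect: comma-separated, UTF-8, mandatory header, '.' decimal.  Score
tables carry ``id,label,score`` with labels in {1, 0, active, inactive}
(case-insensitive); paired tables carry ``x,y``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, SingleClassError
from .roc import LabeledScores

__all__ = ["ResultRecord", "read_scores", "read_xy", "file_digest"]

log = logging.getLogger("molci")

_ACTIVE_LABELS = {"1", "active", "true"}
_INACTIVE_LABELS = {"0", "inactive", "false"}


@dataclass(frozen=True)
class ResultRecord:
    """One reportable result, losslessly JSON round-trippable."""

    metric: str
    estimate: float
    lower: float
    upper: float
    level: float
    method: str
    df: float
    warnings: tuple[str, ...] = field(default_factory=tuple)
    inputs_digest: str = ""

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["warnings"] = list(self.warnings)
        d["df"] = "inf" if np.isinf(self.df) else self.df
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ResultRecord":
        d = json.loads(text)
        d["warnings"] = tuple(d.get("warnings", ()))
        if d.get("df") == "inf":
            d["df"] = float("inf")
        return cls(**d)


def file_digest(path: str | Path) -> str:
    """SHA-256 of the raw file bytes, for provenance in result records."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def read_scores(path: str | Path, higher_is_better: bool = True) -> LabeledScores:
    """Read a labeled score table (header ``id,label,score``)."""
    df = _read_csv(path, ["label", "score"])
    labels = []
    for i, raw in enumerate(df["label"].astype(str).str.strip().str.lower()):
        if raw in _ACTIVE_LABELS:
            labels.append(True)
        elif raw in _INACTIVE_LABELS:
            labels.append(False)
        else:
            raise FormatError(f"{path}: row {i + 2}: unrecognized label {raw!r}")
    scores = pd.to_numeric(df["score"], errors="coerce").to_numpy()
    bad = np.nonzero(~np.isfinite(scores))[0]
    if bad.size:
        raise FormatError(f"{path}: row {bad[0] + 2}: unparseable score")
    data = LabeledScores(scores=scores, labels=np.array(labels),
                         higher_is_better=higher_is_better)
    if data.n_active == 0 or data.n_inactive == 0:
        raise SingleClassError(
            f"{path}: need both classes (got {data.n_active} active, "
            f"{data.n_inactive} inactive)")
    log.info("read %d rows from %s: %d active, %d inactive",
             len(df), path, data.n_active, data.n_inactive)
    return data


def read_xy(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a paired numeric table (header ``x,y``)."""
    df = _read_csv(path, ["x", "y"])
    out = []
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise FormatError(f"{path}: row {bad[0] + 2}: non-numeric {col!r} value")
        out.append(vals)
    log.info("read %d (x, y) pairs from %s", len(df), path)
    return out[0], out[1]
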