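"""Event-table I/O and the canonical column schema.

An *event table* is a :class:`pandas.DataFrame` with one row per acquired
object.  Mandatory columns are ``event_id`` and the two stain intensities
``rsg_intensity`` / ``pi_intensity`` (relative fluorescence units, RFU,
nonnegative).  Feature columns (see :mod:`ifcgate.features`), a
ground-truth label ``true_label`` (simulations only), the assigned
``label`` and a ``replicate_id`` are optional; unknown columns are
carried through untouched.

The canonical on-disk format is plain CSV (UTF-8, comma separated, ``.``
decimal, header row).  FCS 3.0 import/export is provided for
interoperability with cytometry software; FCS stores only the numeric
columns (float32 list mode), so labels survive CSV round-trips only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

MANDATORY_COLUMNS = ("event_id", "rsg_intensity", "pi_intensity")

#: every label the pipeline may assign to an event
LABELS = (
    "active",
    "mid_active_1",
    "mid_active_2",
    "dead",
    "debris",
    "aggregate",
    "out_of_focus",
    "unclassified",
)

#: the four stained-cell physiological subpopulations
CELL_LABELS = ("active", "mid_active_1", "mid_active_2", "dead")


class SchemaError(ValueError):
    """Mandatory columns missing or malformed."""


class ValidationError(ValueError):
    """Values violate the event-table invariants."""


def validate_event_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants and return the table (labels filled in).

    Checks: mandatory columns present, ``event_id`` unique, intensities
    nonnegative and finite, assigned labels drawn from :data:`LABELS`.
    A missing ``label`` column is added as ``"unclassified"``.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if table["event_id"].duplicated().any():
        dup = table.loc[table["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValidationError(f"duplicate event_id: {dup}")
    for col in ("rsg_intensity", "pi_intensity"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r}: negative or non-numeric value at row {row}"
            )
    table = table.copy()
    if "label" not in table.columns:
        table["label"] = "unclassified"
    unknown = set(table["label"].unique()) - set(LABELS)
    if unknown:
        raise ValidationError(f"unknown assigned labels: {sorted(unknown)}")
    return table


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "fcs" if path.suffix.lower() == ".fcs" else "csv"


def read_event_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a validated event table from CSV or FCS.

    Parameters
    ----------
    path
        Input file; format inferred from the extension unless given.
    format
        ``"csv"`` or ``"fcs"``.
    column_map
        Optional rename applied before validation, e.g. mapping FCS
        parameter short names onto the canonical schema
        (``{"FL1-A": "rsg_intensity"}``).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        table = pd.read_csv(path)
    elif fmt == "fcs":
        table = _read_fcs(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if column_map:
        table = table.rename(columns=dict(column_map))
    return validate_event_table(table)


def write_event_table(
    table: pd.DataFrame, path: str | Path, format: str | None = None
) -> None:
    """Write an event table to CSV (full schema) or FCS (numeric columns)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "fcs":
        _write_fcs(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Minimal FCS 3.0 list-mode support (float32, little-endian).  Covers only
# what this package writes; it is not a general-purpose FCS parser.

_FCS_DELIM = "/"


def _write_fcs(table: pd.DataFrame, path: Path) -> None:
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError("FCS export requires at least one numeric column")
    data = np.ascontiguousarray(numeric.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape
    keywords: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(numeric.columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "262144"

    def render_text(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        parts = [_FCS_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_FCS_DELIM}{v}{_FCS_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58  # "FCS3.0" + 4 spaces + 6 offset fields of 8 chars
    text_start = header_len
    # iterate: data offsets depend on TEXT length which depends on offsets
    begin_data = end_data = 0
    for _ in range(3):
        text = render_text(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + data.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)
    text_end = text_start + len(text) - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _read_fcs(path: Path) -> pd.DataFrame:
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise ValueError(f"{path} is not an FCS 3.x file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin = int(kw.get("$BEGINDATA") or raw[26:34])
    if kw.get("$DATATYPE", "F") != "F":
        raise ValueError("only $DATATYPE F (float) FCS files are supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    count = n_par * n_tot
    data = np.frombuffer(raw, dtype=f"{endian}f4", count=count, offset=begin)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(data.reshape(n_tot, n_par).astype(float), columns=names)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Per-run settings shared by CLI and scripts.

    ``acquisition_volume_mL`` is required to express cytometer event
    counts as obj/mL; instruments report it per acquisition, so it is
    explicit user input here.
    """

    seed: int = 0
    acquisition_volume_mL: float = 1e-3
    gate_config: dict = field(default_factory=dict)
    classifier_path: str | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.acquisition_volume_mL > 0:
            raise ValueError("acquisition_volume_mL must be > 0")
        for key, val in self.gate_config.items():
            if not np.isfinite(val):
                raise ValueError(f"gate threshold {key!r} is not finite")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def save(self, path: str | Path) -> None:
        payload = dict(
            seed=self.seed,
            acquisition_volume_mL=self.acquisition_volume_mL,
            gate_config=dict(self.gate_config),
            classifier_path=self.classifier_path,
            output_dir=self.output_dir,
        )
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
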