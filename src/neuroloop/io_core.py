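"""Readers, writers, configuration and logging shared by all modules.

EDF writing is a minimal 16-bit EDF implementation (one 1-second data
record per second, physical dimension uV); reading goes through MNE when
available, with a light-weight independent header validator.  Events travel
as CSV with columns start_s, end_s, duration_s, mean_prob, max_prob, source.
Configuration is YAML with unknown keys rejected; structured logs are JSON
lines carrying a config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EEGRecording, SeizureEvent, ValidationError

EVENT_COLUMNS = ["start_s", "end_s", "duration_s", "mean_prob", "max_prob", "source"]


# ----------------------------------------------------------------------- EDF


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def _phys_str(v: float, width: int = 7) -> str:
    """Positive physical-range value as a short field that parses back exactly.

    Kept to ``width`` characters so a leading minus sign still fits the
    8-character EDF header slot.
    """
    for prec in (6, 5, 4, 3, 2):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    return f"{v:.1e}"[:width]


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a 16-bit EDF file (record duration 1 s; requires integer fs)."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = math.ceil(rec.n_samples / spr)
    ns = rec.n_channels
    start = rec.start_time or datetime(2000, 1, 1)

    data = np.zeros((ns, n_rec * spr))
    data[:, : rec.n_samples] = rec.data
    # quantize with the same (text-rounded) physical range the header carries
    pmax_raw = np.maximum(np.abs(data).max(axis=1), 1e-6)
    pmax = np.array([float(_phys_str(v)) for v in 1.0001 * pmax_raw])
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scaled = np.round(
        (data - pmin[:, None]) / (pmax - pmin)[:, None] * (dmax - dmin) + dmin
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad(f"Startdate {start:%d-%b-%Y} X X X", 80))
        f.write(_pad(f"{start:%d.%m.%y}", 8))
        f.write(_pad(f"{start:%H.%M.%S}", 8))
        f.write(_pad(str(256 * (1 + ns)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(ns), 4))
        for ch in rec.channel_names:
            f.write(_pad(ch, 16))
        for _ in range(ns):
            f.write(_pad("", 80))  # transducer
        for _ in range(ns):
            f.write(_pad("uV", 8))
        for v in pmax:
            f.write(_pad("-" + _phys_str(v), 8))  # physical minima
        for v in pmax:
            f.write(_pad(_phys_str(v), 8))
        for _ in range(ns):
            f.write(_pad(str(dmin), 8))
        for _ in range(ns):
            f.write(_pad(str(dmax), 8))
        for _ in range(ns):
            f.write(_pad("", 80))  # prefiltering
        for _ in range(ns):
            f.write(_pad(str(spr), 8))
        for _ in range(ns):
            f.write(_pad("", 32))
        for r in range(n_rec):
            for c in range(ns):
                f.write(scaled[c, r * spr : (r + 1) * spr].tobytes())


def validate_edf_header(path: str | Path) -> dict:
    """Independent EDF header check; raises with the byte offset on failure.

    Also rejects the mixed-rate dialect (per-channel sampling rates), which
    this package does not support.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValidationError(f"truncated EDF header at byte {len(raw)}")
    if raw[0:8].strip() not in (b"0",):
        raise ValidationError("corrupt EDF header at byte 0: bad version field")
    try:
        ns = int(raw[252:256].decode())
        n_rec = int(raw[236:244].decode())
        dur = float(raw[244:252].decode())
    except ValueError as exc:
        raise ValidationError(f"corrupt EDF header near byte 236: {exc}") from exc
    off = 256 + ns * 216
    spr_field = raw[off : off + ns * 8]
    if len(spr_field) < ns * 8:
        raise ValidationError(f"corrupt EDF header at byte {off}")
    spr = [int(spr_field[i * 8 : (i + 1) * 8].decode()) for i in range(ns)]
    if len(set(spr)) > 1:
        raise ValidationError(
            "unsupported EDF dialect: per-channel sampling rates differ"
        )
    return {"n_signals": ns, "n_records": n_rec, "record_duration": dur,
            "samples_per_record": spr[0]}


def read_edf(
    path: str | Path, modality: str = "scalp", return_events: bool = False
):
    """Read an EDF/EDF+ file into an EEGRecording (physical units uV).

    With ``return_events`` any annotations embedded in the file are also
    returned as a list of SeizureEvent (source 'clinician').
    """
    validate_edf_header(path)
    import mne  # optional dependency, imported lazily

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    start = raw.info["meas_date"]
    rec = EEGRecording(
        data=data,
        channel_names=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        start_time=start.replace(tzinfo=None) if start else None,
        modality=modality,  # type: ignore[arg-type]
    )
    if not return_events:
        return rec
    events = [
        SeizureEvent(float(on), float(on + max(dur, 1e-3)), source="clinician")
        for on, dur in zip(raw.annotations.onset, raw.annotations.duration)
    ]
    return rec, events


# ----------------------------------------------------------------- events CSV


def write_events_csv(path: str | Path, events: list[SeizureEvent]) -> None:
    rows = [
        {
            "start_s": e.start,
            "end_s": e.end,
            "duration_s": e.duration,
            "mean_prob": e.mean_prob,
            "max_prob": e.max_prob,
            "source": e.source,
        }
        for e in sorted(events, key=lambda e: (e.start, e.end))
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[SeizureEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"start_s", "end_s", "source"} - set(df.columns)
    if missing:
        raise ValidationError(f"events CSV missing columns {sorted(missing)}")
    events = []
    for i, row in df.iterrows():
        if not row["end_s"] > row["start_s"]:
            raise ValidationError(f"row {i}: end_s must exceed start_s")
        events.append(
            SeizureEvent(
                start=float(row["start_s"]),
                end=float(row["end_s"]),
                source=str(row["source"]),
                mean_prob=float(row.get("mean_prob", np.nan)),
                max_prob=float(row.get("max_prob", np.nan)),
            )
        )
    return sorted(events, key=lambda e: (e.start, e.end))


# -------------------------------------------------------------------- config


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg


def build_dataclass(cls, values: dict):
    """Instantiate a (possibly nested) config dataclass, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ValidationError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**values)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def log_jsonl(path: str | Path, record: dict) -> None:
    with open(path, "a") as f:
        f.write(json.dumps(record, sort_keys=True, default=str) + "\n")


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
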