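"""Phase-log, ground-truth and scenario file formats.

A phase log is comma-separated text with header
``epc,t_ms,phase_rad,raw_code,rssi_dbm`` preceded by optional ``#``
provenance comment lines (scenario seed or reader id).  Floats are written
with shortest round-trip precision so ``parse(write(x)) == x`` on records.
"""
from __future__ import annotations

import csv
import json
import warnings

import numpy as np
import yaml

from .errors import PhaseLogFormatError
from .streams import TagStream
from .synth import BreathingScenario, TagTruth

COLUMNS = ("epc", "t_ms", "phase_rad", "raw_code", "rssi_dbm")


def write_phase_log(streams: dict[str, TagStream], path,
                    provenance: dict | None = None) -> None:
    """Write streams merged into one reader-style log, sorted by timestamp."""
    rows = []
    for stream in streams.values():
        for i in range(len(stream)):
            rows.append((
                int(stream.t_ms[i]),
                stream.epc,
                float(stream.phase[i]),
                int(stream.raw_code[i]) if stream.raw_code is not None else "",
                float(stream.rssi[i]) if stream.rssi is not None else "",
            ))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for t_ms, epc, phase, raw, rssi in rows:
            writer.writerow([epc, t_ms, repr(phase),
                             raw, "" if rssi == "" else repr(rssi)])


def read_phase_log(path) -> dict[str, TagStream]:
    """Parse a phase log back into per-EPC streams.

    Malformed rows raise :class:`PhaseLogFormatError` naming the line; an
    EPC with non-monotone timestamps triggers a warning and a stable sort.
    """
    records: dict[str, list[tuple[int, float, int | None, float | None]]] = {}
    with open(path, newline="") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            row = next(csv.reader([line]))
            if header is None:
                header = tuple(c.strip() for c in row)
                missing = set(COLUMNS) - set(header)
                if missing:
                    raise PhaseLogFormatError(
                        f"{path}: header is missing columns {sorted(missing)}")
                idx = {c: header.index(c) for c in COLUMNS}
                continue
            try:
                epc = row[idx["epc"]]
                t_ms = int(row[idx["t_ms"]])
                phase = float(row[idx["phase_rad"]])
                raw_field = row[idx["raw_code"]].strip()
                raw = int(raw_field) if raw_field else None
                rssi_field = row[idx["rssi_dbm"]].strip()
                rssi = float(rssi_field) if rssi_field else None
            except (IndexError, ValueError) as exc:
                raise PhaseLogFormatError(
                    f"{path}: malformed row at line {lineno}: {line.strip()!r}") from exc
            records.setdefault(epc, []).append((t_ms, phase, raw, rssi))
        if header is None:
            raise PhaseLogFormatError(f"{path}: empty file, no header")

    streams: dict[str, TagStream] = {}
    for epc, recs in records.items():
        t = [r[0] for r in recs]
        if any(t[i + 1] < t[i] for i in range(len(t) - 1)):
            warnings.warn(f"EPC {epc}: non-monotone timestamps, sorting",
                          stacklevel=2)
            recs = sorted(recs, key=lambda r: r[0])
        has_raw = all(r[2] is not None for r in recs)
        has_rssi = all(r[3] is not None for r in recs)
        streams[epc] = TagStream(
            epc=epc,
            t_ms=np.array([r[0] for r in recs], dtype=np.int64),
            phase=np.array([r[1] for r in recs], dtype=float),
            raw_code=np.array([r[2] for r in recs], dtype=np.int64) if has_raw else None,
            rssi=np.array([r[3] for r in recs], dtype=float) if has_rssi else None,
        )
    return streams


# --------------------------------------------------------------------------
# sidecars
# --------------------------------------------------------------------------

def write_ground_truth(truth: dict[str, TagTruth], path) -> None:
    payload = {
        epc: {
            "subject_id": t.subject_id,
            "body_part": t.body_part,
            "rate_hz": t.rate_hz,
            "amplitude_m": t.amplitude_m,
            "baseline_distance_m": t.baseline_distance_m,
            "apnea_intervals": [list(iv) for iv in t.apnea_intervals],
        }
        for epc, t in truth.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_ground_truth(path) -> dict[str, TagTruth]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        epc: TagTruth(
            epc=epc,
            subject_id=t["subject_id"],
            body_part=t["body_part"],
            rate_hz=t["rate_hz"],
            amplitude_m=t["amplitude_m"],
            baseline_distance_m=t["baseline_distance_m"],
            apnea_intervals=tuple(tuple(iv) for iv in t["apnea_intervals"]),
        )
        for epc, t in payload.items()
    }


def save_scenario(scenario: BreathingScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def load_scenario(path) -> BreathingScenario:
    with open(path) as fh:
        return BreathingScenario.from_dict(yaml.safe_load(fh))
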