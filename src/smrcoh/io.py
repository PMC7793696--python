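"""Recording I/O and study configuration.

Recordings are exchanged as EDF (16-bit, physical unit microvolts), the
universal EEG interchange format, one file per run, with a JSON sidecar
carrying simulation ground truth (coupling, seed, artifact onsets).
Writing uses a minimal EDF implementation (ASCII header + little-endian
int16 records, 1-s data records); reading goes through MNE's EDF reader,
so round trips are cross-checked against an independent implementation.
BrainVision headers (.vhdr) are accepted read-only as an alternate dialect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .eegsim import LearnerParams, Recording
from .nfloop import ProtocolConfig
from .preproc import RejectionCriteria

__all__ = ["write_recording", "read_recording", "StudyConfig", "load_config"]


class FormatError(RuntimeError):
    """Unreadable or structurally invalid recording file."""


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording(path: str | Path, recording: Recording,
                    sidecar: bool = True) -> Path:
    """Write a Recording to EDF (+ JSON sidecar with the meta dict).

    Data records are 1 s long when the sampling rate is an integer and the
    recording spans whole seconds; otherwise a single record holds the whole
    signal.  Each channel is scaled to the int16 range by its own physical
    min/max, so quantization error is (max-min)/65535 per channel.
    """
    path = Path(path)
    data = recording.data
    n_ch, n_samp = data.shape
    fs = recording.fs
    if float(fs).is_integer() and n_samp % int(fs) == 0:
        record_s = 1.0
        spr = int(fs)
    else:
        record_s = n_samp / fs
        spr = n_samp
    n_records = n_samp // spr

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    same = phys_max - phys_min < 1
    phys_max[same] = phys_min[same] + 1
    dig_min, dig_max = -32767, 32767

    header = bytearray()
    header += _ascii(0, 8)
    header += _ascii("X X X X", 80)                       # local patient id
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)   # local recording id
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(f"{record_s:g}", 8)
    header += _ascii(n_ch, 4)
    for lab in recording.labels:
        header += _ascii(lab, 16)
    for _ in recording.labels:
        header += _ascii("AgAgCl electrode", 80)
    for _ in recording.labels:
        header += _ascii("uV", 8)
    for v in phys_min:
        header += _ascii(f"{v:g}", 8)
    for v in phys_max:
        header += _ascii(f"{v:g}", 8)
    for _ in recording.labels:
        header += _ascii(dig_min, 8)
    for _ in recording.labels:
        header += _ascii(dig_max, 8)
    for _ in recording.labels:
        header += _ascii("", 80)
    for _ in recording.labels:
        header += _ascii(spr, 8)
    for _ in recording.labels:
        header += _ascii("", 32)

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((data - phys_min[:, None]) * gain[:, None] + dig_min),
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec_i in range(n_records):
            sl = slice(rec_i * spr, (rec_i + 1) * spr)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())

    if sidecar:
        meta = {
            "fs": fs,
            "labels": list(recording.labels),
            "n_samples": int(n_samp),
            **{k: v for k, v in recording.meta.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path, require_channels: tuple[str, ...] = ("Cz", "CPz")) -> Recording:
    """Read an EDF (or BrainVision .vhdr) file into a Recording in microvolts.

    The JSON sidecar, when present, repopulates the ground-truth meta dict.
    Raises FormatError when the file is unreadable or a required channel
    label is absent.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        if path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:
        raise FormatError(f"{path}: unreadable header ({err})") from err
    labels = tuple(raw.ch_names)
    for ch in require_channels:
        if ch not in labels:
            raise FormatError(f"{path}: required channel {ch!r} missing from {labels}")
    if len([l for l in labels if l.upper() != "EOG"]) < 2:
        raise FormatError(f"{path}: need at least 2 EEG channels, found {labels}")
    data_uV = raw.get_data() * 1e6  # MNE returns volts
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        meta.pop("labels", None)
        meta.pop("fs", None)
        n = meta.pop("n_samples", None)
        if n is not None:
            data_uV = data_uV[:, :n]
    return Recording(data=data_uV, fs=float(raw.info["sfreq"]), labels=labels, meta=meta)


# --------------------------------------------------------------------------
# study configuration


@dataclass
class StudyConfig:
    """Validated study configuration: protocol, rejection criteria, cohort."""

    protocol: ProtocolConfig
    criteria: RejectionCriteria
    groups: dict[str, list[LearnerParams]]  # 'up' / 'down' -> per-subject params
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.groups:
            if name not in ("up", "down"):
                raise ValueError(f"unknown group {name!r}: use 'up' or 'down'")
            if not self.groups[name]:
                raise ValueError(f"group {name!r} has no subjects")


def _build(cls, section: dict, where: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{where}: {err}") from err


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Schema::

        seed: 1
        protocol: {n_sessions: 10, runs_per_session: 7, run_s: 180, ...}
        criteria: {max_step_uV: 50.0, ...}
        groups:
          up:   [{c0: 0.3, beta_session: 0.03}, ...]
          down: [{c0: 0.3, beta_session: 0.0}, ...]

    Unknown keys anywhere are rejected with a message naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - {"seed", "protocol", "criteria", "groups"}
    if unknown:
        raise ValueError(f"config: unknown top-level key(s) {sorted(unknown)}")
    protocol_raw = dict(raw.get("protocol", {}))
    criteria = _build(RejectionCriteria, raw.get("criteria", {}) or {}, "criteria")
    protocol_raw.setdefault("criteria", criteria)
    protocol = _build(ProtocolConfig, protocol_raw, "protocol")
    groups_raw = raw.get("groups", {}) or {}
    groups = {}
    for gname, members in groups_raw.items():
        groups[gname] = [
            _build(LearnerParams, dict(m or {}), f"groups.{gname}[{i}]")
            for i, m in enumerate(members)
        ]
    return StudyConfig(protocol=protocol, criteria=criteria, groups=groups,
                       seed=int(raw.get("seed", 0)))
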