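"""Minimal EDF+ (continuous) writer and reader.

Supports uniformly sampled signals plus one annotation channel with
time-stamped annotation lists (TALs).  This is a deliberately small
implementation of the published 16-bit EDF+ layout — enough to
round-trip this package's sessions with their period/class annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

HEADER_BYTES = 256
SIGNAL_HEADER_BYTES = 256
DIG_MIN, DIG_MAX = -32768, 32767


class EdfFormatError(ValueError):
    """Malformed EDF+ content; message carries the byte offset."""


@dataclass
class EdfAnnotation:
    onset: float  # seconds from recording start
    duration: float | None
    text: str


@dataclass
class EdfFile:
    signals: np.ndarray  # (n_signals, n_samples), physical units
    sampling_rate: float
    labels: list[str]
    annotations: list[EdfAnnotation] = field(default_factory=list)
    physical_range: tuple[float, float] = (-400.0, 400.0)
    recording_id: str = ""
    patient_id: str = "X X X X"


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width, b" ")


def _fmt_num(value: float, width: int) -> bytes:
    text = f"{value:.10g}"
    if len(text) > width:
        text = f"{value:.{max(width - 7, 0)}g}"
    return _fixed(text, width)


def _annotation_bytes(records: list[list[EdfAnnotation]],
                      record_duration: float) -> list[bytes]:
    out = []
    for i, anns in enumerate(records):
        chunk = f"+{i * record_duration:g}\x14\x14\x00".encode("ascii")
        for ann in anns:
            tal = f"+{ann.onset:g}"
            if ann.duration is not None:
                tal += f"\x15{ann.duration:g}"
            tal += "\x14" + ann.text + "\x14\x00"
            chunk += tal.encode("utf-8")
        out.append(chunk)
    return out


def write_edf(path, edf: EdfFile) -> None:
    """Write signals + annotations as EDF+C with 1-s data records."""
    fs = edf.sampling_rate
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise EdfFormatError("sampling rate must be a positive integer in Hz")
    fs = int(round(fs))
    n_sig, n_samples = edf.signals.shape
    n_records = math.ceil(n_samples / fs)
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, :n_samples] = edf.signals

    # Distribute annotations to the record containing their onset.
    per_record: list[list[EdfAnnotation]] = [[] for _ in range(n_records)]
    for ann in sorted(edf.annotations, key=lambda a: a.onset):
        idx = min(int(ann.onset), n_records - 1)
        per_record[idx].append(ann)
    chunks = _annotation_bytes(per_record, 1.0)
    ann_bytes = max(64, max(len(c) for c in chunks))
    if ann_bytes % 2:
        ann_bytes += 1
    ann_samples = ann_bytes // 2

    pmin, pmax = edf.physical_range
    step = (pmax - pmin) / (DIG_MAX - DIG_MIN)
    ns_total = n_sig + 1
    header_bytes = HEADER_BYTES + SIGNAL_HEADER_BYTES * ns_total

    with open(path, "wb") as fh:
        fh.write(_fixed("0", 8))
        fh.write(_fixed(edf.patient_id, 80))
        fh.write(_fixed(edf.recording_id, 80))
        fh.write(_fixed("01.01.00", 8))
        fh.write(_fixed("00.00.00", 8))
        fh.write(_fixed(str(header_bytes), 8))
        fh.write(_fixed("EDF+C", 44))
        fh.write(_fixed(str(n_records), 8))
        fh.write(_fixed("1", 8))
        fh.write(_fixed(str(ns_total), 4))

        labels = list(edf.labels) + ["EDF Annotations"]
        fh.write(b"".join(_fixed(lab, 16) for lab in labels))
        fh.write(b"".join(_fixed("", 80) for _ in labels))
        dims = ["uV"] * n_sig + [""]
        fh.write(b"".join(_fixed(d, 8) for d in dims))
        fh.write(b"".join(_fmt_num(pmin, 8) for _ in range(n_sig)) + _fmt_num(-1, 8))
        fh.write(b"".join(_fmt_num(pmax, 8) for _ in range(n_sig)) + _fmt_num(1, 8))
        fh.write(b"".join(_fixed(str(DIG_MIN), 8) for _ in labels))
        fh.write(b"".join(_fixed(str(DIG_MAX), 8) for _ in labels))
        fh.write(b"".join(_fixed("", 80) for _ in labels))
        samples_per_record = [fs] * n_sig + [ann_samples]
        fh.write(b"".join(_fixed(str(s), 8) for s in samples_per_record))
        fh.write(b"".join(_fixed("", 32) for _ in labels))

        clipped = np.clip(padded, pmin, pmax)
        digital = np.round((clipped - pmin) / step + DIG_MIN).astype("<i2")
        for rec in range(n_records):
            block = digital[:, rec * fs: (rec + 1) * fs]
            fh.write(block.tobytes())
            chunk = chunks[rec].ljust(ann_bytes, b"\x00")
            fh.write(chunk)


def _parse_tals(raw: bytes, offset_hint: int) -> list[EdfAnnotation]:
    out = []
    for tal in raw.split(b"\x00"):
        tal = tal.strip(b"\x00")
        if not tal:
            continue
        try:
            head, *texts = tal.split(b"\x14")
            if b"\x15" in head:
                onset_b, dur_b = head.split(b"\x15")
                duration = float(dur_b)
            else:
                onset_b, duration = head, None
            onset = float(onset_b)
        except ValueError as exc:
            raise EdfFormatError(
                f"malformed TAL near byte {offset_hint}: {tal[:40]!r}"
            ) from exc
        for text in texts:
            if text:
                out.append(EdfAnnotation(onset=onset, duration=duration,
                                         text=text.decode("utf-8")))
    return out


def read_edf(path) -> EdfFile:
    """Read an EDF/EDF+C file written by :func:`write_edf` (or similar)."""
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise EdfFormatError("truncated header at byte 0")
        try:
            n_records = int(header[236:244].decode("ascii").strip())
            record_duration = float(header[244:252].decode("ascii").strip())
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EdfFormatError("unparseable header fields at byte 236") from exc

        sig_header = fh.read(SIGNAL_HEADER_BYTES * ns)
        if len(sig_header) < SIGNAL_HEADER_BYTES * ns:
            raise EdfFormatError(f"truncated signal header at byte {HEADER_BYTES}")

        def fields(start: int, width: int) -> list[str]:
            base = start * ns
            return [sig_header[base + i * width: base + (i + 1) * width]
                    .decode("ascii", errors="replace").strip()
                    for i in range(ns)]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmins = [int(v) for v in fields(16 + 80 + 8 + 8 + 8, 8)]
        dmaxs = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8, 8)]
        nsamp = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]

        try:
            ann_idx = labels.index("EDF Annotations")
        except ValueError:
            raise EdfFormatError(
                "missing 'EDF Annotations' channel (signal labels start at "
                f"byte {HEADER_BYTES})"
            ) from None

        data_start = HEADER_BYTES + SIGNAL_HEADER_BYTES * ns
        signal_idx = [i for i in range(ns) if i != ann_idx]
        buffers = {i: [] for i in signal_idx}
        annotations: list[EdfAnnotation] = []
        record_bytes = sum(2 * s for s in nsamp)
        for rec in range(n_records):
            raw = fh.read(record_bytes)
            if len(raw) < record_bytes:
                raise EdfFormatError(
                    f"truncated data record {rec} at byte "
                    f"{data_start + rec * record_bytes}"
                )
            offset = 0
            for i in range(ns):
                nbytes = 2 * nsamp[i]
                chunk = raw[offset: offset + nbytes]
                offset += nbytes
                if i == ann_idx:
                    annotations.extend(
                        _parse_tals(chunk, data_start + rec * record_bytes))
                else:
                    dig = np.frombuffer(chunk, dtype="<i2").astype(float)
                    step = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
                    buffers[i].append(pmins[i] + (dig - dmins[i]) * step)

    signals = np.vstack([np.concatenate(buffers[i]) for i in signal_idx])
    fs = nsamp[signal_idx[0]] / record_duration
    # Drop the per-record timekeeping annotations (empty text removed in
    # parsing; timestamp TALs have empty text so never appear here).
    return EdfFile(signals=signals, sampling_rate=fs,
                   labels=[labels[i] for i in signal_idx],
                   annotations=annotations,
                   physical_range=(pmins[signal_idx[0]], pmaxs[signal_idx[0]]))
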