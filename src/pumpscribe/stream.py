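"""ASCII streaming of records: serial-friendly line protocol plus CSV/JSON-lines.

The wire format is a semicolon key-value line terminated CR LF, chosen so
any RS232-style acquisition platform can parse it with a trivial
field-split configuration::

    T=<iso8601>;SEQ=<n>;MED=<name>;DOSE=<value>;UNITS=<units>;REM=<remaining>;LC=<0|1>

Absent fields serialize as empty; a frame with no records emits a
heartbeat packet (all record fields empty) so downstream time series stay
aligned.  Creating the virtual serial port itself (e.g. with a null-modem
emulator) is the operator's job — this module only opens a named
port/file and writes 8-N-1 framed ASCII to it.
"""

from __future__ import annotations

import csv
import io
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .config import StreamParams
from .core import PumpRecord
from .errors import EncodingError, SinkError

__all__ = [
    "StreamPacket",
    "encode_packet",
    "decode_packet",
    "write_stream",
    "open_sink",
    "PacketWriter",
    "CSV_HEADER",
]

TERMINATOR = "\r\n"
CSV_HEADER = "timestamp,sequence,medication,dose_value,dose_units,remaining,low_confidence"


@dataclass(frozen=True)
class StreamPacket:
    """One ASCII line bound for the serial consumer."""

    payload: str
    session_id: str
    sequence: int

    def __post_init__(self) -> None:
        if not self.payload.isascii() or not self.payload.isprintable():
            raise EncodingError("payload must be printable ASCII with no CR/LF")

    @property
    def wire(self) -> str:
        return self.payload + TERMINATOR


def _fmt_number(value: float) -> str:
    """Shortest decimal form: integers print without a trailing '.0'."""
    if value == int(value):
        return str(int(value))
    return repr(value)


def encode_packet(
    record: Optional[PumpRecord],
    sequence: int,
    session_id: str = "",
    timestamp: Optional[str] = None,
) -> StreamPacket:
    """Serialize one record (or a heartbeat when ``record`` is ``None``)."""
    if record is None:
        t = timestamp or ""
        payload = f"T={t};SEQ={sequence};MED=;DOSE=;UNITS=;REM=;LC=0"
        return StreamPacket(payload=payload, session_id=session_id, sequence=sequence)
    med = record.medication
    if not med.isascii():
        raise EncodingError(f"medication name is not ASCII: {med!r}")
    payload = (
        f"T={record.timestamp or (timestamp or '')};SEQ={sequence}"
        f";MED={med}"
        f";DOSE={_fmt_number(record.dose_value)}"
        f";UNITS={record.dose_units or ''}"
        f";REM={record.remaining or ''}"
        f";LC={1 if record.low_confidence else 0}"
    )
    return StreamPacket(payload=payload, session_id=session_id, sequence=sequence)


def decode_packet(line: str) -> tuple[Optional[PumpRecord], int]:
    """Parse one wire line back into ``(record_or_None, sequence)``.

    Total over the packet grammar: every line :func:`encode_packet` emits
    decodes back to an equal record.  ``remaining_kind`` is recovered from
    the field's shape (hh:mm -> time, bare number -> volume).
    """
    line = line.rstrip("\r\n")
    fields = dict(part.split("=", 1) for part in line.split(";"))
    seq = int(fields["SEQ"])
    if not fields.get("MED"):
        return None, seq
    remaining = fields.get("REM") or None
    kind = None
    if remaining is not None:
        kind = "time" if ":" in remaining else "volume"
    return (
        PumpRecord(
            medication=fields["MED"],
            dose_value=float(fields["DOSE"]),
            dose_units=fields.get("UNITS") or None,
            remaining=remaining,
            remaining_kind=kind,
            timestamp=fields.get("T") or None,
            low_confidence=fields.get("LC") == "1",
        ),
        seq,
    )


def _open_with_retries(path: Union[str, Path], p: StreamParams) -> TextIO:
    last: Optional[Exception] = None
    for attempt in range(p.retries + 1):
        try:
            return open(path, "a", encoding="ascii", newline="")
        except OSError as exc:
            last = exc
            if attempt < p.retries:
                time.sleep(p.retry_delay_seconds)
    raise SinkError(f"cannot open sink {path!r} after {p.retries + 1} attempts: {last}")


def write_stream(
    packets: Iterable[StreamPacket],
    sink: Union[str, Path, TextIO],
    params: Optional[StreamParams] = None,
) -> int:
    """Write packets in sequence order to a port path, file path, or stream.

    Asserts strict per-session sequence monotonicity and CRLF termination
    on every write; returns the number of packets written.
    """
    params = params or StreamParams()
    own = False
    if isinstance(sink, (str, Path)):
        fh: TextIO = _open_with_retries(sink, params)
        own = True
    else:
        fh = sink
    last_seq: dict[str, int] = {}
    count = 0
    try:
        for pkt in packets:
            prev = last_seq.get(pkt.session_id)
            if prev is not None and pkt.sequence <= prev:
                raise SinkError(
                    f"sequence not strictly increasing in session "
                    f"{pkt.session_id!r}: {pkt.sequence} after {prev}"
                )
            last_seq[pkt.session_id] = pkt.sequence
            wire = pkt.wire
            assert wire.endswith(TERMINATOR)
            fh.write(wire)
            count += 1
        fh.flush()
    finally:
        if own:
            fh.close()
    return count


class PacketWriter:
    """Stateful per-session writer used by the capture loop.

    A sink spec is ``serial:<port-path>``, ``csv:<path>``,
    ``jsonl:<path>``, a bare file path (serial-style lines), or
    ``stdout``.
    """

    def __init__(
        self,
        sink_spec: str,
        session_id: str = "",
        params: Optional[StreamParams] = None,
    ):
        self.params = params or StreamParams()
        self.session_id = session_id
        self._seq = 0
        self.kind, self._fh = self._open(sink_spec)
        if self.kind == "csv" and self._fh.tell() == 0:
            self._fh.write(CSV_HEADER + "\r\n")

    def _open(self, spec: str):
        if spec == "stdout":
            return "serial", sys.stdout
        kind, _, path = spec.partition(":")
        if kind not in ("serial", "csv", "jsonl") or not path:
            kind, path = "serial", spec
        fh = _open_with_retries(path, self.params)
        return kind, fh

    @property
    def sequence(self) -> int:
        return self._seq

    def emit(self, records: Sequence[PumpRecord], timestamp: str) -> list[StreamPacket]:
        """Emit one packet per record, or a heartbeat when there are none."""
        packets = []
        items: Sequence[Optional[PumpRecord]] = records if records else [None]
        for rec in items:
            self._seq += 1
            pkt = encode_packet(rec, self._seq, self.session_id, timestamp=timestamp)
            packets.append(pkt)
            if self.kind == "serial":
                self._fh.write(pkt.wire)
            elif self.kind == "csv":
                row = io.StringIO()
                w = csv.writer(row, lineterminator="")
                if rec is None:
                    w.writerow([timestamp, self._seq, "", "", "", "", 0])
                else:
                    w.writerow(
                        [
                            rec.timestamp or timestamp,
                            self._seq,
                            rec.medication,
                            _fmt_number(rec.dose_value),
                            rec.dose_units or "",
                            rec.remaining or "",
                            1 if rec.low_confidence else 0,
                        ]
                    )
                self._fh.write(row.getvalue() + "\r\n")
            else:  # jsonl
                obj = {"timestamp": timestamp, "sequence": self._seq}
                if rec is not None:
                    obj.update(
                        medication=rec.medication,
                        dose_value=rec.dose_value,
                        dose_units=rec.dose_units,
                        remaining=rec.remaining,
                        remaining_kind=rec.remaining_kind,
                        low_confidence=rec.low_confidence,
                    )
                self._fh.write(json.dumps(obj) + "\n")
        self._fh.flush()
        return packets

    def close(self) -> None:
        if self._fh is not sys.stdout:
            self._fh.close()
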