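"""Minimal Standard MIDI File reader/writer.

Supports exactly what the package needs: monophonic-or-light-polyphonic
note data in format 0 or 1 files, with tempo and time-signature meta
events. Writing produces a single-track format 0 file at a fixed tick
resolution; reading merges all tracks, honours running status, and pairs
note-on/note-off events per (channel, pitch).

Times are exchanged with callers in beats (quarter notes); the tick
resolution (default 480 ticks/beat) bounds round-trip error.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from .errors import FormatError

DEFAULT_TICKS_PER_BEAT = 480


@dataclass(frozen=True)
class MidiNote:
    pitch: int
    onset_beats: float
    duration_beats: float
    velocity: int


@dataclass
class MidiData:
    """Decoded contents of one SMF: notes plus tempo/meter."""

    notes: list[MidiNote]
    tempo_bpm: float = 120.0
    numerator: int = 4
    denominator: int = 4
    ticks_per_beat: int = DEFAULT_TICKS_PER_BEAT


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise FormatError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise FormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise FormatError("variable-length quantity longer than 4 bytes")


def write_midi_file(md: MidiData, path) -> None:
    """Write a format-0 SMF with one track holding all notes."""
    tpb = md.ticks_per_beat
    events: list[tuple[int, int, bytes]] = []  # (tick, priority, payload)

    # meta: tempo (microseconds per quarter) and time signature at tick 0
    mpq = int(round(60_000_000 / md.tempo_bpm))
    events.append((0, 0, b"\xff\x51\x03" + mpq.to_bytes(3, "big")))
    denom_pow = max(0, int(md.denominator).bit_length() - 1)
    events.append((0, 0, b"\xff\x58\x04" + bytes([md.numerator, denom_pow, 24, 8])))

    for note in md.notes:
        if not 0 <= note.pitch <= 127:
            raise FormatError(f"pitch {note.pitch} outside MIDI range")
        vel = min(127, max(1, int(round(note.velocity))))
        on = int(round(note.onset_beats * tpb))
        off = int(round((note.onset_beats + note.duration_beats) * tpb))
        if off <= on:
            off = on + 1  # a note must sound for at least one tick
        events.append((on, 2, bytes([0x90, note.pitch, vel])))
        events.append((off, 1, bytes([0x80, note.pitch, 0])))

    # note-offs sort before note-ons at the same tick so repeated pitches chain
    events.sort(key=lambda e: (e[0], e[1]))

    track = bytearray()
    prev_tick = 0
    for tick, _, payload in events:
        track += _write_varlen(tick - prev_tick)
        track += payload
        prev_tick = tick
    track += _write_varlen(0) + b"\xff\x2f\x00"  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, tpb))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def read_midi_file(path) -> MidiData:
    """Read a format 0 or 1 SMF; merges all tracks."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:4] != b"MThd":
        raise FormatError(f"{path}: not a Standard MIDI File (missing MThd)")
    hlen, fmt, ntracks, division = struct.unpack(">IHHH", blob[4:14])
    if fmt not in (0, 1):
        raise FormatError(f"{path}: unsupported SMF format {fmt}")
    if division & 0x8000:
        raise FormatError(f"{path}: SMPTE time division not supported")
    tpb = division
    pos = 8 + hlen

    tempo_bpm = 120.0
    numerator, denominator = 4, 4
    notes: list[MidiNote] = []

    for _ in range(ntracks):
        if blob[pos : pos + 4] != b"MTrk":
            raise FormatError(f"{path}: expected MTrk chunk")
        (tlen,) = struct.unpack(">I", blob[pos + 4 : pos + 8])
        data = blob[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen

        tick = 0
        p = 0
        status = 0
        active: dict[tuple[int, int], tuple[int, int]] = {}  # (ch, pitch) -> (tick, vel)
        while p < len(data):
            delta, p = _read_varlen(data, p)
            tick += delta
            byte = data[p]
            if byte & 0x80:
                status = byte
                p += 1
            if status == 0xFF:  # meta
                mtype = data[p]
                length, p2 = _read_varlen(data, p + 1)
                payload = data[p2 : p2 + length]
                p = p2 + length
                if mtype == 0x51 and length == 3:
                    tempo_bpm = 60_000_000 / int.from_bytes(payload, "big")
                elif mtype == 0x58 and length >= 2:
                    numerator = payload[0]
                    denominator = 2 ** payload[1]
                elif mtype == 0x2F:
                    break
                continue
            if status in (0xF0, 0xF7):  # sysex
                length, p2 = _read_varlen(data, p)
                p = p2 + length
                continue
            kind = status & 0xF0
            ch = status & 0x0F
            if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                d1, d2 = data[p], data[p + 1]
                p += 2
            elif kind in (0xC0, 0xD0):
                p += 1
                continue
            else:
                raise FormatError(f"{path}: unexpected status byte 0x{status:02x}")
            if kind == 0x90 and d2 > 0:
                active[(ch, d1)] = (tick, d2)
            elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                started = active.pop((ch, d1), None)
                if started is not None:
                    on_tick, vel = started
                    notes.append(
                        MidiNote(
                            pitch=d1,
                            onset_beats=on_tick / tpb,
                            duration_beats=(tick - on_tick) / tpb,
                            velocity=vel,
                        )
                    )

    notes.sort(key=lambda n: (n.onset_beats, n.pitch))
    return MidiData(
        notes=notes,
        tempo_bpm=tempo_bpm,
        numerator=numerator,
        denominator=denominator,
        ticks_per_beat=tpb,
    )
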