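"""Minimal reader/writer for the PhysioNet WFDB file family.

Supports the subset the MIT-BIH arrhythmia database uses: ``.hea`` headers,
``.dat`` signal files in formats 212 (packed 12-bit pairs) and 16
(little-endian int16), and MIT-format ``.atr`` beat annotations.  Samples
are returned in physical units, (adc − baseline) / gain.

The writer exists so records can be synthesized programmatically for tests
and demos; it emits the same subset the reader consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = ["SignalInfo", "read_record", "read_annotations", "write_record", "write_annotations"]

# WFDB annotation code -> mnemonic symbol (ecgcodes table).
CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {v: k for k, v in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


def _parse_gain_field(field: str) -> tuple[float, int | None, str]:
    units = "mV"
    if "/" in field:
        field, units = field.split("/", 1)
    baseline = None
    if "(" in field:
        field, rest = field.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(field) if field else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_header(header_path) -> tuple[str, int, float, int, list[SignalInfo]]:
    lines = []
    with open(header_path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    first = lines[0].split()
    record_name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0
    signals = []
    for line in lines[1 : 1 + n_sig]:
        tok = line.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = _parse_gain_field(tok[2]) if len(tok) > 2 else (200.0, None, "mV")
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else ""
        signals.append(SignalInfo(tok[0], fmt, gain, baseline, units, description))
    return record_name, n_sig, fs, n_samples, signals


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint32)
    first, second = v[0::2], v[1::2]
    out = np.empty((first.size, 3), dtype=np.uint8)
    out[:, 0] = first & 0xFF
    out[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
    out[:, 2] = second & 0xFF
    return out.tobytes()


def read_record(record_path) -> tuple[np.ndarray, float, list[SignalInfo]]:
    """Read `<record_path>.hea` + its .dat file(s).

    Returns (signal matrix of shape (n_samples, n_sig) in physical units,
    sampling frequency, per-signal metadata).  All signals must share one
    .dat file (the MIT-BIH layout).
    """
    record_path = os.fspath(record_path)
    _name, n_sig, fs, n_samples, signals = read_header(record_path + ".hea")
    if n_sig == 0:
        return np.zeros((0, 0)), fs, signals
    dat_files = {s.file_name for s in signals}
    if len(dat_files) != 1:
        raise NotImplementedError("multi-.dat records are not supported")
    fmt = signals[0].fmt
    dat_path = os.path.join(os.path.dirname(record_path), signals[0].file_name)
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    if fmt == 212:
        flat = _decode_212(raw, n_samples * n_sig if n_samples else (len(raw) // 3) * 2)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if n_samples:
            flat = flat[: n_samples * n_sig]
    else:
        raise NotImplementedError(f"signal format {fmt} not supported (only 212 and 16)")
    n_samples = flat.size // n_sig
    adc = flat[: n_samples * n_sig].reshape(n_samples, n_sig)
    phys = np.empty(adc.shape, dtype=np.float64)
    for j, s in enumerate(signals):
        phys[:, j] = (adc[:, j] - s.baseline) / s.gain
    return phys, fs, signals


def read_annotations(path) -> tuple[np.ndarray, list[str]]:
    """Read an MIT-format annotation file; returns (sample indices, symbols).

    Non-beat bookkeeping words (NUM/SUB/CHN/AUX/SKIP) are consumed but only
    annotations with a known mnemonic are emitted.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    times: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw) or (i + 1 == len(raw)):
        if i + 2 > len(raw):
            break
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break  # EOF marker
        if code == _SKIP:
            if i + 4 > len(raw):
                break
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            pending_skip = (high << 16) | low
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        t += interval + pending_skip
        pending_skip = 0
        sym = CODE_TO_SYMBOL.get(code)
        if sym is not None:
            times.append(t)
            symbols.append(sym)
    return np.asarray(times, dtype=np.int64), symbols


def write_record(
    record_path,
    signal: np.ndarray,
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
    fmt: int = 212,
    descriptions: list[str] | None = None,
) -> None:
    """Write a physical-units signal matrix as a `.hea` + `.dat` pair."""
    record_path = os.fspath(record_path)
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim == 1:
        signal = signal[:, None]
    n_samples, n_sig = signal.shape  # caller supplies (n_samples, n_sig)
    record_name = os.path.basename(record_path)
    adc = np.rint(signal * gain + baseline).astype(np.int32)
    if fmt == 212 and (adc.min() < -2048 or adc.max() > 2047):
        raise ValueError("signal exceeds the 12-bit range of format 212")
    dat_name = record_name + ".dat"
    with open(record_path + ".hea", "w") as fh:
        fh.write(f"{record_name} {n_sig} {fs:g} {n_samples}\n")
        for j in range(n_sig):
            desc = (descriptions or [f"sig{j}" for j in range(n_sig)])[j]
            fh.write(f"{dat_name} {fmt} {gain:g}({baseline})/mV 12 {baseline} 0 0 0 {desc}\n")
    flat = adc.reshape(-1)  # sample-interleaved
    with open(os.path.join(os.path.dirname(record_path), dat_name), "wb") as fh:
        if fmt == 212:
            fh.write(_encode_212(flat))
        elif fmt == 16:
            fh.write(flat.astype("<i2").tobytes())
        else:
            raise NotImplementedError(f"signal format {fmt} not supported")


def write_annotations(path, times: np.ndarray, symbols: list[str]) -> None:
    """Write MIT-format annotations (times strictly increasing)."""
    times = np.asarray(times, dtype=np.int64)
    if len(times) != len(symbols):
        raise ValueError("times and symbols must have equal length")
    out = bytearray()
    prev = 0
    for t, sym in zip(times, symbols):
        code = SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"unknown annotation symbol {sym!r}")
        delta = int(t) - prev
        if delta < 0:
            raise ValueError("annotation times must be nondecreasing")
        if delta > 1023:
            # SKIP word (code 59, interval 0) followed by the 32-bit interval,
            # high 16-bit word first, each word little-endian
            skip_word = _SKIP << 10
            out += bytes([skip_word & 0xFF, (skip_word >> 8) & 0xFF])
            out += bytes([(delta >> 16) & 0xFF, (delta >> 24) & 0xFF, delta & 0xFF, (delta >> 8) & 0xFF])
            delta = 0
        word = (code << 10) | delta
        out += bytes([word & 0xFF, (word >> 8) & 0xFF])
        prev = int(t)
    out += b"\x00\x00"  # EOF
    with open(path, "wb") as fh:
        fh.write(bytes(out))
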