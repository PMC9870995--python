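"""EDF (16-bit) and BDF (24-bit) reading and writing.

A deliberately small reader/writer for the subset of the formats this
pipeline needs: continuous recordings, one sampling rate for all channels,
physical units microvolts, 1-second data records.  Signals that do not
fill a whole number of records are zero-padded on write.
"""

from __future__ import annotations

import os

import numpy as np

from .montage import _POSITIONS, standard_positions
from .preprocess import Recording

__all__ = ["read_recording", "write_edf", "write_bdf", "FileFormatError"]

_EDF_DIG = (-32768, 32767)
_BDF_DIG = (-8388608, 8388607)


class FileFormatError(ValueError):
    pass


def _fmt(value, width: int) -> bytes:
    s = f"{value:.6g}" if isinstance(value, float) else str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write(path: str, rec: Recording, bdf: bool) -> None:
    fs = rec.sample_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise FileFormatError("sample rate must be an integer for 1 s records")
    ns = rec.n_channels
    data = rec.signals
    n_records = int(np.ceil(rec.n_samples / spr))
    pad = n_records * spr - rec.n_samples
    if pad:
        data = np.pad(data, ((0, 0), (0, pad)))

    dig_min, dig_max = _BDF_DIG if bdf else _EDF_DIG
    phys_ranges = []
    for ch in range(ns):
        pm = max(np.max(np.abs(data[ch])), 1e-6) * 1.0001
        # parse back the truncated ascii so scaling matches the header
        lo = float(_fmt(-pm, 8).decode())
        hi = float(_fmt(pm, 8).decode())
        phys_ranges.append((lo, hi))

    header = bytearray()
    if bdf:
        header += b"\xffBIOSEMI"
    else:
        header += _fmt("0", 8)
    header += _fmt("", 80) + _fmt("", 80)
    header += _fmt("01.01.00", 8) + _fmt("00.00.00", 8)
    header += _fmt(256 * (1 + ns), 8)
    header += _fmt("24BIT" if bdf else "", 44)
    header += _fmt(n_records, 8) + _fmt("1", 8) + _fmt(ns, 4)
    for lab in rec.channel_labels:
        header += _fmt(lab, 16)
    header += _fmt("", 80) * ns
    header += _fmt("uV", 8) * ns
    for lo, _ in phys_ranges:
        header += _fmt(lo, 8)
    for _, hi in phys_ranges:
        header += _fmt(hi, 8)
    header += _fmt(dig_min, 8) * ns + _fmt(dig_max, 8) * ns
    header += _fmt("", 80) * ns
    header += _fmt(spr, 8) * ns
    header += _fmt("", 32) * ns
    assert len(header) == 256 * (1 + ns)

    digital = np.empty_like(data, dtype=np.int32)
    for ch, (lo, hi) in enumerate(phys_ranges):
        gain = (dig_max - dig_min) / (hi - lo)
        digital[ch] = np.clip(np.round((data[ch] - lo) * gain + dig_min),
                              dig_min, dig_max).astype(np.int32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            if bdf:
                u = block.astype("<i4").view(np.uint8).reshape(ns, spr, 4)
                fh.write(u[:, :, :3].tobytes())
            else:
                fh.write(block.astype("<i2").tobytes())


def write_edf(rec: Recording, path: str) -> None:
    """Write a recording as 16-bit EDF (quantization ~ phys range / 65535)."""
    _write(path, rec, bdf=False)


def write_bdf(rec: Recording, path: str) -> None:
    """Write a recording as 24-bit BDF (full BioSemi resolution)."""
    _write(path, rec, bdf=True)


def _ascii(buf: bytes) -> str:
    return buf.decode("ascii", errors="replace").strip()


def read_recording(path: str) -> Recording:
    """Read an EDF or BDF file into a Recording (signals in microvolts)."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic == b"\xffBIOSEMI":
            bdf, dig = True, _BDF_DIG
        elif magic[:1] == b"0":
            bdf, dig = False, _EDF_DIG
        else:
            raise FileFormatError(
                f"{path}: not an EDF/BDF file (bad version field {magic!r})")
        fh.read(80 + 80 + 8 + 8)
        header_bytes = int(_ascii(fh.read(8)))
        fh.read(44)
        n_records = int(_ascii(fh.read(8)))
        record_dur = float(_ascii(fh.read(8)))
        ns = int(_ascii(fh.read(4)))
        if header_bytes != 256 * (1 + ns):
            raise FileFormatError(f"{path}: corrupt header size field")

        def field(width: int) -> list[str]:
            return [_ascii(fh.read(width)) for _ in range(ns)]

        labels = field(16)
        field(80)  # transducer
        field(8)   # physical dimension
        phys_min = [float(v) for v in field(8)]
        phys_max = [float(v) for v in field(8)]
        dig_min = [int(float(v)) for v in field(8)]
        dig_max = [int(float(v)) for v in field(8)]
        field(80)  # prefiltering
        spr = [int(v) for v in field(8)]
        field(32)

        if len(set(spr)) != 1:
            raise FileFormatError(f"{path}: mixed per-channel sample rates "
                                  "are not supported")
        spr = spr[0]
        bps = 3 if bdf else 2
        expected = header_bytes + n_records * ns * spr * bps
        if size < expected:
            raise FileFormatError(
                f"{path}: truncated data section ({size} bytes, "
                f"expected {expected})")

        raw = fh.read(n_records * ns * spr * bps)

    if bdf:
        u = np.frombuffer(raw, dtype=np.uint8).reshape(n_records, ns, spr, 3)
        vals = (u[..., 0].astype(np.int32)
                | (u[..., 1].astype(np.int32) << 8)
                | (u[..., 2].astype(np.int32) << 16))
        vals = np.where(vals >= 1 << 23, vals - (1 << 24), vals)
    else:
        vals = np.frombuffer(raw, dtype="<i2").reshape(n_records, ns, spr)
    digital = np.transpose(vals, (1, 0, 2)).reshape(ns, -1).astype(float)

    signals = np.empty_like(digital)
    for ch in range(ns):
        gain = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
        signals[ch] = (digital[ch] - dig_min[ch]) * gain + phys_min[ch]
    if dig != (dig_min[0], dig_max[0]):
        pass  # non-default digital range is fine; scaling above is generic

    positions = None
    if all(lab in _POSITIONS for lab in labels):
        positions = standard_positions(labels)
    return Recording(signals=signals, sample_rate=spr / record_dur,
                     channel_labels=labels, positions=positions)
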