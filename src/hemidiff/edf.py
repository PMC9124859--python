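"""A minimal EDF+ writer for simulated recordings.

Writes continuous 16-bit EDF+ files with one annotation channel carrying the
task cues (T1-T4) and rest markers as time-stamped annotation lists (TALs).
Per-channel physical ranges are set symmetrically from the data, so the
round-trip error is the format's 16-bit quantisation step.  Reading is done
with mne (:func:`hemidiff.preprocess.read_edf`).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .preprocess import RawRecording

__all__ = ["write_edf"]

_ANNOT_SAMPLES = 60  # 2-byte samples reserved for TALs per data record


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _physical_max(amax: float) -> tuple[float, str]:
    """Round ``amax`` up to a value whose decimal form fits 7 characters.

    Returns the value together with its exact header string, so the digital
    scale can be computed from what is actually written.
    """
    if amax == 0.0:
        return 1.0, "1"
    for digits in (5, 4, 3, 2, 1):
        exp = math.floor(math.log10(amax))
        factor = 10.0 ** (exp - digits + 1)
        value = math.ceil(amax / factor) * factor
        s = f"{value:.{digits}g}"
        if len(s) <= 7 and float(s) >= amax:
            return float(s), s
    raise ValueError(f"cannot encode physical range {amax!r} in EDF header")


def write_edf(path, raw: RawRecording, record_s: float = 1.0) -> None:
    """Write ``raw`` (volts) to ``path`` as an EDF+ file.

    The recording is padded with zeros to a whole number of ``record_s``
    data records.  Annotations are emitted in the record containing their
    onset.
    """
    if abs(raw.fs * record_s - round(raw.fs * record_s)) > 1e-9:
        raise ValueError("fs * record_s must be an integer sample count")
    spr = int(round(raw.fs * record_s))  # samples per record per channel
    n_chan, n_times = raw.samples.shape
    n_records = max(1, math.ceil(n_times / spr))
    data_uv = raw.samples * 1e6  # store in microvolts

    ranges = [_physical_max(float(np.max(np.abs(ch))) * 1.0001)
              for ch in data_uv]
    pmax = np.array([v for v, _ in ranges])
    pmax_str = [s for _, s in ranges]
    dmin, dmax = -32768, 32767
    scale = pmax / dmax
    digital = np.clip(np.round(data_uv / scale[:, None]), dmin, dmax).astype("<i2")
    if n_records * spr > n_times:
        pad = np.zeros((n_chan, n_records * spr - n_times), dtype="<i2")
        digital = np.concatenate([digital, pad], axis=1)

    ns = n_chan + 1  # + annotation channel
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (ns + 1), 8),
        _field("EDF+C", 44),
        _field(n_records, 8),
        _field(f"{record_s:g}", 8),
        _field(ns, 4),
    ])

    labels = [_field(name, 16) for name in raw.channel_names]
    labels.append(_field("EDF Annotations", 16))
    transducers = [_field("", 80)] * ns
    dims = [_field("uV", 8)] * n_chan + [_field("", 8)]
    pmins = [_field(f"-{s}", 8) for s in pmax_str] + [_field(-1, 8)]
    pmaxs = [_field(s, 8) for s in pmax_str] + [_field(1, 8)]
    dmins = [_field(dmin, 8)] * ns
    dmaxs = [_field(dmax, 8)] * ns
    prefilt = [_field("", 80)] * ns
    nsamps = [_field(spr, 8)] * n_chan + [_field(_ANNOT_SAMPLES, 8)]
    reserved = [_field("", 32)] * ns
    signal_header = b"".join(
        b"".join(block) for block in
        (labels, transducers, dims, pmins, pmaxs, dmins, dmaxs, prefilt,
         nsamps, reserved)
    )

    # Assign each annotation to the data record containing its onset.
    per_record: dict[int, list[bytes]] = {}
    for onset, duration, code in raw.annotations:
        rec = min(int(onset / record_s), n_records - 1)
        tal = (f"+{onset:g}\x15{duration:g}\x14{code}\x14\x00").encode("ascii")
        per_record.setdefault(rec, []).append(tal)

    with open(Path(path), "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            fh.write(digital[:, sl].tobytes(order="C"))
            tal = (f"+{rec * record_s:g}\x14\x14\x00").encode("ascii")
            tal += b"".join(per_record.get(rec, []))
            if len(tal) > 2 * _ANNOT_SAMPLES:
                raise ValueError(
                    f"annotations in record {rec} exceed the reserved "
                    f"{2 * _ANNOT_SAMPLES} bytes"
                )
            fh.write(tal.ljust(2 * _ANNOT_SAMPLES, b"\x00"))
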