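"""Readers and writers: BrainVision, EDF, and plain-text event files.

Event files hold one 0-based sample index per line; blank lines and lines
starting with ``#`` are ignored.

The BrainVision reader/writer covers the multiplexed binary layout with
IEEE_FLOAT_32 or INT_16 data and microvolt units; the EDF reader/writer covers
plain continuous EDF with a common sampling rate across signals.  Both are
sufficient for round-tripping recordings produced by this package and for
typical exported scalp-EEG files.
"""

from __future__ import annotations

import configparser
import datetime as _dt
import warnings
from pathlib import Path

import numpy as np

from .events import EEGRecording, RPeakSeries

__all__ = [
    "read_events",
    "write_events",
    "read_brainvision",
    "write_brainvision",
    "read_edf",
    "write_edf",
    "read_recording",
]


# -- events -----------------------------------------------------------------

def read_events(path, fs: float) -> RPeakSeries:
    """Read R-peak sample indices (one 0-based integer per line)."""
    indices = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            indices.append(int(line))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a sample index: {line!r}") from exc
    return RPeakSeries(indices=np.asarray(indices, dtype=np.int64), fs=fs)


def write_events(path, rpeaks: RPeakSeries) -> None:
    lines = ["# R-peak sample indices (0-based)"]
    lines += [str(int(i)) for i in rpeaks.indices]
    Path(path).write_text("\n".join(lines) + "\n")


# -- BrainVision ------------------------------------------------------------

def write_brainvision(path_vhdr, rec: EEGRecording, rpeaks: RPeakSeries | None = None) -> None:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE_FLOAT_32 multiplexed)."""
    vhdr = Path(path_vhdr)
    stem = vhdr.with_suffix("")
    eeg_name, vmrk_name = stem.name + ".eeg", stem.name + ".vmrk"
    n_ch = rec.n_channels
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.labels, 1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    if rpeaks is not None:
        for j, idx in enumerate(rpeaks.indices, 2):
            mlines.append(f"Mk{j}=Response,R Peak,{int(idx) + 1},1,0")
    stem.with_suffix(".vmrk").write_text("\n".join(mlines) + "\n", encoding="utf-8")

    data32 = rec.data.T.astype("<f4")  # multiplexed: sample-major
    data32.tofile(stem.with_suffix(".eeg"))


def _parse_vhdr(path_vhdr) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str  # keep key case
    text = Path(path_vhdr).read_text(encoding="utf-8", errors="replace")
    # strip the magic first line, keep sections
    body = "\n".join(l for l in text.splitlines() if not l.startswith("Brain Vision"))
    cp.read_string(body)
    return cp


def read_brainvision(path_vhdr) -> tuple[EEGRecording, np.ndarray | None]:
    """Read a BrainVision triplet; returns (recording, R-peak indices or None).

    R peaks are collected from markers whose description contains ``R Peak``
    (marker positions are 1-based).
    """
    vhdr = Path(path_vhdr)
    cp = _parse_vhdr(vhdr)
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("only BINARY BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    binfmt = cp["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32")
    labels, scales = [], []
    for i in range(1, n_ch + 1):
        parts = cp["Channel Infos"][f"Ch{i}"].split(",")
        labels.append(parts[0])
        scales.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    eeg_path = vhdr.parent / common["DataFile"]
    if binfmt == "IEEE_FLOAT_32":
        raw = np.fromfile(eeg_path, dtype="<f4")
    elif binfmt == "INT_16":
        raw = np.fromfile(eeg_path, dtype="<i2").astype(np.float64)
    else:
        raise ValueError(f"unsupported BinaryFormat: {binfmt}")
    if raw.size % n_ch:
        raise ValueError("data file size is not a multiple of the channel count")
    data = raw.reshape(-1, n_ch).T.astype(np.float64)
    data *= np.asarray(scales)[:, None]
    rec = EEGRecording(data=data, fs=fs, labels=labels, stage="raw")

    rpeaks = None
    vmrk = vhdr.parent / common.get("MarkerFile", "")
    if common.get("MarkerFile") and vmrk.exists():
        idx = []
        for line in vmrk.read_text(encoding="utf-8", errors="replace").splitlines():
            if line.startswith("Mk") and "=" in line:
                fields = line.split("=", 1)[1].split(",")
                if len(fields) >= 3 and "R Peak" in fields[1]:
                    idx.append(int(fields[2]) - 1)
        if idx:
            rpeaks = np.asarray(sorted(idx), dtype=np.int64)
    return rec, rpeaks


# -- EDF --------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EEGRecording) -> None:
    """Write a continuous EDF file (int16, 1-second data records)."""
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-6:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(rec.n_samples / spr))
    n_ch = rec.n_channels
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin == 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (n_ch + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    sig = b""
    for lab in rec.labels:
        sig += _edf_field(lab, 16)
    sig += b"".join(_edf_field("", 80) for _ in range(n_ch))
    sig += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    sig += b"".join(_edf_field(f"{pmin[c]:.6g}"[:8], 8) for c in range(n_ch))
    sig += b"".join(_edf_field(f"{pmax[c]:.6g}"[:8], 8) for c in range(n_ch))
    sig += b"".join(_edf_field(str(dmin), 8) for _ in range(n_ch))
    sig += b"".join(_edf_field(str(dmax), 8) for _ in range(n_ch))
    sig += b"".join(_edf_field("", 80) for _ in range(n_ch))
    sig += b"".join(_edf_field(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_edf_field("", 32) for _ in range(n_ch))

    # physical min/max re-read from their 8-char ascii form, so that the
    # round trip uses exactly the stored calibration
    pmin_r = np.array([float(f"{pmin[c]:.6g}"[:8]) for c in range(n_ch)])
    pmax_r = np.array([float(f"{pmax[c]:.6g}"[:8]) for c in range(n_ch)])
    gain = (pmax_r - pmin_r) / (dmax - dmin)
    digital = np.round((padded - pmin_r[:, None]) / gain[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> EEGRecording:
    """Read a continuous EDF file with a common sampling rate across signals."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        n_rec = int(hdr[236:244].decode("ascii").strip())
        rec_dur = float(hdr[244:252].decode("ascii").strip())
        n_ch = int(hdr[252:256].decode("ascii").strip())

        def fields(width: int) -> list[str]:
            raw = fh.read(width * n_ch)
            return [
                raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
                for i in range(n_ch)
            ]

        labels = fields(16)
        fields(80)  # transducer
        fields(8)  # unit
        pmin = np.array([float(v) for v in fields(8)])
        pmax = np.array([float(v) for v in fields(8)])
        dmin = np.array([float(v) for v in fields(8)])
        dmax = np.array([float(v) for v in fields(8)])
        fields(80)  # prefiltering
        spr = [int(v) for v in fields(8)]
        fields(32)  # reserved
        if len(set(spr)) != 1:
            raise ValueError("EDF reader requires a common sampling rate")
        spr0 = spr[0]
        fs = spr0 / rec_dur
        counts = np.fromfile(fh, dtype="<i2", count=n_rec * n_ch * spr0)
    if counts.size != n_rec * n_ch * spr0:
        warnings.warn("EDF data shorter than header declares; truncating", stacklevel=2)
        n_rec = counts.size // (n_ch * spr0)
        counts = counts[: n_rec * n_ch * spr0]
    counts = counts.reshape(n_rec, n_ch, spr0)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (counts - dmin[None, :, None]) * gain[None, :, None] + pmin[None, :, None]
    data = data.transpose(1, 0, 2).reshape(n_ch, -1)
    return EEGRecording(data=data, fs=fs, labels=labels, stage="raw")


def read_recording(path) -> tuple[EEGRecording, np.ndarray | None]:
    """Dispatch on extension: .vhdr -> BrainVision, .edf -> EDF."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".vhdr":
        return read_brainvision(p)
    if suffix == ".edf":
        return read_edf(p), None
    raise ValueError(f"unsupported recording format: {suffix!r} (use .vhdr or .edf)")
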