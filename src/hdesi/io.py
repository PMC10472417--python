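"""File I/O: .sfp electrode files, EDF recordings, events TSV, and the HDF5
lead-field container.

The EDF codec is a deliberately minimal implementation of the classic
European Data Format (ASCII headers, 2-byte little-endian samples, one
physical range per signal): no EDF library is available in the target
environment, and the pipeline only needs faithful round trips of its own
uniform-rate recordings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .forward import ElectrodeArray, LeadField, SourceGrid, ThreeShellHeadModel
from .simulate import SimulatedRecording

__all__ = [
    "read_sfp",
    "write_sfp",
    "read_edf",
    "write_edf",
    "read_events_tsv",
    "write_events_tsv",
    "save_leadfield_h5",
    "load_leadfield_h5",
]

_FID_LABELS = {"FidNz": "nasion", "FidT9": "lpa", "FidT10": "rpa"}
_FID_ORDER = ["FidNz", "FidT9", "FidT10"]


def write_sfp(array: ElectrodeArray, path) -> None:
    """Whitespace text: label x y z (mm), fiducials first as FidNz/FidT9/FidT10."""
    lines = []
    inv = {v: k for k, v in _FID_LABELS.items()}
    for key in ["nasion", "lpa", "rpa"]:
        if key in array.fiducials:
            x, y, z = array.fiducials[key]
            lines.append(f"{inv[key]}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
    for cid, (x, y, z) in zip(array.channel_ids, array.positions):
        lines.append(f"{cid}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfp(path, scalp_radius_mm: float | None = None) -> ElectrodeArray:
    ids, pos, fids = [], [], {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 'label x y z', got {line!r}")
        label = parts[0]
        try:
            xyz = np.array([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-numeric coordinate") from exc
        if label in _FID_LABELS:
            fids[_FID_LABELS[label]] = xyz
        else:
            ids.append(label)
            pos.append(xyz)
    if not ids:
        raise FormatError(f"{path}: no electrode rows")
    pos = np.asarray(pos)
    if scalp_radius_mm is None:
        scalp_radius_mm = float(np.median(np.linalg.norm(pos, axis=1)))
    return ElectrodeArray(tuple(ids), pos, fids, scalp_radius_mm)


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: SimulatedRecording, path) -> None:
    """16-bit EDF with 1-second data records, physical dimension uV.

    The last partial second, if any, is zero-padded; the physical range is the
    symmetric data extremum, so quantization error is <= range / 2^15.
    """
    rate = recording.sampling_rate_Hz
    if rate != int(rate) or rate <= 0:
        raise ParameterError("EDF export needs a positive integer sampling rate")
    rate = int(rate)
    n_ch, n_samp = recording.data.shape
    n_records = int(np.ceil(n_samp / rate))
    padded = np.zeros((n_ch, n_records * rate))
    padded[:, :n_samp] = recording.data

    phys_max = float(np.max(np.abs(padded)))
    phys_max = phys_max if phys_max > 0 else 1.0
    dig_max, dig_min = 32767, -32768
    scale = phys_max / dig_max
    digital = np.clip(np.round(padded / scale), dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        (16, list(recording.channel_ids)),
        (80, ["simulated EEG"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{-phys_max:.6g}"] * n_ch),
        (8, [f"{phys_max:.6g}"] * n_ch),
        (8, [dig_min] * n_ch),
        (8, [dig_max] * n_ch),
        (80, [""] * n_ch),
        (8, [rate] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            block = digital[:, rec * rate : (rec + 1) * rate]
            fh.write(block.tobytes())


def read_edf(path) -> SimulatedRecording:
    """Read an EDF file written by :func:`write_edf` (uniform rate, uV)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header ({len(raw)} bytes)")
    try:
        header_bytes = int(raw[184:192].decode("ascii").strip())
        n_records = int(raw[236:244].decode("ascii").strip())
        record_dur = float(raw[244:252].decode("ascii").strip())
        n_ch = int(raw[252:256].decode("ascii").strip())
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: malformed EDF fixed header") from exc
    if len(raw) < header_bytes or header_bytes != 256 * (1 + n_ch):
        raise FormatError(f"{path}: header length field inconsistent")

    def sig_field(offset: int, width: int, conv):
        base = 256 + offset
        out = []
        for c in range(n_ch):
            cell = raw[base + c * width : base + (c + 1) * width]
            try:
                out.append(conv(cell.decode("ascii").strip()))
            except (ValueError, UnicodeDecodeError) as exc:
                raise FormatError(f"{path}: malformed signal header field") from exc
        return out

    labels = sig_field(0, 16, str)
    off = 0
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8]
    cursor = {}
    for name, w in zip(
        ["label", "transducer", "dim", "pmin", "pmax", "dmin", "dmax", "prefilter", "spr"],
        widths,
    ):
        cursor[name] = off
        off += w * n_ch
    phys_min = sig_field(cursor["pmin"], 8, float)
    phys_max = sig_field(cursor["pmax"], 8, float)
    dig_min = sig_field(cursor["dmin"], 8, int)
    dig_max = sig_field(cursor["dmax"], 8, int)
    spr = sig_field(cursor["spr"], 8, int)
    if len(set(spr)) != 1:
        raise FormatError(f"{path}: mixed per-signal rates are not supported")
    rate = spr[0] / record_dur

    expected = header_bytes + n_records * sum(spr) * 2
    if len(raw) < expected:
        raise FormatError(f"{path}: data section truncated")
    data = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    data = data.reshape(n_records, n_ch, spr[0]).transpose(1, 0, 2).reshape(n_ch, -1)
    out = np.empty(data.shape)
    for c in range(n_ch):
        gain = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        out[c] = phys_min[c] + (data[c].astype(float) - dig_min[c]) * gain
    return SimulatedRecording(
        data=out,
        sampling_rate_Hz=rate,
        channel_ids=tuple(labels),
        events=(),
        seed=None,
    )


# --------------------------------------------------------------------------
# events TSV (BIDS-style)
# --------------------------------------------------------------------------

_EVENT_COLUMNS = ["onset", "duration", "trial_type", "sample", "channel", "probability", "grid_index"]


def write_events_tsv(events: pd.DataFrame | list[dict], path) -> None:
    """BIDS-style events table; missing optional columns are written as 'n/a'."""
    df = pd.DataFrame(events)
    if "onset" not in df.columns:
        raise ParameterError("events need at least an 'onset' column")
    for col in _EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = "n/a"
    df = df[_EVENT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a readable TSV ({exc})") from exc
    if "onset" not in df.columns:
        raise FormatError(f"{path}: missing required 'onset' column")
    return df


# --------------------------------------------------------------------------
# lead-field container
# --------------------------------------------------------------------------


def save_leadfield_h5(leadfield: LeadField, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=leadfield.gain)
        f["gain"].attrs["units"] = "uV per nAm"
        f["gain"].attrs["reference"] = "average"
        f.create_dataset("electrode_positions", data=leadfield.electrodes.positions)
        f.create_dataset(
            "channel_ids",
            data=np.array(leadfield.electrodes.channel_ids, dtype="S"),
        )
        for key, val in leadfield.electrodes.fiducials.items():
            f.create_dataset(f"fiducials/{key}", data=np.asarray(val))
        f.create_dataset("grid_positions", data=leadfield.grid.positions)
        f.attrs["grid_spacing_mm"] = leadfield.grid.spacing_mm
        f.attrs["radii_mm"] = leadfield.head.radii_mm
        f.attrs["conductivities_S_per_m"] = leadfield.head.conductivities_S_per_m
        f.attrs["n_terms"] = leadfield.n_terms
        f.attrs["scalp_radius_mm"] = leadfield.electrodes.scalp_radius_mm


def load_leadfield_h5(path) -> LeadField:
    import h5py

    with h5py.File(path, "r") as f:
        head = ThreeShellHeadModel(
            radii_mm=tuple(f.attrs["radii_mm"]),
            conductivities_S_per_m=tuple(f.attrs["conductivities_S_per_m"]),
        )
        fiducials = {}
        if "fiducials" in f:
            fiducials = {k: f[f"fiducials/{k}"][()] for k in f["fiducials"]}
        electrodes = ElectrodeArray(
            channel_ids=tuple(s.decode() for s in f["channel_ids"][()]),
            positions=f["electrode_positions"][()],
            fiducials=fiducials,
            scalp_radius_mm=float(f.attrs["scalp_radius_mm"]),
        )
        grid = SourceGrid(
            spacing_mm=float(f.attrs["grid_spacing_mm"]),
            positions=f["grid_positions"][()],
        )
        return LeadField(
            gain=f["gain"][()],
            electrodes=electrodes,
            grid=grid,
            head=head,
            n_terms=int(f.attrs["n_terms"]),
        )
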