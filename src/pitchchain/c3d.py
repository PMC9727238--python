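"""Minimal C3D point-data reader/writer.

Implements the subset of the C3D standard needed to archive marker
trajectories: Intel byte order, floating-point point data with residuals, no
analog channels.  Invalid samples are stored with a negative residual, the
standard convention for occluded points.  The writer emits a conventional
POINT/ANALOG parameter section so files remain readable by mainstream C3D
software; the reader accepts metre- or millimetre-scaled files.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_c3d", "write_c3d"]

_BLOCK = 512
_PROC_INTEL = 84  # 83 + 1


def _param_records(labels: list[str], n_frames: int, rate: float,
                   data_start_block: int, units: str) -> bytes:
    """Serialize the POINT/ANALOG parameter section records."""
    out = io = bytearray()

    def rec_group(gid: int, name: str, desc: str = "") -> None:
        name_b, desc_b = name.encode(), desc.encode()
        io.append(len(name_b))
        io.append((-gid) & 0xFF)  # negative id marks a group
        io.extend(name_b)
        io.extend(struct.pack("<h", 2 + 1 + len(desc_b)))
        io.append(len(desc_b))
        io.extend(desc_b)

    def rec_param(gid: int, name: str, dtype: int, dims: list[int],
                  payload: bytes, last: bool = False) -> None:
        name_b = name.encode()
        io.append(len(name_b))
        io.append(gid & 0xFF)
        io.extend(name_b)
        tail = 1 + 1 + len(dims) + len(payload) + 1  # type+ndim+dims+data+desclen
        io.extend(struct.pack("<h", 0 if last else 2 + tail))
        io.extend(struct.pack("<b", dtype))
        io.append(len(dims))
        for d in dims:
            io.append(d)
        io.extend(payload)
        io.append(0)  # empty description

    label_len = max(4, max((len(s) for s in labels), default=4))
    label_blob = b"".join(s.encode().ljust(label_len)[:label_len] for s in labels)

    rec_group(1, "POINT")
    rec_param(1, "USED", 2, [], struct.pack("<h", len(labels)))
    rec_param(1, "FRAMES", 2, [], struct.pack("<h", min(n_frames, 32767)))
    rec_param(1, "DATA_START", 2, [], struct.pack("<h", data_start_block))
    rec_param(1, "RATE", 4, [], struct.pack("<f", rate))
    rec_param(1, "SCALE", 4, [], struct.pack("<f", -1.0))
    rec_param(1, "UNITS", -1, [len(units)], units.encode())
    rec_param(1, "LABELS", -1, [label_len, len(labels)], label_blob)
    rec_group(2, "ANALOG")
    rec_param(2, "USED", 2, [], struct.pack("<h", 0), last=True)
    return bytes(out)


def write_c3d(path: str | Path, labels: list[str], points: np.ndarray,
              valid: np.ndarray | None = None, rate: float = 400.0,
              units: str = "m") -> None:
    """Write ``points`` of shape (T, n_markers, 3) to a C3D file.

    ``valid`` (T, n_markers) marks good samples; invalid ones get residual −1.
    Coordinates are written unscaled in ``units`` ('m' or 'mm').
    """
    points = np.asarray(points, dtype=np.float32)
    T, n, _ = points.shape
    if valid is None:
        valid = np.ones((T, n), dtype=bool)

    # Size the parameter section first (data must start on a block boundary).
    for n_param_blocks in range(1, 64):
        data_start = 2 + n_param_blocks  # header block + param blocks, 1-based
        params = _param_records(labels, T, rate, data_start, units)
        if 4 + len(params) <= n_param_blocks * _BLOCK:
            break
    else:  # pragma: no cover - labels would have to be enormous
        raise ValueError("parameter section too large")

    header = np.zeros(256, dtype="<i2")
    header[0] = (0x50 << 8) | 2  # param section at block 2, magic 0x50
    header[1] = n
    header[2] = 0  # analog channels
    header[3] = 1  # first frame (1-based)
    header[4] = T
    header[5] = 10  # max interpolation gap (informational)
    header[6:8] = np.frombuffer(struct.pack("<f", -1.0), dtype="<i2")
    header[8] = data_start
    header[9] = 0  # analog samples per frame
    header[10:12] = np.frombuffer(struct.pack("<f", rate), dtype="<i2")

    param_block = bytearray(n_param_blocks * _BLOCK)
    param_block[0] = 1
    param_block[1] = 0x50
    param_block[2] = n_param_blocks
    param_block[3] = _PROC_INTEL
    param_block[4:4 + len(params)] = params

    frame_words = np.zeros((T, n, 4), dtype=np.float32)
    frame_words[:, :, :3] = points
    frame_words[:, :, 3] = np.where(valid, 0.0, -1.0)

    with Path(path).open("wb") as fh:
        fh.write(header.tobytes())
        fh.write(bytes(param_block))
        fh.write(frame_words.astype("<f4").tobytes())


def _parse_params(blob: bytes) -> dict[tuple[str, str], tuple[int, list[int], bytes]]:
    """Walk parameter records; returns {(GROUP, PARAM): (dtype, dims, data)}."""
    groups: dict[int, str] = {}
    params: dict[tuple[int, str], tuple[int, list[int], bytes]] = {}
    pos = 4  # skip the 4-byte parameter header
    while pos + 2 <= len(blob):
        nname = struct.unpack_from("<b", blob, pos)[0]
        gid = struct.unpack_from("<b", blob, pos + 1)[0]
        if nname == 0:
            break
        name = blob[pos + 2: pos + 2 + abs(nname)].decode(errors="replace").strip()
        p = pos + 2 + abs(nname)
        offset = struct.unpack_from("<h", blob, p)[0]
        if gid < 0:  # group record
            groups[-gid] = name
        else:  # parameter record
            dtype = struct.unpack_from("<b", blob, p + 2)[0]
            ndim = blob[p + 3]
            dims = list(blob[p + 4: p + 4 + ndim])
            size = abs(dtype) * int(np.prod(dims)) if dims else abs(dtype)
            data = blob[p + 4 + ndim: p + 4 + ndim + size]
            params[(gid, name)] = (dtype, dims, data)
        if offset <= 0:
            break
        pos = p + offset
    named: dict[tuple[str, str], tuple[int, list[int], bytes]] = {}
    for (gid, name), v in params.items():
        named[(groups.get(gid, str(gid)), name)] = v
    return named


def read_c3d(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray, float]:
    """Read point data from a C3D file.

    Returns ``(labels, points, valid, rate)`` with points (T, n, 3) in metres.
    Only Intel-ordered floating-point point data is supported.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _BLOCK:
        raise IOError(f"{path}: truncated C3D file")
    header = np.frombuffer(raw[:_BLOCK], dtype="<i2")
    param_block = header[0] & 0xFF
    if (header[0] >> 8) & 0xFF != 0x50:
        raise IOError(f"{path}: not a C3D file (bad magic)")
    n_points = int(header[1])
    first, last = int(header[3]), int(header[4])
    scale = struct.unpack("<f", header[6:8].tobytes())[0]
    data_start = int(header[8])
    rate = struct.unpack("<f", header[10:12].tobytes())[0]
    if scale >= 0:
        raise NotImplementedError(f"{path}: integer-scaled C3D not supported")

    pstart = (param_block - 1) * _BLOCK
    n_param_blocks = raw[pstart + 2]
    proc = raw[pstart + 3]
    if proc not in (0, _PROC_INTEL):
        raise NotImplementedError(f"{path}: unsupported processor type {proc}")
    params = _parse_params(raw[pstart: pstart + n_param_blocks * _BLOCK])

    n_frames = last - first + 1
    if ("POINT", "FRAMES") in params:
        dtype, dims, data = params[("POINT", "FRAMES")]
        hdr_frames = struct.unpack("<h", data[:2])[0] if dtype == 2 else n_frames
        if hdr_frames > 0:
            n_frames = max(n_frames, hdr_frames)

    labels = [f"M{i}" for i in range(n_points)]
    if ("POINT", "LABELS") in params:
        _, dims, data = params[("POINT", "LABELS")]
        if len(dims) == 2:
            ll, nn = dims
            labels = [
                data[i * ll:(i + 1) * ll].decode(errors="replace").strip()
                for i in range(min(nn, n_points))
            ]
    unit_factor = 1.0
    if ("POINT", "UNITS") in params:
        units = params[("POINT", "UNITS")][2].decode(errors="replace").strip().lower()
        unit_factor = 0.001 if units == "mm" else 1.0

    off = (data_start - 1) * _BLOCK
    need = n_frames * n_points * 4 * 4
    words = np.frombuffer(raw[off: off + need], dtype="<f4")
    if words.size < n_frames * n_points * 4:
        raise IOError(f"{path}: data section truncated")
    words = words.reshape(n_frames, n_points, 4)
    points = words[:, :, :3].astype(float) * unit_factor
    valid = words[:, :, 3] >= 0
    return labels, points, valid.astype(bool), float(rate)
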