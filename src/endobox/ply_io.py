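"""Reader/writer for the PLY polygon format (ASCII and binary little-endian).

Only the two elements a wireframe design needs are interpreted: ``vertex``
(properties ``x``, ``y``, ``z``) and ``face`` (one list property holding the
vertex indices of each face).  Extra scalar vertex properties are parsed and
discarded; anything else is rejected so that write -> read -> write round
trips are byte-identical.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["PlyFormatError", "read_ply", "write_ply"]


class PlyFormatError(ValueError):
    """The file cannot be parsed as the supported PLY subset."""


_SCALAR = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}
_INT_TYPES = set("bBhHiI")


def _parse_header(raw: bytes):
    if not raw.startswith(b"ply"):
        raise PlyFormatError("missing 'ply' magic")
    end_tag = raw.find(b"end_header")
    if end_tag < 0:
        raise PlyFormatError("missing end_header")
    body_start = raw.index(b"\n", end_tag) + 1
    try:
        header_lines = raw[:end_tag].decode("ascii").splitlines()
    except UnicodeDecodeError as exc:  # pragma: no cover - defensive
        raise PlyFormatError("non-ASCII header") from exc

    fmt = None
    elements: list[tuple[str, int, list[tuple]]] = []
    for line in header_lines[1:]:
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise PlyFormatError(f"unsupported format {tok[1]!r}")
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise PlyFormatError("property before element")
            if tok[1] == "list":
                count_t, item_t, name = tok[2], tok[3], tok[4]
                elements[-1][2].append(("list", name, _SCALAR[count_t], _SCALAR[item_t]))
            else:
                elements[-1][2].append(("scalar", tok[2], _SCALAR[tok[1]]))
        else:
            raise PlyFormatError(f"unsupported header line {line!r}")
    if fmt is None:
        raise PlyFormatError("missing format line")
    return fmt, elements, raw[body_start:]


def _read_body_ascii(body: bytes, elements):
    tokens = body.split()
    pos = 0
    out = {}
    for name, count, props in elements:
        rows = []
        for _ in range(count):
            row = {}
            for prop in props:
                if prop[0] == "scalar":
                    _, pname, code = prop
                    val = tokens[pos]; pos += 1
                    row[pname] = int(val) if code in _INT_TYPES else float(val)
                else:
                    _, pname, _cc, ic = prop
                    n = int(tokens[pos]); pos += 1
                    vals = tokens[pos:pos + n]; pos += n
                    if len(vals) != n:
                        raise PlyFormatError("truncated list property")
                    row[pname] = [int(v) if ic in _INT_TYPES else float(v) for v in vals]
            rows.append(row)
        out[name] = rows
    return out


def _read_body_binary(body: bytes, elements):
    pos = 0
    out = {}
    for name, count, props in elements:
        rows = []
        for _ in range(count):
            row = {}
            for prop in props:
                if prop[0] == "scalar":
                    _, pname, code = prop
                    size = struct.calcsize("<" + code)
                    (row[pname],) = struct.unpack_from("<" + code, body, pos)
                    pos += size
                else:
                    _, pname, cc, ic = prop
                    (n,) = struct.unpack_from("<" + cc, body, pos)
                    pos += struct.calcsize("<" + cc)
                    vals = struct.unpack_from("<" + str(n) + ic, body, pos)
                    pos += struct.calcsize("<" + str(n) + ic)
                    row[pname] = list(vals)
            rows.append(row)
        out[name] = rows
    return out


def read_ply(path) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Parse a PLY file into ``(vertices, faces)``.

    Returns the (V, 3) float array of vertex coordinates and the list of
    face vertex-index tuples (quads and larger polygons preserved).
    """
    raw = Path(path).read_bytes()
    fmt, elements, body = _parse_header(raw)
    names = [e[0] for e in elements]
    if "vertex" not in names or "face" not in names:
        raise PlyFormatError("PLY must contain 'vertex' and 'face' elements")
    data = (_read_body_ascii if fmt == "ascii" else _read_body_binary)(body, elements)

    try:
        vertices = np.array(
            [[row["x"], row["y"], row["z"]] for row in data["vertex"]], dtype=float
        )
    except KeyError as exc:
        raise PlyFormatError("vertex element lacks x/y/z properties") from exc
    if vertices.size == 0:
        raise PlyFormatError("no vertices")

    faces = []
    for row in data["face"]:
        idx = row.get("vertex_indices", row.get("vertex_index"))
        if idx is None:
            raise PlyFormatError("face element lacks vertex index list")
        faces.append(tuple(int(i) for i in idx))
    return vertices, faces


def _fmt_float(x: float) -> str:
    return format(float(x), ".17g")


def write_ply(path, vertices, faces, binary: bool = False) -> None:
    """Write vertices/faces to *path* (ASCII by default)."""
    vertices = np.asarray(vertices, dtype=float)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header += [
        f"element vertex {len(vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    head = ("\n".join(header) + "\n").encode("ascii")
    if binary:
        chunks = [head]
        for v in vertices:
            chunks.append(struct.pack("<3d", *v))
        for f in faces:
            chunks.append(struct.pack("<B" + str(len(f)) + "i", len(f), *f))
        Path(path).write_bytes(b"".join(chunks))
    else:
        lines = []
        for v in vertices:
            lines.append(" ".join(_fmt_float(c) for c in v))
        for f in faces:
            lines.append(" ".join([str(len(f))] + [str(i) for i in f]))
        Path(path).write_bytes(head + ("\n".join(lines) + "\n").encode("ascii"))
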