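"""File formats: calibration text files, ASCII PLY point clouds, CSV tables.

Calibration file layout (plain text, one ``key: values`` pair per line)::

    stereodeform-calibration 1
    image_size: 640 480
    K_L: <9 floats, row major>
    K_R: <9 floats, row major>
    dist_L: <5 floats>
    dist_R: <5 floats>
    R_ext: <9 floats, row major>
    t_ext: <3 floats>

Floats are written with ``repr``-level precision (%.17g) so that a
write/read cycle is bit-exact.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .exceptions import StereoDeformError
from .geometry import CameraRig

MAGIC = "stereodeform-calibration 1"


def _fmt(values) -> str:
    return " ".join("%.17g" % v for v in np.asarray(values, dtype=float).ravel())


def write_calibration(path, rig: CameraRig) -> None:
    lines = [
        MAGIC,
        f"image_size: {rig.image_size[0]} {rig.image_size[1]}",
        f"K_L: {_fmt(rig.K_L)}",
        f"K_R: {_fmt(rig.K_R)}",
        f"dist_L: {_fmt(rig.dist_L)}",
        f"dist_R: {_fmt(rig.dist_R)}",
        f"R_ext: {_fmt(rig.R_ext)}",
        f"t_ext: {_fmt(rig.t_ext)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path) -> CameraRig:
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != MAGIC:
        raise StereoDeformError(f"{path}: not a stereodeform calibration file")
    kv: dict[str, list[float]] = {}
    for line in text[1:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, rest = line.partition(":")
        kv[key.strip()] = [float(t) for t in rest.split()]
    try:
        return CameraRig(
            K_L=np.array(kv["K_L"]).reshape(3, 3),
            K_R=np.array(kv["K_R"]).reshape(3, 3),
            dist_L=np.array(kv["dist_L"]),
            dist_R=np.array(kv["dist_R"]),
            R_ext=np.array(kv["R_ext"]).reshape(3, 3),
            t_ext=np.array(kv["t_ext"]),
            image_size=(int(kv["image_size"][0]), int(kv["image_size"][1])),
        )
    except KeyError as exc:
        raise StereoDeformError(f"{path}: missing calibration key {exc}") from exc


def write_ply(path, points: np.ndarray, deformation: np.ndarray | None = None) -> None:
    """Write an ASCII PLY cloud with x, y, z (mm) and an optional per-vertex
    scalar ``deformation`` property (mm)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size and points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    n = 0 if points.size == 0 else points.shape[0]
    buf = _io.StringIO()
    buf.write("ply\nformat ascii 1.0\ncomment stereodeform point cloud, units mm\n")
    buf.write(f"element vertex {n}\n")
    buf.write("property double x\nproperty double y\nproperty double z\n")
    if deformation is not None:
        deformation = np.asarray(deformation, dtype=float).ravel()
        if deformation.size != n:
            raise ValueError("deformation length must match point count")
        buf.write("property double deformation\n")
    buf.write("end_header\n")
    for i in range(n):
        row = "%.10g %.10g %.10g" % tuple(points[i])
        if deformation is not None:
            row += " %.10g" % deformation[i]
        buf.write(row + "\n")
    Path(path).write_text(buf.getvalue())


def write_match_csv(path, matches) -> None:
    """Match table: left col,row, right col,row, similarity M, appearance A, stage."""
    import pandas as pd

    rows = [
        {
            "left_col": m.left.x[0], "left_row": m.left.x[1],
            "right_col": m.right.x[0], "right_row": m.right.x[1],
            "M": m.M, "A": m.A, "stage": m.stage,
        }
        for m in matches
    ]
    pd.DataFrame(rows, columns=["left_col", "left_row", "right_col", "right_row",
                                "M", "A", "stage"]).to_csv(path, index=False)


def write_deformation_csv(path, field) -> None:
    """Deformation table: id, image location, 3D position (mm), D (mm), flags."""
    import pandas as pd

    pd.DataFrame(
        {
            "point_id": field.ids,
            "w_col": field.w[:, 0], "w_row": field.w[:, 1],
            "x_mm": field.current[:, 0], "y_mm": field.current[:, 1],
            "z_mm": field.current[:, 2],
            "D_mm": field.D,
            "stable": field.stable.astype(int),
            "confidence": field.confidence,
        }
    ).to_csv(path, index=False)


def read_material_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Material calibration CSV with columns displacement_mm, force_N."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("displacement_mm", "force_N"):
        if col not in df.columns:
            raise StereoDeformError(f"{path}: missing column {col!r}")
    return df["displacement_mm"].to_numpy(float), df["force_N"].to_numpy(float)


def write_material_csv(path, displacements, forces) -> None:
    import pandas as pd

    pd.DataFrame(
        {"displacement_mm": np.asarray(displacements, float),
         "force_N": np.asarray(forces, float)}
    ).to_csv(path, index=False)


def write_force_csv(path, rows) -> None:
    """Force report: one row per frame with peak displacement and force."""
    import pandas as pd

    pd.DataFrame(
        rows, columns=["frame", "peak_mm", "force_N", "extrapolated"]
    ).to_csv(path, index=False)


def read_ply(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read back an ASCII PLY written by :func:`write_ply`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise StereoDeformError(f"{path}: not a PLY file")
    n = 0
    props: list[str] = []
    body_at = None
    for i, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "element" and tok[1] == "vertex":
            n = int(tok[2])
        elif tok[0] == "property":
            props.append(tok[2])
        elif tok[0] == "end_header":
            body_at = i + 1
            break
    if body_at is None:
        raise StereoDeformError(f"{path}: malformed PLY header")
    data = np.array(
        [[float(v) for v in lines[body_at + j].split()] for j in range(n)], dtype=float
    ).reshape(n, len(props))
    cols = {p: data[:, k] for k, p in enumerate(props)}
    pts = np.stack([cols["x"], cols["y"], cols["z"]], axis=-1) if n else np.empty((0, 3))
    deform = cols.get("deformation")
    return pts, deform
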