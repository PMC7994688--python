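"""Readers and writers for the pipeline's on-disk formats.

Skeleton meshes are exchanged as VTK legacy ASCII polydata with point-data
arrays "normal" (vectors) and "half_thickness" (scalars); scalar volumes as
NIfTI-1; subject tables, vertex datasets, cluster and association tables as
headed CSV; configuration as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .mesh import SkeletonMesh
from .projection import VertexDataset
from .synthetic import MEASURES, SubjectRecord
from .tensor import DwiProtocol, ScalarVolume

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


# ---------------------------------------------------------------------------
# VTK legacy polydata

def write_mesh(mesh: SkeletonMesh, path, extra_point_data: dict | None = None):
    """Write a skeleton mesh as VTK legacy ASCII polydata.

    Point data carries "normal" (VECTORS) and "half_thickness" (SCALARS);
    ``extra_point_data`` adds further scalar arrays (e.g. t maps, cluster
    labels).  The tract name is stored in the title line.
    """
    path = Path(path)
    v, t = mesh.vertices, mesh.triangles
    lines = [
        "# vtk DataFile Version 3.0",
        f"tract:{mesh.name}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(_FLOAT_FMT % x for x in row) for row in v]
    lines.append(f"POLYGONS {len(t)} {4 * len(t)}")
    lines += ["3 %d %d %d" % tuple(row) for row in t]
    lines.append(f"POINT_DATA {len(v)}")
    lines.append("VECTORS normal double")
    lines += [" ".join(_FLOAT_FMT % x for x in row) for row in mesh.normals]
    lines.append("SCALARS half_thickness double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [_FLOAT_FMT % x for x in mesh.half_thickness]
    for name, values in (extra_point_data or {}).items():
        values = np.asarray(values, dtype=float)
        if values.shape != (len(v),):
            raise FormatError(f"point array {name!r} must have {len(v)} values")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [_FLOAT_FMT % x for x in values]
    path.write_text("\n".join(lines) + "\n")


class _Tokens:
    """Token stream over a text file, tracking line numbers for errors."""

    def __init__(self, path):
        self.path = Path(path)
        self.items = []  # (line_no, token)
        for i, line in enumerate(self.path.read_text().splitlines(), 1):
            for tok in line.split():
                self.items.append((i, tok))
        self.pos = 0
        self.line = 0

    def next(self, what="token"):
        if self.pos >= len(self.items):
            raise FormatError(f"truncated file: expected {what}",
                              path=str(self.path), line=self.line)
        self.line, tok = self.items[self.pos]
        self.pos += 1
        return tok

    def next_int(self, what="integer"):
        tok = self.next(what)
        try:
            return int(tok)
        except ValueError:
            raise FormatError(f"expected {what}, got {tok!r}",
                              path=str(self.path), line=self.line) from None

    def next_float(self, what="number"):
        tok = self.next(what)
        try:
            return float(tok)
        except ValueError:
            raise FormatError(f"expected {what}, got {tok!r}",
                              path=str(self.path), line=self.line) from None

    def expect(self, literal):
        tok = self.next(literal)
        if tok.upper() != literal.upper():
            raise FormatError(f"expected {literal!r}, got {tok!r}",
                              path=str(self.path), line=self.line)
        return tok

    @property
    def exhausted(self):
        return self.pos >= len(self.items)


def read_mesh(path) -> tuple[SkeletonMesh, dict]:
    """Read VTK legacy ASCII polydata written by :func:`write_mesh`.

    Returns (mesh, extra_point_data).  Malformed files raise
    :class:`FormatError` with file/line information.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if len(text) < 5 or not text[0].startswith("# vtk DataFile"):
        raise FormatError("not a VTK legacy data file", path=str(path), line=1)
    name = text[1].removeprefix("tract:").strip()
    if text[2].strip().upper() != "ASCII":
        raise FormatError("only ASCII VTK files are supported",
                          path=str(path), line=3)
    if text[3].split() != ["DATASET", "POLYDATA"]:
        raise FormatError("expected DATASET POLYDATA", path=str(path), line=4)

    toks = _Tokens(path)
    # Skip the four header lines' tokens.
    while toks.next() != "POLYDATA":
        pass
    toks.expect("POINTS")
    n_pts = toks.next_int("point count")
    toks.next("dtype")
    verts = np.array(
        [[toks.next_float("coordinate") for _ in range(3)] for _ in range(n_pts)]
    )
    toks.expect("POLYGONS")
    n_poly = toks.next_int("polygon count")
    toks.next_int("polygon size")
    tris = np.empty((n_poly, 3), dtype=int)
    for i in range(n_poly):
        k = toks.next_int("polygon arity")
        if k != 3:
            raise FormatError(f"only triangles supported, got arity {k}",
                              path=str(path), line=toks.line)
        tris[i] = [toks.next_int("vertex index") for _ in range(3)]
    toks.expect("POINT_DATA")
    n_pd = toks.next_int("point-data count")
    if n_pd != n_pts:
        raise FormatError(
            f"POINT_DATA count {n_pd} does not match POINTS {n_pts}",
            path=str(path), line=toks.line)

    normals = None
    half = None
    extra = {}
    while not toks.exhausted:
        kind = toks.next("array kind").upper()
        if kind == "VECTORS":
            arr_name = toks.next("array name")
            toks.next("dtype")
            data = np.array(
                [[toks.next_float() for _ in range(3)] for _ in range(n_pts)]
            )
            if arr_name == "normal":
                normals = data
            else:
                extra[arr_name] = data
        elif kind == "SCALARS":
            arr_name = toks.next("array name")
            toks.next("dtype")
            toks.next("n components")
            toks.expect("LOOKUP_TABLE")
            toks.next("table name")
            data = np.array([toks.next_float() for _ in range(n_pts)])
            if arr_name == "half_thickness":
                half = data
            else:
                extra[arr_name] = data
        else:
            raise FormatError(f"unsupported point-data section {kind!r}",
                              path=str(path), line=toks.line)
    if normals is None or half is None:
        raise FormatError(
            "mesh file lacks required point data 'normal'/'half_thickness'",
            path=str(path))
    return SkeletonMesh(name, verts, tris, normals, half), extra


# ---------------------------------------------------------------------------
# NIfTI volumes

def write_scalar_volume(volume: ScalarVolume, path):
    nib.save(nib.Nifti1Image(volume.data, volume.affine), str(path))


def read_scalar_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(np.asarray(img.get_fdata(), dtype=float), img.affine)


# ---------------------------------------------------------------------------
# FSL-style bval/bvec protocol files

def write_protocol(protocol: DwiProtocol, bval_path, bvec_path):
    """bvals on one row; bvecs as three whitespace-separated rows."""
    Path(bval_path).write_text(
        " ".join(_FLOAT_FMT % b for b in protocol.b_values) + "\n")
    rows = [" ".join(_FLOAT_FMT % x for x in protocol.directions[:, i])
            for i in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_protocol(bval_path, bvec_path) -> DwiProtocol:
    try:
        bvals = np.loadtxt(str(bval_path), ndmin=1)
        bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    except ValueError as e:
        raise FormatError(f"malformed bval/bvec file: {e}") from None
    if bvecs.shape[0] != 3:
        raise FormatError(
            f"bvec file must have three rows, got {bvecs.shape[0]}",
            path=str(bvec_path))
    if bvecs.shape[1] != bvals.shape[0]:
        raise FormatError("bval/bvec volume counts differ", path=str(bval_path))
    return DwiProtocol(bvals, bvecs.T)


# ---------------------------------------------------------------------------
# Subject table CSV

SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex", "wmh_present") + tuple(
    f"score_{i + 1}" for i in range(len(MEASURES))
)


def write_subject_table(records, path):
    """CSV with header subject_id,group,age,sex,wmh_present,score_1..score_9.

    score_i columns follow the canonical measure order of
    :data:`tractstats.synthetic.MEASURES`; empty when a record has no scores.
    """
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "wmh_present": r.wmh_present,
        }
        for i, m in enumerate(MEASURES):
            row[f"score_{i + 1}"] = r.scores.get(m, np.nan) if r.scores else np.nan
        rows.append(row)
    pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS)).to_csv(path, index=False)


def read_subject_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"subject table is missing required columns: {', '.join(missing)}",
            missing=missing)
    records = []
    for _, row in df.iterrows():
        score_vals = [row[f"score_{i + 1}"] for i in range(len(MEASURES))]
        has_scores = not any(pd.isna(v) for v in score_vals)
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            wmh_present=bool(row["wmh_present"]),
            scores={m: float(v) for m, v in zip(MEASURES, score_vals)}
            if has_scores else {},
        ))
    return records


# ---------------------------------------------------------------------------
# Vertex datasets as CSV (rows = subjects, columns = vertex index)

def write_vertex_dataset(dataset: VertexDataset, path):
    dataset.to_frame().to_csv(path, float_format=_FLOAT_FMT)


def read_vertex_dataset(path, tract: str | None = None) -> VertexDataset:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.name != "subject_id":
        raise SchemaError("vertex dataset must be indexed by subject_id",
                          missing=["subject_id"])
    if tract is None:
        tract = Path(path).stem
    return VertexDataset(tract, list(df.index), df.to_numpy())


# ---------------------------------------------------------------------------
# Cluster results table

def cluster_table(results) -> pd.DataFrame:
    rows = [{
        "tract": r.tract,
        "cluster_id": i,
        "n_vertices": len(r.vertices),
        "mass_mm2": r.mass,
        "peak_t": r.peak_t,
        "direction": r.direction,
        "p_fwer": r.p_fwer,
        "significant": r.significant,
    } for i, r in enumerate(results)]
    cols = ["tract", "cluster_id", "n_vertices", "mass_mm2", "peak_t",
            "direction", "p_fwer", "significant"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# JSON config / provenance

def read_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed JSON: {e.msg}",
                          path=str(path), line=e.lineno) from None


def write_json(obj: dict, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(obj: dict) -> str:
    canonical = json.dumps(obj, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()
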