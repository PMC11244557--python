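"""File formats: NIfTI-1 volumes, TSV tables, GMT gene-set collections.

Volumes are stored float32 (computation is float64); voxel size and TR
are carried in the NIfTI header pixdims.  All readers validate eagerly
and raise errors naming the offending file, line, or identifier.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMap
from .enrich import GeneSet
from .preproc import BoldSeries, NuisanceSet
from .rnaseq import CountMatrix

NUISANCE_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz", "vent"]


def _check_exists(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    return p


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_bold(b: BoldSeries, path) -> None:
    img = nib.Nifti1Image(b.data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((*b.voxel_size_mm, b.tr_s))
    img.header["descrip"] = b.subject_id.encode()[:79]
    nib.save(img, str(path))


def read_bold(path, mask: np.ndarray | None = None,
              subject_id: str | None = None) -> BoldSeries:
    """Read a 4D NIfTI-1 volume; TR from pixdim[4], voxel size from pixdim[1:4]."""
    img = nib.load(str(_check_exists(path)))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    vox = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if subject_id is None:
        subject_id = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data, mask, vox, tr, subject_id)


def write_map(m: ConnectivityMap, path) -> None:
    img = nib.Nifti1Image(m.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def read_map(path, kind: str = "global", mask: np.ndarray | None = None,
             subject_id: str = "") -> ConnectivityMap:
    img = nib.load(str(_check_exists(path)))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {data.ndim}D")
    if mask is None:
        mask = np.isfinite(data)
    return ConnectivityMap(data, kind, mask, subject_id)


def write_map_like(obj, path) -> None:
    """Write any 3D-``data`` holder (ConnectivityMap, StatMap) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(obj.data, dtype=np.float32),
                             affine=np.eye(4)), str(path))


def write_mask(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(_check_exists(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data > 0


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_nuisance(nu: NuisanceSet, path) -> None:
    df = pd.DataFrame(nu.as_matrix(), columns=NUISANCE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_nuisance(path) -> NuisanceSet:
    df = pd.read_csv(_check_exists(path), sep="\t")
    missing = [c for c in NUISANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing nuisance columns {missing}")
    return NuisanceSet(df[NUISANCE_COLUMNS[:6]].to_numpy(),
                       df["vent"].to_numpy())


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts(path, gene_meta: pd.DataFrame | None = None,
                design: pd.DataFrame | None = None) -> CountMatrix:
    """Counts TSV: header row of sample IDs, first column gene IDs."""
    df = pd.read_csv(_check_exists(path), sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if not df.map(lambda v: float(v).is_integer()).all().all():
        raise ValueError(f"{path}: counts must be integers")
    return CountMatrix(df.astype(np.int64), gene_meta, design)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_design(path, id_col: str = "sample") -> pd.DataFrame:
    df = pd.read_csv(_check_exists(path), sep="\t")
    for col in (id_col, "sex", "genotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: design lacks required column {col!r}")
    from .statmap import effect_codes

    effect_codes(df)  # validates factor levels
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate {id_col} {dup!r}")
    return df


def write_gene_meta(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_meta(path) -> pd.DataFrame:
    return pd.read_csv(_check_exists(path), sep="\t", index_col=0,
                       keep_default_na=False)


def read_homolog_table(path) -> pd.DataFrame:
    df = pd.read_csv(_check_exists(path), sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: homolog table needs two columns")
    return df


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, namespace: str = "mouse") -> list[GeneSet]:
    """GMT: one set per line — name, description, members, tab-separated."""
    sets = []
    for ln, line in enumerate(Path(_check_exists(path)).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}, line {ln}: GMT lines need name, description and at "
                f"least one member (got {len(fields)} fields)"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"{path}, line {ln}: gene set {name!r} is empty")
        sets.append(GeneSet(name, frozenset(members), namespace))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    lines = [
        "\t".join([s.name, s.namespace, *sorted(s.genes)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
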