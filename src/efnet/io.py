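"""File I/O: GIFTI surfaces and maps, TSV fallbacks, connectome containers.

Vertex indexing is 0-based everywhere in memory; writers and readers keep
that convention explicit in the files they produce (the TSV formats carry
an explicit ``vertex_id`` column).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import DenseConnectome
from .surface import Parcellation, ScalarMap, SurfaceMesh

# -- GIFTI ----------------------------------------------------------------


def write_surface_gifti(mesh: SurfaceMesh, path: "str | Path") -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def read_surface_gifti(path: "str | Path", hemisphere: str = "L") -> SurfaceMesh:
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(
        vertices=np.asarray(coords, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        hemisphere=hemisphere,
    )


def write_scalar_gifti(smap: ScalarMap, path: "str | Path") -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                smap.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
        ]
    )
    nib.save(img, str(path))


def read_scalar_gifti(path: "str | Path", mesh_id: str = "") -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(
        values=np.asarray(img.darrays[0].data, dtype=float), mesh_id=mesh_id
    )


# -- plain-text fallbacks -------------------------------------------------


def write_surface_tsv(
    mesh: SurfaceMesh, vertices_path: "str | Path", faces_path: "str | Path"
) -> None:
    pd.DataFrame(mesh.vertices, columns=["x", "y", "z"]).to_csv(
        vertices_path, sep="\t", index=False
    )
    pd.DataFrame(mesh.faces, columns=["v0", "v1", "v2"]).to_csv(
        faces_path, sep="\t", index=False
    )


def read_surface_tsv(
    vertices_path: "str | Path",
    faces_path: "str | Path",
    hemisphere: str = "L",
) -> SurfaceMesh:
    v = pd.read_csv(vertices_path, sep="\t")[["x", "y", "z"]].to_numpy(float)
    f = pd.read_csv(faces_path, sep="\t")[["v0", "v1", "v2"]].to_numpy(np.int64)
    return SurfaceMesh(vertices=v, faces=f, hemisphere=hemisphere)


def write_scalar_tsv(smap: ScalarMap, path: "str | Path") -> None:
    pd.DataFrame({"value": smap.values}).to_csv(path, sep="\t", index=False)


def read_scalar_tsv(path: "str | Path", mesh_id: str = "") -> ScalarMap:
    values = pd.read_csv(path, sep="\t")["value"].to_numpy(float)
    return ScalarMap(values=values, mesh_id=mesh_id)


def write_parcellation_tsv(
    parc: Parcellation,
    vertex_path: "str | Path",
    network_path: "str | Path",
) -> None:
    pd.DataFrame(
        {
            "vertex_id": np.arange(parc.n_vertices),
            "parcel_id": parc.vertex_parcel,
        }
    ).to_csv(vertex_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(parc.parcel_network.items()),
        columns=["parcel_id", "network_name"],
    ).to_csv(network_path, sep="\t", index=False)


def read_parcellation_tsv(
    vertex_path: "str | Path", network_path: "str | Path"
) -> Parcellation:
    vdf = pd.read_csv(vertex_path, sep="\t").sort_values("vertex_id")
    if not (vdf["vertex_id"].to_numpy() == np.arange(len(vdf))).all():
        raise ValueError("vertex_id column must cover 0..V-1")
    ndf = pd.read_csv(network_path, sep="\t")
    mapping = dict(
        zip(ndf["parcel_id"].astype(int), ndf["network_name"].astype(str))
    )
    return Parcellation(
        vertex_parcel=vdf["parcel_id"].to_numpy(np.int64),
        parcel_network=mapping,
    )


# -- dense connectomes ----------------------------------------------------


def write_connectome(
    fc: DenseConnectome, path: "str | Path", dtype: str = "float32"
) -> None:
    """Binary container (.npy) with a JSON sidecar recording shape/dtype."""
    path = Path(path)
    np.save(path, fc.matrix.astype(dtype))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(fc.matrix.shape),
                "dtype": dtype,
                "vertex_order": "mesh vertex order, 0-based",
                "connectome_id": fc.connectome_id,
            },
            indent=2,
        )
    )


def read_connectome(path: "str | Path") -> DenseConnectome:
    path = Path(path)
    m = np.load(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cid = ""
    if sidecar.exists():
        cid = json.loads(sidecar.read_text()).get("connectome_id", "")
    return DenseConnectome(matrix=m, connectome_id=cid)


def write_connectome_tsv_gz(fc: DenseConnectome, path: "str | Path") -> None:
    """Gzipped TSV alternative for small matrices."""
    pd.DataFrame(fc.matrix).to_csv(
        path, sep="\t", index=False, header=False, compression="gzip"
    )


def read_connectome_tsv_gz(path: "str | Path") -> DenseConnectome:
    m = pd.read_csv(path, sep="\t", header=None, compression="gzip").to_numpy(
        float
    )
    return DenseConnectome(matrix=m)
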