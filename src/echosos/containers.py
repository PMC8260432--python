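"""NPZ container I/O for the package's data objects.

Every container embeds a format version tag and the grid geometry as
scalar attributes; loading verifies the tag and the presence of every
required field, so stale or foreign files fail with a named-field error
rather than garbage arrays.  A foreign multistatic RF recording can be
mapped into a :class:`ChannelData` container by writing the documented
fields (``rf``, ``fs``, ``t0``, ``fc``, transducer scalars and the
descriptor table).
"""
from __future__ import annotations

import numpy as np

from .displacement import DelaySet
from .forward import PathMatrix
from .grids import Grid
from .phantoms import SoSMap
from .rfsim import ChannelData, Transducer, TxDescriptor
from scipy import sparse

__all__ = ["save_sos_map", "load_sos_map", "save_channel_data",
           "load_channel_data", "save_delay_set", "load_delay_set",
           "save_path_matrix", "load_path_matrix", "CONTAINER_VERSION"]

CONTAINER_VERSION = "echosos-1"


def _check(npz, kind: str, required: tuple[str, ...]) -> None:
    ver = str(npz.get("container_version", ""))
    if ver != CONTAINER_VERSION:
        raise ValueError(
            f"container version {ver!r} does not match {CONTAINER_VERSION!r}")
    if str(npz.get("container_kind", "")) != kind:
        raise ValueError(f"expected a {kind!r} container, got "
                         f"{npz.get('container_kind')!r}")
    for key in required:
        if key not in npz:
            raise ValueError(f"container missing required field {key!r}")


def _grid_attrs(g: Grid) -> dict:
    return dict(nx=g.nx, nz=g.nz, dx=g.dx, dz=g.dz,
                origin_x=g.x0, origin_z=g.z0)


def _grid_from(npz) -> Grid:
    return Grid(int(npz["nx"]), int(npz["nz"]), float(npz["dx"]),
                float(npz["dz"]), float(npz["origin_x"]), float(npz["origin_z"]))


def save_sos_map(path, m: SoSMap) -> None:
    masks = {f"mask_{k}": v for k, v in m.masks.items()}
    np.savez(path, container_version=CONTAINER_VERSION,
             container_kind="sos_map", sos=m.values,
             **_grid_attrs(m.grid), **masks)


def load_sos_map(path) -> SoSMap:
    with np.load(path, allow_pickle=False) as npz:
        _check(npz, "sos_map", ("sos", "nx", "nz", "dx", "dz",
                                "origin_x", "origin_z"))
        masks = {k[5:]: npz[k].astype(bool) for k in npz.files
                 if k.startswith("mask_")}
        return SoSMap(npz["sos"], _grid_from(npz), masks=masks)


def _descriptor_table(descs: list[TxDescriptor]) -> dict:
    nan = float("nan")
    return dict(
        tx_kind=np.array([d.kind for d in descs]),
        tx_element=np.array([-1 if d.element is None else d.element for d in descs]),
        tx_angle_deg=np.array([nan if d.angle_deg is None else d.angle_deg
                               for d in descs]),
        tx_code_row=np.array([-1 if d.code_row is None else d.code_row
                              for d in descs]),
    )


def _descriptors_from(npz) -> list[TxDescriptor]:
    out = []
    for kind, el, ang, row in zip(npz["tx_kind"], npz["tx_element"],
                                  npz["tx_angle_deg"], npz["tx_code_row"]):
        out.append(TxDescriptor(
            str(kind),
            element=None if el < 0 else int(el),
            angle_deg=None if np.isnan(ang) else float(ang),
            code_row=None if row < 0 else int(row)))
    return out


def save_channel_data(path, data: ChannelData) -> None:
    t = data.transducer
    np.savez(path, container_version=CONTAINER_VERSION,
             container_kind="channel_data", rf=data.rf, fs=data.fs,
             t0=data.t0, fc=data.fc, n_channels=t.n_channels, pitch=t.pitch,
             transducer_fc=t.fc, transducer_fs=t.fs,
             element_x=t.element_x, **_descriptor_table(data.tx_descriptors))


def load_channel_data(path) -> ChannelData:
    with np.load(path, allow_pickle=False) as npz:
        _check(npz, "channel_data",
               ("rf", "fs", "t0", "fc", "n_channels", "pitch", "tx_kind",
                "tx_element", "tx_angle_deg", "tx_code_row"))
        t = Transducer(int(npz["n_channels"]), float(npz["pitch"]),
                       float(npz.get("transducer_fc", npz["fc"])),
                       float(npz.get("transducer_fs", npz["fs"])))
        return ChannelData(npz["rf"], float(npz["fs"]), float(npz["t0"]),
                           _descriptors_from(npz), t, fc=float(npz["fc"]))


def save_delay_set(path, ds: DelaySet) -> None:
    np.savez(path, container_version=CONTAINER_VERSION,
             container_kind="delay_set", delays=ds.delays, quality=ds.quality,
             valid=ds.valid, scheme=ds.scheme,
             pair_tx_i=np.array([p[0] for p in ds.pair_table], dtype=float),
             pair_tx_j=np.array([p[1] for p in ds.pair_table], dtype=float),
             pair_psi=np.array([p[2] for p in ds.pair_table], dtype=float),
             **_grid_attrs(ds.grid))


def load_delay_set(path) -> DelaySet:
    with np.load(path, allow_pickle=False) as npz:
        _check(npz, "delay_set", ("delays", "quality", "valid", "pair_tx_i",
                                  "pair_tx_j", "pair_psi", "nx", "nz"))
        scheme = str(npz["scheme"])
        cast = float if scheme == "pw" else int
        table = [(cast(i), cast(j), float(p)) for i, j, p in
                 zip(npz["pair_tx_i"], npz["pair_tx_j"], npz["pair_psi"])]
        return DelaySet(npz["delays"], npz["quality"],
                        npz["valid"].astype(bool), table, _grid_from(npz),
                        scheme=scheme)


def save_path_matrix(path, L: PathMatrix) -> None:
    coo = L.matrix.tocoo()
    np.savez(path, container_version=CONTAINER_VERSION,
             container_kind="path_matrix", row=coo.row, col=coo.col,
             data=coo.data, shape=np.array(coo.shape), delays=L.delays,
             meta_entry=L.row_meta["entry"], meta_ix=L.row_meta["ix"],
             meta_iz=L.row_meta["iz"], **_grid_attrs(L.recon_grid))


def load_path_matrix(path) -> PathMatrix:
    with np.load(path, allow_pickle=False) as npz:
        _check(npz, "path_matrix", ("row", "col", "data", "shape", "delays",
                                    "meta_entry", "meta_ix", "meta_iz", "nx"))
        shape = tuple(int(s) for s in npz["shape"])
        mat = sparse.coo_matrix((npz["data"], (npz["row"], npz["col"])),
                                shape=shape).tocsr()
        meta = np.empty(npz["meta_entry"].size,
                        dtype=[("entry", np.intp), ("ix", np.intp),
                               ("iz", np.intp)])
        meta["entry"] = npz["meta_entry"]
        meta["ix"] = npz["meta_ix"]
        meta["iz"] = npz["meta_iz"]
        return PathMatrix(mat, _grid_from(npz), npz["delays"], meta)
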