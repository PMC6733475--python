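"""HDF5 serialization of models and observables.

Model files store fields dense, couplings as sparse (i, j, a, b, value)
triplets over the upper triangle of the mask, the overlap multipliers, the
mask itself, and a content hash so sampled ensembles can be traced back to
the exact model that produced them.
"""

from __future__ import annotations

import numpy as np
import h5py

from .alignment import ObservableSet
from .potts import InteractionMask, PottsModel


def save_model(model: PottsModel, path) -> None:
    n, q = model.n_sites, model.q
    iu = np.argwhere(np.triu(model.mask.allowed, 1))
    entries = []
    for i, j in iu:
        blk = model.J[i, j]
        nz = np.argwhere(blk != 0.0)
        for a, b in nz:
            entries.append((i, j, a, b, blk[a, b]))
    coords = np.array([e[:4] for e in entries], dtype=np.int32).reshape(-1, 4)
    values = np.array([e[4] for e in entries], dtype=float)
    with h5py.File(path, "w") as f:
        f.create_dataset("h", data=model.h)
        f.create_dataset("J_coords", data=coords)
        f.create_dataset("J_values", data=values)
        f.create_dataset("lambda", data=model.lam)
        f.create_dataset("mask", data=model.mask.allowed)
        f.attrs["L"] = model.L
        f.attrs["q"] = q
        f.attrs["content_hash"] = model.content_hash()
        f.attrs["format"] = "repeatscape-model-v1"


def load_model(path) -> PottsModel:
    with h5py.File(path, "r") as f:
        h = f["h"][...]
        coords = f["J_coords"][...]
        values = f["J_values"][...]
        lam = f["lambda"][...]
        mask = f["mask"][...].astype(bool)
        stored_hash = f.attrs.get("content_hash", "")
    n, q = h.shape
    J = np.zeros((n, n, q, q))
    for (i, j, a, b), v in zip(coords, values):
        J[i, j, a, b] = v
        J[j, i, b, a] = v
    model = PottsModel(h=h, J=J, lam=lam, mask=InteractionMask(mask))
    if stored_hash and model.content_hash() != stored_hash:
        raise ValueError(f"content hash mismatch reading {path}")
    return model


def save_observables(obs: ObservableSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("f1", data=obs.f1)
        f.create_dataset("f2", data=obs.f2)
        f.create_dataset("p_id", data=obs.p_id)
        f.attrs["n_eff"] = obs.n_eff
        f.attrs["L"] = obs.L
        f.attrs["q"] = obs.q
        f.attrs["format"] = "repeatscape-observables-v1"


def load_observables(path) -> ObservableSet:
    with h5py.File(path, "r") as f:
        return ObservableSet(
            f1=f["f1"][...],
            f2=f["f2"][...],
            p_id=f["p_id"][...],
            n_eff=float(f.attrs["n_eff"]),
            L=int(f.attrs["L"]),
            q=int(f.attrs["q"]),
        )
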