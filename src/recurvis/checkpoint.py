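"""HDF5 checkpoints for networks and cached front-end activations."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .network import (LayerSpec, Network, NetworkSpec, Projection,
                      ProjectionSpec)

_SCALARS = ("dt", "gain", "theta", "e_rev", "l_rev", "i_rev", "g_bar_l",
            "g_bar_i", "fb_scale", "kwta_q", "init_mean", "init_range")


def save_network(net: Network, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        spec = {
            "layers": [[ls.name, ls.size, ls.k] for ls in net.spec.layers],
            "projections": [[p.sender, p.receiver, bool(p.feedback)]
                            for p in net.spec.projections],
            **{k: float(getattr(net.spec, k)) for k in _SCALARS},
        }
        f.attrs["spec"] = yaml.safe_dump(spec)
        g = f.create_group("weights")
        for i, p in enumerate(net.projections):
            d = g.create_dataset(f"p{i:03d}", data=p.weights)
            d.attrs["sender"] = p.sender
            d.attrs["receiver"] = p.receiver
            d.attrs["feedback"] = p.feedback
            d.attrs["fb_gain"] = p.fb_gain


def load_network(path: str | Path) -> Network:
    with h5py.File(path, "r") as f:
        raw = yaml.safe_load(f.attrs["spec"])
        spec = NetworkSpec(
            layers=tuple(LayerSpec(n, int(s), int(k)) for n, s, k in raw["layers"]),
            projections=tuple(ProjectionSpec(s, r, bool(fb))
                              for s, r, fb in raw["projections"]),
            **{k: raw[k] for k in _SCALARS})
        projections = []
        g = f["weights"]
        for key in sorted(g.keys()):
            d = g[key]
            projections.append(Projection(
                sender=d.attrs["sender"], receiver=d.attrs["receiver"],
                weights=np.asarray(d), feedback=bool(d.attrs["feedback"]),
                fb_gain=float(d.attrs["fb_gain"])))
    return Network(spec, projections)


def save_model(model, path: str | Path) -> None:
    """Checkpoint a :class:`~recurvis.learning.RecurrentModel`: network
    weights plus the front-end and readout configuration."""
    save_network(model.net, path)
    with h5py.File(path, "a") as f:
        f.attrs["model"] = yaml.safe_dump({
            "categories": list(model.categories),
            "kwta_pct": float(model.kwta_pct),
            "v1_gain": float(model.v1_gain),
            "max_cycles": int(model.max_cycles),
            "tol": float(model.tol),
            "bank": {"n_orientations": int(model.bank.n_orientations),
                     "n_scales": int(model.bank.n_scales),
                     "filter_size": int(model.bank.filters[0][0].shape[1]),
                     "pool_size": int(model.bank.pool_size)},
        })


def load_model(path: str | Path):
    from .learning import RecurrentModel
    from .v1 import build_filter_bank

    net = load_network(path)
    with h5py.File(path, "r") as f:
        meta = yaml.safe_load(f.attrs["model"])
    bank = build_filter_bank(**meta["bank"])
    return RecurrentModel(net=net, bank=bank, categories=meta["categories"],
                          kwta_pct=meta["kwta_pct"], v1_gain=meta["v1_gain"],
                          max_cycles=meta["max_cycles"], tol=meta["tol"])


class ActivationCache:
    """Optional HDF5 cache of encoded front-end activations, keyed by image
    id and filter-bank hash."""

    def __init__(self, path: str | Path, bank_hash: str):
        self.path = Path(path)
        self.bank_hash = bank_hash

    def _key(self, image_id: str) -> str:
        return f"{self.bank_hash}/{image_id}"

    def get(self, image_id: str) -> np.ndarray | None:
        if not self.path.exists():
            return None
        with h5py.File(self.path, "r") as f:
            key = self._key(image_id)
            return np.asarray(f[key]) if key in f else None

    def put(self, image_id: str, flat_activation: np.ndarray) -> None:
        with h5py.File(self.path, "a") as f:
            key = self._key(image_id)
            if key in f:
                del f[key]
            f.create_dataset(key, data=flat_activation)
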