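"""File formats: TIFF stacks, complex-field TIFFs, tables, model weights.

Model serialization is a portable ``.npz`` of the weight arrays next to a
YAML config describing the architecture; loading verifies the config against
the rebuilt network and refuses mismatches rather than casting silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import NetworkConfig, build_network
from .nn import Sequential
from .simulate import ComplexField

__all__ = [
    "write_stack",
    "read_stack",
    "write_complex_field",
    "read_complex_field",
    "save_network",
    "load_network",
]


def write_stack(path, images: np.ndarray) -> None:
    """Write a (T, H, W) image stack (or one 2D image) as multi-page TIFF."""
    arr = np.asarray(images, dtype=np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr if arr.ndim == 3 else arr[None]


def write_complex_field(path, fld: ComplexField) -> None:
    """Two-page TIFF (real, imaginary) with background/pixel metadata."""
    pages = np.stack([fld.real, fld.imag]).astype(np.float32)
    meta = {
        "background_real": float(fld.background.real),
        "background_imag": float(fld.background.imag),
        "sigma": float(fld.sigma),
        "pixel_size": float(fld.pixel_size),
        "planes": "real,imag",
    }
    tifffile.imwrite(str(path), pages, metadata=meta, photometric="minisblack")


def read_complex_field(path) -> ComplexField:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ValueError("expected a two-page (real, imag) TIFF")
    bg = complex(float(meta.get("background_real", 1.0)), float(meta.get("background_imag", 0.0)))
    return ComplexField(
        pages[0].astype(float),
        pages[1].astype(float),
        background=bg,
        sigma=float(meta.get("sigma", 0.0)),
        pixel_size=float(meta.get("pixel_size", 0.114)),
    )


def _config_dict(cfg: NetworkConfig) -> dict:
    return {
        "in_channels": cfg.in_channels,
        "channels": cfg.channels,
        "kernel": cfg.kernel,
        "pre_pool_layers": cfg.pre_pool_layers,
        "post_pool_layers": cfg.post_pool_layers,
        "pool": cfg.pool,
        "extra_channels": cfg.extra_channels,
    }


def save_network(path, network: Sequential, cfg: NetworkConfig, extra_meta: dict | None = None) -> None:
    """Save weights to ``<path>`` (npz) and the config to ``<path>.yaml``."""
    path = Path(path)
    np.savez(path, **{f"param_{i}": p for i, p in enumerate(network.params)})
    doc = {"network": _config_dict(cfg)}
    if extra_meta:
        doc["meta"] = extra_meta
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(doc, fh)


def load_network(path) -> tuple[Sequential, NetworkConfig, dict]:
    """Rebuild a network from weights + YAML config; shape mismatches raise."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        doc = yaml.safe_load(fh)
    cfg = NetworkConfig(**doc["network"])
    network = build_network(cfg, np.random.default_rng(0))
    with np.load(path) as data:
        arrays = [data[f"param_{i}"] for i in range(len(data.files))]
    params = network.params
    if len(arrays) != len(params):
        raise ValueError("weights file does not match the declared architecture")
    for p, a in zip(params, arrays):
        if p.shape != a.shape:
            raise ValueError(
                f"weight shape {a.shape} does not match architecture {p.shape}; refusing to cast"
            )
        p[...] = a
    return network, cfg, doc.get("meta", {})
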