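"""File formats: PNG frames, CSV manifests and tables, the model file.

Conventions
-----------
* VIS frames: 8-bit RGB PNG.
* NIR frames: 16-bit grayscale PNG holding 10-bit data scaled by 64
  (DN_stored = DN * 64), so standard viewers show a sensible image; the
  reader divides the scale back out.
* A campaign manifest is a CSV with one row per frame:
  ``pair_id, path, band, time, true_ri, seed``.
* The trained network is stored as a versioned JSON document with dims,
  scalers and weight matrices (text, diff-able, no pickle).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import FormatError
from .imaging import FramePair, ImageFrame
from .network import BPNetwork

__all__ = [
    "write_frame",
    "read_frame",
    "write_campaign",
    "read_campaign",
    "save_network",
    "load_network",
    "write_report",
]

_NIR_SCALE = 64  # 10-bit data in a 16-bit container

MODEL_FORMAT = "plasmoncam-bpnet"
MODEL_VERSION = 1


def write_frame(frame: ImageFrame, path) -> None:
    """Write one frame as PNG following the band's storage convention."""
    path = Path(path)
    if frame.band == "VIS":
        Image.fromarray(frame.pixels.astype(np.uint8), mode="RGB").save(path)
    else:
        data = (frame.pixels[:, :, 0].astype(np.uint16) * _NIR_SCALE)
        Image.fromarray(data).save(path)


def read_frame(path, band: str) -> ImageFrame:
    """Read a PNG/TIFF frame back into an :class:`ImageFrame`."""
    arr = np.asarray(Image.open(path))
    if band == "VIS":
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise FormatError(f"{path}: VIS frame must be RGB")
        return ImageFrame(arr[:, :, :3].astype(np.uint16), 8, "VIS")
    if band == "NIR":
        if arr.ndim != 2:
            raise FormatError(f"{path}: NIR frame must be single-channel")
        return ImageFrame((arr.astype(np.uint32) // _NIR_SCALE).astype(np.uint16), 10, "NIR")
    raise FormatError(f"unknown band {band!r}")


def write_campaign(pairs: list[FramePair], directory, seed: int | None = None) -> Path:
    """Write a simulated campaign: PNG frames plus a manifest CSV.

    Returns the manifest path (``manifest.csv`` inside ``directory``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pair in enumerate(pairs):
        for band, frame in (("VIS", pair.vis), ("NIR", pair.nir)):
            name = f"frame_{i:04d}_{band.lower()}.png"
            write_frame(frame, directory / name)
            rows.append(
                {
                    "pair_id": i,
                    "path": name,
                    "band": band,
                    "time": pair.time_s,
                    "true_ri": pair.true_ri,
                    "seed": seed,
                }
            )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_campaign(manifest_path) -> list[FramePair]:
    """Load frame pairs from a manifest CSV (simulated or user-supplied).

    The manifest must pair one VIS and one NIR row per ``pair_id``; paths
    are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"pair_id", "path", "band", "time", "true_ri"}
    if not required <= set(table.columns):
        raise FormatError(f"manifest lacks columns {sorted(required - set(table.columns))}")
    base = manifest_path.parent
    pairs = []
    for pair_id, group in table.groupby("pair_id", sort=True):
        by_band = {row.band: row for row in group.itertuples()}
        if set(by_band) != {"VIS", "NIR"}:
            raise FormatError(f"pair {pair_id} must have exactly one VIS and one NIR frame")
        vis = read_frame(base / by_band["VIS"].path, "VIS")
        nir = read_frame(base / by_band["NIR"].path, "NIR")
        true_ri = float(by_band["VIS"].true_ri)
        pairs.append(FramePair(vis, nir, true_ri, float(by_band["VIS"].time)))
    return pairs


def save_network(net: BPNetwork, path) -> None:
    """Serialize a trained network (weights + scalers) as versioned JSON."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "input_dim": net.input_dim,
        "hidden_dim": net.hidden_dim,
        "w1": net.w1.tolist(),
        "b1": net.b1.tolist(),
        "w2": net.w2.tolist(),
        "b2": net.b2.tolist(),
        "x_mean": None if net.x_mean is None else net.x_mean.tolist(),
        "x_std": None if net.x_std is None else net.x_std.tolist(),
        "y_mean": net.y_mean,
        "y_std": net.y_std,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_network(path) -> BPNetwork:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a {MODEL_FORMAT} file")
    if doc.get("version") != MODEL_VERSION:
        raise FormatError(f"{path}: unsupported model version {doc.get('version')}")
    return BPNetwork(
        w1=np.asarray(doc["w1"], dtype=float),
        b1=np.asarray(doc["b1"], dtype=float),
        w2=np.asarray(doc["w2"], dtype=float),
        b2=np.asarray(doc["b2"], dtype=float),
        x_mean=None if doc["x_mean"] is None else np.asarray(doc["x_mean"], dtype=float),
        x_std=None if doc["x_std"] is None else np.asarray(doc["x_std"], dtype=float),
        y_mean=doc["y_mean"],
        y_std=doc["y_std"],
    )


def write_report(values: dict, text_path, kv_path=None, title: str = "report") -> None:
    """Write a human-readable report plus a machine-readable key=value twin."""
    lines = [title, "-" * len(title)]
    lines += [f"{k}: {v}" for k, v in values.items()]
    Path(text_path).write_text("\n".join(lines) + "\n")
    if kv_path is not None:
        Path(kv_path).write_text("".join(f"{k}={v}\n" for k, v in values.items()))
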