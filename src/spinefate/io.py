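"""Shared I/O: tidy CSV tables, multi-page TIFF stacks, configs, manifests.

Conventions: fate matrices are tidy long-format CSVs (one row per
spine x session; robust to irregular schedules); images are multi-page
TIFFs with the pixel size recorded in the resolution tags and the channel
map in the image description; pixel coordinates are 0-based (row, col).
Every manifest records the seed so any artifact can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dynamics import FateMatrix

__all__ = [
    "read_config",
    "write_config",
    "write_fate_matrix",
    "read_fate_matrix",
    "write_image_stack",
    "read_image_stack",
    "write_events",
    "read_events",
    "write_manifest",
    "sha256_file",
]


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def write_fate_matrix(fm: FateMatrix, obs_path, lengths_path=None) -> None:
    fm.observations.to_csv(obs_path, index=False)
    if lengths_path is not None and fm.dendrite_length_um is not None:
        fm.dendrite_length_um.rename_axis("dendrite_id").reset_index().to_csv(
            lengths_path, index=False
        )


def read_fate_matrix(obs_path, lengths_path=None) -> FateMatrix:
    obs = pd.read_csv(obs_path)
    lengths = None
    if lengths_path is not None and Path(lengths_path).exists():
        ldf = pd.read_csv(lengths_path)
        lengths = ldf.set_index("dendrite_id").iloc[:, 0]
    return FateMatrix(observations=obs, dendrite_length_um=lengths)


def write_image_stack(channels: Mapping[str, np.ndarray], path, pixel_size_um: float) -> None:
    """Multi-page TIFF, one page per channel, pixel size in resolution tags."""
    import tifffile

    names = list(channels)
    stack = np.stack([np.asarray(channels[n]) for n in names])
    res = 1.0 / pixel_size_um  # pixels per micron
    tifffile.imwrite(
        path,
        stack,
        resolution=(res, res),
        resolutionunit="MICROMETER",
        description=json.dumps({"channels": names, "pixel_size_um": pixel_size_um}),
    )


def read_image_stack(path) -> tuple[dict[str, np.ndarray], float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    names = meta["channels"]
    return {n: stack[i] for i, n in enumerate(names)}, float(meta["pixel_size_um"])


EVENT_COLUMNS = ["spine_id", "group", "mouse_id", "time_days", "status"]


def write_events(events: pd.DataFrame, path, group: str = "") -> None:
    df = events.copy()
    if "group" not in df:
        df["group"] = group
    df[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, seed: int, artifacts: list[str], extra: Mapping | None = None) -> Path:
    """Manifest of a run: seed, artifact paths and checksums."""
    out_dir = Path(out_dir)
    entries = [
        {"path": a, "sha256": sha256_file(out_dir / a)} for a in sorted(artifacts)
    ]
    manifest = {"seed": int(seed), "artifacts": entries}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
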