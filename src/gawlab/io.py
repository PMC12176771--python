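"""File interchange: mask stacks, feature tables, and parameter sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .extraction import MaskStack
from .features import FEATURE_NAMES, GlottalFeatureVector

__all__ = [
    "write_mask_stack",
    "read_mask_stack",
    "write_feature_table",
    "read_feature_table",
    "write_params_sidecar",
]


def write_mask_stack(stack: MaskStack, path, sidecar: dict | None = None) -> None:
    """Write a mask stack as a multi-page TIFF (uint8, 0/255) plus an optional
    JSON sidecar echoing the generation parameters."""
    path = Path(path)
    tifffile.imwrite(path, (stack.frames.astype(np.uint8) * 255), compression=None)
    meta = {"fs": stack.fs, "n_frames": int(stack.n_frames)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_mask_stack(path) -> MaskStack:
    path = Path(path)
    frames = tifffile.imread(path) > 0
    meta = json.loads(path.with_suffix(".json").read_text())
    return MaskStack(frames=frames, fs=float(meta["fs"]))


def write_feature_table(vectors, path) -> None:
    """Write feature vectors as CSV; the header is exactly the 48 canonical
    feature names in fixed order."""
    rows = [v.values if isinstance(v, GlottalFeatureVector) else np.asarray(v) for v in vectors]
    pd.DataFrame(rows, columns=list(FEATURE_NAMES)).to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df


def write_params_sidecar(params, path) -> None:
    """JSON sidecar for any dataclass-like parameter object."""
    from dataclasses import asdict, is_dataclass

    payload = asdict(params) if is_dataclass(params) else dict(params)
    clean = {k: v for k, v in payload.items() if not callable(v)}
    Path(path).write_text(json.dumps(clean, indent=1, default=str))
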