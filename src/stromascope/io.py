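"""TIFF / CSV / YAML input-output helpers.

Multi-channel cores are written as multi-page TIFFs with the channel name in
each page's description tag; label masks as uint16 TIFFs; tables as CSV with
a fixed float format so re-runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from stromascope.datatypes import MultiplexCoreImage
from stromascope.errors import ParameterError

FLOAT_FORMAT = "%.6g"


def write_core_tiff(path, image: MultiplexCoreImage) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tw:
        for name, ch in image.channels.items():
            tw.write(ch, description=name,
                     resolution=(1e4 / image.pixel_size_um,) * 2,
                     metadata=None)


def read_core_tiff(path, core_id: str | None = None,
                   pixel_size_um: float = 0.25) -> MultiplexCoreImage:
    path = Path(path)
    channels = {}
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            name = (page.description or f"ch{i}").strip()
            channels[name] = page.asarray()
    if not channels:
        raise ParameterError(f"no pages in {path}")
    return MultiplexCoreImage(
        core_id=core_id or path.stem, channels=channels,
        pixel_size_um=pixel_size_um,
    )


def write_label_tiff(path, labels: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = labels.astype(np.uint16) if labels.max() < 2**16 else labels.astype(np.uint32)
    tifffile.imwrite(path, arr)


def write_table(path, df: pd.DataFrame) -> None:
    """Deterministic CSV: fixed float format, no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
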