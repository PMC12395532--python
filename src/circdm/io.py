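"""Format plumbing: TSV tables, 16-bit TIFF channels, JSON/YAML configs.

TSV dialect: tab-separated, UTF-8, header row required, ``.`` for missing
values.  Images are written one channel per file as 16-bit grayscale TIFF
(values scaled from [0, 1] to the full uint16 range) with a JSON sidecar
carrying lineage and ground truth, so a simulated experiment round-trips
through the filesystem without loss beyond the stated bit depth.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .burden import ExpressionMatrix
from .simulate import FieldOfView

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_expression_matrix",
    "load_channel",
    "save_field",
    "load_field",
    "load_config",
]

log = logging.getLogger("circdm")

MISSING = "."
U16_MAX = 65535


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_expression_matrix(
    counts_path, samples_path, feature_class: str = "circular"
) -> ExpressionMatrix:
    """Count matrix TSV (first column = feature id) + sample sheet TSV.

    The sample sheet needs columns ``sample``, ``group``, ``library_size``
    and optionally ``stratum``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = read_tsv(samples_path, required=("sample", "group", "library_size"))
    sheet = sheet.set_index("sample")
    missing = [s for s in counts.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    return ExpressionMatrix(
        counts=counts,
        library_sizes=sheet["library_size"].astype(float),
        groups=sheet["group"],
        feature_class=feature_class,
        strata=sheet["stratum"] if "stratum" in sheet.columns else None,
    )


def load_channel(path) -> np.ndarray:
    """Read a single-channel image and normalize it to [0, 1].

    uint8/uint16 images are divided by their type maximum; anything else is
    min-max scaled (logged), matching how arbitrary-depth microscope
    exports are brought onto the unit scale.
    """
    arr = tifffile.imread(str(path)) if str(path).lower().endswith((".tif", ".tiff")) else None
    if arr is None:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        return arr.astype(float) / U16_MAX
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255
    arr = arr.astype(float)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        log.info("min-max normalizing %s (dtype %s)", path, arr.dtype)
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def save_field(field: FieldOfView, directory, stem: str) -> dict[str, str]:
    """Write one field's channels as 16-bit TIFFs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, channel in field.channels.items():
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(str(p), np.round(channel * U16_MAX).astype(np.uint16))
        paths[name] = p.name
    sidecar = {
        "experiment": field.experiment,
        "sample": field.sample,
        "state": field.state,
        "channels": paths,
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return paths


def load_field(directory, stem: str) -> FieldOfView:
    directory = Path(directory)
    with open(directory / f"{stem}.json") as fh:
        sidecar = json.load(fh)
    channels = {
        name: load_channel(directory / fname) for name, fname in sidecar["channels"].items()
    }
    return FieldOfView(
        experiment=sidecar["experiment"],
        sample=sidecar["sample"],
        state=sidecar["state"],
        channels=channels,
    )


def load_config(path) -> dict:
    """YAML or JSON config file -> dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
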