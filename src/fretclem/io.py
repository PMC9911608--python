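"""Readers and writers for the interchange formats.

All tables are comma-separated UTF-8 with a mandatory header row and '.'
decimal; TIFFs are little-endian and uncompressed.  Write-then-read is the
identity on content: CSV numerics survive via repr round-trip, TIFF planes
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decay import DecayHistogram
from .errors import ParseError
from .image import FlimImage

__all__ = [
    "read_histogram_csv",
    "write_histogram_csv",
    "read_fiducials_csv",
    "write_fiducials_csv",
    "read_flim_tiff",
    "write_flim_tiff",
    "read_labeled_mask",
    "write_labeled_mask",
    "write_records_csv",
    "read_records_csv",
]

FIDUCIAL_COLUMNS = ("flim_x", "flim_y", "em_x", "em_y")


def _read_csv(path, required_columns):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: line 1: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def write_histogram_csv(hist: DecayHistogram, path) -> None:
    """Two-column CSV (bin_start_ns, counts); bin width implied by the grid."""
    df = pd.DataFrame(
        {"bin_start_ns": hist.bin_edges[:-1], "counts": hist.counts}
    )
    df.to_csv(path, index=False)


def read_histogram_csv(path, background_per_bin: float = 0.0) -> DecayHistogram:
    """Read a decay histogram; uniform binning is validated on construction."""
    df = _read_csv(path, ("bin_start_ns", "counts"))
    starts = df["bin_start_ns"].to_numpy(dtype=float)
    if len(starts) < 2:
        raise ParseError(f"{path}: need at least 2 bins")
    width = starts[1] - starts[0]
    edges = np.append(starts, starts[-1] + width)
    try:
        return DecayHistogram(
            bin_edges=edges,
            counts=df["counts"].to_numpy(),
            background_per_bin=background_per_bin,
        )
    except Exception as exc:
        raise ParseError(f"{path}: field bin_start_ns/counts: {exc}") from exc


def write_fiducials_csv(flim_xy, em_xy, path) -> None:
    flim_xy = np.atleast_2d(flim_xy)
    em_xy = np.atleast_2d(em_xy)
    pd.DataFrame(
        {
            "flim_x": flim_xy[:, 0],
            "flim_y": flim_xy[:, 1],
            "em_x": em_xy[:, 0],
            "em_y": em_xy[:, 1],
        }
    ).to_csv(path, index=False)


def read_fiducials_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, FIDUCIAL_COLUMNS)
    return (
        df[["flim_x", "flim_y"]].to_numpy(dtype=float),
        df[["em_x", "em_y"]].to_numpy(dtype=float),
    )


def write_flim_tiff(img: FlimImage, path) -> None:
    """Two-plane TIFF: photon counts (uint32) and lifetime sums (float64),
    with pixel size and cell id in the JSON image description."""
    meta = {"pixel_size_nm": img.pixel_size_nm, "cell_id": img.cell_id}
    with tifffile.TiffWriter(path) as tw:
        tw.write(
            img.photon_counts.astype(np.uint32),
            description=json.dumps(meta),
        )
        tw.write(img.lifetime_weighted_sum.astype(np.float64))


def read_flim_tiff(path) -> FlimImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) < 2:
            raise ParseError(f"{path}: expected 2 planes, found {len(tf.pages)}")
        counts = tf.pages[0].asarray()
        sums = tf.pages[1].asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        try:
            meta = json.loads(desc.value) if desc is not None else {}
        except json.JSONDecodeError:
            meta = {}
    if "pixel_size_nm" not in meta:
        raise ParseError(f"{path}: field pixel_size_nm missing from description")
    return FlimImage(
        photon_counts=counts.astype(np.int64),
        lifetime_weighted_sum=sums,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        cell_id=str(meta.get("cell_id", "")),
    )


def write_labeled_mask(mask: np.ndarray, classes: pd.DataFrame, tiff_path,
                       csv_path) -> None:
    """Labeled 16-bit TIFF plus class table CSV (label, curvature_class)."""
    tifffile.imwrite(tiff_path, np.asarray(mask).astype(np.uint16))
    classes[["label", "curvature_class"]].to_csv(csv_path, index=False)


def read_labeled_mask(tiff_path, csv_path) -> tuple[np.ndarray, pd.DataFrame]:
    mask = tifffile.imread(tiff_path).astype(np.int64)
    classes = _read_csv(csv_path, ("label", "curvature_class"))
    return mask, classes


def write_records_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_records_csv(path, required=()) -> pd.DataFrame:
    return _read_csv(path, required)
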