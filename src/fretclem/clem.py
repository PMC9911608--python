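"""FRET-CLEM correlation engine.

Registers FLIM images onto platinum-replica EM frames of the same unroofed
membrane via an affine transform fitted to fiducial structures, extracts
per-structure mean lifetimes from rectangular ROIs, groups structures by
lattice curvature class (flat / domed / sphere) with per-cell normalisation
to the flat-class mean, applies the cell-level acceptor-expression filter,
and computes EM lattice morphometrics (mean area, density, occupied
membrane fraction).

Coordinate convention throughout: 0-based, origin top-left, x = column,
y = row, pixel centers at integer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFiducialsError,
    InsufficientPhotonsError,
    InvalidParameterError,
)
from .image import FlimImage

__all__ = [
    "AffineTransform2D",
    "CCSRecord",
    "CellSummary",
    "fit_affine",
    "transform_image_nn",
    "roi_mean_lifetime",
    "summarize_cell",
    "filter_cells_by_lifetime",
    "morphometrics",
    "LIFETIME_FILTER_NS",
]

#: cellular-average lifetime ceiling (ns) ensuring acceptor expression
LIFETIME_FILTER_NS = 2.1

CURVATURE_CLASSES = ("flat", "domed", "sphere")


@dataclass
class AffineTransform2D:
    """2-D affine map: em_xy = A @ flim_xy + b (both in pixel coordinates)."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.b = np.asarray(self.b, dtype=float).reshape(2)
        if abs(np.linalg.det(self.A)) <= 1e-12:
            raise InvalidParameterError("affine linear part is singular")

    def __call__(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.A.T + self.b

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.b)

    @property
    def scale(self) -> float:
        """Isotropic scale estimate sqrt(|det A|)."""
        return math.sqrt(abs(np.linalg.det(self.A)))


@dataclass
class CCSRecord:
    """One clathrin-coated structure after correlation."""

    structure_id: str
    cell_id: str
    curvature_class: str
    area_nm2: float
    centroid_em_xy: tuple[float, float]
    mean_lifetime_ns: float
    photons: int

    def __post_init__(self):
        if self.curvature_class not in CURVATURE_CLASSES:
            raise InvalidParameterError(
                f"curvature_class must be one of {CURVATURE_CLASSES}"
            )
        if self.area_nm2 <= 0:
            raise InvalidParameterError("area must be positive")
        if self.photons < 0:
            raise InvalidParameterError("photons must be >= 0")


@dataclass
class CellSummary:
    """Per-cell curvature-class lifetime summary.

    ``delta_vs_flat_ns`` holds mean(class) - mean(flat) in ns; the flat
    entry is 0 by construction and classes absent from the cell are NaN.
    """

    cell_id: str
    class_mean_ns: dict
    delta_vs_flat_ns: dict
    cellular_average_lifetime_ns: float
    n_structures: dict


def fit_affine(flim_xy, em_xy) -> tuple[AffineTransform2D, float]:
    """Least-squares affine from fiducial point pairs.

    Minimises sum ||A @ flim + b - em||^2; exact (zero residual) when the
    pairs are affine-consistent.  Returns the transform and the RMS
    residual in EM pixels.  Sphere-class structures should not be used as
    fiducials (they can shift during critical point drying); flat and
    domed structures are the appropriate landmarks.

    Raises
    ------
    DegenerateFiducialsError
        Fewer than 3 pairs, or all source points collinear.
    """
    flim_xy = np.atleast_2d(np.asarray(flim_xy, dtype=float))
    em_xy = np.atleast_2d(np.asarray(em_xy, dtype=float))
    if flim_xy.shape != em_xy.shape or flim_xy.shape[1] != 2:
        raise InvalidParameterError("fiducial arrays must both be (n, 2)")
    n = len(flim_xy)
    if n < 3:
        raise DegenerateFiducialsError(f"need >= 3 fiducial pairs, got {n}")
    # collinearity: rank of centred source points
    centred = flim_xy - flim_xy.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise DegenerateFiducialsError("fiducial points are collinear")
    X = np.hstack([flim_xy, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(X, em_xy, rcond=None)
    A = coef[:2].T
    b = coef[2]
    T = AffineTransform2D(A, b)
    residual = float(np.sqrt(np.mean(np.sum((T(flim_xy) - em_xy) ** 2, axis=1))))
    return T, residual


def transform_image_nn(
    img: FlimImage, T: AffineTransform2D, out_shape: tuple[int, int],
    out_pixel_size_nm: float | None = None,
) -> FlimImage:
    """Resample a FLIM image into the EM frame by nearest-neighbour lookup.

    Each output (EM-frame) pixel takes the value of the nearest input pixel
    under the inverse map T^-1 — photon counts stay integral and no photon
    is invented by interpolation.  Output pixels that map outside the input
    are zero.
    """
    Tinv = T.inverse()
    ny, nx = out_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    src = Tinv(np.column_stack([xx.ravel(), yy.ravel()]))
    sx = np.rint(src[:, 0]).astype(np.int64)
    sy = np.rint(src[:, 1]).astype(np.int64)
    in_ny, in_nx = img.shape
    valid = (sx >= 0) & (sx < in_nx) & (sy >= 0) & (sy < in_ny)
    counts = np.zeros(ny * nx, dtype=img.photon_counts.dtype)
    sums = np.zeros(ny * nx, dtype=float)
    counts[valid] = img.photon_counts[sy[valid], sx[valid]]
    sums[valid] = img.lifetime_weighted_sum[sy[valid], sx[valid]]
    if out_pixel_size_nm is None:
        out_pixel_size_nm = img.pixel_size_nm / T.scale
    return FlimImage(
        photon_counts=counts.reshape(out_shape),
        lifetime_weighted_sum=sums.reshape(out_shape),
        pixel_size_nm=out_pixel_size_nm,
        cell_id=img.cell_id,
    )


def roi_mean_lifetime(
    img: FlimImage, roi: tuple[int, int, int, int]
) -> tuple[float, int]:
    """Photon-weighted mean lifetime over a rectangular ROI.

    ``roi`` is (x0, y0, x1, y1), half-open in pixels.  Equivalent to
    pooling every photon in the ROI into one decay and taking its mean:
    sum(lifetime_weighted_sum) / sum(photon_counts).
    """
    x0, y0, x1, y1 = roi
    ny, nx = img.shape
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise InvalidParameterError(f"ROI {roi} outside image bounds {(nx, ny)}")
    counts = img.photon_counts[y0:y1, x0:x1]
    total = int(counts.sum())
    if total == 0:
        raise InsufficientPhotonsError(f"no photons in ROI {roi}")
    mean = float(img.lifetime_weighted_sum[y0:y1, x0:x1].sum() / total)
    return mean, total


def summarize_cell(records: list[CCSRecord] | pd.DataFrame) -> CellSummary:
    """Per-cell curvature-class means, referenced to the flat-class mean.

    FRET efficiencies vary between cells with probe expression, so each
    lattice class is compared with the mean of flat structures from the
    same membrane: delta(class) = mean(class) - mean(flat) in ns.  Classes
    absent from the cell yield NaN, not 0.

    Raises
    ------
    InvalidParameterError
        No flat structures in the cell (no reference; exclude the cell).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {
                "cell_id": [r.cell_id for r in records],
                "curvature_class": [r.curvature_class for r in records],
                "mean_lifetime_ns": [r.mean_lifetime_ns for r in records],
                "photons": [r.photons for r in records],
            }
        )
    if df.empty:
        raise InvalidParameterError("no structures to summarize")
    cells = df["cell_id"].unique()
    if len(cells) != 1:
        raise InvalidParameterError(f"records span multiple cells: {list(cells)}")
    means = df.groupby("curvature_class")["mean_lifetime_ns"].mean()
    counts = df.groupby("curvature_class")["mean_lifetime_ns"].size()
    if "flat" not in means.index:
        raise InvalidParameterError(
            f"cell {cells[0]!r} has no flat structures; no reference class"
        )
    flat_mean = float(means["flat"])
    class_mean = {c: float(means.get(c, np.nan)) for c in CURVATURE_CLASSES}
    delta = {c: class_mean[c] - flat_mean for c in CURVATURE_CLASSES}
    # photon-weighted cellular average: total photon pool over all structures
    cellular = float(
        np.average(df["mean_lifetime_ns"], weights=np.maximum(df["photons"], 1))
    )
    return CellSummary(
        cell_id=str(cells[0]),
        class_mean_ns=class_mean,
        delta_vs_flat_ns=delta,
        cellular_average_lifetime_ns=cellular,
        n_structures={c: int(counts.get(c, 0)) for c in CURVATURE_CLASSES},
    )


def filter_cells_by_lifetime(
    summaries: list[CellSummary], threshold_ns: float = LIFETIME_FILTER_NS
) -> list[CellSummary]:
    """Keep cells whose cellular average lifetime is strictly below the
    threshold (default 2.1 ns).

    In donor+acceptor experiments the dark acceptor cannot be confirmed by
    its own fluorescence; a short cellular average lifetime is the evidence
    that it is expressed.  Apply only in donor+acceptor mode.
    """
    return [s for s in summaries if s.cellular_average_lifetime_ns < threshold_ns]


def morphometrics(
    mask: np.ndarray,
    classes: pd.DataFrame,
    membrane_area_nm2: float,
    pixel_size_nm: float,
) -> pd.DataFrame:
    """EM lattice morphometrics per curvature class.

    Parameters
    ----------
    mask : labeled 2-D integer array (0 = background).
    classes : DataFrame with columns ``label`` and ``curvature_class``
        covering every label present in the mask.
    membrane_area_nm2 : total measured membrane area; must be at least the
        summed structure area.
    pixel_size_nm : EM pixel size.

    Returns a DataFrame indexed by class with columns ``n`` (count),
    ``mean_area_nm2``, ``density_per_um2`` (count per µm² of membrane) and
    ``occupied_pct`` (summed class area / membrane area × 100).  Classes
    with no structures report zeros.
    """
    mask = np.asarray(mask)
    if {"label", "curvature_class"} - set(classes.columns):
        raise InvalidParameterError("classes needs columns label, curvature_class")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    table = classes.set_index("label")["curvature_class"]
    missing = [int(l) for l in labels if l not in table.index]
    if missing:
        raise InvalidParameterError(f"labels missing from class table: {missing}")
    px_area = pixel_size_nm**2
    counts = np.bincount(mask.ravel(), minlength=int(labels.max()) + 1 if len(labels) else 1)
    areas = {int(l): counts[int(l)] * px_area for l in labels}
    total_area = sum(areas.values())
    if membrane_area_nm2 < total_area:
        raise InvalidParameterError(
            "membrane_area_nm2 smaller than summed structure area"
        )
    rows = []
    for cls in CURVATURE_CLASSES:
        cls_labels = [l for l in areas if table.loc[l] == cls]
        cls_areas = [areas[l] for l in cls_labels]
        n = len(cls_labels)
        rows.append(
            {
                "curvature_class": cls,
                "n": n,
                "mean_area_nm2": float(np.mean(cls_areas)) if n else 0.0,
                "density_per_um2": n / (membrane_area_nm2 / 1e6),
                "occupied_pct": 100.0 * sum(cls_areas) / membrane_area_nm2,
            }
        )
    return pd.DataFrame(rows).set_index("curvature_class")
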