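"""Color-coded principal-component maps of MQN chemical space.

A PCA is fitted once on a *reference* MQN matrix (centered, unscaled
covariance PCA: the 42 integer counts share a scale, and the resulting
size-dominated first component has positive loadings in all descriptors).
Any other molecule set is then *projected* onto the reference (PC1, PC2)
plane — never refitted — and rasterized onto a square pixel grid
(1000 x 1000 by default).  Each occupied pixel is colour-coded in HSL space
by the mean of a molecular property over its members (hue runs
blue-cyan-green-yellow-red-magenta with increasing mean, passing through
orange between yellow and red) and fades towards grey as the within-pixel
standard deviation grows.  The *average molecule* of a pixel is the member
with the smallest city-block distance to the pixel's mean MQN vector.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from . import mqn as _mqn

DEFAULT_GRID = 1000
RANGE_PAD = 0.01  # axis span expanded by 1% (0.5% each side)


class ChemicalSpacePCA(BaseEstimator, TransformerMixin):
    """Covariance PCA of an MQN reference set with a fixed sign convention.

    Parameters
    ----------
    n_components : int
        Components kept (at least 3 so PC3 slicing stays available).
    standardize : bool
        Scale columns to unit variance before the eigendecomposition
        (correlation PCA).  Off by default: unscaled MQN counts give the
        characteristic size-dominated PC1 with all-positive loadings.

    Fitted attributes: ``mean_`` (42,), ``components_`` (k, 42) orthonormal
    loadings, ``explained_variance_ratio_`` (k,), ``axis_ranges_``
    ((k, 2) reference min/max per axis expanded by 1%).

    Sign convention: each component is flipped if its loading sum is
    negative, making PC1 a positive combination of all counts whenever the
    data are size-dominated.
    """

    def __init__(self, n_components: int = 3, standardize: bool = False):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X: np.ndarray, y=None) -> "ChemicalSpacePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need an (n >= 3, 42) MQN matrix")
        if np.unique(X, axis=0).shape[0] < 2:
            raise ValueError("reference matrix rank too low: fewer than 2 distinct rows")

        self.scale_ = X.std(axis=0, ddof=0) if self.standardize else None
        if self.scale_ is not None:
            self.scale_ = np.where(self.scale_ > 0, self.scale_, 1.0)

        k = min(max(self.n_components, 3), min(X.shape))
        work = X / self.scale_ if self.scale_ is not None else X
        pca = PCA(n_components=k)
        pca.fit(work)
        components = pca.components_.copy()
        flip = components.sum(axis=1) < 0
        components[flip] *= -1.0
        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = k

        proj = self.transform(X)
        lo, hi = proj.min(axis=0), proj.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        pad = span * RANGE_PAD / 2.0
        self.axis_ranges_ = np.stack([lo - pad, hi + pad], axis=1)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project MQN rows with the reference means and loadings (no refit)."""
        X = np.asarray(X, dtype=float)
        if self.scale_ is not None:
            X = X / self.scale_
        return (X - self.mean_) @ self.components_.T

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "axis_ranges": self.axis_ranges_.tolist(),
            "standardize": self.standardize,
            "scale": None if self.scale_ is None else self.scale_.tolist(),
            "mqn_names": list(_mqn.MQN_NAMES),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ChemicalSpacePCA":
        payload = json.loads(Path(path).read_text())
        model = cls(
            n_components=len(payload["components"]),
            standardize=payload["standardize"],
        )
        model.mean_ = np.asarray(payload["mean"])
        model.components_ = np.asarray(payload["components"])
        model.explained_variance_ratio_ = np.asarray(
            payload["explained_variance_ratio"]
        )
        model.axis_ranges_ = np.asarray(payload["axis_ranges"])
        model.scale_ = None if payload["scale"] is None else np.asarray(payload["scale"])
        model.n_components_ = len(model.components_)
        return model


def fit_pca(reference: np.ndarray, **kwargs) -> ChemicalSpacePCA:
    return ChemicalSpacePCA(**kwargs).fit(reference)


def project(model: ChemicalSpacePCA, mqn_rows: np.ndarray) -> np.ndarray:
    return model.transform(mqn_rows)


# --------------------------------------------------------------------------
# Rasterization
# --------------------------------------------------------------------------

@dataclass
class Pixel:
    members: list[str] = field(default_factory=list)
    rows: list[int] = field(default_factory=list)  # row indices into the MQN matrix
    mean: float | None = None
    sd: float | None = None
    avg_id: str | None = None
    hsl: tuple[float, float, float] | None = None

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def hex_colour(self) -> str | None:
        if self.hsl is None:
            return None
        h, s, l = self.hsl
        r, g, b = colorsys.hls_to_rgb((h % 360.0) / 360.0, l, s)
        return "#{:02x}{:02x}{:02x}".format(
            round(r * 255), round(g * 255), round(b * 255)
        )


@dataclass
class PixelMap:
    grid_size: int
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    pixels: dict[tuple[int, int], Pixel]
    mqn_rows: np.ndarray | None = None

    @property
    def occupied(self) -> int:
        return len(self.pixels)


def _to_pixel(value: float, lo: float, hi: float, grid: int) -> int:
    if hi <= lo:
        return 0
    p = int(np.floor((value - lo) / (hi - lo) * grid))
    return min(max(p, 0), grid - 1)  # out-of-range points clamp to the border


def rasterize(
    projections: np.ndarray,
    ids: Sequence[str],
    mqn_rows: np.ndarray | None = None,
    grid_size: int = DEFAULT_GRID,
    ranges: np.ndarray | None = None,
) -> PixelMap:
    """Assign each projected molecule to exactly one (PC1, PC2) pixel.

    ``ranges`` are the reference axis ranges from the fitted model; if
    omitted they are derived from the projections themselves (expanded by
    1%).  Supplying ``mqn_rows`` enables per-pixel average molecules.
    """
    projections = np.asarray(projections, dtype=float).reshape(-1, projections.shape[-1] if np.ndim(projections) > 1 else 2)
    if ranges is None and len(projections) == 0:
        ranges = np.array([[0.0, 1.0], [0.0, 1.0]])
    if ranges is None:
        lo, hi = projections.min(axis=0), projections.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        pad = span * RANGE_PAD / 2.0
        ranges = np.stack([lo - pad, hi + pad], axis=1)
    (x_lo, x_hi), (y_lo, y_hi) = ranges[0], ranges[1]

    pixels: dict[tuple[int, int], Pixel] = {}
    for row, (mol_id, point) in enumerate(zip(ids, projections)):
        key = (
            _to_pixel(point[0], x_lo, x_hi, grid_size),
            _to_pixel(point[1], y_lo, y_hi, grid_size),
        )
        px = pixels.setdefault(key, Pixel())
        px.members.append(mol_id)
        px.rows.append(row)

    pixmap = PixelMap(grid_size, (x_lo, x_hi), (y_lo, y_hi), pixels, mqn_rows)
    if mqn_rows is not None:
        for px in pixels.values():
            px.avg_id = average_molecule(px, np.asarray(mqn_rows))
    return pixmap


def average_molecule(pixel: Pixel, mqn_rows: np.ndarray) -> str:
    """The member closest (city-block) to the pixel's mean MQN vector.

    Ties break to the lowest id.
    """
    rows = np.asarray(pixel.rows)
    sub = mqn_rows[rows]
    centre = sub.mean(axis=0)
    dists = np.abs(sub - centre).sum(axis=1)
    best = dists.min()
    candidates = [pixel.members[i] for i in np.flatnonzero(dists == best)]
    return min(candidates)


# --------------------------------------------------------------------------
# Colour coding
# --------------------------------------------------------------------------

#: Hue waypoints (degrees), traversed linearly with increasing pixel mean:
#: blue, cyan, green, yellow, red, magenta.  Orange (~30 degrees) lies on
#: the yellow-to-red leg.
HUE_PATH = (240.0, 180.0, 120.0, 60.0, 0.0, -60.0)


def _hue(t: float) -> float:
    """Position t in [0, 1] along the blue-to-magenta hue path, in degrees."""
    t = min(max(t, 0.0), 1.0)
    segs = len(HUE_PATH) - 1
    x = t * segs
    i = min(int(np.floor(x)), segs - 1)
    frac = x - i
    return (HUE_PATH[i] + (HUE_PATH[i + 1] - HUE_PATH[i]) * frac) % 360.0


def colour_pixels(
    pixmap: PixelMap,
    values: Mapping[str, float] | Sequence[float],
) -> PixelMap:
    """Colour-code occupied pixels by a per-molecule property.

    ``values`` maps molecule id -> property value (or is a sequence aligned
    with the rasterized rows).  Hue follows the blue-to-magenta path over
    the occupied-pixel mean range; saturation is ``max(0, 1 - sd/sd95)``
    with ``sd95`` the 95th percentile of positive pixel SDs (single-member
    pixels have sd 0, hence full saturation); lightness is fixed at 0.5.
    """
    for px in pixmap.pixels.values():
        if isinstance(values, Mapping):
            vals = np.asarray([values[m] for m in px.members], dtype=float)
        else:
            vals = np.asarray([values[r] for r in px.rows], dtype=float)
        px.mean = float(vals.mean())
        px.sd = float(vals.std(ddof=0))

    means = np.asarray([px.mean for px in pixmap.pixels.values()])
    sds = np.asarray([px.sd for px in pixmap.pixels.values()])
    if means.size == 0:
        return pixmap
    m_lo, m_hi = means.min(), means.max()
    pos_sds = sds[sds > 0]
    sd95 = float(np.percentile(pos_sds, 95)) if pos_sds.size else 1.0

    for px in pixmap.pixels.values():
        t = 0.0 if m_hi <= m_lo else (px.mean - m_lo) / (m_hi - m_lo)
        sat = max(0.0, 1.0 - px.sd / sd95) if sd95 > 0 else 1.0
        px.hsl = (_hue(t), sat, 0.5)
    return pixmap


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def export_map(
    pixmap: PixelMap, png_path: str | Path | None, tsv_path: str | Path
) -> None:
    """Write the map as a PNG raster and a per-pixel TSV.

    The TSV lists occupied pixels only (x, y, count, mean, sd, avg_id,
    colour); the PNG paints empty pixels white and puts pixel (0, 0) at the
    bottom-left.
    """
    rows = []
    for (x, y), px in sorted(pixmap.pixels.items()):
        rows.append(
            {
                "x": x,
                "y": y,
                "count": px.count,
                "mean": px.mean,
                "sd": px.sd,
                "avg_id": px.avg_id,
                "colour": px.hex_colour,
            }
        )
    pd.DataFrame(
        rows, columns=["x", "y", "count", "mean", "sd", "avg_id", "colour"]
    ).to_csv(tsv_path, sep="\t", index=False)

    if png_path is not None:
        from PIL import Image

        g = pixmap.grid_size
        img = np.full((g, g, 3), 255, dtype=np.uint8)
        for (x, y), px in pixmap.pixels.items():
            colour = px.hex_colour
            rgb = (
                tuple(int(colour[i : i + 2], 16) for i in (1, 3, 5))
                if colour
                else (0, 0, 0)
            )
            img[g - 1 - y, x] = rgb
        Image.fromarray(img, mode="RGB").save(png_path)
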