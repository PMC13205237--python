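"""Quantitative IHC scoring: deconvolution, registration, segmentation, qi, Pr.

The quantification contract is marker-agnostic and recognizer-agnostic:

* per cell ``i``, the positivity score is the exact pixel-area ratio
  ``qi = A_positive,i / A_cell,i``;
* a cell is called positive when ``qi >= alpha`` (inclusive boundary);
* per region of interest ``r``, the positivity rate is
  ``Pr = 100 * N_positive,r / N_total,r``.

``alpha`` can be supplied manually or derived from the empirical qi
distribution by an exact Otsu criterion (between-class variance maximised
over the midpoints of sorted unique qi values).

Cell detection is classical: global optical-density threshold on the nuclear
counterstain channel, distance transform, and marker-controlled watershed.
Registration is translation-only, estimated by cross-correlation in the
frequency domain. The proportion of positive cells, not staining intensity,
is the sole quantitative output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .synthetic import DAB_OD, HEMATOXYLIN_OD, StainTilePair

__all__ = [
    "QuantConfig",
    "CellRecord",
    "RoiQuantification",
    "QcReport",
    "deconvolve",
    "register",
    "segment_cells",
    "auto_threshold",
    "score_cells",
    "quantify_roi",
    "qc_tile",
    "quantify_tile_pair",
    "cells_to_frame",
]


@dataclass
class QuantConfig:
    """Tunables of the quantification pipeline.

    ``nuclear_od_threshold`` is the global foreground threshold on the
    counterstain OD channel; ``positive_od_threshold`` is the pixel-level
    chromogen OD above which a pixel counts toward ``A_positive``.
    """

    stain_vectors: tuple[np.ndarray, np.ndarray] = (HEMATOXYLIN_OD, DAB_OD)
    nuclear_od_threshold: float = 0.15
    positive_od_threshold: float = 0.20
    min_area_px: int = 12
    min_peak_separation: int = 5
    artifact_ceiling: float = 0.20
    min_snr: float = 2.0
    artifact_block: int = 16


@dataclass
class CellRecord:
    """One segmented cell with its exact area-ratio positivity score."""

    cell_id: int
    centroid: tuple[float, float]  # (row, col), 0-based
    area_px: int
    positive_area_px: int
    qi: float
    is_positive: bool


@dataclass
class QcReport:
    background_median_od: float
    signal_to_noise: float
    artifact_fraction: float
    pass_flag: bool


@dataclass
class RoiQuantification:
    roi_id: str
    n_total: int
    n_positive: int
    positivity_rate_pct: float
    alpha: float
    qc: QcReport | None = None

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _as_od(rgb: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density of an 8-bit RGB raster."""
    return -np.log((rgb.astype(float) + 1.0) / 256.0)


def deconvolve(rgb_tile: np.ndarray, stain_vectors=None) -> np.ndarray:
    """Unmix an RGB tile into per-stain optical-density channels.

    The pixel OD vector is projected onto the stain basis with the
    pseudo-inverse; negative projections are clipped to zero. Returns an
    array of shape ``(H, W, n_stains)`` in the order the vectors were given.
    """
    if stain_vectors is None:
        stain_vectors = (HEMATOXYLIN_OD, DAB_OD)
    basis = np.stack([np.asarray(v, dtype=float) for v in stain_vectors])
    if basis.ndim != 2 or basis.shape[1] != 3 or not 2 <= basis.shape[0] <= 3:
        raise ValueError("expected two or three RGB stain vectors")
    if np.linalg.matrix_rank(basis) < basis.shape[0]:
        raise ValueError("stain matrix is rank-deficient; vectors must be linearly independent")
    od = _as_od(rgb_tile).reshape(-1, 3)
    conc = od @ np.linalg.pinv(basis)
    conc = np.clip(conc, 0.0, None)
    return conc.reshape(rgb_tile.shape[0], rgb_tile.shape[1], basis.shape[0])


def _to_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr


def register(reference_tile: np.ndarray, moving_tile: np.ndarray) -> tuple[int, int]:
    """Estimate the integer (rows, cols) translation of ``moving_tile``
    relative to ``reference_tile`` by frequency-domain cross-correlation.

    The returned shift is the displacement the moving tile has undergone:
    translating the moving tile by its negation re-aligns the pair.
    """
    ref = _to_gray(reference_tile)
    mov = _to_gray(moving_tile)
    if ref.shape != mov.shape:
        raise ValueError("tiles must share dimensions")
    if ref.std() == 0 or mov.std() == 0:
        raise ValueError("featureless (constant) tile: translation is unidentifiable")
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1, normalization="phase")
    # phase_cross_correlation returns the shift to apply to `mov` to match
    # `ref`, i.e. the negative of the displacement mov has undergone.
    dy, dx = (-int(round(s)) for s in shift)
    return dy, dx


def segment_cells(nuclear_od: np.ndarray, config: QuantConfig | None = None) -> np.ndarray:
    """Label individual cells on a non-negative nuclear-OD channel.

    Foreground by global OD threshold; touching cells are split by a
    watershed on the negated distance transform, seeded at distance-map local
    maxima with a minimum separation; objects below ``min_area_px`` are
    dropped. Background is 0, labels are positive integers.
    """
    config = config or QuantConfig()
    od = np.asarray(nuclear_od, dtype=float)
    if od.ndim != 2:
        raise ValueError("expected a single-channel raster")
    fg = od > config.nuclear_od_threshold
    if not fg.any():
        return np.zeros(od.shape, dtype=np.int32)
    comp, _ = ndimage.label(fg)
    sizes = np.bincount(comp.ravel())
    fg &= sizes[comp] >= config.min_area_px
    if not fg.any():
        return np.zeros(od.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=config.min_peak_separation, labels=fg, exclude_border=False
    )
    markers = np.zeros(od.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(fg)
    labels = watershed(-dist, markers, mask=fg)
    # drop fragments below the area floor, then relabel densely
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < config.min_area_px)
    labels[np.isin(labels, small[small > 0])] = 0
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out.astype(np.int32)


def auto_threshold(qi_values) -> float:
    """Otsu's criterion on the empirical qi distribution, computed exactly.

    Candidate thresholds are the midpoints of consecutive sorted unique qi
    values; the between-class variance ``w0*w1*(mu0-mu1)^2`` is maximised
    exhaustively. Ties go to the smallest candidate.
    """
    q = np.sort(np.asarray(qi_values, dtype=float))
    if q.size < 2:
        raise ValueError("need at least two qi values")
    uniq = np.unique(q)
    if uniq.size < 2:
        raise ValueError(
            "all qi values identical; automatic thresholding is undefined — supply alpha manually"
        )
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = q.size
    best_alpha, best_var = mids[0], -np.inf
    csum = np.cumsum(q)
    for t in mids:
        k = np.searchsorted(q, t)  # size of the low class
        w0 = k / n
        w1 = 1.0 - w0
        mu0 = csum[k - 1] / k
        mu1 = (csum[-1] - csum[k - 1]) / (n - k)
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var = var
            best_alpha = t
    return float(best_alpha)


def score_cells(labeled_mask: np.ndarray, positive_mask: np.ndarray, alpha: float) -> list[CellRecord]:
    """Exact per-cell areas, positivity scores and calls.

    ``qi = positive_area_px / area_px`` counted within each label;
    ``is_positive`` uses the inclusive rule ``qi >= alpha``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    labels = np.asarray(labeled_mask)
    pos = np.asarray(positive_mask, dtype=bool)
    if labels.shape != pos.shape:
        raise ValueError("masks must share dimensions")
    n_labels = int(labels.max())
    if n_labels == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
    pos_areas = np.bincount(labels.ravel(), weights=pos.ravel().astype(float),
                            minlength=n_labels + 1)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n_labels + 1))
    records = []
    for cid in range(1, n_labels + 1):
        a = int(areas[cid])
        if a == 0:
            continue
        ap = int(pos_areas[cid])
        qi = ap / a
        records.append(
            CellRecord(
                cell_id=cid,
                centroid=(float(centroids[cid - 1][0]), float(centroids[cid - 1][1])),
                area_px=a,
                positive_area_px=ap,
                qi=qi,
                is_positive=bool(qi >= alpha),
            )
        )
    return records


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "row": [c.centroid[0] for c in cells],
            "col": [c.centroid[1] for c in cells],
            "area_px": [c.area_px for c in cells],
            "positive_area_px": [c.positive_area_px for c in cells],
            "qi": [c.qi for c in cells],
            "is_positive": [c.is_positive for c in cells],
        }
    )


def quantify_roi(cells: list[CellRecord], roi_id: str, alpha: float,
                 qc: QcReport | None = None) -> RoiQuantification:
    """Positivity rate ``Pr = 100 * N_positive / N_total`` for one ROI."""
    if len(cells) == 0:
        raise ValueError("no cells segmented in this ROI")
    n_total = len(cells)
    n_positive = sum(c.is_positive for c in cells)
    return RoiQuantification(
        roi_id=roi_id,
        n_total=n_total,
        n_positive=n_positive,
        positivity_rate_pct=100.0 * n_positive / n_total,
        alpha=alpha,
        qc=qc,
    )


def qc_tile(pair: StainTilePair, config: QuantConfig | None = None) -> QcReport:
    """Background staining, signal-to-noise and artifact screening.

    Background is the median OD outside segmented cells; SNR is the in-cell
    mean OD minus background, divided by the background OD standard deviation.
    The artifact fraction counts pixels in saturated-black or exactly
    flat-constant blocks. A tile fails QC when the artifact fraction exceeds
    the configured ceiling or the SNR falls below its floor; a blank tile
    (nothing segmented) fails with SNR reported as 0.
    """
    config = config or QuantConfig()
    ihc = np.asarray(pair.ihc_rgb)
    gray = _to_gray(ihc)
    od_total = -np.log((gray + 1.0) / 256.0)

    # Artifact screen on non-overlapping blocks: saturated black or zero variance.
    b = config.artifact_block
    h, w = gray.shape
    artifact_px = 0
    for r0 in range(0, h, b):
        for c0 in range(0, w, b):
            block = gray[r0 : r0 + b, c0 : c0 + b]
            if block.mean() < 10.0 or block.std() == 0.0:
                artifact_px += block.size
    artifact_fraction = artifact_px / gray.size

    conc = deconvolve(ihc, config.stain_vectors)
    labels = segment_cells(conc[:, :, 0], config)
    in_cell = labels > 0
    if not in_cell.any() or in_cell.all():
        return QcReport(
            background_median_od=float(np.median(od_total)),
            signal_to_noise=0.0,
            artifact_fraction=float(artifact_fraction),
            pass_flag=False,
        )
    bg = od_total[~in_cell]
    background = float(np.median(bg))
    noise_sd = float(bg.std())
    if noise_sd == 0:
        snr = 0.0
    else:
        snr = float((od_total[in_cell].mean() - background) / noise_sd)
    pass_flag = bool(artifact_fraction <= config.artifact_ceiling and snr >= config.min_snr)
    return QcReport(
        background_median_od=background,
        signal_to_noise=snr,
        artifact_fraction=float(artifact_fraction),
        pass_flag=pass_flag,
    )


def quantify_tile_pair(
    pair: StainTilePair,
    roi_id: str = "roi",
    alpha: float | str = "auto",
    config: QuantConfig | None = None,
) -> tuple[RoiQuantification, list[CellRecord]]:
    """End-to-end quantification of one H&E/IHC tile pair.

    Registers the IHC tile to the H&E tile (translation only), undoes the
    shift, crops the vacated border, unmixes counterstain and chromogen,
    segments cells on the counterstain OD channel, scores each cell, derives
    ``alpha`` automatically unless given, and returns the ROI quantification
    together with the per-cell records.
    """
    config = config or QuantConfig()
    dy, dx = register(pair.he_rgb, pair.ihc_rgb)
    from .synthetic import _translate  # shared translation helper

    ihc = _translate(np.asarray(pair.ihc_rgb), (-dy, -dx), fill=255)
    m = max(abs(dy), abs(dx))
    if m > 0:
        ihc = ihc[m:-m or None, m:-m or None]
    conc = deconvolve(ihc, config.stain_vectors)
    labels = segment_cells(conc[:, :, 0], config)
    positive_mask = conc[:, :, 1] > config.positive_od_threshold
    if alpha == "auto":
        provisional = score_cells(labels, positive_mask, alpha=1.0)
        if not provisional:
            raise ValueError("no cells segmented in this ROI")
        alpha_val = auto_threshold([c.qi for c in provisional])
    else:
        alpha_val = float(alpha)
    cells = score_cells(labels, positive_mask, alpha_val)
    qc = qc_tile(pair, config)
    roi = quantify_roi(cells, roi_id, alpha_val, qc)
    return roi, cells
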