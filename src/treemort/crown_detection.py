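"""Treetop detection and crown segmentation on a canopy height model.

Treetops are local maxima of the CHM within a height-dependent circular
window; crowns are delineated by marker-based watershed on the inverted
CHM, masked to pixels at or above the minimum mapped height. This mirrors
the standard local-maxima + watershed workflow used for conical conifer
crowns, where apices are well defined and crowns barely overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

MIN_CROWN_PIXELS = 3


def default_window_radius(height):
    """Search-window radius in metres for a given apex height: max(1.5, 0.05*h)."""
    return np.maximum(1.5, 0.05 * np.asarray(height, dtype=float))


@dataclass
class CrownMap:
    """Labeled crown raster plus per-crown metrics.

    ``labels`` is 0 for background; label k > 0 is crown k. ``crowns`` has
    one row per crown: crown_id, apex_row, apex_col, apex_x, apex_y,
    max_height (the apex CHM value, used as tree height Z downstream),
    pixel_count, area_m2, centroid_x, centroid_y.
    """

    labels: np.ndarray
    crowns: pd.DataFrame
    resolution_m: float


def _circular_offsets(radius_px: int):
    r = int(radius_px)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = (dx ** 2 + dy ** 2) <= r ** 2
    return dy[keep], dx[keep]


def detect_treetops(chm: np.ndarray, min_height: float = 5.0,
                    window_radius_fn=default_window_radius,
                    resolution_m: float = 0.6) -> pd.DataFrame:
    """Detect treetops as height-dependent circular-window local maxima.

    A pixel is a treetop if its CHM value is >= `min_height` and no pixel
    within its window is higher; among equal-valued pixels in the window the
    one earliest in row-major order wins, so plateaus yield exactly one top
    and output order is deterministic.

    Returns a DataFrame with columns row, col, x, y, height (row-major order).
    """
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    chm = np.asarray(chm, dtype=float)
    if not np.isfinite(chm).all():
        raise ValueError("CHM must be finite")
    rows, cols = chm.shape
    candidate = chm >= min_height
    if not candidate.any():
        return pd.DataFrame(columns=["row", "col", "x", "y", "height"])

    # bucket candidates by integer window radius so each bucket can be
    # screened with one maximum_filter pass
    radii_m = window_radius_fn(chm)
    radii_px = np.maximum(np.round(radii_m / resolution_m).astype(int), 1)
    tops_mask = np.zeros_like(candidate)
    for r_px in np.unique(radii_px[candidate]):
        sel = candidate & (radii_px == r_px)
        if not sel.any():
            continue
        dy, dx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
        footprint = (dx ** 2 + dy ** 2) <= r_px ** 2
        local_max = ndimage.maximum_filter(chm, footprint=footprint, mode="constant",
                                           cval=-np.inf)
        tops_mask |= sel & (chm >= local_max)

    # resolve plateau ties: drop any candidate with an equal-valued,
    # earlier (row-major) pixel inside its own window
    trows, tcols = np.nonzero(tops_mask)
    keep_rows, keep_cols = [], []
    for rr, cc in zip(trows, tcols):
        r_px = radii_px[rr, cc]
        dy, dx = _circular_offsets(r_px)
        yy = rr + dy
        xx = cc + dx
        ok = (yy >= 0) & (yy < rows) & (xx >= 0) & (xx < cols)
        yy, xx = yy[ok], xx[ok]
        vals = chm[yy, xx]
        h = chm[rr, cc]
        if (vals > h).any():
            continue
        eq = vals == h
        if ((yy[eq] * cols + xx[eq]) < (rr * cols + cc)).any():
            continue
        keep_rows.append(rr)
        keep_cols.append(cc)
    keep_rows = np.asarray(keep_rows, dtype=int)
    keep_cols = np.asarray(keep_cols, dtype=int)
    order = np.argsort(keep_rows * cols + keep_cols)
    keep_rows, keep_cols = keep_rows[order], keep_cols[order]
    return pd.DataFrame({
        "row": keep_rows,
        "col": keep_cols,
        "x": (keep_cols + 0.5) * resolution_m,
        "y": (keep_rows + 0.5) * resolution_m,
        "height": chm[keep_rows, keep_cols],
    })


def segment_crowns(chm: np.ndarray, treetops: pd.DataFrame,
                   min_height: float = 5.0, resolution_m: float = 0.6) -> CrownMap:
    """Delineate crowns by watershed of the inverted CHM from treetop markers.

    The watershed floods -CHM from the markers over the mask CHM >=
    min_height with 4-connectivity, so every above-threshold pixel joins
    the catchment of exactly one treetop. Catchments smaller than
    MIN_CROWN_PIXELS are merged into the neighboring crown with the highest
    shared-border CHM; masked components containing no marker are labeled
    as new crowns seeded at their own maximum so the labels always partition
    the mask.
    """
    chm = np.asarray(chm, dtype=float)
    mask = chm >= min_height
    labels = np.zeros(chm.shape, dtype=np.int32)
    if len(treetops) == 0:
        return CrownMap(labels=labels,
                        crowns=_crown_table(labels, chm, resolution_m, {}),
                        resolution_m=resolution_m)
    t_rows = treetops["row"].to_numpy(dtype=int)
    t_cols = treetops["col"].to_numpy(dtype=int)
    below = ~mask[t_rows, t_cols]
    if below.any():
        bad = np.nonzero(below)[0]
        raise ValueError(
            "treetop markers on below-threshold pixels at (row, col): "
            + ", ".join(f"({t_rows[i]}, {t_cols[i]})" for i in bad[:10]))
    markers = np.zeros(chm.shape, dtype=np.int32)
    markers[t_rows, t_cols] = np.arange(1, len(treetops) + 1)
    labels = watershed(-chm, markers=markers, mask=mask, connectivity=1)

    # orphan masked components (no marker fell inside them) become crowns
    # seeded at their own maximum
    orphan = mask & (labels == 0)
    if orphan.any():
        comp, ncomp = ndimage.label(orphan, structure=np.array([[0, 1, 0],
                                                                [1, 1, 1],
                                                                [0, 1, 0]]))
        next_label = labels.max() + 1
        for ci in range(1, ncomp + 1):
            labels[comp == ci] = next_label
            next_label += 1

    labels = _merge_small_crowns(labels, chm)
    apex = _apex_lookup(labels, chm)
    return CrownMap(labels=labels, crowns=_crown_table(labels, chm, resolution_m, apex),
                    resolution_m=resolution_m)


def _merge_small_crowns(labels: np.ndarray, chm: np.ndarray) -> np.ndarray:
    """Merge crowns below the minimum pixel count into the 4-neighbor crown
    with the highest CHM on the shared border; isolated small crowns keep
    their label."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < MIN_CROWN_PIXELS]
        merged_any = False
        for sid in small:
            mask = labels == sid
            best_label, best_h = 0, -np.inf
            rr, cc = np.nonzero(mask)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = rr + dr, cc + dc
                ok = (nr >= 0) & (nr < labels.shape[0]) & (nc >= 0) & (nc < labels.shape[1])
                nr, nc = nr[ok], nc[ok]
                neigh = labels[nr, nc]
                for j in np.nonzero((neigh > 0) & (neigh != sid))[0]:
                    h = chm[nr[j], nc[j]]
                    if h > best_h:
                        best_h, best_label = h, neigh[j]
            if best_label:
                labels[mask] = best_label
                merged_any = True
        if not merged_any:
            break
    return labels


def _apex_lookup(labels, chm):
    apex = {}
    for cid in np.unique(labels[labels > 0]):
        mask = labels == cid
        idx = np.argmax(np.where(mask, chm, -np.inf))
        apex[int(cid)] = np.unravel_index(idx, chm.shape)
    return apex


def _crown_table(labels, chm, resolution_m, apex):
    recs = []
    for cid in sorted(apex):
        mask = labels == cid
        npx = int(mask.sum())
        rr, cc = np.nonzero(mask)
        ar, ac = apex[cid]
        recs.append({
            "crown_id": cid,
            "apex_row": ar, "apex_col": ac,
            "apex_x": (ac + 0.5) * resolution_m, "apex_y": (ar + 0.5) * resolution_m,
            "max_height": chm[ar, ac],
            "pixel_count": npx,
            "area_m2": npx * resolution_m ** 2,
            "centroid_x": (cc.mean() + 0.5) * resolution_m if npx else np.nan,
            "centroid_y": (rr.mean() + 0.5) * resolution_m if npx else np.nan,
        })
    cols = ["crown_id", "apex_row", "apex_col", "apex_x", "apex_y", "max_height",
            "pixel_count", "area_m2", "centroid_x", "centroid_y"]
    return pd.DataFrame(recs, columns=cols)


def check_crown_map(crown_map: CrownMap, chm: np.ndarray, min_height: float) -> None:
    """Assert the CrownMap partition invariants; raises AssertionError."""
    labels = crown_map.labels
    mask = np.asarray(chm) >= min_height
    assert ((labels > 0) == mask).all(), "labels do not partition the mask"
    table = crown_map.crowns
    assert table["crown_id"].is_unique
    for t in table.itertuples():
        m = labels == t.crown_id
        assert m[t.apex_row, t.apex_col], "apex outside its crown"
        assert np.isclose(chm[t.apex_row, t.apex_col], t.max_height)
        assert np.isclose(np.max(np.where(m, chm, -np.inf)), t.max_height), \
            "crown max_height != apex height"
        ncomp = ndimage.label(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
        assert ncomp == 1, "crown pixel set not 4-connected"


def crown_cover_fraction(chm: np.ndarray, min_height: float = 5.0,
                         cell_size_m: float = 100.0,
                         resolution_m: float = 0.6) -> np.ndarray:
    """Aggregate the CHM to percent canopy cover per coarse cell.

    Cover is the percentage of pixels with CHM strictly above ``min_height``
    in each ``cell_size_m`` x ``cell_size_m`` block; ``cell_size_m`` must be
    an integer multiple of the pixel size. Trailing partial blocks are
    dropped.
    """
    factor = cell_size_m / resolution_m
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("cell_size_m must be an integer multiple of resolution_m")
    f = int(round(factor))
    chm = np.asarray(chm)
    rows = (chm.shape[0] // f) * f
    cols = (chm.shape[1] // f) * f
    above = (chm[:rows, :cols] > min_height).astype(float)
    blocks = above.reshape(rows // f, f, cols // f, f)
    return blocks.mean(axis=(1, 3)) * 100.0
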