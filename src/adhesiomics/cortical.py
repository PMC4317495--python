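"""Geometric quantification of microtubule targeting of the cell cortex.

Fixed-image quantifications: microtubule counts in 5 x 2 um boxes tiling the
cell periphery, background-filtered intensity over micropatterned ligand
patches, and positive-signal area fractions. Live-imaging quantifications:
per-frame distance from each microtubule tip to the cell edge, residence
lifetime within a 2 um cortical band at a 10 s frame interval, and comet
displacement summaries.

All coordinates are in micrometres; the cell boundary is a simple closed
polygon traced from the actin channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "peripheral_boxes",
    "mt_box_counts",
    "patch_quantify",
    "tip_edge_distance",
    "membrane_residence",
    "displacement_stats",
    "signal_fraction",
    "PeripheralBox",
]


def _as_ccw_polygon(boundary) -> Polygon:
    poly = boundary if isinstance(boundary, Polygon) else Polygon(boundary)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("boundary must be a simple closed polygon with positive area")
    return shapely.geometry.polygon.orient(poly, sign=1.0)  # CCW exterior


@dataclass
class PeripheralBox:
    """One 5 x 2 um (by default) box along the cell edge."""

    polygon: Polygon
    arc_start: float
    arc_length: float
    short: bool  # True for a trailing box shorter than the nominal length


def _edge_geometry(poly: Polygon):
    xy = np.asarray(poly.exterior.coords)  # closed ring, CCW
    verts = xy[:-1]
    nv = len(verts)
    edges = xy[1:] - xy[:-1]
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    if (lengths == 0).any():
        raise ValueError("degenerate (zero-length) polygon edge")
    units = edges / lengths[:, None]
    # inward normal of a CCW ring: rotate edge direction by +90 degrees
    normals = np.stack([-units[:, 1], units[:, 0]], axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    return verts, nv, units, lengths, normals, cum


def peripheral_boxes(
    boundary,
    length_um: float = 5.0,
    depth_um: float = 2.0,
) -> list[PeripheralBox]:
    """Tile the cell periphery with boxes of ``length_um`` arc length that
    extend ``depth_um`` inward from the edge.

    Boxes are strips between the boundary and its inward offset, split every
    ``length_um`` of arc length starting at the first polygon vertex; corner
    vertices inside a box are offset along the miter direction so the strips
    cover the periphery without gaps. A trailing box shorter than
    ``length_um`` is flagged ``short``.
    """
    poly = _as_ccw_polygon(boundary)
    verts, nv, units, lengths, normals, cum = _edge_geometry(poly)
    perimeter = cum[-1]
    if perimeter < length_um:
        raise ValueError("perimeter shorter than one box length")

    def point_at(s: float) -> np.ndarray:
        i = min(np.searchsorted(cum, s, side="right") - 1, nv - 1)
        return verts[i] + units[i] * (s - cum[i])

    def edge_at(s: float, forward: bool) -> int:
        # edge containing arc position s; at a vertex, pick the edge the box
        # continues into (forward) or arrives from (backward)
        side = "right" if forward else "left"
        i = np.searchsorted(cum, s, side=side) - 1
        return int(np.clip(i, 0, nv - 1))

    def miter_offset(vi: int) -> np.ndarray:
        n_prev = normals[(vi - 1) % nv]
        n_next = normals[vi]
        m = n_prev + n_next
        norm = np.hypot(*m)
        if norm < 1e-12:  # 180-degree fold; fall back to one normal
            return verts[vi] + n_next * depth_um
        m = m / norm
        return verts[vi] + m * (depth_um / np.dot(m, n_next))

    boxes = []
    n_boxes = int(np.ceil(perimeter / length_um - 1e-9))
    for k in range(n_boxes):
        s0 = k * length_um
        s1 = min((k + 1) * length_um, perimeter)
        outer = [point_at(s0)]
        inner = [point_at(s0) + normals[edge_at(s0, forward=True)] * depth_um]
        for vi in range(nv):
            s = cum[vi]
            if s0 < s < s1 - 1e-12:
                outer.append(verts[vi])
                inner.append(miter_offset(vi))
        end = point_at(s1 if s1 < perimeter else 0.0)
        outer.append(end)
        inner.append(end + normals[edge_at(s1, forward=False)] * depth_um)
        ring = outer + inner[::-1]
        box = Polygon(ring)
        if not box.is_valid:
            box = box.buffer(0)
        boxes.append(
            PeripheralBox(
                polygon=box,
                arc_start=s0,
                arc_length=s1 - s0,
                short=(s1 - s0) < length_um - 1e-9,
            )
        )
    return boxes


def mt_box_counts(microtubules, boxes: list[PeripheralBox]):
    """Count microtubules per peripheral box.

    A microtubule increments a box count iff its polyline intersects the box
    (touching the border counts); one microtubule may count in several boxes
    but at most once per box.

    Returns (counts array, mean, sd) with sd the population s.d. over boxes.
    """
    lines = [m if isinstance(m, LineString) else LineString(m) for m in microtubules]
    counts = np.zeros(len(boxes), dtype=int)
    for line in lines:
        for j, box in enumerate(boxes):
            if line.intersects(box.polygon):
                counts[j] += 1
    return counts, float(counts.mean()), float(counts.std())


def patch_quantify(
    image: np.ndarray,
    centres_um: np.ndarray,
    pixel_size_um: float,
    diameter_um: float = 2.0,
    rolling_ball_px: int = 50,
    segments=None,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Background-filtered intensity and microtubule category per ligand patch.

    The image is background filtered with a rolling-ball radius of
    ``rolling_ball_px`` pixels; the mean filtered intensity is measured inside
    each 2 um patch disc. When ground-truth microtubule ``segments``
    (polylines in um) are supplied, each patch is categorized by the number of
    microtubules crossing its disc: 0 -> "none", 1-2 -> "1-2",
    >=3 -> "several". A ``cell_mask`` restricts patches to those overlapping
    the cell.
    """
    from skimage.restoration import rolling_ball

    image = np.asarray(image, dtype=float)
    background = rolling_ball(image, radius=rolling_ball_px)
    filtered = image - background
    h, w = image.shape
    radius_px = diameter_um / 2.0 / pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    discs = None
    if segments is not None:
        seg_lines = [s if isinstance(s, LineString) else LineString(s) for s in segments]
    for i, (cx, cy) in enumerate(np.asarray(centres_um, dtype=float)):
        cx_px, cy_px = cx / pixel_size_um, cy / pixel_size_um
        if not (0 <= cx_px < w and 0 <= cy_px < h):
            raise ValueError(f"patch {i} centre outside image")
        disc = (xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= radius_px**2
        if cell_mask is not None:
            if not (disc & cell_mask).any():
                continue
        if not disc.any():
            raise ValueError(f"patch {i} covers no pixels (pixel size too coarse)")
        mean_int = float(filtered[disc].mean())
        category = None
        if segments is not None:
            disc_geom = Point(cx, cy).buffer(diameter_um / 2.0)
            n_mt = sum(1 for line in seg_lines if line.intersects(disc_geom))
            category = "none" if n_mt == 0 else ("1-2" if n_mt <= 2 else "several")
        rows.append((i, cx, cy, mean_int, category))
    return pd.DataFrame(
        rows, columns=["patch", "x_um", "y_um", "mean_intensity", "category"]
    ).set_index("patch")


def tip_edge_distance(track, boundary, strict: bool = True) -> np.ndarray:
    """Per-frame Euclidean distance from the microtubule tip to the cell edge.

    ``track`` is an (n, 2) array of tip positions in um (or a DataFrame with
    x_um / y_um columns). Tips outside the boundary raise an error when
    ``strict``; otherwise their distance is reported as negative (signed
    outside).
    """
    if isinstance(track, pd.DataFrame):
        pts = track[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(track, dtype=float).reshape(-1, 2)
    poly = _as_ccw_polygon(boundary)
    points = shapely.points(pts)
    dist = shapely.distance(points, poly.exterior)
    inside = shapely.covers(poly, points)
    if not inside.all():
        if strict:
            bad = np.nonzero(~inside)[0]
            raise ValueError(f"tip positions outside the cell boundary at frames {bad.tolist()}")
        dist = np.where(inside, dist, -dist)
    return np.asarray(dist, dtype=float)


def membrane_residence(
    distances,
    band_um: float = 2.0,
    dt_s: float = 10.0,
    bins=None,
):
    """Residence lifetime at the membrane: the longest uninterrupted run of
    frames with tip-to-edge distance <= ``band_um``, times the frame interval.

    Returns (lifetime_s, bin_label); ``bins`` is an optional increasing list
    of right edges in seconds for histogram classes (label ``"<=edge"`` or
    ``">last"``).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    within = d <= band_um
    best = run = 0
    for w in within:
        run = run + 1 if w else 0
        best = max(best, run)
    lifetime = best * dt_s
    label = None
    if bins is not None:
        label = f">{bins[-1]:g}"
        for edge in bins:
            if lifetime <= edge:
                label = f"<={edge:g}"
                break
    return lifetime, label


def displacement_stats(
    tracks: pd.DataFrame,
    pause_threshold_um: float = 0.1,
) -> pd.DataFrame:
    """Frame-to-frame displacement summaries per microtubule track.

    Growth excursions are maximal runs of frames whose displacement exceeds
    ``pause_threshold_um`` per frame (pauses and shrinkage-free segments are
    excluded from excursion speed). Reports per track: mean displacement per
    frame, number of excursions, and mean excursion speed (um/frame; NaN when
    no excursion).
    """
    rows = []
    for mt_id, grp in tracks.sort_values("frame").groupby("mt_id"):
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(xy) < 2:
            continue
        disp = np.hypot(*np.diff(xy, axis=0).T)
        moving = disp > pause_threshold_um
        excursions = []
        cur = []
        for m, s in zip(moving, disp):
            if m:
                cur.append(s)
            elif cur:
                excursions.append(cur)
                cur = []
        if cur:
            excursions.append(cur)
        exc_speed = (
            float(np.mean([np.mean(e) for e in excursions])) if excursions else float("nan")
        )
        rows.append((mt_id, float(disp.mean()), len(excursions), exc_speed))
    return pd.DataFrame(
        rows, columns=["mt_id", "mean_displacement_um", "n_excursions", "excursion_speed_um"]
    ).set_index("mt_id")


def signal_fraction(
    positive_mask: np.ndarray,
    regions,
    pixel_size_um: float,
    min_area_um2: float = 40.0,
) -> float:
    """Percentage of positive signal within measurement regions of at least
    ``min_area_um2``.

    ``regions`` is a list of boolean masks (same shape as ``positive_mask``);
    regions smaller than the area floor are excluded from both numerator and
    denominator.
    """
    positive_mask = np.asarray(positive_mask, dtype=bool)
    px_area = pixel_size_um**2
    pos = total = 0
    for region in regions:
        region = np.asarray(region, dtype=bool)
        area = region.sum() * px_area
        if area < min_area_um2:
            continue
        pos += (positive_mask & region).sum()
        total += region.sum()
    if total == 0:
        raise ValueError("no measurement region reaches the minimum area")
    return 100.0 * pos / total
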