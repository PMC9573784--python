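"""Mask morphometry: stigma area and ovary diameter.

Stigma area is the mask pixel count times the squared pixel pitch -- the
phenotype is defined directly on the annotated envelope, with no boundary
smoothing.  Ovary diameter implements a five-step geometric procedure:

1. centroid of the stigma mask (unweighted mean of member-pixel coordinates);
2. centroid of the ovary mask;
3. the line through the ovary centroid perpendicular to the centroid-centroid
   axis (the carpel's long axis);
4. the two points where that line exits the ovary mask, found by marching
   from the ovary centroid in both directions in 0.25-px steps with
   nearest-pixel membership, keeping the membership run that contains the
   centroid (robust to ragged or concave rasterised boundaries);
5. the Euclidean distance between the exit points, converted to mm.

When the stigma mask is empty or the two centroids (nearly) coincide -- e.g.
a fully deteriorated stigma resting on the ovary -- the carpel long axis is
estimated instead as the major principal axis of the ovary mask's second
moments, and the measurement is flagged ``fallback_axis``.

Coordinates are (row, col) with the origin at the top-left pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CarpelImage

__all__ = [
    "CarpelMeasurement",
    "stigma_area",
    "ovary_diameter",
    "measure_batch",
    "measurements_to_frame",
    "MEASUREMENT_COLUMNS",
    "render_overlay",
]

MARCH_STEP = 0.25  # px
MEASUREMENT_COLUMNS = [
    "image_id", "cultivar", "timepoint_days", "fixation",
    "stigma_area_mm2", "ovary_diameter_mm", "stigma_px", "ovary_px",
    "mm_per_px", "flags",
]


@dataclass
class CarpelMeasurement:
    """One output row: both phenotypes for one image."""

    image_id: str
    stigma_area_mm2: float
    ovary_diameter_mm: float
    stigma_px: int
    ovary_px: int
    mm_per_px: float
    flags: set = field(default_factory=set)
    cultivar: str = ""
    timepoint_days: float = float("nan")
    fixation: bool = False
    diameter_endpoints: tuple | None = None


def stigma_area(mask: np.ndarray, mm_per_px: float):
    """Stigma area in mm^2: pixel count x mm_per_px^2.

    Returns ``(area_mm2, flags)``; an empty mask yields 0 with the
    ``empty_stigma`` flag.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    flags = set() if n else {"empty_stigma"}
    return n * mm_per_px ** 2, flags


def _centroid(mask: np.ndarray) -> np.ndarray:
    coords = np.argwhere(mask)
    return coords.mean(axis=0)


def _principal_axis(mask: np.ndarray) -> np.ndarray:
    """Unit vector of the major principal axis of the mask's second moments."""
    coords = np.argwhere(mask).astype(float)
    cov = np.cov(coords.T) if len(coords) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    return evecs[:, int(np.argmax(evals))]


def _march(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray):
    """Exit points of the membership run containing the origin.

    Samples ``origin + t * direction`` at 0.25-px steps for both signs of
    ``t``, classifying each sample by its nearest pixel.  Returns the two
    endpoints of the contiguous in-mask run around t = 0 (or the run nearest
    to the origin when the origin pixel itself is background) and whether the
    march reached the image border.
    """
    rows, cols = mask.shape
    t_max = float(np.hypot(rows, cols))
    ts = np.arange(-t_max, t_max + MARCH_STEP, MARCH_STEP)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, rows - 1)
    cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, cols - 1)
    inside = (pts[:, 0] >= -0.5) & (pts[:, 0] <= rows - 0.5) \
        & (pts[:, 1] >= -0.5) & (pts[:, 1] <= cols - 0.5)
    member = mask[rr, cc] & inside

    i0 = int(np.argmin(np.abs(ts)))
    if not member.any():
        return None, None, False
    if not member[i0]:
        member_idx = np.flatnonzero(member)
        i0 = int(member_idx[np.argmin(np.abs(ts[member_idx]))])
    lo = i0
    while lo - 1 >= 0 and member[lo - 1]:
        lo -= 1
    hi = i0
    while hi + 1 < len(ts) and member[hi + 1]:
        hi += 1
    off_edge = (lo == 0) or (hi == len(ts) - 1) \
        or not inside[max(lo - 1, 0)] or not inside[min(hi + 1, len(ts) - 1)]
    return pts[lo], pts[hi], off_edge


def ovary_diameter(ovary_mask: np.ndarray, stigma_mask: np.ndarray | None,
                   mm_per_px: float):
    """Transverse ovary diameter in mm.

    Returns ``(diameter_mm, flags, endpoints)`` with endpoints in (row, col)
    pixel coordinates for overlay rendering.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    ovary_mask = np.asarray(ovary_mask).astype(bool)
    if not ovary_mask.any():
        raise ValueError("empty ovary mask: no diameter is defined")
    flags: set = set()
    ov_c = _centroid(ovary_mask)

    axis = None
    if stigma_mask is not None and np.asarray(stigma_mask).any():
        st_c = _centroid(np.asarray(stigma_mask).astype(bool))
        sep = st_c - ov_c
        if np.hypot(*sep) >= 1.0:
            axis = sep / np.hypot(*sep)
    if axis is None:
        axis = _principal_axis(ovary_mask)
        flags.add("fallback_axis")
        if stigma_mask is None or not np.asarray(stigma_mask).any():
            flags.add("empty_stigma")

    perp = np.array([-axis[1], axis[0]])
    p_lo, p_hi, off_edge = _march(ovary_mask, ov_c, perp)
    if p_lo is None:
        raise ValueError("measurement line does not intersect the ovary mask")
    if off_edge:
        flags.add("off_edge")
    diameter = float(np.hypot(*(p_hi - p_lo))) * mm_per_px
    return diameter, flags, (tuple(p_lo), tuple(p_hi))


def measure_batch(images, stigma_masks, ovary_masks, manifest: pd.DataFrame):
    """Measure every image in manifest order.

    ``images`` / masks are dicts keyed by image_id (ovary masks may be None
    for stigma-only runs -- the diameter is then NaN).  Rows whose scale is
    missing or invalid are recorded as errors and skipped; flagged rows are
    retained for downstream human verification.

    Returns ``(measurements, errors)`` where errors is a list of
    ``(image_id, message)``.
    """
    out: list[CarpelMeasurement] = []
    errors: list[tuple[str, str]] = []
    for _, row in manifest.iterrows():
        image_id = str(row["image_id"])
        scale = row.get("mm_per_px", np.nan)
        try:
            scale = float(scale)
        except (TypeError, ValueError):
            scale = np.nan
        if not np.isfinite(scale) or scale <= 0:
            errors.append((image_id, "missing or non-positive mm_per_px"))
            continue
        if image_id not in stigma_masks:
            errors.append((image_id, "no stigma mask"))
            continue
        st = stigma_masks[image_id]
        ov = ovary_masks.get(image_id) if ovary_masks is not None else None
        area, flags = stigma_area(st, scale)
        diameter = float("nan")
        endpoints = None
        ov_px = 0
        if ov is not None and np.asarray(ov).any():
            diameter, dflags, endpoints = ovary_diameter(ov, st, scale)
            flags |= dflags
            ov_px = int(np.asarray(ov).astype(bool).sum())
        elif ov is not None:
            flags.add("empty_ovary")
        out.append(CarpelMeasurement(
            image_id=image_id,
            stigma_area_mm2=area,
            ovary_diameter_mm=diameter,
            stigma_px=int(np.asarray(st).astype(bool).sum()),
            ovary_px=ov_px,
            mm_per_px=scale,
            flags=flags,
            cultivar=str(row.get("cultivar", "")),
            timepoint_days=float(row.get("timepoint_days", np.nan)),
            fixation=bool(row.get("fixation", False)),
            diameter_endpoints=endpoints,
        ))
    return out, errors


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Measurement rows as a DataFrame with the canonical column order."""
    rows = []
    for m in measurements:
        rows.append({
            "image_id": m.image_id,
            "cultivar": m.cultivar,
            "timepoint_days": m.timepoint_days,
            "fixation": m.fixation,
            "stigma_area_mm2": m.stigma_area_mm2,
            "ovary_diameter_mm": m.ovary_diameter_mm,
            "stigma_px": m.stigma_px,
            "ovary_px": m.ovary_px,
            "mm_per_px": m.mm_per_px,
            "flags": ";".join(sorted(m.flags)),
        })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def render_overlay(image, stigma_mask=None, ovary_mask=None,
                   endpoints=None) -> np.ndarray:
    """Verification overlay: tissue outlines plus the diameter segment."""
    from skimage.draw import line as draw_line
    from skimage.segmentation import find_boundaries

    px = (image.pixels if isinstance(image, CarpelImage)
          else np.asarray(image)).copy()
    if stigma_mask is not None and np.asarray(stigma_mask).any():
        px[find_boundaries(np.asarray(stigma_mask).astype(bool), mode="outer")] = (
            255, 220, 0)
    if ovary_mask is not None and np.asarray(ovary_mask).any():
        px[find_boundaries(np.asarray(ovary_mask).astype(bool), mode="outer")] = (
            0, 140, 255)
    if endpoints is not None:
        (r0, c0), (r1, c1) = endpoints
        rr, cc = draw_line(int(round(r0)), int(round(c0)),
                           int(round(r1)), int(round(c1)))
        keep = (rr >= 0) & (rr < px.shape[0]) & (cc >= 0) & (cc < px.shape[1])
        px[rr[keep], cc[keep]] = (0, 90, 255)
    return px
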