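"""Agreement between two annotation sources (e.g. manual vs network).

The primary statistic is the Dice similarity coefficient
``DSC = 2|A∩B| / (|A| + |B|)``: 0 means no spatial overlap, 1 complete
overlap.  Two empty masks score 1 by convention (both annotators agree that
the tissue is absent); empty-vs-non-empty scores 0.

Cross-validation groups images by developmental stage (1 young, 2 fully
developed, 3 visibly deteriorated) crossed with sampling method (fixed or
non-fixed) and reports per-group DSC means alongside descriptive paired
differences of the derived measurements.  No hypothesis testing is done
here -- the report is meant for inspection, not inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["dice", "DiceReport", "cross_validate"]

VALID_STAGES = (1, 2, 3)
VALID_FIXATIONS = ("fixed", "non_fixed")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on the same grid."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


@dataclass
class DiceReport:
    """Per-image and per-group Dice agreement."""

    per_image: pd.DataFrame       # image_id, stage, fixation, dsc
    groups: pd.DataFrame          # stage, fixation, mean, sd, n
    overall_mean: float


def cross_validate(manual_masks: dict, auto_masks: dict,
                   stage_labels: dict, fixation_labels: dict,
                   manual_measurements: pd.DataFrame | None = None,
                   auto_measurements: pd.DataFrame | None = None):
    """Stage x fixation Dice breakdown plus paired measurement summaries.

    Masks are dicts keyed by image_id; every id must appear in both sources.
    Measurement frames (optional) need columns image_id, stigma_area_mm2,
    ovary_diameter_mm; the paired summary reports auto - manual differences.

    Returns ``(DiceReport, paired_summary)`` -- the summary is None when no
    measurement frames are given.
    """
    ids_m, ids_a = set(manual_masks), set(auto_masks)
    if ids_m != ids_a:
        offenders = sorted(ids_m.symmetric_difference(ids_a))
        raise ValueError(f"image_id sets differ between sources: {offenders}")

    rows = []
    for image_id in sorted(ids_m):
        stage = int(stage_labels[image_id])
        fixation = str(fixation_labels[image_id])
        if stage not in VALID_STAGES:
            raise ValueError(f"{image_id}: stage must be one of {VALID_STAGES}")
        if fixation not in VALID_FIXATIONS:
            raise ValueError(f"{image_id}: fixation must be one of {VALID_FIXATIONS}")
        rows.append({
            "image_id": image_id,
            "stage": stage,
            "fixation": fixation,
            "dsc": dice(manual_masks[image_id], auto_masks[image_id]),
        })
    per_image = pd.DataFrame(rows)
    groups = (per_image.groupby(["stage", "fixation"])["dsc"]
              .agg(mean="mean", sd="std", n="size").reset_index())
    report = DiceReport(per_image=per_image, groups=groups,
                        overall_mean=float(per_image["dsc"].mean()))

    paired = None
    if manual_measurements is not None and auto_measurements is not None:
        m = manual_measurements.set_index("image_id")
        a = auto_measurements.set_index("image_id")
        missing = ids_m.symmetric_difference(m.index) \
            | ids_m.symmetric_difference(a.index)
        if missing:
            raise ValueError(
                f"measurement image_ids do not match masks: {sorted(missing)}")
        labels = per_image.set_index("image_id")[["stage", "fixation"]]
        recs = []
        for trait in ("stigma_area_mm2", "ovary_diameter_mm"):
            diff = (a[trait] - m[trait]).to_frame("diff").join(labels)
            rel = ((a[trait] - m[trait]) / m[trait].replace(0, np.nan)) \
                .to_frame("rel").join(labels)
            g = diff.groupby(["stage", "fixation"])["diff"] \
                .agg(mean_diff="mean", sd_diff="std", n="size")
            g["mean_rel_err"] = rel.groupby(["stage", "fixation"])["rel"].mean()
            g["trait"] = trait
            recs.append(g.reset_index())
        paired = pd.concat(recs, ignore_index=True)
    return report, paired
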