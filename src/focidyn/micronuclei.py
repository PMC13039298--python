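"""Heterochromatic micronucleus scoring and HP1α-colocalized focus counts.

A micronucleus is scored as a DAPI-positive object, much smaller than a
nucleus, lying entirely outside every main nucleus's periphery; it is called
heterochromatic (HP1α-positive) when its mean HP1α signal exceeds a robust
background threshold (median + k·MAD of the extranuclear HP1α signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .detection import NucleusMask, Spot, segment_nuclei


@dataclass
class MicronucleusCall:
    centroid: tuple[float, float]  # (x, y) px
    area: float  # px²
    hp1a_positive: bool
    distance_to_nucleus: float  # px, centroid to nearest main-nucleus boundary


def hp1a_threshold(hp1a: np.ndarray, background_mask: np.ndarray, k: float = 3.0) -> float:
    """Robust HP1α positivity threshold: background median + k·MAD."""
    bg = np.asarray(hp1a, dtype=float)[background_mask]
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + k * mad


def detect_micronuclei(
    dapi: np.ndarray,
    hp1a: np.ndarray,
    min_nucleus_area: int = 500,
    min_mn_area: float | None = None,
    max_mn_area: float | None = None,
    periphery_margin: int = 2,
    hp1a_k: float = 3.0,
    smoothing_sigma: float = 2.0,
) -> list[MicronucleusCall]:
    """Score micronuclei in a fixed-cell DAPI/HP1α field.

    Main nuclei are DAPI objects of area ≥ ``min_nucleus_area``; candidate
    micronuclei are DAPI objects whose area falls within
    ``[min_mn_area, max_mn_area]`` (defaults: 1/100 and 1/9 of the median
    main-nucleus area — micronuclei are conventionally well under a third of
    the nuclear diameter) and whose pixels lie entirely outside the main
    nuclei dilated by ``periphery_margin`` px. Each candidate is flagged
    ``hp1a_positive`` when its mean HP1α exceeds the extranuclear
    median + ``hp1a_k``·MAD.
    """
    dapi = np.asarray(dapi, dtype=float)
    hp1a = np.asarray(hp1a, dtype=float)
    if dapi.shape != hp1a.shape:
        raise ValueError("DAPI and HP1α channels must share geometry")
    # segment all DAPI-positive objects regardless of size
    all_objects = segment_nuclei(dapi, smoothing_sigma=smoothing_sigma, min_nucleus_area=1)
    labels = all_objects.labels
    if labels.max() == 0:
        return []
    props = measure.regionprops(labels)
    main_ids = [p.label for p in props if p.area >= min_nucleus_area]
    main_mask = np.isin(labels, main_ids)

    if main_ids:
        median_area = float(np.median([p.area for p in props if p.label in set(main_ids)]))
    else:
        median_area = float(min_nucleus_area)
    if min_mn_area is None:
        min_mn_area = median_area / 100.0
    if max_mn_area is None:
        max_mn_area = median_area / 9.0

    if periphery_margin > 0 and main_mask.any():
        structure = np.ones((3, 3), dtype=bool)
        dilated_main = ndimage.binary_dilation(main_mask, structure, iterations=periphery_margin)
    else:
        dilated_main = main_mask
    dist_to_main = ndimage.distance_transform_edt(~main_mask) if main_mask.any() else None

    bg_mask = labels == 0
    thr = hp1a_threshold(hp1a, bg_mask, k=hp1a_k)

    calls: list[MicronucleusCall] = []
    for p in props:
        if p.label in set(main_ids):
            continue
        if not (min_mn_area <= p.area <= max_mn_area):
            continue
        obj = labels == p.label
        if np.any(obj & dilated_main):  # touches the dilated periphery → excluded
            continue
        mean_hp1a = float(hp1a[obj].mean())
        cy, cx = p.centroid
        dist = float(dist_to_main[int(round(cy)), int(round(cx))]) if dist_to_main is not None else np.inf
        calls.append(
            MicronucleusCall(
                centroid=(float(cx), float(cy)),
                area=float(p.area),
                hp1a_positive=mean_hp1a > thr,  # strict: a flat channel is never positive
                distance_to_nucleus=dist,
            )
        )
    return calls


def count_colocalized_foci(
    spots: list[Spot],
    hp1a: np.ndarray,
    mask: NucleusMask,
    hp1a_k: float = 3.0,
    hp1a_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-nucleus counts of foci lying in HP1α-positive (heterochromatic) regions.

    A focus is HP1α-associated iff the thresholded HP1α mask is positive at
    its rounded position. The threshold is median + k·MAD of the HP1α signal
    outside the nuclei unless an explicit ``hp1a_mask`` is supplied.
    """
    hp1a = np.asarray(hp1a, dtype=float)
    if hp1a_mask is None:
        thr = hp1a_threshold(hp1a, mask.labels == 0, k=hp1a_k)
        hp1a_mask = hp1a > thr
    h, w = hp1a.shape
    counts = {nid: [0, 0] for nid in range(1, mask.n_nuclei + 1)}  # [total, in_hp1a]
    for s in spots:
        if s.nucleus_id is None or s.nucleus_id not in counts:
            continue
        counts[s.nucleus_id][0] += 1
        r = min(max(int(round(s.y)), 0), h - 1)
        c = min(max(int(round(s.x)), 0), w - 1)
        if hp1a_mask[r, c]:
            counts[s.nucleus_id][1] += 1
    return pd.DataFrame(
        [
            {"nucleus_id": nid, "n_foci": tot, "n_foci_in_hp1a": pos}
            for nid, (tot, pos) in counts.items()
        ],
        columns=["nucleus_id", "n_foci", "n_foci_in_hp1a"],
    )


def micronuclei_to_dataframe(calls: list[MicronucleusCall], image_id: str = "0") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"image_id": image_id, "centroid_x": c.centroid[0], "centroid_y": c.centroid[1],
             "area_px": c.area, "hp1a_positive": c.hp1a_positive}
            for c in calls
        ],
        columns=["image_id", "centroid_x", "centroid_y", "area_px", "hp1a_positive"],
    )
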