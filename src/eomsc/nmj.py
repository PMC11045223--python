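"""NMJ innervation scoring and peri-NMJ satellite-cell counting.

Whole-mount muscle stacks are scored in two steps.  First each candidate
neuromuscular junction (an α-bungarotoxin/AChR patch, "BTX") is classified by
the fraction of its area covered by presynaptic synaptophysin signal ("SYP"):
well innervated when coverage exceeds 60%, partially innervated in the closed
30–60% band, poorly innervated below 30%.  Second, satellite cells are
counted around each junction: nuclei are segmented from the DAPI channel,
called Pax7-positive when enough of their nuclear area carries Pax7 signal
(the DAPI mask filters out non-nuclear staining), and counted when the
nuclear centroid falls strictly inside a disc of 75 µm diameter centred on
the junction centroid.  Per-mouse category ratios are the unit of analysis
for group summaries.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import LabeledRegions, MultiChannelStack, binarize, label_regions, max_project

__all__ = [
    "CATEGORIES",
    "NMJRecord",
    "InnervationSummary",
    "detect_nmjs",
    "syp_coverage",
    "classify_innervation",
    "count_peri_nmj_scs",
    "quantify_nmj_stack",
    "summarize_innervation",
]

#: Innervation categories in decreasing coverage order.
CATEGORIES = ("well", "partial", "poor")

#: Coverage bounds: > WELL_MIN is "well", < PARTIAL_MIN is "poor",
#: the closed interval [PARTIAL_MIN, WELL_MIN] is "partial".
WELL_MIN = 0.6
PARTIAL_MIN = 0.3

DEFAULT_DISC_DIAMETER_UM = 75.0
#: Patches below this area are not scored as NMJs (rejects speckle).
DEFAULT_MIN_NMJ_AREA_UM2 = 20.0
DEFAULT_MIN_NUCLEUS_AREA_UM2 = 5.0
#: Fraction of a nucleus's DAPI pixels that must exceed the Pax7 threshold.
DEFAULT_NUCLEAR_POSITIVITY_FRACTION = 0.5


@dataclass
class NMJRecord:
    """One scored NMJ: where it is, how covered, and its peri-NMJ SC count."""

    id: int
    centroid_um: tuple[float, float]
    area_um2: float
    syp_coverage: float
    category: str
    peri_sc_count: int
    group: str | None = None


@dataclass
class InnervationSummary:
    """Per-group innervation tally: counts and ratios per category."""

    group: str
    n_nmjs: int
    counts: dict[str, int]
    ratios: dict[str, float]


def detect_nmjs(
    stack: MultiChannelStack,
    btx_channel: str = "BTX",
    min_area_um2: float = DEFAULT_MIN_NMJ_AREA_UM2,
    threshold: float | None = None,
) -> LabeledRegions:
    """Segment candidate NMJs from the BTX channel of a projected stack.

    Otsu thresholding by default; pass ``threshold`` for a fixed cutoff.
    Returns the labelled BTX patches with at least ``min_area_um2``.
    """
    proj = max_project(stack, btx_channel)
    if threshold is None:
        mask = binarize(proj, "otsu")
    else:
        mask = binarize(proj, "fixed", threshold)
    return label_regions(mask, stack.pixel_size, min_area_um2=min_area_um2)


def syp_coverage(btx_region_mask: np.ndarray, syp_mask: np.ndarray) -> float:
    """Fraction of a BTX patch's pixels that also carry SYP signal."""
    btx_region_mask = np.asarray(btx_region_mask, dtype=bool)
    syp_mask = np.asarray(syp_mask, dtype=bool)
    if btx_region_mask.shape != syp_mask.shape:
        raise ValueError("BTX and SYP masks must share shape")
    n_btx = int(btx_region_mask.sum())
    if n_btx == 0:
        raise ValueError("coverage is undefined for an empty BTX region")
    return float((btx_region_mask & syp_mask).sum()) / n_btx


def classify_innervation(coverage: float) -> str:
    """Map SYP coverage to well / partial / poor.

    ``coverage > 0.6`` is well innervated, the closed band ``[0.3, 0.6]``
    partially innervated, ``< 0.3`` poorly innervated; both boundary values
    are partial.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1]; got {coverage}")
    if coverage > WELL_MIN:
        return "well"
    if coverage >= PARTIAL_MIN:
        return "partial"
    return "poor"


def _call_nuclei(
    stack: MultiChannelStack,
    marker_channel: str,
    dapi_channel: str,
    min_nucleus_area_um2: float,
    positivity_fraction: float,
) -> tuple[LabeledRegions, np.ndarray]:
    """Segment DAPI nuclei and flag those positive for a nuclear marker.

    A nucleus is marker-positive when more than ``positivity_fraction`` of its
    DAPI-mask pixels exceed the marker's Otsu threshold; restricting the
    marker to the DAPI mask removes non-nuclear staining.
    """
    dapi_mask = binarize(max_project(stack, dapi_channel), "otsu")
    nuclei = label_regions(dapi_mask, stack.pixel_size, min_area_um2=min_nucleus_area_um2)
    marker_mask = binarize(max_project(stack, marker_channel), "otsu")
    flags = np.zeros(len(nuclei), dtype=bool)
    for i, rid in enumerate(nuclei.table["id"]):
        px = nuclei.labels == rid
        flags[i] = marker_mask[px].mean() > positivity_fraction
    return nuclei, flags


def count_peri_nmj_scs(
    stack: MultiChannelStack,
    nmj_centroids_um: np.ndarray,
    pax7_channel: str = "Pax7",
    dapi_channel: str = "DAPI",
    disc_diameter_um: float = DEFAULT_DISC_DIAMETER_UM,
    min_nucleus_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2,
    positivity_fraction: float = DEFAULT_NUCLEAR_POSITIVITY_FRACTION,
) -> np.ndarray:
    """Count nuclear-Pax7+ cells within a disc around each NMJ centroid.

    A nucleus is counted for an NMJ when its centroid lies strictly within
    ``disc_diameter_um / 2`` of the NMJ centroid (75 µm diameter by default).
    Returns one integer per row of ``nmj_centroids_um`` (rows = (y, x) µm).
    """
    if disc_diameter_um <= 0:
        raise ValueError("disc diameter must be > 0")
    nmj_centroids_um = np.atleast_2d(np.asarray(nmj_centroids_um, dtype=float))
    counts = np.zeros(len(nmj_centroids_um), dtype=int)
    if nmj_centroids_um.size == 0:
        return counts
    nuclei, pax7_flags = _call_nuclei(
        stack, pax7_channel, dapi_channel, min_nucleus_area_um2, positivity_fraction
    )
    if len(nuclei) == 0:
        return counts
    centroids = nuclei.centroids_um()[pax7_flags]
    if centroids.size == 0:
        return counts
    radius = disc_diameter_um / 2.0
    for i, c in enumerate(nmj_centroids_um):
        d = np.hypot(centroids[:, 0] - c[0], centroids[:, 1] - c[1])
        counts[i] = int((d < radius).sum())
    return counts


def quantify_nmj_stack(
    stack: MultiChannelStack,
    btx_channel: str = "BTX",
    syp_channel: str = "SYP",
    pax7_channel: str = "Pax7",
    dapi_channel: str = "DAPI",
    min_area_um2: float = DEFAULT_MIN_NMJ_AREA_UM2,
    disc_diameter_um: float = DEFAULT_DISC_DIAMETER_UM,
    group: str | None = None,
    count_scs: bool = True,
) -> list[NMJRecord]:
    """Full scoring of one stack: detect, classify and (optionally) count SCs."""
    regions = detect_nmjs(stack, btx_channel, min_area_um2)
    if len(regions) == 0:
        return []
    syp_mask = binarize(max_project(stack, syp_channel), "otsu")
    centroids = regions.centroids_um()
    if count_scs and pax7_channel in stack.channel_names:
        sc_counts = count_peri_nmj_scs(
            stack, centroids, pax7_channel, dapi_channel, disc_diameter_um
        )
    else:
        sc_counts = np.zeros(len(regions), dtype=int)
    records = []
    for row, sc in zip(regions.table.itertuples(index=False), sc_counts):
        cov = syp_coverage(regions.region_mask(row.id), syp_mask)
        records.append(
            NMJRecord(
                id=int(row.id),
                centroid_um=(row.centroid_y_um, row.centroid_x_um),
                area_um2=row.area_um2,
                syp_coverage=cov,
                category=classify_innervation(cov),
                peri_sc_count=int(sc),
                group=group,
            )
        )
    return records


def summarize_innervation(
    records: list[NMJRecord],
    condition_of: dict[str, str] | None = None,
) -> tuple[list[InnervationSummary], pd.DataFrame]:
    """Per-group category ratios, then per-condition means of group ratios.

    Each record must carry a ``group`` label (one mouse in the source design;
    the mouse, not the NMJ, is the unit of analysis).  ``condition_of`` maps
    group labels to condition labels; per-condition rows average the per-group
    ratio vectors.  Returns the per-group summaries and a condition-level
    DataFrame (columns ``condition, n_groups, mean_well, mean_partial,
    mean_poor``).
    """
    by_group: dict[str, list[NMJRecord]] = defaultdict(list)
    for rec in records:
        if rec.group is None:
            raise ValueError("every record needs a group label for summarization")
        by_group[rec.group].append(rec)

    summaries = []
    for group, recs in by_group.items():
        counts = {cat: sum(r.category == cat for r in recs) for cat in CATEGORIES}
        n = len(recs)
        ratios = {cat: counts[cat] / n for cat in CATEGORIES}
        summaries.append(InnervationSummary(group=group, n_nmjs=n, counts=counts, ratios=ratios))

    cond_rows = []
    if condition_of is None:
        condition_of = {s.group: s.group for s in summaries}
    by_cond: dict[str, list[InnervationSummary]] = defaultdict(list)
    for s in summaries:
        by_cond[condition_of.get(s.group, s.group)].append(s)
    for cond, ss in by_cond.items():
        cond_rows.append(
            {
                "condition": cond,
                "n_groups": len(ss),
                **{f"mean_{cat}": float(np.mean([s.ratios[cat] for s in ss])) for cat in CATEGORIES},
            }
        )
    return summaries, pd.DataFrame(cond_rows)


def records_to_frame(records: list[NMJRecord]) -> pd.DataFrame:
    """Flatten NMJ records to a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "centroid_y_um": [r.centroid_um[0] for r in records],
            "centroid_x_um": [r.centroid_um[1] for r in records],
            "area_um2": [r.area_um2 for r in records],
            "syp_coverage": [r.syp_coverage for r in records],
            "category": [r.category for r in records],
            "peri_sc_count": [r.peri_sc_count for r in records],
        }
    )
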