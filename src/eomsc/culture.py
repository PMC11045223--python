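"""Cultured-cell state and neuromuscular coculture quantification.

Covers four read-outs of satellite-cell culture experiments:

* Pax7/Ki67 state ratios of DAPI-segmented nuclei (proliferation vs
  reserve-cell balance of cultured satellite cells);
* the fusion index — the fraction of nuclei lying within myosin-heavy-chain
  (MHC) positive myotubes;
* the coculture innervation ratio — among AChR clusters (BTX patches) larger
  than 10 µm² sitting on myotubes that touch motor-neuron neurites, the
  fraction overlapping the neurite mask;
* lengths of the longest neurites crossing from the neuronal into the
  myotube compartment of a microfluidic chamber, measured as geodesic
  path length along the skeletonized neurite.

Ratios are computed per image; the image is the unit of analysis for group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skimage.morphology import skeletonize

from .imaging import MultiChannelStack, binarize, label_regions, max_project
from .nmj import (
    DEFAULT_MIN_NUCLEUS_AREA_UM2,
    DEFAULT_NUCLEAR_POSITIVITY_FRACTION,
    _call_nuclei,
)

__all__ = [
    "NucleusCall",
    "CocultureField",
    "classify_nuclei",
    "fusion_index",
    "build_coculture_field",
    "innervation_ratio",
    "longest_neurite_lengths",
]

#: AChR clusters at or below this area (µm²) do not enter the innervation
#: ratio denominator ("larger than 10 µm²" rule).
DEFAULT_MIN_PATCH_AREA_UM2 = 10.0

#: Reported nucleus states, in reporting order; the fourth state
#: (Pax7-Ki67+) closes the partition.
NUCLEUS_STATES = ("pax7+ki67+", "pax7+ki67-", "pax7-ki67-", "pax7-ki67+")


@dataclass
class NucleusCall:
    """One segmented nucleus with its marker and localization flags."""

    centroid_um: tuple[float, float]
    pax7_positive: bool
    ki67_positive: bool
    inside_mhc: bool

    @property
    def state(self) -> str:
        return (
            f"pax7{'+' if self.pax7_positive else '-'}"
            f"ki67{'+' if self.ki67_positive else '-'}"
        )


@dataclass
class CocultureField:
    """Binary-mask view of one coculture image.

    ``patches`` has one row per AChR cluster with columns
    ``id, area_um2, myotube_id, on_contacting_myotube, innervated``;
    ``myotube_contact`` maps myotube label -> has >= 1 px neurite overlap.
    """

    myotube_labels: np.ndarray
    neurite_mask: np.ndarray
    patches: pd.DataFrame = field(repr=False)
    myotube_contact: dict[int, bool] = field(default_factory=dict)


def classify_nuclei(
    stack: MultiChannelStack,
    pax7_channel: str = "Pax7",
    ki67_channel: str = "Ki67",
    dapi_channel: str = "DAPI",
    mhc_channel: str | None = None,
    min_nucleus_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2,
    positivity_fraction: float = DEFAULT_NUCLEAR_POSITIVITY_FRACTION,
) -> tuple[list[NucleusCall], dict[str, float]]:
    """Assign every DAPI nucleus a Pax7 x Ki67 state and report state ratios.

    A nucleus is positive for a marker when more than ``positivity_fraction``
    of its DAPI pixels exceed that marker's Otsu threshold.  Returns the
    nucleus calls and a ratio dict over the four states (ratios sum to 1).
    Raises if no nuclei are found — ratios are undefined then.
    """
    nuclei, pax7_flags = _call_nuclei(
        stack, pax7_channel, dapi_channel, min_nucleus_area_um2, positivity_fraction
    )
    if len(nuclei) == 0:
        raise ValueError("no nuclei segmented; state ratios are undefined")
    _, ki67_flags = _call_nuclei(
        stack, ki67_channel, dapi_channel, min_nucleus_area_um2, positivity_fraction
    )
    if mhc_channel is not None and mhc_channel in stack.channel_names:
        mhc_mask = binarize(max_project(stack, mhc_channel), "otsu")
    else:
        mhc_mask = None
    calls = []
    for (_, row), p, k in zip(nuclei.table.iterrows(), pax7_flags, ki67_flags):
        cy, cx = row["centroid_y_um"], row["centroid_x_um"]
        if mhc_mask is None:
            inside = False
        else:
            iy = min(int(round(cy / stack.pixel_size)), mhc_mask.shape[0] - 1)
            ix = min(int(round(cx / stack.pixel_size)), mhc_mask.shape[1] - 1)
            inside = bool(mhc_mask[iy, ix])
        calls.append(
            NucleusCall(centroid_um=(cy, cx), pax7_positive=bool(p), ki67_positive=bool(k), inside_mhc=inside)
        )
    n = len(calls)
    ratios = {s: sum(c.state == s for c in calls) / n for s in NUCLEUS_STATES}
    return calls, ratios


def fusion_index(
    stack: MultiChannelStack,
    mhc_channel: str = "MHC",
    dapi_channel: str = "DAPI",
    min_nucleus_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2,
) -> float:
    """Fraction of nuclei whose centroid lies inside the binarized MHC mask."""
    dapi_mask = binarize(max_project(stack, dapi_channel), "otsu")
    nuclei = label_regions(dapi_mask, stack.pixel_size, min_area_um2=min_nucleus_area_um2)
    if len(nuclei) == 0:
        raise ValueError("no nuclei segmented; fusion index is undefined")
    mhc_mask = binarize(max_project(stack, mhc_channel), "otsu")
    inside = 0
    for _, row in nuclei.table.iterrows():
        iy = min(int(round(row["centroid_y_um"] / stack.pixel_size)), mhc_mask.shape[0] - 1)
        ix = min(int(round(row["centroid_x_um"] / stack.pixel_size)), mhc_mask.shape[1] - 1)
        inside += bool(mhc_mask[iy, ix])
    return inside / len(nuclei)


def build_coculture_field(
    stack: MultiChannelStack,
    mhc_channel: str = "MHC",
    neurite_channel: str = "NF",
    btx_channel: str = "BTX",
    min_patch_area_um2: float = 0.0,
) -> CocultureField:
    """Segment a coculture image into the masks innervation scoring needs.

    Myotube instances are connected components of the binarized MHC mask
    (touching myotubes merge — accepted limitation).  A myotube "contacts"
    the neurites when the masks share at least one pixel.  Each BTX patch is
    assigned to the myotube it overlaps most (0 when it lies off-myotube) and
    flagged innervated when it overlaps the neurite mask by >= 1 pixel.
    """
    mhc_mask = binarize(max_project(stack, mhc_channel), "otsu")
    myotubes = label_regions(mhc_mask, stack.pixel_size)
    neurite_mask = binarize(max_project(stack, neurite_channel), "otsu")
    contact = {
        int(rid): bool(neurite_mask[myotubes.labels == rid].any())
        for rid in myotubes.table["id"]
    }
    patches = label_regions(
        binarize(max_project(stack, btx_channel), "otsu"),
        stack.pixel_size,
        min_area_um2=min_patch_area_um2,
    )
    rows = []
    for _, prow in patches.table.iterrows():
        pmask = patches.labels == prow["id"]
        under = myotubes.labels[pmask]
        under = under[under > 0]
        mid = int(np.bincount(under).argmax()) if under.size else 0
        rows.append(
            {
                "id": int(prow["id"]),
                "area_um2": prow["area_um2"],
                "myotube_id": mid,
                "on_contacting_myotube": bool(contact.get(mid, False)),
                "innervated": bool(neurite_mask[pmask].any()),
            }
        )
    table = pd.DataFrame(
        rows, columns=["id", "area_um2", "myotube_id", "on_contacting_myotube", "innervated"]
    )
    return CocultureField(
        myotube_labels=myotubes.labels,
        neurite_mask=neurite_mask,
        patches=table,
        myotube_contact=contact,
    )


def innervation_ratio(
    field: CocultureField, min_patch_area_um2: float = DEFAULT_MIN_PATCH_AREA_UM2
) -> float:
    """Innervated fraction of qualifying AChR clusters in one field.

    Denominator: patches strictly larger than ``min_patch_area_um2`` sitting
    on neurite-contacting myotubes (myotubes with zero-pixel neurite overlap
    are excluded).  Numerator: those overlapping the neurite mask.  Raises
    when the denominator is empty — the ratio is undefined then.
    """
    q = field.patches[
        (field.patches["area_um2"] > min_patch_area_um2)
        & field.patches["on_contacting_myotube"]
    ]
    if len(q) == 0:
        raise ValueError("no qualifying AChR clusters; innervation ratio is undefined")
    return float(q["innervated"].mean())


def _skeleton_graph(skel: np.ndarray, pixel_pitch_um: float) -> nx.Graph:
    """8-connected graph over skeleton pixels; edges weigh 1 or sqrt(2) pitches."""
    g = nx.Graph()
    ys, xs = np.nonzero(skel)
    pixels = set(zip(ys.tolist(), xs.tolist()))
    for y, x in pixels:
        g.add_node((y, x))
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
            n = (y + dy, x + dx)
            if n in pixels:
                w = pixel_pitch_um * (np.sqrt(2.0) if dy and dx else 1.0)
                g.add_edge((y, x), n, weight=w)
    return g


def longest_neurite_lengths(
    neurite_mask: np.ndarray, boundary_x_um: float, pixel_size: float
) -> list[float]:
    """Geodesic lengths of neurites crossing into the myotube compartment.

    The mask is skeletonized; for every connected neurite with skeleton
    pixels on both sides of the vertical boundary at ``boundary_x_um`` (the
    myotube-compartment edge of the microgrooves, myotube side at larger x),
    the length reported is the longest geodesic distance from its boundary
    crossing to any tip, walked only through the myotube side.  Neurites
    entirely on the neuronal side are excluded; result may be empty.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    skel = skeletonize(np.asarray(neurite_mask, dtype=bool))
    graph = _skeleton_graph(skel, pixel_size)
    boundary_px = boundary_x_um / pixel_size
    lengths = []
    for comp in nx.connected_components(graph):
        xs = np.array([x for _, x in comp], dtype=float)
        if not ((xs <= boundary_px).any() and (xs > boundary_px).any()):
            continue
        sub = graph.subgraph([n for n in comp if n[1] > boundary_px])
        # entry nodes: myotube-side pixels adjacent to a neuronal-side pixel
        entries = [
            n
            for n in sub.nodes
            if any(m[1] <= boundary_px for m in graph.neighbors(n))
        ]
        if not entries:
            continue
        best = 0.0
        for comp2 in nx.connected_components(sub):
            comp_entries = [n for n in entries if n in comp2]
            if not comp_entries:
                continue
            sg = sub.subgraph(comp2)
            for e in comp_entries:
                dist = nx.single_source_dijkstra_path_length(sg, e, weight="weight")
                best = max(best, max(dist.values()))
        lengths.append(best)
    return lengths
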