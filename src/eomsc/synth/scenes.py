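"""Synthetic fluorescence scenes with exact ground truth.

Two scene families are generated as named-channel z-stacks:

* whole-mount NMJ scenes (channels BTX, SYP, Pax7, DAPI): elliptical BTX
  patches with a planted SYP coverage fraction, surrounded by Pax7+/DAPI
  nuclei at controlled distances inside the 75 µm counting disc, plus
  distractor nuclei (Pax7- anywhere, Pax7+ outside every disc);
* culture / coculture fields (channels DAPI, Pax7, Ki67, MHC, NF, BTX):
  horizontal myotube ribbons, nuclei with planted Pax7 x Ki67 x inside-MHC
  states, neurites contacting a planted subset of myotubes, and AChR patches
  of known area with planted innervation flags.

Shapes are rendered hard-edged (binary occupancy times a signal amplitude)
so that thresholding recovers the planted geometry exactly at zero noise; an
optional Gaussian ``blur_sigma`` softens edges for robustness experiments.
Structures live on one random z-slice each; maximum-intensity projection
restores the designed 2D scene.  Discs never overlap (enforced by rejection
sampling), so per-NMJ satellite-cell counts are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..imaging import MultiChannelStack, write_stack
from ..nmj import classify_innervation

__all__ = [
    "PlacementError",
    "NMJSceneSpec",
    "CultureSceneSpec",
    "SceneGroundTruth",
    "gen_nmj_stack",
    "gen_culture_image",
    "gen_neurite_crossing_mask",
    "write_scene",
]

SIGNAL_AMPLITUDE = 200.0
NUCLEUS_RADIUS_UM = 2.5
#: Minimum centre-to-centre separation between nuclei, in nucleus radii,
#: so DAPI components never merge.
NUCLEUS_SEPARATION_FACTOR = 2.6
PLACEMENT_RETRY_CAP = 1000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a placement constraint."""


@dataclass
class NMJSceneSpec:
    """Parameters of one synthetic whole-mount NMJ scene.

    ``target_syp_coverage`` and ``planted_sc_counts`` may be scalars (shared
    by all NMJs), sequences of length ``n_nmjs``, or None (drawn uniformly in
    [0, 1] / in {0..4} respectively).  ``distractor_nuclei`` alternates
    Pax7- nuclei placed anywhere with Pax7+ nuclei kept outside every disc.
    """

    image_shape: tuple[int, int, int] = (3, 512, 512)  # (z, y, x) voxels
    pixel_size: float = 0.5  # µm per pixel in y and x
    n_nmjs: int = 3
    nmj_area_range_um2: tuple[float, float] = (150.0, 350.0)
    target_syp_coverage: float | list[float] | None = None
    planted_sc_counts: int | list[int] | None = None
    distractor_nuclei: int = 10
    disc_diameter_um: float = 75.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_nmjs < 0 or self.distractor_nuclei < 0:
            raise ValueError("counts must be >= 0")
        if self.target_syp_coverage is not None:
            for c in np.atleast_1d(self.target_syp_coverage):
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"target_syp_coverage must be in [0, 1]; got {c}")

    def resolve_coverages(self, rng: np.random.Generator) -> np.ndarray:
        if self.target_syp_coverage is None:
            return rng.uniform(0.0, 1.0, self.n_nmjs)
        arr = np.atleast_1d(np.asarray(self.target_syp_coverage, dtype=float))
        if arr.size == 1:
            return np.full(self.n_nmjs, arr[0])
        if arr.size != self.n_nmjs:
            raise ValueError("target_syp_coverage length must equal n_nmjs")
        return arr

    def resolve_sc_counts(self, rng: np.random.Generator) -> np.ndarray:
        if self.planted_sc_counts is None:
            return rng.integers(0, 5, self.n_nmjs)
        arr = np.atleast_1d(np.asarray(self.planted_sc_counts, dtype=int))
        if arr.size == 1:
            return np.full(self.n_nmjs, arr[0])
        if arr.size != self.n_nmjs:
            raise ValueError("planted_sc_counts length must equal n_nmjs")
        return arr


@dataclass
class CultureSceneSpec:
    """Parameters of one synthetic culture / coculture field.

    ``state_counts`` maps the nucleus state strings (``"pax7+ki67+"`` etc.)
    to counts; ``n_fused`` of all nuclei are placed inside myotube ribbons
    (states assigned round-robin).  ``patch_specs`` is a list of
    ``(area_um2, innervated, on_contacting_myotube)`` tuples for AChR
    clusters; ``n_contacting_myotubes`` of the ribbons are crossed by a
    neurite.
    """

    image_shape: tuple[int, int, int] = (1, 512, 512)
    pixel_size: float = 0.5
    n_myotubes: int = 3
    n_contacting_myotubes: int = 2
    state_counts: dict[str, int] = dc_field(
        default_factory=lambda: {"pax7+ki67+": 6, "pax7+ki67-": 3, "pax7-ki67-": 3}
    )
    n_fused: int = 4
    patch_specs: list[tuple[float, bool, bool]] = dc_field(default_factory=list)
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_contacting_myotubes > self.n_myotubes:
            raise ValueError("cannot contact more myotubes than exist")
        if self.n_fused > sum(self.state_counts.values()):
            raise ValueError("n_fused exceeds the total nucleus count")
        for area, innervated, on_contacting in self.patch_specs:
            if area <= 0:
                raise ValueError("patch areas must be > 0")
            if innervated and not on_contacting:
                raise ValueError(
                    "an innervated patch implies neurite overlap, hence a contacting myotube"
                )


@dataclass
class SceneGroundTruth:
    """Exact planted truth of a generated scene.

    ``nmjs``: one row per NMJ (centroid/area/coverage/category/peri-SC count,
    or patch area + innervation flags for culture patches).  ``nuclei``: one
    row per nucleus with marker and localization flags.  ``myotubes``: one
    row per myotube ribbon with its neurite-contact flag (culture scenes).
    """

    nmjs: pd.DataFrame
    nuclei: pd.DataFrame
    myotubes: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        payload = {
            "nmjs": self.nmjs.to_dict(orient="list"),
            "nuclei": self.nuclei.to_dict(orient="list"),
            "myotubes": self.myotubes.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SceneGroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            nmjs=pd.DataFrame(payload["nmjs"]),
            nuclei=pd.DataFrame(payload["nuclei"]),
            myotubes=pd.DataFrame(payload["myotubes"]),
        )


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _place_separated(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    min_sep: float,
    existing: list[tuple[float, float]] | None = None,
    accept=None,
    what: str = "points",
) -> list[tuple[float, float]]:
    """Rejection-sample n points with pairwise (and vs existing) separation."""
    y0, y1, x0, x1 = bounds
    if y1 <= y0 or x1 <= x0:
        raise PlacementError(f"no room to place {what}: empty placement bounds")
    placed: list[tuple[float, float]] = []
    others = list(existing or [])
    for _ in range(n):
        for attempt in range(PLACEMENT_RETRY_CAP):
            cy = rng.uniform(y0, y1)
            cx = rng.uniform(x0, x1)
            if accept is not None and not accept(cy, cx):
                continue
            if all(np.hypot(cy - py, cx - px) > min_sep for py, px in placed + others):
                placed.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place {what} with separation > {min_sep:.1f} px after "
                f"{PLACEMENT_RETRY_CAP} attempts; reduce the count or enlarge the image"
            )
    return placed


def _stamp(channel_stack: np.ndarray, z: int, mask: np.ndarray) -> None:
    channel_stack[z][mask] = SIGNAL_AMPLITUDE


def _finalize(voxels: np.ndarray, spec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed + 999_983)  # independent noise stream
    if spec.blur_sigma > 0:
        for z in range(voxels.shape[0]):
            for c in range(voxels.shape[1]):
                voxels[z, c] = gaussian_filter(voxels[z, c], spec.blur_sigma)
    if spec.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise_sd, voxels.shape)
    return np.clip(voxels, 0.0, None)


def gen_nmj_stack(spec: NMJSceneSpec) -> tuple[MultiChannelStack, SceneGroundTruth]:
    """Generate a whole-mount NMJ scene and its exact ground truth.

    Each planted NMJ is an axis-aligned elliptical BTX patch; its SYP signal
    occupies a contiguous sweep (lowest-x fraction) of the patch's pixels so
    the binarized SYP/BTX overlap equals the target coverage up to pixel
    quantization.  Each planted satellite cell is a DAPI disc co-stained for
    Pax7 at a recorded distance < 37.5 µm from its NMJ centroid; distractor
    nuclei are Pax7- (anywhere) or Pax7+ (outside every disc).  Raises
    :class:`PlacementError` when the requested NMJs cannot keep their discs
    disjoint inside the image.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.image_shape
    px = spec.pixel_size
    channels = ["BTX", "SYP", "Pax7", "DAPI"]
    voxels = np.zeros((nz, len(channels), ny, nx), dtype=float)
    ci = {c: i for i, c in enumerate(channels)}

    disc_r_px = spec.disc_diameter_um / 2.0 / px
    nuc_r_px = NUCLEUS_RADIUS_UM / px
    margin = disc_r_px + nuc_r_px + 2
    coverages = spec.resolve_coverages(rng)
    sc_counts = spec.resolve_sc_counts(rng)

    centres = _place_separated(
        rng,
        spec.n_nmjs,
        (margin, ny - margin, margin, nx - margin),
        min_sep=spec.disc_diameter_um / px,  # disc diameter => discs disjoint
        what="NMJ centroids (non-overlapping 75 µm discs)",
    )

    nmj_rows = []
    nucleus_centres: list[tuple[float, float]] = []
    nucleus_rows = []
    for i, ((cy, cx), cov, n_sc) in enumerate(zip(centres, coverages, sc_counts)):
        area_um2 = rng.uniform(*spec.nmj_area_range_um2)
        area_px = area_um2 / px**2
        aspect = rng.uniform(0.6, 1.4)
        ry = np.sqrt(area_px * aspect / np.pi)
        rx = area_px / (np.pi * ry)
        patch = _ellipse_mask((ny, nx), cy, cx, ry, rx)
        z = int(rng.integers(0, nz))
        _stamp(voxels[:, ci["BTX"]], z, patch)
        # contiguous SYP sub-region: lowest-x sweep of the patch pixels
        pys, pxs = np.nonzero(patch)
        order = np.lexsort((pys, pxs))
        n_take = int(round(cov * len(pxs)))
        syp = np.zeros((ny, nx), dtype=bool)
        syp[pys[order[:n_take]], pxs[order[:n_take]]] = True
        _stamp(voxels[:, ci["SYP"]], z, syp)
        true_cov = n_take / len(pxs)
        # true patch centroid from rendered pixels
        tcy, tcx = pys.mean(), pxs.mean()
        nmj_rows.append(
            {
                "id": i + 1,
                "centroid_y_um": tcy * px,
                "centroid_x_um": tcx * px,
                "area_um2": len(pxs) * px**2,
                "true_coverage": true_cov,
                "true_category": classify_innervation(true_cov),
                "true_peri_sc_count": int(n_sc),
            }
        )
        # planted peri-NMJ satellite cells: inside the disc, clear of its rim
        sc_max_r = disc_r_px - nuc_r_px - 2
        placed = _place_separated(
            rng,
            int(n_sc),
            (cy - sc_max_r, cy + sc_max_r, cx - sc_max_r, cx + sc_max_r),
            min_sep=NUCLEUS_SEPARATION_FACTOR * nuc_r_px,
            existing=nucleus_centres,
            accept=lambda yy, xx, cy=cy, cx=cx, r=sc_max_r: np.hypot(yy - cy, xx - cx) < r,
            what="peri-NMJ satellite-cell nuclei",
        )
        for (nyc, nxc) in placed:
            nucleus_centres.append((nyc, nxc))
            nucleus_rows.append(
                {
                    "centroid_y_um": nyc * px,
                    "centroid_x_um": nxc * px,
                    "pax7_flag": True,
                    "ki67_flag": False,
                    "inside_mhc_flag": False,
                    "nmj_id": i + 1,
                    "distance_um": float(np.hypot(nyc - cy, nxc - cx) * px),
                }
            )

    # distractors: alternate Pax7- anywhere / Pax7+ strictly outside all discs
    def outside_discs(yy, xx):
        return all(
            np.hypot(yy - cy, xx - cx) > disc_r_px + nuc_r_px + 2 for cy, cx in centres
        )

    for j in range(spec.distractor_nuclei):
        pax7 = j % 2 == 1
        placed = _place_separated(
            rng,
            1,
            (nuc_r_px + 1, ny - nuc_r_px - 1, nuc_r_px + 1, nx - nuc_r_px - 1),
            min_sep=NUCLEUS_SEPARATION_FACTOR * nuc_r_px,
            existing=nucleus_centres,
            accept=(lambda yy, xx: outside_discs(yy, xx)) if pax7 else None,
            what="distractor nuclei",
        )
        nyc, nxc = placed[0]
        nucleus_centres.append((nyc, nxc))
        nucleus_rows.append(
            {
                "centroid_y_um": nyc * px,
                "centroid_x_um": nxc * px,
                "pax7_flag": pax7,
                "ki67_flag": False,
                "inside_mhc_flag": False,
                "nmj_id": 0,
                "distance_um": np.nan,
            }
        )

    for row, (nyc, nxc) in zip(nucleus_rows, nucleus_centres):
        disc = _disk_mask((ny, nx), nyc, nxc, nuc_r_px)
        z = int(rng.integers(0, nz))
        _stamp(voxels[:, ci["DAPI"]], z, disc)
        if row["pax7_flag"]:
            _stamp(voxels[:, ci["Pax7"]], z, disc)

    voxels = _finalize(voxels, spec)
    stack = MultiChannelStack(voxels=voxels, channel_names=channels, pixel_size=px)
    truth = SceneGroundTruth(
        nmjs=pd.DataFrame(
            nmj_rows,
            columns=[
                "id", "centroid_y_um", "centroid_x_um", "area_um2",
                "true_coverage", "true_category", "true_peri_sc_count",
            ],
        ),
        nuclei=pd.DataFrame(
            nucleus_rows,
            columns=[
                "centroid_y_um", "centroid_x_um", "pax7_flag", "ki67_flag",
                "inside_mhc_flag", "nmj_id", "distance_um",
            ],
        ),
    )
    return stack, truth


def gen_culture_image(spec: CultureSceneSpec) -> tuple[MultiChannelStack, SceneGroundTruth]:
    """Generate a culture / coculture field and its exact ground truth.

    Myotubes are horizontal MHC ribbons; the first ``n_contacting_myotubes``
    are crossed by a neurite line (NF channel).  Nuclei carry planted
    Pax7 x Ki67 states, ``n_fused`` of them centred inside ribbons.  AChR
    patches (BTX) sit on myotubes per ``patch_specs``; innervated patches lie
    on the neurite path, non-innervated ones are offset from it.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.image_shape
    px = spec.pixel_size
    channels = ["DAPI", "Pax7", "Ki67", "MHC", "NF", "BTX"]
    voxels = np.zeros((nz, len(channels), ny, nx), dtype=float)
    ci = {c: i for i, c in enumerate(channels)}
    nuc_r_px = NUCLEUS_RADIUS_UM / px

    # myotube ribbons: evenly spaced horizontal bands with clear gaps
    band_h = max(int(24.0 / px), int(4 * nuc_r_px) + 4)
    pitch = ny // max(spec.n_myotubes, 1)
    if band_h + int(2 * nuc_r_px) + 4 >= pitch:
        raise PlacementError("myotube ribbons would merge; reduce n_myotubes or enlarge image")
    myotube_rows = []
    ribbons = []
    for m in range(spec.n_myotubes):
        y0 = m * pitch + (pitch - band_h) // 2
        contact = m < spec.n_contacting_myotubes
        ribbons.append((y0, y0 + band_h, contact))
        z = int(rng.integers(0, nz))
        voxels[z, ci["MHC"], y0 : y0 + band_h, :] = SIGNAL_AMPLITUDE
        # neurite: a 2 px line along the ribbon centre
        yline = y0 + band_h // 2
        if contact:
            zn = int(rng.integers(0, nz))
            voxels[zn, ci["NF"], yline : yline + 2, :] = SIGNAL_AMPLITUDE
        myotube_rows.append(
            {"id": m + 1, "y0_um": y0 * px, "y1_um": (y0 + band_h) * px, "contact_flag": contact}
        )

    # AChR patches on ribbons; innervated ones centred on the neurite line
    patch_rows = []
    used_x: list[float] = []
    for k, (area_um2, innervated, on_contacting) in enumerate(spec.patch_specs):
        candidates = [r for r in ribbons if r[2] == on_contacting]
        if not candidates:
            raise PlacementError("no myotube matches the requested contact flag for a patch")
        y0, y1, contact = candidates[k % len(candidates)]
        r_px = np.sqrt(area_um2 / np.pi) / px
        yline = y0 + (y1 - y0) // 2
        cy = yline + 0.5 if innervated else yline + r_px + 5
        if cy + r_px >= y1:  # fall back to below-line placement inside the ribbon
            cy = yline - r_px - 5
            if cy - r_px <= y0:
                raise PlacementError("AChR patch does not fit inside its myotube ribbon")
        for attempt in range(PLACEMENT_RETRY_CAP):
            cx = rng.uniform(3 * r_px, nx - 3 * r_px)
            if all(abs(cx - ux) > 4 * r_px + 4 for ux in used_x):
                break
        else:
            raise PlacementError("could not place AChR patches without overlap")
        used_x.append(cx)
        patch = _disk_mask((ny, nx), cy, cx, r_px)
        z = int(rng.integers(0, nz))
        _stamp(voxels[:, ci["BTX"]], z, patch)
        pys, pxs = np.nonzero(patch)
        patch_rows.append(
            {
                "id": k + 1,
                "centroid_y_um": pys.mean() * px,
                "centroid_x_um": pxs.mean() * px,
                "area_um2": len(pxs) * px**2,
                "innervated_flag": bool(innervated),
                "on_contacting_myotube": bool(on_contacting),
            }
        )

    # nuclei: assign states, split into fused (inside ribbons) and unfused
    states = [s for s, n in spec.state_counts.items() for _ in range(n)]
    rng.shuffle(states)
    fused_flags = [i < spec.n_fused for i in range(len(states))]
    nucleus_rows = []
    nucleus_centres: list[tuple[float, float]] = []
    gap_bounds = []
    edges = [0] + [e for y0, y1, _ in ribbons for e in (y0, y1)] + [ny]
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a > 2 * nuc_r_px + 4:
            gap_bounds.append((a + nuc_r_px + 2, b - nuc_r_px - 2))
    if not gap_bounds and any(not f for f in fused_flags):
        raise PlacementError("no inter-myotube gap can host unfused nuclei")
    # keep nuclei clear of neurite lines and patches so DAPI stays clean
    for state, fused in zip(states, fused_flags):
        if fused:
            y0, y1, _ = ribbons[int(rng.integers(0, len(ribbons)))]
            bounds = (y0 + nuc_r_px + 3, y1 - nuc_r_px - 3)
        else:
            bounds = gap_bounds[int(rng.integers(0, len(gap_bounds)))]
        placed = _place_separated(
            rng,
            1,
            (bounds[0], bounds[1], nuc_r_px + 2, nx - nuc_r_px - 2),
            min_sep=NUCLEUS_SEPARATION_FACTOR * nuc_r_px,
            existing=nucleus_centres,
            accept=lambda yy, xx: all(abs(xx - ux) > 25 for ux in used_x),
            what="culture nuclei",
        )
        nyc, nxc = placed[0]
        nucleus_centres.append((nyc, nxc))
        disc = _disk_mask((ny, nx), nyc, nxc, nuc_r_px)
        z = int(rng.integers(0, nz))
        _stamp(voxels[:, ci["DAPI"]], z, disc)
        pax7 = state.startswith("pax7+")
        ki67 = state.endswith("ki67+")
        if pax7:
            _stamp(voxels[:, ci["Pax7"]], z, disc)
        if ki67:
            _stamp(voxels[:, ci["Ki67"]], z, disc)
        nucleus_rows.append(
            {
                "centroid_y_um": nyc * px,
                "centroid_x_um": nxc * px,
                "pax7_flag": pax7,
                "ki67_flag": ki67,
                "inside_mhc_flag": bool(fused),
                "nmj_id": 0,
                "distance_um": np.nan,
            }
        )

    voxels = _finalize(voxels, spec)
    stack = MultiChannelStack(voxels=voxels, channel_names=channels, pixel_size=px)
    truth = SceneGroundTruth(
        nmjs=pd.DataFrame(
            patch_rows,
            columns=[
                "id", "centroid_y_um", "centroid_x_um", "area_um2",
                "innervated_flag", "on_contacting_myotube",
            ],
        ),
        nuclei=pd.DataFrame(
            nucleus_rows,
            columns=[
                "centroid_y_um", "centroid_x_um", "pax7_flag", "ki67_flag",
                "inside_mhc_flag", "nmj_id", "distance_um",
            ],
        ),
        myotubes=pd.DataFrame(myotube_rows, columns=["id", "y0_um", "y1_um", "contact_flag"]),
    )
    return stack, truth


def gen_neurite_crossing_mask(
    lengths_um: list[float],
    boundary_x_um: float,
    image_shape: tuple[int, int] = (256, 1200),
    pixel_size: float = 0.5,
    tail_um: float = 20.0,
) -> np.ndarray:
    """Binary mask of horizontal neurites crossing a compartment boundary.

    Each requested neurite starts ``tail_um`` before ``boundary_x_um`` (on
    the neuronal side) and extends the planted length beyond it into the
    myotube compartment, on its own row; used as an analytic ground truth
    for geodesic length measurement.
    """
    ny, nx = image_shape
    mask = np.zeros((ny, nx), dtype=bool)
    bcol = int(round(boundary_x_um / pixel_size))
    pitch = ny // (len(lengths_um) + 1)
    for i, length in enumerate(lengths_um):
        row = (i + 1) * pitch
        x0 = max(0, bcol - int(round(tail_um / pixel_size)))
        x1 = bcol + int(round(length / pixel_size))
        if x1 >= nx:
            raise ValueError("planted neurite extends past the image; widen image_shape")
        mask[row, x0 : x1 + 1] = True
    return mask


def write_scene(stack: MultiChannelStack, truth: SceneGroundTruth, stem: str | Path) -> None:
    """Write a scene as ``<stem>.tif`` plus a ``<stem>.truth.json`` sidecar."""
    stem = Path(stem)
    write_stack(stack, stem.with_suffix(".tif"))
    truth.to_json(stem.with_suffix(".truth.json"))
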