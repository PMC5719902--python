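"""Per-placenta morphometric descriptors of the arterial network and disc shape.

The arterial feature vector has 28 entries.  The first fifteen are the
descriptors with published definitions (counts and their tree identities,
thickness statistics with the population 1/T normalizer, total cylinder
volume, arc/chord tortuosity statistics, the fourth-pixel branch angle,
growth extension to the disc boundary, vessel-to-disc coverage and the
normalized cube-law residual).  The remaining thirteen extend the same
descriptor families with min/median/kurtosis variants and segment-length
statistics.  Eight further descriptors characterize the chorionic-disc
shape.

Features that are undefined for a particular network (e.g. ``MeanAngle``
when no bifurcation exists) are reported as NaN, the package-wide
missing-value sentinel; downstream model fitting drops such placentas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import kurtosis as _kurtosis
from skimage.measure import label as _sk_label, regionprops

from .skeleton import (
    DEFAULT_SPUR_PX,
    SkeletonGraph,
    VesselMask,
    VesselSegment,
    build_graph,
    measure_thickness,
    prune_spurs,
    skeletonize,
)

logger = logging.getLogger(__name__)

SENTINEL = float("nan")

#: The fifteen descriptors with published definitions, in their published rank order.
CORE_ARTERIAL_FEATURES: List[str] = [
    "MeanThickness",
    "MeanTortuosity",
    "MurrayL1FitError",
    "StdThickness",
    "StdDevTortuosity",
    "MaxTortuosity",
    "MeanAngle",
    "NumEndPoints",
    "ArcLength",
    "NumBranchPoints",
    "MurrayBranchesUsed",
    "Volume",
    "NumGenerations",
    "MeanDistEndPointToPerim",
    "VesselToDiscPercent",
]

#: Extended summary statistics completing the 28-attribute arterial set.
EXTRA_ARTERIAL_FEATURES: List[str] = [
    "MedianAngle",
    "KurtosisTortuosity",
    "MinThickness",
    "MedianThickness",
    "KurtosisThickness",
    "MinTortuosity",
    "MedianTortuosity",
    "MinAngle",
    "KurtosisAngle",
    "MeanSegmentLength",
    "StdSegmentLength",
    "MedianSegmentLength",
    "MaxSegmentLength",
]

ARTERIAL_FEATURES: List[str] = CORE_ARTERIAL_FEATURES + EXTRA_ARTERIAL_FEATURES

SHAPE_FEATURES: List[str] = [
    "DiscArea",
    "DiscPerimeter",
    "DiscEquivalentDiameter",
    "DiscEccentricity",
    "DiscMaxRadius",
    "DiscMinRadius",
    "CentroidToCordDisplacement",
    "DiscCircularity",
]

ALL_FEATURES: List[str] = ARTERIAL_FEATURES + SHAPE_FEATURES

FEATURE_UNITS: Dict[str, str] = {
    "MeanThickness": "cm",
    "StdThickness": "cm",
    "MinThickness": "cm",
    "MedianThickness": "cm",
    "KurtosisThickness": "1",
    "Volume": "cm^3",
    "ArcLength": "cm",
    "MeanTortuosity": "1",
    "StdDevTortuosity": "1",
    "MaxTortuosity": "1",
    "MinTortuosity": "1",
    "MedianTortuosity": "1",
    "KurtosisTortuosity": "1",
    "MeanAngle": "deg",
    "MedianAngle": "deg",
    "MinAngle": "deg",
    "KurtosisAngle": "1",
    "NumEndPoints": "count",
    "NumBranchPoints": "count",
    "MurrayBranchesUsed": "count",
    "NumGenerations": "count",
    "MeanDistEndPointToPerim": "cm",
    "VesselToDiscPercent": "%",
    "MurrayL1FitError": "1",
    "MeanSegmentLength": "cm",
    "StdSegmentLength": "cm",
    "MedianSegmentLength": "cm",
    "MaxSegmentLength": "cm",
    "DiscArea": "cm^2",
    "DiscPerimeter": "cm",
    "DiscEquivalentDiameter": "cm",
    "DiscEccentricity": "1",
    "DiscMaxRadius": "cm",
    "DiscMinRadius": "cm",
    "CentroidToCordDisplacement": "cm",
    "DiscCircularity": "1",
}


@dataclass
class NetworkCounts:
    """Node/branch counts and the tree identities that bind them.

    With x end nodes and y branch nodes a tree has n = x + y nodes,
    n - 1 branches, and z = y - 1 branches used for cube-law fitting.
    """

    num_end_points: int
    num_branch_points: int
    murray_branches_used: int
    total_branches: int
    num_generations: int


@dataclass
class FeatureVector:
    """Named descriptor values for one placenta (28 arterial + 8 shape)."""

    values: Dict[str, float]
    units: Dict[str, str] = field(default_factory=lambda: dict(FEATURE_UNITS))

    @property
    def arterial(self) -> Dict[str, float]:
        return {k: self.values[k] for k in ARTERIAL_FEATURES}

    @property
    def shape(self) -> Dict[str, float]:
        return {k: self.values[k] for k in SHAPE_FEATURES}

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self):
        import pandas as pd

        return pd.Series({k: self.values[k] for k in ALL_FEATURES})


def _pop_sd(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def count_features(graph: SkeletonGraph) -> NetworkCounts:
    """Count end nodes (x), branch nodes (y), z = y - 1 and generations.

    The root counts as an end node when its degree is 1.  ``NumGenerations``
    is the edge-depth of the deepest branch node (0 when there is none),
    i.e. the number of successive branching generations below the root.
    """
    if graph.n == 0:
        return NetworkCounts(0, 0, 0, 0, 0)
    x = len(graph.end_nodes())
    y = len(graph.branch_nodes())
    z = max(y - 1, 0)
    branch_gens = [nd.generation for nd in graph.branch_nodes()]
    return NetworkCounts(
        num_end_points=x,
        num_branch_points=y,
        murray_branches_used=z,
        total_branches=len(graph.segments),
        num_generations=max(branch_gens) if branch_gens else 0,
    )


def thickness_stats(segments: Sequence[VesselSegment]) -> Tuple[float, float]:
    """Mean and population SD of per-segment thickness, cm."""
    vals = np.array([s.thickness_cm for s in segments if s.thickness_cm is not None])
    if len(vals) == 0:
        return SENTINEL, SENTINEL
    return float(vals.mean()), _pop_sd(vals)


def total_volume(segments: Sequence[VesselSegment]) -> float:
    """Sum of per-vessel cylinder volumes pi (d/2)^2 c, cm^3."""
    vol = 0.0
    for s in segments:
        if s.thickness_cm is None:
            continue
        vol += np.pi * (s.thickness_cm / 2.0) ** 2 * s.arc_length_cm
    return float(vol)


def tortuosity_stats(
    segments: Sequence[VesselSegment],
) -> Tuple[float, float, float, float]:
    """Mean, population SD, max and excess kurtosis of arc/chord tortuosity.

    Segments with zero chord (closed-loop remnants) are excluded and logged.
    """
    ratios = []
    excluded = 0
    for s in segments:
        if s.chord_cm <= 0:
            excluded += 1
            continue
        ratios.append(s.arc_length_cm / s.chord_cm)
    if excluded:
        logger.warning("tortuosity_stats: excluded %d zero-chord segment(s)", excluded)
    if not ratios:
        return SENTINEL, SENTINEL, SENTINEL, SENTINEL
    r = np.array(ratios)
    kurt = float(_kurtosis(r, fisher=True, bias=True)) if len(r) > 1 else 0.0
    return float(r.mean()), _pop_sd(r), float(r.max()), kurt


def branch_angles(
    graph: SkeletonGraph,
) -> Tuple[List[float], float, float]:
    """Fourth-pixel branch angles at bifurcations, in degrees.

    For every branch node with exactly two child segments, the angle between
    the vectors running from the node pixel to the fourth pixel along each
    child path (the last pixel when the child is shorter).  Nodes with three
    or more children are skipped; they are rare (>90% of branch points
    bifurcate) and their geometry is ambiguous at pixel resolution.
    """
    angles: List[float] = []
    skipped = 0
    for nd in graph.branch_nodes():
        children = graph.children_of(nd.id)
        if len(children) != 2:
            if len(children) > 2:
                skipped += 1
            continue
        vecs = []
        ok = True
        for seg in children:
            path = seg.pixel_path
            if len(path) < 2:
                ok = False
                break
            idx = min(4, len(path) - 1)
            v = path[idx].astype(float) - path[0].astype(float)
            if np.hypot(*v) == 0:
                ok = False
                break
            vecs.append(v / np.hypot(*v))
        if not ok:
            continue
        cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
        angles.append(float(np.degrees(np.arccos(cosang))))
    if skipped:
        logger.debug("branch_angles: skipped %d node(s) with >2 children", skipped)
    if not angles:
        return [], SENTINEL, SENTINEL
    a = np.array(angles)
    return angles, float(a.mean()), float(np.median(a))


def growth_extension(graph: SkeletonGraph, boundary) -> float:
    """Mean distance from arterial end nodes to the nearest boundary point, cm.

    ``boundary`` is either the disc mask (its edge pixels are used) or an
    (n, 2) array of boundary polygon vertices in pixel coordinates.
    """
    ends = graph.end_nodes()
    if not ends:
        return SENTINEL
    pts = _boundary_points(boundary)
    if len(pts) == 0:
        raise ValueError("boundary is empty")
    tree = cKDTree(pts)
    coords = np.array([nd.rc for nd in ends], dtype=float)
    d, _ = tree.query(coords)
    if isinstance(boundary, np.ndarray) and boundary.dtype == bool:
        inside = boundary[coords[:, 0].astype(int), coords[:, 1].astype(int)]
        if not inside.all():
            logger.warning(
                "growth_extension: %d end node(s) outside the disc boundary",
                int((~inside).sum()),
            )
    return float(np.mean(d)) / graph.scale_px_per_cm


def _boundary_points(boundary) -> np.ndarray:
    """Boundary as points: edge pixels of a mask, or a vertex array as-is."""
    b = np.asarray(boundary)
    if b.ndim == 2 and b.shape[1] == 2 and b.dtype != bool:
        return b.astype(float)
    mask = b.astype(bool)
    edge = mask & ~ndimage.binary_erosion(mask)
    return np.argwhere(edge).astype(float)


def vessel_to_disc_percent(vessel_mask: np.ndarray, disc_mask: np.ndarray) -> float:
    """100 x (vessel pixels inside the disc) / (disc pixels)."""
    disc = np.asarray(disc_mask, bool)
    if not disc.any():
        raise ValueError("disc mask is empty")
    vessel = np.asarray(vessel_mask, bool)
    return 100.0 * float((vessel & disc).sum()) / float(disc.sum())


def murray_l1_fit_error(graph: SkeletonGraph, normalized: bool = True) -> float:
    """Mean normalized cube-law residual over bifurcations.

    At each bifurcation with parent thickness t_p and child thicknesses
    t_1, t_2 the residual is |t_p^3 - (t_1^3 + t_2^3)| / t_p^3 (unnormalized
    if requested).  Returns 0 when the tree has no usable bifurcation.
    """
    residuals = []
    for nd in graph.branch_nodes():
        children = graph.children_of(nd.id)
        parent = graph.parent_segment(nd.id)
        if parent is None or len(children) != 2:
            continue
        tp = parent.thickness_cm
        t1, t2 = children[0].thickness_cm, children[1].thickness_cm
        if tp is None or t1 is None or t2 is None or tp <= 0:
            continue
        res = abs(tp**3 - (t1**3 + t2**3))
        residuals.append(res / tp**3 if normalized else res)
    return float(np.mean(residuals)) if residuals else 0.0


def segment_length_stats(
    segments: Sequence[VesselSegment],
) -> Tuple[float, float, float, float]:
    vals = np.array([s.arc_length_cm for s in segments])
    if len(vals) == 0:
        return SENTINEL, SENTINEL, SENTINEL, SENTINEL
    return (
        float(vals.mean()),
        _pop_sd(vals),
        float(np.median(vals)),
        float(vals.max()),
    )


def shape_features(
    disc_mask: np.ndarray, cord_xy: Tuple[int, int], scale: float
) -> Dict[str, float]:
    """Eight chorionic-disc shape descriptors (areas cm^2, lengths cm)."""
    disc = np.asarray(disc_mask, bool)
    if not disc.any():
        raise ValueError("disc mask is empty")
    props = regionprops(_sk_label(disc))[0]
    area_px = float(props.area)
    perim_px = float(props.perimeter_crofton)
    area = area_px / scale**2
    perim = perim_px / scale
    edge = disc & ~ndimage.binary_erosion(disc)
    edge_pts = np.argwhere(edge).astype(float)
    centroid = np.array(props.centroid)
    radii = np.hypot(*(edge_pts - centroid).T)
    cord = np.array([float(cord_xy[0]), float(cord_xy[1])])
    return {
        "DiscArea": area,
        "DiscPerimeter": perim,
        "DiscEquivalentDiameter": float(np.sqrt(4.0 * area / np.pi)),
        "DiscEccentricity": float(props.eccentricity),
        "DiscMaxRadius": float(radii.max()) / scale,
        "DiscMinRadius": float(radii.min()) / scale,
        "CentroidToCordDisplacement": float(np.hypot(*(centroid - cord))) / scale,
        "DiscCircularity": float(4.0 * np.pi * area / perim**2) if perim > 0 else SENTINEL,
    }


#: Pinhole background pockets up to this many pixels are filled before
#: thinning; they arise where strokes merge at shallow angles and would
#: otherwise become spurious skeleton loops.
MAX_HOLE_PX = 64


def _fill_small_holes(grid: np.ndarray, max_px: int = MAX_HOLE_PX) -> np.ndarray:
    holes, n = ndimage.label(~grid)
    if n == 0:
        return grid
    sizes = np.bincount(holes.ravel())
    border = set(np.unique(np.concatenate([holes[0], holes[-1], holes[:, 0], holes[:, -1]])))
    fill = np.zeros(n + 1, dtype=bool)
    for lab in range(1, n + 1):
        if lab not in border and sizes[lab] <= max_px:
            fill[lab] = True
    return grid | fill[holes]


def extract_graph(mask: VesselMask, spur_px: float = DEFAULT_SPUR_PX) -> SkeletonGraph:
    """Run the preprocessing chain: skeletonize, graph, thickness, prune."""
    clean = _fill_small_holes(mask.grid)
    skel = skeletonize(clean)
    edt = ndimage.distance_transform_edt(clean)
    graph = build_graph(skel, mask.cord_xy, mask.scale_px_per_cm, edt=edt)
    if graph.segments:
        measure_thickness(clean, graph)
        prune_spurs(graph, spur_px / mask.scale_px_per_cm)
        measure_thickness(clean, graph)  # merged segments need re-measuring
    return graph


def extract_all(mask: VesselMask, spur_px: float = DEFAULT_SPUR_PX) -> FeatureVector:
    """Full feature vector (28 arterial + 8 shape) for one vessel mask."""
    graph = extract_graph(mask, spur_px=spur_px)
    segs = list(graph.segments.values())
    counts = count_features(graph)
    mean_t, std_t = thickness_stats(segs)
    mean_tor, std_tor, max_tor, kurt_tor = tortuosity_stats(segs)
    angle_list, mean_ang, med_ang = branch_angles(graph)
    mean_len, std_len, med_len, max_len = segment_length_stats(segs)

    thick = np.array([s.thickness_cm for s in segs if s.thickness_cm is not None])
    tor = np.array([s.arc_length_cm / s.chord_cm for s in segs if s.chord_cm > 0])
    ang = np.array(angle_list)

    values: Dict[str, float] = {
        "MeanThickness": mean_t,
        "MeanTortuosity": mean_tor,
        "StdThickness": std_t,
        "StdDevTortuosity": std_tor,
        "MaxTortuosity": max_tor,
        "MeanAngle": mean_ang,
        "NumEndPoints": float(counts.num_end_points),
        "ArcLength": float(sum(s.arc_length_cm for s in segs)),
        "NumBranchPoints": float(counts.num_branch_points),
        "MurrayBranchesUsed": float(counts.murray_branches_used),
        "Volume": total_volume(segs),
        "NumGenerations": float(counts.num_generations),
        "MurrayL1FitError": murray_l1_fit_error(graph),
        "MedianAngle": med_ang,
        "KurtosisTortuosity": kurt_tor,
        "MinThickness": float(thick.min()) if len(thick) else SENTINEL,
        "MedianThickness": float(np.median(thick)) if len(thick) else SENTINEL,
        "KurtosisThickness": (
            float(_kurtosis(thick, fisher=True, bias=True)) if len(thick) > 1 else SENTINEL
        ),
        "MinTortuosity": float(tor.min()) if len(tor) else SENTINEL,
        "MedianTortuosity": float(np.median(tor)) if len(tor) else SENTINEL,
        "MinAngle": float(ang.min()) if len(ang) else SENTINEL,
        "KurtosisAngle": (
            float(_kurtosis(ang, fisher=True, bias=True)) if len(ang) > 1 else SENTINEL
        ),
        "MeanSegmentLength": mean_len,
        "StdSegmentLength": std_len,
        "MedianSegmentLength": med_len,
        "MaxSegmentLength": max_len,
    }
    if mask.boundary is not None:
        values["MeanDistEndPointToPerim"] = growth_extension(graph, mask.boundary)
        values["VesselToDiscPercent"] = vessel_to_disc_percent(mask.grid, mask.boundary)
        values.update(shape_features(mask.boundary, mask.cord_xy, mask.scale_px_per_cm))
    else:
        values["MeanDistEndPointToPerim"] = SENTINEL
        values["VesselToDiscPercent"] = SENTINEL
        values.update({k: SENTINEL for k in SHAPE_FEATURES})
    return FeatureVector(values=values)
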