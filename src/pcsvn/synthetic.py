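"""Synthetic chorionic-surface vascular networks with known ground truth.

The study images (a high-risk enriched cohort and a population-based
cohort) are not publicly deposited, so every downstream stage is exercised
on simulated data instead.  The generator grows a rooted, strictly
bifurcating arterial tree on a circular chorionic disc:

* the root sits at the cord insertion (disc center) and emits one trunk;
* tips bifurcate with a sampled opening angle until the target number of
  branch points is reached, growth being pulled toward the disc boundary;
* remaining tips then run outward and stop at a sampled distance from the
  disc perimeter (the growth-extension descriptor);
* each segment is a smooth polyline whose arc/chord ratio (tortuosity) is
  planted exactly, with a straight lead-in after every branch node so that
  the fourth-pixel branch angle measures the planted opening angle;
* thickness tapers down the tree by a cube-law (Murray) split with noise,
  then is rescaled to a planted per-placenta mean.

Self-intersections are avoided by rejection sampling against an occupancy
grid; geometry lives in cm with the disc center at the origin, and
``rasterize`` stamps it onto the study raster (1380x1440 px, 35 px/cm,
cord at the canvas center).

Cohort sampling plants per-placenta values of the five principal
descriptors drawn from the published cohort statistics, corrected by a
pilot-estimated extraction transfer so that the *extracted* cohort means
match the published targets (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TreeSpec",
    "GroundTruth",
    "CohortSpec",
    "PlacentaSample",
    "COHORT_TARGETS",
    "sample_tree",
    "rasterize",
    "sample_cohort",
    "sample_feature_table",
    "cohort_tree_spec",
]

# ---------------------------------------------------------------------------
# published cohort statistics (mean, SD) of the five principal descriptors.
# "earli" is the high-risk enriched cohort, "ncs" the population-based one.
# Thickness and distances are interpreted in cm (consistent with the
# 35 px/cm raster scale), angles in degrees; the unit assumption is recorded
# here rather than hard-coded downstream.
# ---------------------------------------------------------------------------
COHORT_TARGETS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "earli": {
        "NumBranchPoints": (36.74, 15.66),
        "MeanThickness": (0.16, 0.03),
        "StdDevTortuosity": (0.06, 0.03),
        "MeanDistEndPointToPerim": (2.82, 0.48),
        "MeanAngle": (100.64, 3.51),
    },
    "ncs": {
        "NumBranchPoints": (48.48, 16.34),
        "MeanThickness": (0.13, 0.02),
        "StdDevTortuosity": (0.08, 0.03),
        "MeanDistEndPointToPerim": (2.96, 0.41),
        "MeanAngle": (102.28, 2.87),
    },
}

COHORT_UNITS = {"lengths": "cm", "angles": "deg"}

#: Extraction-transfer offsets (extracted minus planted cohort mean) of the
#: five planted descriptors, estimated once from a pilot simulation at the
#: default raster scale and subtracted when planting (docs/methods.md).
CALIBRATION_OFFSETS: Dict[str, Dict[str, float]] = {
    "earli": {
        "NumBranchPoints": -0.23,
        "MeanThickness": -0.0213,
        "StdDevTortuosity": 0.0101,
        "MeanDistEndPointToPerim": 0.1025,
        "MeanAngle": 12.96,
    },
    "ncs": {
        "NumBranchPoints": 0.25,
        "MeanThickness": -0.0221,
        "StdDevTortuosity": 0.0076,
        "MeanDistEndPointToPerim": 0.1489,
        "MeanAngle": 8.21,
    },
}

_MIN_THICKNESS_CM = 0.08  # keep strokes >= ~3 px at 35 px/cm
_STRAIGHT_LEADIN_CM = 0.35  # straight run after a branch node (angle fidelity)
_CLEARANCE_CM = 0.34  # centerline-to-centerline separation between vessels
_SAMPLE_STEP_CM = 0.02  # polyline sampling resolution


@dataclass
class TreeSpec:
    """Generative parameters of one synthetic arterial tree.

    Branch-point and tortuosity parameters are (mean, dispersion) pairs;
    setting a dispersion to zero plants the mean exactly.  ``seed`` makes
    ``sample_tree`` reproducible when no generator is passed explicitly.
    """

    disc_radius_cm: float = 9.5
    mean_branch_points: float = 42.0
    sd_branch_points: float = 0.0
    mean_segment_cm: float = 1.25
    sd_segment_cm: float = 0.4
    tortuosity_amplitude: float = 0.10  # mean excess arc/chord ratio
    tortuosity_spread: float = 0.06  # per-segment SD of the excess
    root_thickness_cm: float = 0.25
    mean_thickness_cm: Optional[float] = None  # rescale target; None keeps taper
    murray_exponent: float = 3.0
    murray_noise: float = 0.15
    branch_angle_deg: float = 101.0
    branch_angle_sd: float = 6.0
    extension_pull: float = 0.55
    tip_margin_cm: float = 2.9  # mean leaf distance to the disc perimeter
    tip_margin_sd_cm: float = 0.35
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.disc_radius_cm <= 0:
            raise ValueError("disc_radius_cm must be positive")
        for name in (
            "sd_branch_points",
            "sd_segment_cm",
            "tortuosity_amplitude",
            "tortuosity_spread",
            "murray_noise",
            "branch_angle_sd",
            "tip_margin_sd_cm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_branch_points < 0:
            raise ValueError("mean_branch_points must be >= 0")
        if self.root_thickness_cm <= 0:
            raise ValueError("root_thickness_cm must be positive")
        if self.murray_exponent <= 0:
            raise ValueError("murray_exponent must be positive")


@dataclass
class GTNode:
    id: int
    pos_cm: np.ndarray  # (2,) xy in cm, disc center at origin
    kind: str  # 'end' | 'branch'
    generation: int


@dataclass
class GTSegment:
    polyline_cm: np.ndarray  # (M, 2)
    thickness_cm: float
    parent_node: int
    child_node: int
    arc_cm: float
    chord_cm: float

    @property
    def tortuosity(self) -> float:
        return self.arc_cm / self.chord_cm if self.chord_cm > 0 else np.nan


@dataclass
class GroundTruth:
    """Geometric tree plus the descriptor values it was planted with."""

    nodes: List[GTNode]
    segments: List[GTSegment]
    disc_radius_cm: float
    true_counts: Tuple[int, int]  # (end nodes, branch points)
    true_feature_values: Dict[str, float]
    #: number of segments that needed a fallback (shortened/strict) placement;
    #: 0 marks a "clean" fixture on which extraction recovers counts exactly
    n_fallback: int = 0

    def to_json_dict(self) -> dict:
        return {
            "disc_radius_cm": self.disc_radius_cm,
            "true_counts": list(self.true_counts),
            "true_feature_values": self.true_feature_values,
            "nodes": [
                {
                    "id": n.id,
                    "pos_cm": [float(v) for v in n.pos_cm],
                    "kind": n.kind,
                    "generation": n.generation,
                }
                for n in self.nodes
            ],
            "segments": [
                {
                    "parent_node": s.parent_node,
                    "child_node": s.child_node,
                    "thickness_cm": float(s.thickness_cm),
                    "arc_cm": float(s.arc_cm),
                    "chord_cm": float(s.chord_cm),
                    "polyline_cm": np.asarray(s.polyline_cm).round(4).tolist(),
                }
                for s in self.segments
            ],
        }


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _polyline_arc(pts: np.ndarray) -> float:
    d = np.diff(pts, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _segment_base_path(start: np.ndarray, d: np.ndarray, L: float) -> np.ndarray:
    n = max(int(np.ceil(L / _SAMPLE_STEP_CM)), 8)
    t = np.linspace(0.0, L, n)
    return start[None, :] + d[None, :] * t[:, None]


def _turn_scalar(
    dx: float, dy: float, tx: float, ty: float, max_turn_rad: float
) -> Tuple[float, float]:
    """Rotate unit direction (dx, dy) toward (tx, ty) by at most max_turn_rad."""
    ang = math.atan2(dx * ty - dy * tx, dx * tx + dy * ty)
    if ang > max_turn_rad:
        ang = max_turn_rad
    elif ang < -max_turn_rad:
        ang = -max_turn_rad
    c, s = math.cos(ang), math.sin(ang)
    return c * dx - s * dy, s * dx + c * dy


def _curved_path(
    start: np.ndarray,
    d: np.ndarray,
    L: float,
    target_dir: np.ndarray,
    head: float,
    max_turn_deg_per_cm: float = 30.0,
) -> np.ndarray:
    """Length-L centerline: straight lead-in along ``d``, then bending
    toward the fixed direction ``target_dir``."""
    h = _SAMPLE_STEP_CM
    max_turn = math.radians(max_turn_deg_per_cm) * h
    px, py = float(start[0]), float(start[1])
    dx, dy = float(d[0]), float(d[1])
    tx, ty = float(target_dir[0]), float(target_dir[1])
    pts = [(px, py)]
    s = 0.0
    while s < L:
        if s >= head:
            dx, dy = _turn_scalar(dx, dy, tx, ty, max_turn)
        px += dx * h
        py += dy * h
        s += h
        pts.append((px, py))
    return np.array(pts)


def _leaf_base_path(
    start: np.ndarray,
    d: np.ndarray,
    r_target: float,
    head: float,
    aim: np.ndarray,
) -> Optional[np.ndarray]:
    """Curved leaf centerline: straight lead-in along ``d``, then homing
    toward ``aim`` (a point on the stop circle inside the leaf's wedge)
    until radius ``r_target`` is reached."""
    if float(np.hypot(*start)) >= r_target - 0.05:
        return _segment_base_path(start, d, 0.6)
    h = _SAMPLE_STEP_CM
    max_turn = math.radians(55.0) * h  # max bend per step (55 deg/cm)
    px, py = float(start[0]), float(start[1])
    dx, dy = float(d[0]), float(d[1])
    ax, ay = float(aim[0]), float(aim[1])
    pts = [(px, py)]
    s = 0.0
    while math.hypot(px, py) < r_target:
        if s > 9.0:
            return None
        if s >= head:
            vx, vy = ax - px, ay - py
            vn = math.hypot(vx, vy)
            if vn > 0.2:
                tx, ty = vx / vn, vy / vn
            else:
                rn = math.hypot(px, py)
                tx, ty = (px / rn, py / rn) if rn > 1e-9 else (dx, dy)
            dx, dy = _turn_scalar(dx, dy, tx, ty, max_turn)
        px += dx * h
        py += dy * h
        s += h
        pts.append((px, py))
    # a leaf shorter than ~0.55 cm would not survive spur pruning; extend it
    while s < 0.55:
        px += dx * h
        py += dy * h
        s += h
        pts.append((px, py))
    return np.array(pts)


def _apply_wiggle(
    base: np.ndarray,
    excess: float,
    rng: np.random.Generator,
    head: float = 0.0,
    tail: float = 0.15,
) -> np.ndarray:
    """Displace a base centerline along its normals until arc = chord*(1+excess).

    The displacement envelope vanishes (with ~zero slope) at both ends and
    is held at zero over the first ``head`` cm so branch-angle geometry at
    the start node stays intact.  The amplitude is found by bisection; when
    the base path is already longer than the target (a strongly curved leaf
    run) it is returned unchanged.
    """
    chord = float(np.hypot(*(base[-1] - base[0])))
    if excess <= 1e-6 or chord < 0.3:
        return base
    d = np.diff(base, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    target = chord * (1.0 + excess)
    if target <= total + 1e-6:
        return base
    tang = np.vstack([d[0], d]) + np.vstack([d, d[-1]])
    tang = tang / np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    a = min(head, 0.4 * total)
    b = total - min(tail, 0.2 * total)
    u = np.clip((s - a) / max(b - a, 1e-9), 0.0, 1.0)
    lobes = max(1, int(round((b - a) / 1.2)))
    if lobes > 1 and rng.random() < 0.5:
        lobes -= 1
    phase = float(rng.choice([-1.0, 1.0]))
    shape = np.sin(np.pi * u) ** 2 * np.sin(np.pi * lobes * u) * phase

    def arc_for(amp: float) -> float:
        return _polyline_arc(base + normal * (amp * shape)[:, None])

    lo, hi = 0.0, chord
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if arc_for(mid) < target:
            lo = mid
        else:
            hi = mid
    amp = 0.5 * (lo + hi)
    return base + normal * (amp * shape)[:, None]


def _wiggly_polyline(
    start: np.ndarray,
    end: np.ndarray,
    excess: float,
    rng: np.random.Generator,
    straight_head: float = 0.0,
) -> np.ndarray:
    """Smooth polyline from start to end with arc = chord * (1 + excess)."""
    d = end - start
    L = float(np.hypot(*d))
    base = _segment_base_path(start, _unit(d), L)
    return _apply_wiggle(base, excess, rng, head=straight_head)


class _Occupancy:
    """Coarse spatial hash of accepted centerline points for collision tests.

    Points carry the stroke thickness of their segment, so the required
    separation between two centerlines is the sum of their half-widths plus
    a gap wide enough for the skeletons to stay distinct after rasterizing.
    Points are stored under an integer tag per segment so a partially placed
    bifurcation can be rolled back cleanly.
    """

    GAP_CM = 0.15  # ~5 px of background between strokes at 35 px/cm

    def __init__(self, cell: float = 0.6) -> None:
        self.cell = cell
        self.cells: Dict[Tuple[int, int], List[Tuple[np.ndarray, float, int]]] = {}
        self.tag_keys: Dict[int, List[Tuple[int, int]]] = {}
        self._step = max(1, int(0.05 / _SAMPLE_STEP_CM))

    def _key(self, p: np.ndarray) -> Tuple[int, int]:
        return (int(np.floor(p[0] / self.cell)), int(np.floor(p[1] / self.cell)))

    def add_polyline(self, pts: np.ndarray, thickness: float, tag: int) -> None:
        keys = []
        for p in pts[:: self._step]:
            k = self._key(p)
            self.cells.setdefault(k, []).append((float(p[0]), float(p[1]), thickness, tag))
            keys.append(k)
        self.tag_keys[tag] = keys

    def remove(self, tag: int) -> None:
        for k in self.tag_keys.pop(tag, []):
            self.cells[k] = [rec for rec in self.cells[k] if rec[3] != tag]

    def collides(
        self,
        pts: np.ndarray,
        thickness: float,
        origin: np.ndarray,
        exempt_tags: frozenset,
        r_exempt: Optional[float] = None,
    ) -> bool:
        """True when the candidate centerline comes too close to stored ink.

        Segments of the same junction family (the parent and any sibling,
        identified by tag) are exempt, but only near the shared node — a
        leaf curving back onto its own parent further out is still a
        collision.  The exemption radius scales with the stroke width so a
        segment's far end is always vetted against its uncle's ink before
        children can spawn there.
        """
        if r_exempt is None:
            r_exempt = max(0.6, 2.2 * (thickness + self.GAP_CM))
        ox, oy = float(origin[0]), float(origin[1])
        cell = self.cell
        cells = self.cells
        half_t = 0.5 * thickness + self.GAP_CM
        for p in pts[:: self._step]:
            px, py = float(p[0]), float(p[1])
            near_origin = math.hypot(px - ox, py - oy) < r_exempt
            kx, ky = int(math.floor(px / cell)), int(math.floor(py / cell))
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for qx, qy, tq, tg in cells.get((kx + dx, ky + dy), ()):
                        if tg in exempt_tags and near_origin:
                            continue
                        if math.hypot(px - qx, py - qy) < half_t + 0.5 * tq:
                            return True
        return False


# ---------------------------------------------------------------------------
# sample_tree
# ---------------------------------------------------------------------------


def sample_tree(spec: TreeSpec, rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Grow one synthetic arterial tree on the disc.

    Returns geometry (polylines in cm, per-segment thickness) together with
    the planted descriptor values.  Raises ``ValueError`` when the requested
    number of branch points cannot be placed on the disc without collisions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    R = spec.disc_radius_cm
    y_target = int(round(max(0.0, rng.normal(spec.mean_branch_points, spec.sd_branch_points))))
    if spec.sd_branch_points == 0:
        y_target = int(round(spec.mean_branch_points))

    max_y = int(0.55 * np.pi * R**2 / (spec.mean_segment_cm * _CLEARANCE_CM * 2.0))
    if y_target > max_y:
        raise ValueError(
            f"target_branch_points={y_target} unreachable on a disc of radius "
            f"{R} cm with segment length {spec.mean_segment_cm} cm and clearance "
            f"{_CLEARANCE_CM} cm (max ~{max_y})"
        )

    occ = _Occupancy()
    nodes: List[GTNode] = []
    segments: List[GTSegment] = []
    planted_angles: List[float] = []
    planted_excess: List[float] = []
    fallback_count = [0]

    def new_node(pos: np.ndarray, kind: str, gen: int) -> int:
        nodes.append(GTNode(len(nodes), pos.copy(), kind, gen))
        return nodes[-1].id

    def seg_excess() -> float:
        amp, spread = spec.tortuosity_amplitude, spec.tortuosity_spread
        if amp <= 0:
            return 0.0
        if spread <= 0:
            return amp
        shape = (amp / spread) ** 2
        return float(rng.gamma(shape, spread**2 / amp))

    def seg_len() -> float:
        mu, sd = spec.mean_segment_cm, spec.sd_segment_cm
        if sd <= 0:
            return mu
        shape = (mu / sd) ** 2
        return float(np.clip(rng.gamma(shape, sd**2 / mu), 0.8, 3.2))

    def radial(pos: np.ndarray) -> np.ndarray:
        return _unit(pos) if np.hypot(*pos) > 1e-9 else _unit(rng.normal(size=2))

    root_pos = np.zeros(2)
    root_id = new_node(root_pos, "end", 0)

    # the cord trunk bifurcates close to the insertion, so the two main
    # stems can fan out over the whole disc
    trunk_dir = _unit(rng.normal(size=2))
    trunk_len = float(np.clip(rng.normal(1.0, 0.15), 0.8, 1.3))
    tag_counter = [0]

    node_tags: Dict[int, List[int]] = {root_id: []}

    def place(
        parent_id: int,
        pts: np.ndarray,
        thickness: float,
        depth: int,
        excess: float,
        check: bool = True,
        strict: bool = False,
    ) -> Optional[int]:
        start = pts[0]
        if np.any(np.hypot(pts[:, 0], pts[:, 1]) > R - 0.10):
            return None
        exempt = frozenset(node_tags.get(parent_id, ()))
        # strict mode shrinks the family exemption to the node blob itself,
        # so fallback stubs cannot hide alongside their parent
        r_ex = 0.35 if strict else None
        if check and occ.collides(pts, thickness, origin=start, exempt_tags=exempt, r_exempt=r_ex):
            return None
        cid = new_node(pts[-1], "end", depth)
        segments.append(
            GTSegment(
                polyline_cm=pts,
                thickness_cm=thickness,
                parent_node=parent_id,
                child_node=cid,
                arc_cm=_polyline_arc(pts),
                chord_cm=float(np.hypot(*(pts[-1] - pts[0]))),
            )
        )
        tag_counter[0] += 1
        occ.add_polyline(pts, thickness, tag_counter[0])
        node_tags.setdefault(parent_id, []).append(tag_counter[0])
        node_tags[cid] = [tag_counter[0]]
        planted_excess.append(excess)
        return cid

    t_root = spec.root_thickness_cm

    if y_target == 0:
        L = max(min(trunk_len + 2.0, R - spec.tip_margin_cm), 0.8)
        e = seg_excess()
        pts = _wiggly_polyline(root_pos, root_pos + trunk_dir * L, e, rng)
        cid = place(root_id, pts, t_root, 1, e)
        if cid is None:  # pragma: no cover - an empty disc cannot collide
            raise ValueError("could not place the degenerate root segment")
        return _finalize(spec, nodes, segments, planted_angles, planted_excess, fallback_count[0])

    # --- abstract topology first: exactly y_target internal slots ---------
    # shallow open slots are preferred, giving moderately balanced trees
    # (deep, lopsided topologies force leaves into long boundary runs)
    open_slots = [0]
    slot_depth = {0: 1}
    internal: set = set()
    child_slots: Dict[int, Tuple[int, int]] = {}
    next_slot = 1
    for _ in range(y_target):
        wts = np.array([0.55 ** slot_depth[s] for s in open_slots])
        i_idx = int(rng.choice(len(open_slots), p=wts / wts.sum()))
        i = open_slots.pop(i_idx)
        internal.add(i)
        child_slots[i] = (next_slot, next_slot + 1)
        for c in (next_slot, next_slot + 1):
            slot_depth[c] = slot_depth[i] + 1
        open_slots.extend((next_slot, next_slot + 1))
        next_slot += 2

    # leaves below each slot (drives the angular-wedge allocation)
    n_leaves: Dict[int, int] = {}
    for slot in range(next_slot - 1, -1, -1):
        if slot in internal:
            a, b = child_slots[slot]
            n_leaves[slot] = n_leaves[a] + n_leaves[b]
        else:
            n_leaves[slot] = 1

    def place_with_retries(
        slot: int,
        parent_id: int,
        pos: np.ndarray,
        d: np.ndarray,
        thickness: float,
        depth: int,
        head: float,
        wedge: Tuple[float, float],
    ) -> Tuple[int, np.ndarray]:
        """Realize one slot's segment; the topology is already committed, so
        after the retries run out the segment is stamped without the
        collision check (rare, logged implicitly through extraction noise)."""
        is_leaf = slot not in internal
        theta_c = 0.5 * (wedge[0] + wedge[1])
        wedge_dir = np.array([np.cos(theta_c), np.sin(theta_c)])
        r_now = float(np.hypot(*pos))
        for attempt in range(12):
            jitter = float(np.clip(rng.normal(0.0, 4.0 * attempt), -70.0, 70.0))
            dd = d if attempt == 0 else _unit(_rot(d, jitter))
            e = seg_excess()
            if is_leaf:
                d_stop = float(
                    np.clip(rng.normal(spec.tip_margin_cm, spec.tip_margin_sd_cm), 0.5, R - 1.0)
                )
                aim = (R - d_stop) * wedge_dir
                base = _leaf_base_path(pos, dd, R - d_stop, head, aim)
                if base is None:
                    continue
            else:
                L = seg_len()
                # steer toward a point on the wedge centerline a little
                # further out, so strayed subtrees come back to their sector
                aim = (r_now + max(L, 1.0)) * wedge_dir
                tgt = _unit(aim - pos) if np.hypot(*(aim - pos)) > 0.3 else wedge_dir
                base = _curved_path(pos, dd, L, tgt, head, max_turn_deg_per_cm=45.0)
            pts = _apply_wiggle(base, e, rng, head)
            cid = place(parent_id, pts, thickness, depth, e)
            if cid is not None:
                return cid, dd
        # crowded neighborhood, plan B: truncate the natural (curved) run
        fallback_count[0] += 1
        if is_leaf:
            base_full = _leaf_base_path(pos, d, R - spec.tip_margin_cm, head, pos * 2.0)
        else:
            base_full = _curved_path(pos, d, seg_len(), wedge_dir, head)
        if base_full is not None:
            for frac in (0.7, 0.5, 0.35):
                m = max(int(len(base_full) * frac), int(0.5 / _SAMPLE_STEP_CM))
                if m >= len(base_full):
                    continue
                cid = place(parent_id, base_full[:m], thickness, depth, 0.0, strict=True)
                if cid is not None:
                    return cid, d
        # plan C: short straight probes in any free direction, with the
        # strict (node-blob-only) exemption so a stub cannot hide alongside
        # its parent
        for L in (1.1, 0.8, 0.6, 0.45):
            for k in range(16):
                dd = _unit(_rot(d, rng.normal(0.0, 15.0) if k < 4 else rng.uniform(-160.0, 160.0)))
                end = pos + dd * L
                r_end = float(np.hypot(*end))
                if r_end > R - 0.15:
                    end = end * (R - 0.15) / r_end
                pts = _segment_base_path(pos, _unit(end - pos), float(np.hypot(*(end - pos))))
                cid = place(parent_id, pts, thickness, depth, 0.0, strict=True)
                if cid is not None:
                    return cid, dd
        # last resort: stamp a stub without the collision check so the
        # committed topology survives (essentially never reached)
        end = pos + d * 0.5
        r_end = float(np.hypot(*end))
        if r_end > R - 0.15:
            end = end * (R - 0.15) / r_end
        pts = _segment_base_path(pos, _unit(end - pos), float(np.hypot(*(end - pos))))
        cid = place(parent_id, pts, thickness, depth, 0.0, check=False)
        return cid, d

    # trunk realizes slot 0; its wedge is the full circle about its azimuth
    trunk_az = float(np.arctan2(trunk_dir[1], trunk_dir[0]))
    queue: List[tuple] = [
        (0, root_id, root_pos, trunk_dir, t_root, 1, 0.0, (trunk_az - np.pi, trunk_az + np.pi))
    ]
    while queue:
        slot, parent_id, pos, d, t_here, depth, head, wedge = queue.pop(0)
        if slot == 0 and slot in internal:
            # trunk: fixed modest length
            for attempt in range(12):
                dd = d if attempt == 0 else _unit(_rot(d, rng.normal(0.0, 6.0)))
                e = seg_excess()
                pts = _wiggly_polyline(pos, pos + dd * trunk_len, e, rng)
                cid = place(parent_id, pts, t_here, depth, e)
                if cid is not None:
                    d = dd
                    break
            else:
                raise ValueError("could not place the trunk segment on the disc")
        else:
            cid, d = place_with_retries(slot, parent_id, pos, d, t_here, depth, head, wedge)
        if slot not in internal:
            continue
        # bifurcate at the new node
        node_pos = nodes[cid].pos_cm
        nodes[cid].kind = "branch"
        phi = float(np.clip(rng.normal(spec.branch_angle_deg, spec.branch_angle_sd), 40.0, 165.0))
        planted_angles.append(phi)
        u = rng.uniform(0.40, 0.60)
        pull = spec.extension_pull
        theta_c = 0.5 * (wedge[0] + wedge[1])
        wedge_dir = np.array([np.cos(theta_c), np.sin(theta_c)])
        anchor = (float(np.hypot(*node_pos)) + 1.5) * wedge_dir
        pull_dir = _unit(anchor - node_pos) if np.hypot(*(anchor - node_pos)) > 0.3 else wedge_dir
        base_dir = _unit((1.0 - pull) * d + pull * pull_dir)
        d1 = _rot(base_dir, +phi * u)  # counter-clockwise child
        d2 = _rot(base_dir, -phi * (1.0 - u))
        w = rng.uniform(0.42, 0.58)
        gamma = max(spec.murray_exponent + rng.normal(0.0, spec.murray_noise), 1.5)
        c1, c2 = child_slots[slot]
        # split the wedge in proportion to the leaf counts below each child;
        # the counter-clockwise child takes the upper (larger-angle) part
        lo, hi = wedge
        f1 = n_leaves[c1] / (n_leaves[c1] + n_leaves[c2])
        cut = hi - f1 * (hi - lo)
        queue.append(
            (c1, cid, node_pos, d1, t_here * w ** (1.0 / gamma), depth + 1, _STRAIGHT_LEADIN_CM, (cut, hi))
        )
        queue.append(
            (c2, cid, node_pos, d2, t_here * (1.0 - w) ** (1.0 / gamma), depth + 1, _STRAIGHT_LEADIN_CM, (lo, cut))
        )

    return _finalize(spec, nodes, segments, planted_angles, planted_excess, fallback_count[0])


def _ray_circle(p: np.ndarray, d: np.ndarray, r: float) -> Optional[float]:
    """Smallest positive t with |p + t d| = r (d unit)."""
    b = float(np.dot(p, d))
    c = float(np.dot(p, p)) - r * r
    disc = b * b - c
    if disc < 0:
        return None
    t = -b + np.sqrt(disc)
    return t if t > 0 else None


def _finalize(
    spec: TreeSpec,
    nodes: List[GTNode],
    segments: List[GTSegment],
    planted_angles: List[float],
    planted_excess: List[float],
    n_fallback: int = 0,
) -> GroundTruth:
    """Clamp/rescale thicknesses and assemble the ground-truth record."""
    for s in segments:
        s.thickness_cm = max(s.thickness_cm, _MIN_THICKNESS_CM)
    if spec.mean_thickness_cm is not None and segments:
        cur = float(np.mean([s.thickness_cm for s in segments]))
        c = spec.mean_thickness_cm / cur
        for s in segments:
            s.thickness_cm = max(s.thickness_cm * c, _MIN_THICKNESS_CM)

    x = sum(1 for n in nodes if n.kind == "end")
    y = sum(1 for n in nodes if n.kind == "branch")
    torts = np.array([s.tortuosity for s in segments]) if segments else np.array([])
    thick = np.array([s.thickness_cm for s in segments]) if segments else np.array([])
    R = spec.disc_radius_cm
    end_d = [R - float(np.hypot(*n.pos_cm)) for n in nodes if n.kind == "end"]
    branch_gens = [n.generation for n in nodes if n.kind == "branch"]
    truth_features = {
        "NumEndPoints": float(x),
        "NumBranchPoints": float(y),
        "MurrayBranchesUsed": float(max(y - 1, 0)),
        "NumGenerations": float(max(branch_gens) if branch_gens else 0),
        "MeanThickness": float(thick.mean()) if len(thick) else np.nan,
        "StdDevTortuosity": (
            float(np.sqrt(np.mean((torts - torts.mean()) ** 2))) if len(torts) else np.nan
        ),
        "MeanTortuosity": float(torts.mean()) if len(torts) else np.nan,
        "MeanAngle": float(np.mean(planted_angles)) if planted_angles else np.nan,
        "MeanDistEndPointToPerim": float(np.mean(end_d)) if end_d else np.nan,
        "ArcLength": float(sum(s.arc_cm for s in segments)),
    }
    return GroundTruth(
        nodes=nodes,
        segments=segments,
        disc_radius_cm=R,
        true_counts=(x, y),
        true_feature_values=truth_features,
        n_fallback=n_fallback,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(
    truth: GroundTruth,
    canvas: Tuple[int, int] = (1380, 1440),
    scale: float = 35.0,
) -> Tuple[np.ndarray, np.ndarray, Tuple[int, int]]:
    """Stamp a ground-truth tree onto the study raster.

    Returns ``(vessel_mask, disc_mask, cord_xy)`` with the cord insertion at
    the canvas center.  Strokes are drawn as bands of half-width
    ``thickness * scale / 2`` around each polyline, so the expected drawn
    width equals ``thickness * scale`` px.  A tree whose ink would leave the
    canvas raises ``ValueError``.
    """
    h, w = int(canvas[0]), int(canvas[1])
    cord = (h // 2, w // 2)
    center = np.array([cord[0], cord[1]], dtype=float)

    rr, cc = np.ogrid[:h, :w]
    disc_r_px = truth.disc_radius_cm * scale
    disc_mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= disc_r_px**2

    vessel = np.zeros((h, w), dtype=bool)
    for s in truth.segments:
        # cm (x, y) -> px (row, col); y maps to rows, x to cols
        pts = np.column_stack(
            [center[0] + s.polyline_cm[:, 1] * scale, center[1] + s.polyline_cm[:, 0] * scale]
        )
        r_half = s.thickness_cm * scale / 2.0
        if (
            pts[:, 0].min() < r_half
            or pts[:, 1].min() < r_half
            or pts[:, 0].max() > h - 1 - r_half
            or pts[:, 1].max() > w - 1 - r_half
        ):
            raise ValueError("tree exceeds the canvas; enlarge canvas or shrink the disc")
        _stamp_band(vessel, pts, r_half, scale)
    return vessel, disc_mask, cord


def _stamp_band(canvas: np.ndarray, pts: np.ndarray, r_half: float, scale: float) -> None:
    """Set pixels whose centers lie within r_half of the densified polyline."""
    # resample the polyline at ~0.35 px spacing
    d = np.diff(pts, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    arc = steps.sum()
    if arc == 0:
        return
    n = max(int(arc / 0.35), 2)
    t = np.concatenate([[0.0], np.cumsum(steps)]) / arc
    u = np.linspace(0.0, 1.0, n)
    dense = np.column_stack([np.interp(u, t, pts[:, 0]), np.interp(u, t, pts[:, 1])])

    r0 = max(int(np.floor(dense[:, 0].min() - r_half - 1)), 0)
    r1 = min(int(np.ceil(dense[:, 0].max() + r_half + 1)), canvas.shape[0] - 1)
    c0 = max(int(np.floor(dense[:, 1].min() - r_half - 1)), 0)
    c1 = min(int(np.ceil(dense[:, 1].max() + r_half + 1)), canvas.shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return
    grid_r, grid_c = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    pix = np.column_stack([grid_r.ravel(), grid_c.ravel()]).astype(float)
    tree = cKDTree(dense)
    dist, _ = tree.query(pix, distance_upper_bound=r_half + 1e-9)
    hit = np.isfinite(dist)
    sub = canvas[r0 : r1 + 1, c0 : c1 + 1]
    sub |= hit.reshape(grid_r.shape)
    canvas[r0 : r1 + 1, c0 : c1 + 1] = sub


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


@dataclass
class PlacentaSample:
    vessel_mask: np.ndarray
    disc_mask: np.ndarray
    cord_xy: Tuple[int, int]
    truth: GroundTruth
    label: str
    scale: float


def cohort_tree_spec(
    cohort: str, rng: np.random.Generator, disc_radius_cm: Optional[float] = None
) -> TreeSpec:
    """Draw one placenta's TreeSpec from the calibrated cohort distributions."""
    key = cohort.lower()
    if key not in COHORT_TARGETS:
        raise ValueError(f"unknown cohort {cohort!r}; expected 'earli' or 'ncs'")
    tgt = COHORT_TARGETS[key]
    off = CALIBRATION_OFFSETS[key]

    def plant(name: str) -> Tuple[float, float]:
        mean, sd = tgt[name]
        return mean - off[name], sd

    R = disc_radius_cm if disc_radius_cm is not None else float(np.clip(rng.normal(9.5, 0.5), 8.4, 10.6))

    y_mean, y_sd = plant("NumBranchPoints")
    t_mean, t_sd = plant("MeanThickness")
    tor_mean, tor_sd = plant("StdDevTortuosity")
    d_mean, d_sd = plant("MeanDistEndPointToPerim")
    a_mean, a_sd = plant("MeanAngle")

    y_i = max(3.0, rng.normal(y_mean, y_sd))
    thick_i = float(np.clip(rng.normal(t_mean, t_sd), 0.085, 0.30))
    spread_i = float(np.clip(rng.normal(tor_mean, tor_sd), 0.006, 0.25))
    dist_i = float(np.clip(rng.normal(d_mean, d_sd), 0.9, R - 1.2))
    # between-placenta spread of the planted mean angle; the within-tree
    # angle noise and pixel quantization add the rest of the published SD
    a_between = max(a_sd**2 - 1.6**2, 0.5) ** 0.5
    angle_i = float(np.clip(rng.normal(a_mean, a_between), 70.0, 150.0))

    # leaf stop distance compensating the root end point sitting at depth R
    n_leaves = y_i + 1.0
    tip_margin = ((y_i + 2.0) * dist_i - R) / n_leaves
    tip_margin = float(np.clip(tip_margin, 0.7, R - 1.2))

    return TreeSpec(
        disc_radius_cm=R,
        mean_branch_points=y_i,
        sd_branch_points=0.0,
        tortuosity_amplitude=max(0.085, 1.4 * spread_i),
        tortuosity_spread=spread_i,
        # root caliber chosen so the post-hoc rescale to the planted mean is
        # ~1, keeping collision clearances honest during growth
        root_thickness_cm=float(np.clip(thick_i / 0.52, 0.15, 0.45)),
        mean_thickness_cm=thick_i,
        branch_angle_deg=angle_i,
        branch_angle_sd=5.0,
        tip_margin_cm=tip_margin,
        tip_margin_sd_cm=0.35,
    )


def sample_cohort(
    earli_like: bool,
    n: int,
    seed: Optional[int] = None,
    scale: float = 35.0,
    canvas: Tuple[int, int] = (1380, 1440),
    raster: bool = True,
) -> List[PlacentaSample]:
    """Simulate a cohort of placentas with cohort-calibrated parameters.

    ``earli_like=True`` draws from the high-risk enriched cohort
    distributions, else from the population-based ones.  With
    ``raster=False`` only the geometric ground truth is generated (masks are
    ``None``), which is much faster.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = "earli" if earli_like else "ncs"
    label = "high_risk" if earli_like else "low_risk"
    out: List[PlacentaSample] = []
    for _ in range(n):
        for _retry in range(6):
            spec = cohort_tree_spec(cohort, rng)
            try:
                truth = sample_tree(spec, rng)
                break
            except ValueError:
                continue
        else:
            raise ValueError(f"failed to grow a {cohort} tree after 6 attempts")
        if raster:
            vessel, disc, cord = rasterize(truth, canvas=canvas, scale=scale)
        else:
            vessel, disc, cord = None, None, (canvas[0] // 2, canvas[1] // 2)
        out.append(
            PlacentaSample(
                vessel_mask=vessel,
                disc_mask=disc,
                cord_xy=cord,
                truth=truth,
                label=label,
                scale=scale,
            )
        )
    return out


# ---------------------------------------------------------------------------
# fast path: feature tables without images
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Distributional description of a two-cohort feature table.

    ``feature_stats`` maps feature name -> ((mean, sd) high_risk,
    (mean, sd) low_risk).  Noise features are standard normal in both
    cohorts.  ``correlated`` plants an equicorrelation of 0.3 among the
    informative columns within each cohort.
    """

    feature_stats: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = field(
        default_factory=lambda: {
            name: (COHORT_TARGETS["earli"][name], COHORT_TARGETS["ncs"][name])
            for name in COHORT_TARGETS["earli"]
        }
    )
    n_per_cohort: Tuple[int, int] = (89, 201)
    n_noise_features: int = 0
    correlated: bool = False
    seed: Optional[int] = None
    labels: Tuple[str, str] = ("high_risk", "low_risk")

    def __post_init__(self) -> None:
        for (m1, s1), (m2, s2) in self.feature_stats.values():
            if s1 < 0 or s2 < 0:
                raise ValueError("feature SDs must be >= 0")
        if self.n_per_cohort[0] <= 0 or self.n_per_cohort[1] <= 0:
            raise ValueError("n_per_cohort entries must be positive")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")


def sample_feature_table(spec: CohortSpec):
    """Draw a labeled feature table from a :class:`CohortSpec`.

    Returns a pandas DataFrame with one row per placenta, a ``cohort``
    label column, and ``df.attrs['informative']`` listing the columns whose
    cohort means differ.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    names = list(spec.feature_stats)
    k = len(names)
    rows = []
    labels = []
    for which, n in zip((0, 1), spec.n_per_cohort):
        means = np.array([spec.feature_stats[f][which][0] for f in names])
        sds = np.array([spec.feature_stats[f][which][1] for f in names])
        if spec.correlated and k > 1:
            rho = 0.3
            cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
            z = rng.multivariate_normal(np.zeros(k), cov, size=n)
        else:
            z = rng.normal(size=(n, k))
        block = means[None, :] + z * sds[None, :]
        noise = rng.normal(size=(n, spec.n_noise_features))
        rows.append(np.hstack([block, noise]))
        labels.extend([spec.labels[which]] * n)
    cols = names + [f"Noise{i+1:02d}" for i in range(spec.n_noise_features)]
    df = pd.DataFrame(np.vstack(rows), columns=cols)
    df["cohort"] = labels
    informative = [
        f
        for f in names
        if spec.feature_stats[f][0][0] != spec.feature_stats[f][1][0]
    ]
    df.attrs["informative"] = informative
    df.attrs["label_col"] = "cohort"
    return df
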