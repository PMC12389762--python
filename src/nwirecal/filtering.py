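"""N-wire structural-prior filtering and per-frame feature assembly.

Candidate blobs are grouped into wire-layer triplets using three
geometric regularities of the phantom's image:

* *intra-layer collinearity* — the three crossings of one layer lie on
  a nearly horizontal line (slopes ``|k1|, |k2| < eps``),
* *inter-layer parallelism* — layer lines share a common main slope,
  found with a sliding window over the sorted triplet slopes,
* *distance consistency* — point spacings are uniform within a layer
  and between adjacent layers (tolerance ``diff`` pixels).

Retained points are re-centred on the brightest 8-neighbourhood mean
inside a search window, and triplets are assigned to phantom layers
top-to-bottom with A/B/C labels left-to-right.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .detect import CandidatePoint, DetectionParams, detect_candidates
from .exceptions import InsufficientStructureError

__all__ = [
    "FilterParams",
    "Triplet",
    "FrameDetection",
    "collinear_triplets",
    "main_slope",
    "filter_parallel",
    "filter_spacing",
    "resolve_conflicts",
    "refine_center",
    "assign_layers_and_labels",
    "detect_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Structural-prior thresholds.

    ``eps_collinear`` and ``eps_parallel`` are slope tolerances (0.05);
    ``window_w`` equals the number of wire layers; ``diff_px`` is the
    distance-consistency tolerance (10 px); ``refine_radius`` the centre
    search radius (30 px); ``match_tol`` (5 px) is used by evaluation
    only. ``ref_slope`` offsets the collinearity test for rotated
    acquisitions (default 0: wires run along image rows).
    """

    eps_collinear: float = 0.05
    eps_parallel: float = 0.05
    window_w: int = 3
    diff_px: float = 10.0
    refine_radius: int = 30
    match_tol: float = 5.0
    ref_slope: float = 0.0
    use_spacing: bool = True  # ablation switch for the spacing stage

    def __post_init__(self) -> None:
        if min(self.eps_collinear, self.eps_parallel, self.diff_px, self.refine_radius, self.match_tol) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")


@dataclass(frozen=True)
class Triplet:
    """Three candidate points ordered by increasing u, with the fitted
    line slope and (once assigned) the phantom layer index."""

    points: tuple[CandidatePoint, CandidatePoint, CandidatePoint]
    slope: float
    layer_index: int | None = None

    def __post_init__(self) -> None:
        us = [p.u for p in self.points]
        if len({(p.u, p.v) for p in self.points}) != 3:
            raise ValueError("triplet points must be distinct")
        if sorted(us) != us:
            raise ValueError("triplet points must be ordered by increasing u")

    @property
    def pixels(self) -> np.ndarray:
        return np.array([[p.u, p.v] for p in self.points], dtype=float)

    @property
    def response_sum(self) -> float:
        return float(sum(p.response for p in self.points))

    @property
    def mean_v(self) -> float:
        return float(np.mean([p.v for p in self.points]))

    @property
    def middle(self) -> CandidatePoint:
        return self.points[1]


@dataclass(frozen=True)
class FrameDetection:
    """Per-frame result: at most one labeled triplet per phantom layer
    plus the main slope of the frame."""

    frame_index: int
    triplets: tuple[Triplet, ...]
    k_main: float = float("nan")
    flip_horizontal: bool = False

    @property
    def n_layers_detected(self) -> int:
        return len(self.triplets)

    def labeled_points(self) -> list[tuple[int, str, float, float]]:
        """Flat list of (layer_index, label, u, v); labels A/B/C run
        left-to-right, or right-to-left when flip_horizontal is set."""
        out = []
        labels = ("C", "B", "A") if self.flip_horizontal else ("A", "B", "C")
        for t in self.triplets:
            for lab, p in zip(labels, t.points):
                out.append((t.layer_index, lab, float(p.u), float(p.v)))
        return out

    def triplet_for_layer(self, layer_index: int) -> Triplet | None:
        for t in self.triplets:
            if t.layer_index == layer_index:
                return t
        return None


def _slope(p: CandidatePoint, q: CandidatePoint) -> float | None:
    du = q.u - p.u
    if du == 0:
        return None  # vertical pair fails the near-horizontal prior
    return (q.v - p.v) / du


def collinear_triplets(
    candidates: list[CandidatePoint],
    eps_collinear: float = 0.05,
    ref_slope: float = 0.0,
) -> list[Triplet]:
    """Enumerate u-ordered candidate triplets and retain those whose
    middle-to-neighbour slopes both satisfy ``|k - ref_slope| < eps``.

    The stored slope is the mean of the two segment slopes.
    """
    pts = sorted(candidates, key=lambda p: (p.u, p.v))
    n = len(pts)
    # adjacency of near-horizontal ordered pairs keeps enumeration cheap
    ok = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            k = _slope(pts[i], pts[j])
            if k is not None and abs(k - ref_slope) < eps_collinear:
                ok[i][j] = True
    out: list[Triplet] = []
    for left, mid, right in itertools.combinations(range(n), 3):
        if ok[left][mid] and ok[mid][right]:
            k1 = _slope(pts[mid], pts[left])
            k2 = _slope(pts[mid], pts[right])
            out.append(Triplet((pts[left], pts[mid], pts[right]), slope=(k1 + k2) / 2.0))
    return out


def main_slope(triplets: list[Triplet], window_w: int) -> float:
    """Main phantom slope via the sliding window with smallest spread.

    Slopes are sorted into a sequence S; the window of size ``window_w``
    minimising ``S[i+W-1] - S[i]`` is selected (first index on ties) and
    its mean slope returned.
    """
    if len(triplets) < window_w:
        raise InsufficientStructureError(
            f"need at least {window_w} collinear triplets, got {len(triplets)}"
        )
    s = np.sort(np.array([t.slope for t in triplets]))
    spreads = s[window_w - 1 :] - s[: len(s) - window_w + 1]
    i = int(np.argmin(spreads))  # argmin returns the first minimiser
    return float(np.mean(s[i : i + window_w]))


def filter_parallel(triplets: list[Triplet], k_main: float, eps_parallel: float = 0.05) -> list[Triplet]:
    """Keep triplets whose slope differs from the main slope by less
    than ``eps_parallel``."""
    return [t for t in triplets if abs(t.slope - k_main) < eps_parallel]


def _intra_ok(t: Triplet, diff_px: float) -> bool:
    p = t.pixels
    d12 = np.linalg.norm(p[1] - p[0])
    d23 = np.linalg.norm(p[2] - p[1])
    return abs(d12 - d23) <= diff_px


def _inter_violations(rows: list[Triplet], diff_px: float) -> list[tuple[int, int, int]]:
    """Indices of consecutive row triples whose B-to-B gaps differ by
    more than ``diff_px``."""
    bad = []
    for i in range(len(rows) - 2):
        g1 = np.linalg.norm(rows[i + 1].middle.pixel - rows[i].middle.pixel)
        g2 = np.linalg.norm(rows[i + 2].middle.pixel - rows[i + 1].middle.pixel)
        if abs(g1 - g2) > diff_px:
            bad.append((i, i + 1, i + 2))
    return bad


def resolve_conflicts(triplets: list[Triplet]) -> list[Triplet]:
    """Greedy candidate-sharing resolution: triplets are taken in order
    of descending summed response; one that reuses an already-claimed
    candidate is dropped. Run before the spacing stage so overlapping
    triplets cannot masquerade as multiple rows at one height."""
    chosen: list[Triplet] = []
    used: set[tuple[float, float]] = set()
    for t in sorted(triplets, key=lambda t: -t.response_sum):
        keys = {(p.u, p.v) for p in t.points}
        if keys & used:
            continue
        chosen.append(t)
        used |= keys
    return chosen


def filter_spacing(triplets: list[Triplet], diff_px: float = 10.0) -> list[Triplet]:
    """Distance-consistency filtering.

    Intra-layer rule: the two point gaps of a triplet may differ by at
    most ``diff`` px. Inter-layer rule: B-to-B gaps of vertically
    adjacent rows must be consistent to within ``diff`` px. When an
    inter-layer violation implicates three rows, the row whose removal
    minimises the remaining violations is dropped (ties: lowest summed
    response).
    """
    kept = [t for t in triplets if _intra_ok(t, diff_px)]
    rows = sorted(kept, key=lambda t: t.mean_v)
    for _ in range(len(rows)):
        viol = _inter_violations(rows, diff_px)
        if not viol:
            break
        involved = sorted({i for tri in viol for i in tri})
        best_rows, best_score = None, None
        for i in involved:
            trial = rows[:i] + rows[i + 1 :]
            score = (len(_inter_violations(trial, diff_px)), rows[i].response_sum)
            if best_score is None or score < best_score:
                best_score, best_rows = score, trial
        rows = best_rows
    return rows


def refine_center(image, point, refine_radius: int = 30) -> tuple[int, int]:
    """Re-centre a point on the pixel whose 8-connected neighbourhood has
    the highest mean intensity inside a ``(2r+1)^2`` window (clipped to
    the image); ties break in row-major order. Returns integer (u, v).
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    u0, v0 = int(round(point[0])), int(round(point[1]))
    r = int(refine_radius)
    c0, c1 = max(u0 - r, 0), min(u0 + r, w - 1)
    r0, r1 = max(v0 - r, 0), min(v0 + r, h - 1)
    if c0 > c1 or r0 > r1:
        raise ValueError("refinement window lies outside the image")
    # mean of the 8 neighbours = (3x3 sum - centre) / 8
    sum3 = ndimage.uniform_filter(img, size=3, mode="reflect") * 9.0
    nmean = (sum3 - img) / 8.0
    window = nmean[r0 : r1 + 1, c0 : c1 + 1]
    flat = int(np.argmax(window))  # first occurrence in row-major order
    dv, du = divmod(flat, window.shape[1])
    return (c0 + du, r0 + dv)


def assign_layers_and_labels(
    triplets: list[Triplet],
    n_layers: int,
    flip_horizontal: bool = False,
    frame_index: int = 0,
    k_main: float = float("nan"),
) -> FrameDetection:
    """Assign surviving triplets to phantom layers.

    Candidate-sharing conflicts are resolved greedily by descending
    summed response; if more triplets than layers survive, the strongest
    ``n_layers`` are kept. Rows are ordered by mean v (image top row
    maps to the layer nearest the probe) and labeled A/B/C by increasing
    u (decreasing when ``flip_horizontal``).
    """
    chosen = sorted(resolve_conflicts(triplets), key=lambda t: -t.response_sum)[:n_layers]
    chosen = sorted(chosen, key=lambda t: t.mean_v)
    assigned = tuple(replace(t, layer_index=i) for i, t in enumerate(chosen))
    return FrameDetection(frame_index, assigned, k_main=k_main, flip_horizontal=flip_horizontal)


def detect_frame(
    image,
    det_params: DetectionParams | None = None,
    filt_params: FilterParams | None = None,
    n_layers: int = 3,
    frame_index: int = 0,
    flip_horizontal: bool = False,
) -> FrameDetection:
    """Full per-frame pipeline: candidates -> collinearity -> main slope
    -> parallelism -> spacing -> centre refinement -> layer assignment.

    A frame with too little structure yields an empty detection (logged)
    rather than an error; the solver simply skips it.
    """
    det_params = det_params or DetectionParams()
    filt_params = filt_params or FilterParams()
    candidates = detect_candidates(image, det_params)
    triplets = collinear_triplets(candidates, filt_params.eps_collinear, filt_params.ref_slope)
    try:
        k_main = main_slope(triplets, filt_params.window_w)
    except InsufficientStructureError as exc:
        logger.warning("frame %d: %s", frame_index, exc)
        return FrameDetection(frame_index, (), flip_horizontal=flip_horizontal)
    triplets = filter_parallel(triplets, k_main, filt_params.eps_parallel)
    triplets = resolve_conflicts(triplets)
    if filt_params.use_spacing:
        triplets = filter_spacing(triplets, filt_params.diff_px)
    refined: list[Triplet] = []
    for t in triplets:
        pts = []
        for p in t.points:
            u, v = refine_center(image, (p.u, p.v), filt_params.refine_radius)
            pts.append(CandidatePoint(u=u, v=v, response=p.response, scale=p.scale))
        pts.sort(key=lambda p: (p.u, p.v))
        if len({(p.u, p.v) for p in pts}) != 3:
            continue  # refinement collapsed two points onto one pixel
        refined.append(Triplet(tuple(pts), slope=t.slope))
    return assign_layers_and_labels(
        refined, n_layers, flip_horizontal=flip_horizontal, frame_index=frame_index, k_main=k_main
    )
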