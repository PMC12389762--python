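"""Shape-prior candidate detection.

Wire cross-sections appear as bright blob-like spots under the beam's
point spread function. Candidates are found by a three-stage cascade:

1. a *directional top-hat* (image minus the pixel-wise maximum of
   morphological openings with thin line elements at several angles)
   removes elongated echo artifacts and large background structures,
2. a *scale-normalized multi-scale Hessian determinant* responds to
   blob-like structure independently of its apparent size, so the same
   detector works across imaging depths,
3. a relative threshold (``delta = delta_frac * max(response)``) and
   8-connected non-maximum suppression yield the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "ResponseMap",
    "CandidatePoint",
    "directional_top_hat",
    "hessian_det_response",
    "fuse_and_threshold",
    "extract_candidates",
    "detect_candidates",
]

DEFAULT_SCALES = (1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0)
DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the candidate detector.

    ``scales`` spans the apparent blob sizes seen at 5-12 cm imaging
    depths; ``se_length`` (21 px) is longer than any expected blob but
    shorter than typical artifacts; ``delta_frac`` is the relative
    response threshold (0.04)."""

    se_length: int = 21
    se_angles: tuple[float, ...] = DEFAULT_ANGLES
    scales: tuple[float, ...] = DEFAULT_SCALES
    delta_frac: float = 0.04
    max_candidates: int = 60

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or min(self.scales) <= 0:
            raise ValueError("scales must be non-empty and strictly positive")
        if not (0.0 < self.delta_frac < 1.0):
            raise ValueError("delta_frac must lie in (0, 1)")
        if self.se_length < 3:
            raise ValueError("se_length must be at least 3 px")


@dataclass(frozen=True)
class ResponseMap:
    """Fused multi-scale response Lambda and the per-pixel best scale
    (0 where the response is below threshold)."""

    values: np.ndarray
    best_scale: np.ndarray


@dataclass(frozen=True, order=True)
class CandidatePoint:
    """A candidate blob centre: integer pixel (u, v), fused response and
    the scale at which the response peaked."""

    u: int = field(compare=False)
    v: int = field(compare=False)
    response: float = field(compare=True)
    scale: float = field(compare=False)

    @property
    def pixel(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """A 1-px-wide line structuring element of the given length/angle."""
    ang = np.deg2rad(angle_deg % 180.0)
    half = (length - 1) / 2.0
    dr, dc = -np.sin(ang), np.cos(ang)  # rows grow downward
    r1, c1 = int(round(half * dr)), int(round(half * dc))
    r0, c0 = -r1, -c1
    n_rows = abs(r1 - r0) + 1
    n_cols = abs(c1 - c0) + 1
    fp = np.zeros((n_rows, n_cols), dtype=bool)
    # Bresenham-style rasterisation of the centred segment
    n_steps = max(n_rows, n_cols)
    rr = np.rint(np.linspace(0, r1 - r0, n_steps)).astype(int)
    cc = np.rint(np.linspace(0, c1 - c0, n_steps)).astype(int)
    fp[rr, cc] = True
    return fp


def directional_top_hat(image, se_length: int = 21, se_angles=DEFAULT_ANGLES) -> np.ndarray:
    """Directional white top-hat: ``image - B`` where B is the pixel-wise
    maximum of grey openings with line elements at each angle.

    Any structure elongated along at least one tested direction is
    treated as background and removed; compact blobs survive.
    """
    if se_length < 3:
        raise ValueError("se_length must be at least 3 px")
    img = np.asarray(image, dtype=float)
    background = None
    for ang in se_angles:
        a = ang % 180.0
        if a in (0.0, 90.0):
            size = (1, se_length) if a == 0.0 else (se_length, 1)
            opened = ndimage.grey_opening(img, size=size, mode="reflect")
        else:
            fp = _line_footprint(se_length, a)
            opened = ndimage.grey_opening(img, footprint=fp, mode="reflect")
        background = opened if background is None else np.maximum(background, opened)
    return np.clip(img - background, 0.0, None)


def _gaussian_derivative_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled Gaussian and its first/second derivatives with kernel
    half-width ceil(3 sigma). The second-derivative taps are re-centred
    to sum to zero so the operator annihilates constants (and, by
    symmetry, linear ramps) exactly."""
    r = int(np.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    g0 = np.exp(-(x**2) / (2.0 * sigma**2))
    g0 /= g0.sum()
    g1 = -x / sigma**2 * g0
    g2 = (x**2 - sigma**2) / sigma**4 * g0
    g2 -= g2.mean()
    return g0, g1, g2


def hessian_det_response(image, sigma: float) -> np.ndarray:
    """Scale-normalized Hessian determinant ``(Ixx*Iyy - Ixy^2) * sigma^4``.

    Second derivatives come from separable Gaussian-derivative
    convolution at scale ``sigma`` (kernel half-width ~3 sigma,
    reflective borders). Negative values (ridges, saddles) are retained
    at this stage.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(image, dtype=float)
    g0, g1, g2 = _gaussian_derivative_kernels(sigma)

    def sep(k_row, k_col):
        # axis 0 is rows (y = v), axis 1 is columns (x = u)
        out = ndimage.correlate1d(img, k_row, axis=0, mode="reflect")
        return ndimage.correlate1d(out, k_col, axis=1, mode="reflect")

    ixx = sep(g0, g2)
    iyy = sep(g2, g0)
    ixy = sep(g1, g1)
    return (ixx * iyy - ixy**2) * sigma**4


def fuse_and_threshold(responses, scales, delta_frac: float = 0.04) -> ResponseMap:
    """Per-pixel maximum across scales, then the relative threshold
    ``delta = delta_frac * max``: sub-threshold entries are zeroed, the
    rest keep their response value."""
    if len(responses) == 0:
        raise ValueError("need at least one per-scale response")
    if len(responses) != len(scales):
        raise ValueError("one scale per response required")
    stack = np.stack([np.asarray(r, dtype=float) for r in responses])
    fused = stack.max(axis=0)
    best_idx = stack.argmax(axis=0)
    best_scale = np.asarray(scales, dtype=float)[best_idx]
    peak = fused.max()
    if peak <= 0:
        z = np.zeros_like(fused)
        return ResponseMap(z, np.zeros_like(fused))
    delta = delta_frac * peak
    keep = fused >= delta
    return ResponseMap(np.where(keep, fused, 0.0), np.where(keep, best_scale, 0.0))


def extract_candidates(rmap: ResponseMap) -> list[CandidatePoint]:
    """8-connected non-maximum suppression on the fused response.

    A pixel qualifies when its value is positive and strictly greater
    than every 8-neighbour; on equal-valued plateaus that beat all outer
    neighbours, the first pixel in row-major order is emitted. Sorted by
    descending response.
    """
    lam = rmap.values
    if lam.max() <= 0:
        return []
    local_max = (lam >= ndimage.maximum_filter(lam, size=3, mode="constant")) & (lam > 0)
    labels, n = ndimage.label(local_max, structure=np.ones((3, 3), dtype=int))
    out: list[CandidatePoint] = []
    for idx in range(1, n + 1):
        mask = labels == idx
        rows, cols = np.nonzero(mask)
        value = lam[rows[0], cols[0]]
        # reject plateaus that touch an equal-or-greater outside pixel
        ring = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool)) & ~mask
        if ring.any() and lam[ring].max() >= value:
            continue
        r, c = int(rows[0]), int(cols[0])  # row-major tie-break
        out.append(CandidatePoint(u=c, v=r, response=float(value), scale=float(rmap.best_scale[r, c])))
    out.sort(key=lambda p: -p.response)
    return out


def detect_candidates(image, params: DetectionParams | None = None) -> list[CandidatePoint]:
    """Full candidate detection: top-hat -> per-scale Hessian ->
    fuse/threshold -> non-maximum suppression (top ``max_candidates``)."""
    params = params or DetectionParams()
    filtered = directional_top_hat(image, params.se_length, params.se_angles)
    responses = [hessian_det_response(filtered, s) for s in params.scales]
    rmap = fuse_and_threshold(responses, params.scales, params.delta_frac)
    cands = extract_candidates(rmap)
    return cands[: params.max_candidates]
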