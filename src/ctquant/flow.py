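"""Dense two-frame optical flow by local polynomial expansion (Farnebäck).

Each frame is approximated, pixel-wise, by a quadratic polynomial
``f(u) ≈ uᵀ A u + bᵀ u + c`` fitted by weighted least squares over a
``poly_n`` neighborhood with a Gaussian applicability of scale
``poly_sigma``. For a pure translation ``d`` of a quadratic patch the
coefficients of the two frames satisfy ``A d = -½ (b₂ - b₁)``; the
displacement field is obtained by solving that relation in a least-squares
sense over a ``winsize`` neighborhood, iterated with warping inside a
coarse-to-fine image pyramid.

Default parameters match the study configuration: pyramid scale 0.6, four
levels, window size 7, eight iterations per level, poly_n 5, poly_sigma 1.5.

Convention: ``dx`` is displacement along axis 1 (columns), ``dy`` along
axis 0 (rows); ``flow[y, x]`` is the motion of the pixel at (row y, col x)
from the first frame to the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FarnebackParams",
    "FlowField",
    "CumulativeFlow",
    "FlowSummary",
    "polynomial_expansion",
    "farneback_flow",
    "accumulate_flow",
    "summarize_flow",
]


@dataclass(frozen=True)
class FarnebackParams:
    pyr_scale: float = 0.6
    levels: int = 4
    winsize: int = 7
    iterations: int = 8
    poly_n: int = 5
    poly_sigma: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.pyr_scale < 1:
            raise ValueError("pyr_scale must be in (0, 1)")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.winsize % 2 == 0 or self.poly_n % 2 == 0:
            raise ValueError("winsize and poly_n must be odd")


@dataclass
class FlowField:
    dx: np.ndarray
    dy: np.ndarray
    pair: tuple[int, int] = (0, 1)
    confidence: np.ndarray | None = None  # False near borders

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


@dataclass
class CumulativeFlow:
    cum_x: np.ndarray
    cum_y: np.ndarray
    frame_range: tuple[int, int]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.cum_x, self.cum_y)


@dataclass
class FlowSummary:
    max_px: float
    max_cm: float
    background_median_px: float
    quiver_x: np.ndarray  # strided positions (cols)
    quiver_y: np.ndarray
    quiver_u: np.ndarray  # strided vectors
    quiver_v: np.ndarray


def _poly_basis(poly_n: int, poly_sigma: float):
    """Inverse normal matrix and separable applicability for the LS fit."""
    r = (poly_n - 1) // 2
    u = np.arange(-r, r + 1, dtype=float)
    a = np.exp(-(u**2) / (2.0 * poly_sigma**2))
    # basis order: 1, x, y, x^2, y^2, xy   (x = cols, y = rows)
    X, Y = np.meshgrid(u, u)  # X varies along cols, Y along rows
    W = np.outer(a, a)
    phis = [np.ones_like(X), X, Y, X**2, Y**2, X * Y]
    G = np.empty((6, 6))
    for i in range(6):
        for j in range(6):
            G[i, j] = np.sum(W * phis[i] * phis[j])
    return np.linalg.inv(G), u, a


def polynomial_expansion(
    frame: np.ndarray,
    poly_n: int = 5,
    poly_sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel quadratic coefficients (A, b, c) of the local intensity.

    Returns ``A`` with shape (H, W, 2, 2) ordered (x, y), ``b`` with shape
    (H, W, 2) and ``c`` with shape (H, W). Computed by separable weighted
    correlations with reflective boundary handling.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D grayscale")
    if min(frame.shape) < poly_n:
        raise ValueError("frame smaller than the polynomial neighborhood")
    Ginv, u, a = _poly_basis(poly_n, poly_sigma)

    kern = {
        "1": a,
        "x": a * u,
        "x2": a * u**2,
    }

    def corr(img, krow, kcol):
        # krow applies along axis 0 (y), kcol along axis 1 (x)
        tmp = ndimage.correlate1d(img, kcol, axis=1, mode="reflect")
        return ndimage.correlate1d(tmp, krow, axis=0, mode="reflect")

    p = np.stack(
        [
            corr(frame, kern["1"], kern["1"]),   # 1
            corr(frame, kern["1"], kern["x"]),   # x
            corr(frame, kern["x"], kern["1"]),   # y
            corr(frame, kern["1"], kern["x2"]),  # x^2
            corr(frame, kern["x2"], kern["1"]),  # y^2
            corr(frame, kern["x"], kern["x"]),   # xy
        ],
        axis=-1,
    )
    coef = p @ Ginv.T  # (H, W, 6): c, bx, by, axx, ayy, axy
    c = coef[..., 0]
    b = coef[..., 1:3]
    A = np.empty(frame.shape + (2, 2))
    A[..., 0, 0] = coef[..., 3]
    A[..., 1, 1] = coef[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * coef[..., 5]
    return A, b, c


def _pyramid(frame: np.ndarray, params: FarnebackParams) -> list[np.ndarray]:
    levels = [np.asarray(frame, dtype=float)]
    for _ in range(params.levels - 1):
        prev = levels[-1]
        if min(prev.shape) * params.pyr_scale < params.poly_n + 2:
            break
        sigma = 0.5 / params.pyr_scale  # anti-aliasing before resampling
        smoothed = ndimage.gaussian_filter(prev, sigma, mode="reflect")
        levels.append(ndimage.zoom(smoothed, params.pyr_scale, order=1, mode="reflect", grid_mode=True))
    return levels[::-1]  # coarsest first


def _sample(fieldlist, yy, xx):
    return [
        ndimage.map_coordinates(f, [yy, xx], order=1, mode="nearest")
        for f in fieldlist
    ]


def _flow_at_level(f1, f2, d0x, d0y, params: FarnebackParams):
    A1, b1, _ = polynomial_expansion(f1, params.poly_n, params.poly_sigma)
    A2, b2, _ = polynomial_expansion(f2, params.poly_n, params.poly_sigma)
    H, W = f1.shape
    yy0, xx0 = np.mgrid[0:H, 0:W].astype(float)
    dx, dy = d0x.copy(), d0y.copy()
    for _ in range(params.iterations):
        yy = np.clip(yy0 + dy, 0, H - 1)
        xx = np.clip(xx0 + dx, 0, W - 1)
        A2w = _sample([A2[..., 0, 0], A2[..., 0, 1], A2[..., 1, 1]], yy, xx)
        b2w = _sample([b2[..., 0], b2[..., 1]], yy, xx)
        Axx = 0.5 * (A1[..., 0, 0] + A2w[0])
        Axy = 0.5 * (A1[..., 0, 1] + A2w[1])
        Ayy = 0.5 * (A1[..., 1, 1] + A2w[2])
        dbx = -0.5 * (b2w[0] - b1[..., 0]) + Axx * dx + Axy * dy
        dby = -0.5 * (b2w[1] - b1[..., 1]) + Axy * dx + Ayy * dy
        # normal equations of A d = db, averaged over the window
        G11 = Axx * Axx + Axy * Axy
        G12 = Axx * Axy + Axy * Ayy
        G22 = Axy * Axy + Ayy * Ayy
        h1 = Axx * dbx + Axy * dby
        h2 = Axy * dbx + Ayy * dby
        blur = lambda z: ndimage.uniform_filter(z, size=params.winsize, mode="reflect")
        G11, G12, G22, h1, h2 = map(blur, (G11, G12, G22, h1, h2))
        # Tikhonov term relative to the trace: keeps low-contrast regions
        # solvable (their normal equations are small but well conditioned)
        # while flat regions fall back to zero displacement
        lam = 1e-6 * (G11 + G22) + 1e-30
        G11 = G11 + lam
        G22 = G22 + lam
        det = G11 * G22 - G12 * G12
        dx = (G22 * h1 - G12 * h2) / det
        dy = (G11 * h2 - G12 * h1) / det
    return dx, dy


def farneback_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    params: FarnebackParams | None = None,
    pair: tuple[int, int] = (0, 1),
) -> FlowField:
    """Dense displacement field carrying frame_a onto frame_b."""
    params = params or FarnebackParams()
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frame size mismatch")
    pyr_a = _pyramid(a, params)
    pyr_b = _pyramid(b, params)
    dx = np.zeros_like(pyr_a[0])
    dy = np.zeros_like(pyr_a[0])
    for lvl, (fa, fb) in enumerate(zip(pyr_a, pyr_b)):
        if dx.shape != fa.shape:
            zy = fa.shape[0] / dx.shape[0]
            zx = fa.shape[1] / dx.shape[1]
            dx = ndimage.zoom(dx, (zy, zx), order=1, mode="nearest") * zx
            dy = ndimage.zoom(dy, (zy, zx), order=1, mode="nearest") * zy
        dx, dy = _flow_at_level(fa, fb, dx, dy, params)
    conf = np.zeros(a.shape, dtype=bool)
    m = params.poly_n
    conf[m:-m, m:-m] = True
    return FlowField(dx=dx, dy=dy, pair=pair, confidence=conf)


def accumulate_flow(flows: Sequence[FlowField]) -> CumulativeFlow:
    """Per-pixel running sum of incremental frame-to-frame flow.

    The sum is taken at fixed pixel locations (Eulerian accumulation): the
    cumulative arrays describe total displacement reported at each pixel,
    not trajectories of material points.
    """
    flows = list(flows)
    if not flows:
        raise ValueError("empty flow sequence")
    shape = flows[0].dx.shape
    if any(f.dx.shape != shape or f.dy.shape != shape for f in flows):
        raise ValueError("inhomogeneous flow dimensions")
    cum_x = np.sum([f.dx for f in flows], axis=0)
    cum_y = np.sum([f.dy for f in flows], axis=0)
    return CumulativeFlow(cum_x, cum_y, (flows[0].pair[0], flows[-1].pair[1]))


def summarize_flow(
    cum: CumulativeFlow,
    calibration: float = 465.0,
    stride: int = 20,
    background_mask: np.ndarray | None = None,
) -> FlowSummary:
    """Calibrated maxima, background level and strided quiver data.

    ``calibration`` is in px/cm. ``background_mask`` designates pixels
    assumed static (default: everything below the 90th magnitude
    percentile, a convention for the skin surrounding the moving
    instrument).
    """
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    mag = cum.magnitude()
    max_px = float(mag.max()) if mag.size else 0.0
    if background_mask is None:
        background_mask = mag <= np.percentile(mag, 90)
    bg = float(np.median(mag[background_mask])) if background_mask.any() else 0.0
    ys = np.arange(0, mag.shape[0], stride)
    xs = np.arange(0, mag.shape[1], stride)
    qy, qx = np.meshgrid(ys, xs, indexing="ij")
    return FlowSummary(
        max_px=max_px,
        max_cm=max_px / calibration,
        background_median_px=bg,
        quiver_x=qx,
        quiver_y=qy,
        quiver_u=cum.cum_x[qy, qx],
        quiver_v=cum.cum_y[qy, qx],
    )
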