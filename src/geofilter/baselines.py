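"""Comparator filters: anisotropic diffusion, bilateral, and robust LMS.

These are the classical edge-preserving methods the geodesic filter is
benchmarked against:

* gradient anisotropic diffusion (Perona-Malik): explicit Euler steps of
  ``dI/dt = div(g(|grad I|) grad I)`` with 4-neighbour fluxes;
* curvature anisotropic diffusion: level-set mean-curvature flow modulated
  by a decreasing conductance, ``dI/dt = g(kappa) |grad I| kappa`` with
  ``kappa = div(grad I / |grad I|)``;
* bilateral filtering: normalised product of spatial and range Gaussians;
* LMS filtering: per-window least-median-of-squares polynomial surface fit
  via RANSAC, outlier rejection at 2.5x the robust (MAD) scale, and a
  least-squares refit on the inliers; the window median is the fallback when
  too few inliers remain.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .grid import ImageGrid

__all__ = [
    "DiffusionParams",
    "BilateralParams",
    "LmsParams",
    "SingularFitError",
    "conductance",
    "gradient_anisotropic_diffusion",
    "curvature_anisotropic_diffusion",
    "bilateral_filter",
    "min_sample_size",
    "ransac_iterations",
    "fit_polynomial_window",
    "lms_ransac",
    "robust_threshold",
    "classify_inliers",
    "lms_filter",
    "LmsFit",
]

MAD_SCALE = 1.4826  # normal-consistency constant for the MAD scale estimate
INLIER_FACTOR = 2.5


# ---------------------------------------------------------------------------
# anisotropic diffusion


@dataclass(frozen=True)
class DiffusionParams:
    """Anisotropic-diffusion configuration.

    ``conductance`` is the gradient (or curvature) scale C of the edge-
    stopping function; ``iterations`` the number of explicit Euler steps;
    ``time_step`` the step size (<= 0.25 for 4-neighbour stability);
    ``form`` selects the exponential or rational conductance.
    """

    conductance: float = 10.0
    iterations: int = 5
    time_step: float = 0.25
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.conductance <= 0:
            raise ValueError(f"conductance must be > 0, got {self.conductance}")
        if self.iterations < 0:
            raise ValueError(f"iterations must be >= 0, got {self.iterations}")
        if not (0 < self.time_step <= 0.25):
            raise ValueError(f"time_step must be in (0, 0.25], got {self.time_step}")
        if self.form not in ("exponential", "rational"):
            raise ValueError(f"unknown conductance form {self.form!r}")


def conductance(s: float | np.ndarray, C: float, form: str = "exponential"):
    """Edge-stopping function g(s): exp(-s^2/C^2) or 1 / (1 + s^2/C^2)."""
    if C <= 0:
        raise ValueError(f"conductance scale must be > 0, got {C}")
    s2 = np.square(s) / (C * C)
    if form == "exponential":
        return np.exp(-s2)
    if form == "rational":
        return 1.0 / (1.0 + s2)
    raise ValueError(f"unknown conductance form {form!r}")


def _neighbor_differences(plane: np.ndarray):
    """4-neighbour differences with replicated (zero-flux) borders."""
    p = np.pad(plane, 1, mode="edge")
    north = p[:-2, 1:-1] - plane
    south = p[2:, 1:-1] - plane
    west = p[1:-1, :-2] - plane
    east = p[1:-1, 2:] - plane
    return north, south, west, east


def gradient_anisotropic_diffusion(image: ImageGrid, params: DiffusionParams) -> ImageGrid:
    """Perona-Malik diffusion, channels processed independently."""
    out = image.values.copy()
    for c in range(out.shape[2]):
        plane = out[:, :, c]
        for _ in range(params.iterations):
            flux = 0.0
            for d in _neighbor_differences(plane):
                flux = flux + conductance(np.abs(d), params.conductance, params.form) * d
            plane = plane + params.time_step * flux
        out[:, :, c] = plane
    return ImageGrid(out)


_CURVATURE_EPS = 1e-8


def curvature_anisotropic_diffusion(image: ImageGrid, params: DiffusionParams) -> ImageGrid:
    """Conductance-modulated mean-curvature flow.

    ``I += tau * g(|kappa|) * |grad I| * kappa`` with centred differences;
    the gradient magnitude in the normalisation is regularised by 1e-8.
    """
    out = image.values.copy()
    for c in range(out.shape[2]):
        plane = out[:, :, c]
        for _ in range(params.iterations):
            gx, gy = _centered_gradient(plane)
            mag = np.sqrt(gx * gx + gy * gy)
            safe = mag + _CURVATURE_EPS
            nx, ny = gx / safe, gy / safe
            kappa = _centered_gradient(nx)[0] + _centered_gradient(ny)[1]
            g = conductance(np.abs(kappa), params.conductance, params.form)
            plane = plane + params.time_step * g * mag * kappa
        out[:, :, c] = plane
    return ImageGrid(out)


def _centered_gradient(plane: np.ndarray):
    p = np.pad(plane, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return gx, gy


# ---------------------------------------------------------------------------
# bilateral


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral kernel side ``size`` (odd), spatial scale ``sigma_d``,
    signal scale ``sigma_c`` (both on the pixel / 0-255 scales)."""

    size: int = 5
    sigma_d: float = 2.0
    sigma_c: float = 30.0

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"kernel side must be odd >= 3, got {self.size}")
        if self.sigma_d <= 0 or self.sigma_c <= 0:
            raise ValueError("sigma_d and sigma_c must be positive")


def bilateral_filter(image: ImageGrid, params: BilateralParams) -> ImageGrid:
    """Normalised double-Gaussian weighted mean over the s x s neighbourhood.

    The range kernel uses the joint Euclidean signal difference across
    channels; windows are clipped at the image border (missing pixels simply
    carry zero weight).
    """
    h = params.size // 2
    vals = image.values
    padded = np.pad(vals, ((h, h), (h, h), (0, 0)), constant_values=np.nan)
    num = np.zeros_like(vals)
    den = np.zeros(vals.shape[:2])
    H, W = den.shape
    inv2sd = 1.0 / (2.0 * params.sigma_d**2)
    inv2sc = 1.0 / (2.0 * params.sigma_c**2)
    for dy in range(-h, h + 1):
        for dx in range(-h, h + 1):
            shifted = padded[h + dy : h + dy + H, h + dx : h + dx + W]
            diff = shifted - vals  # NaN where the window leaves the image
            diff2 = np.sum(diff * diff, axis=-1)
            w = np.exp(-(dx * dx + dy * dy) * inv2sd - diff2 * inv2sc)
            w = np.where(np.isfinite(diff2), w, 0.0)
            # accumulate deviations from the center pixel: constant images
            # stay exactly constant
            num += w[:, :, None] * np.nan_to_num(diff, nan=0.0)
            den += w
    return ImageGrid(vals + num / den[:, :, None])


# ---------------------------------------------------------------------------
# robust LMS surface filter


@dataclass(frozen=True)
class LmsParams:
    """LMS filter configuration: window side ``size``, polynomial ``degree``
    (1 or 2), RANSAC confidence ``confidence``, assumed outlier ratio
    ``outlier_ratio``, and the RNG ``seed`` driving minimal-sample draws."""

    size: int = 5
    degree: int = 1
    confidence: float = 0.99
    outlier_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"window side must be odd >= 3, got {self.size}")
        if self.degree not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {self.degree}")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")
        if not (0 < self.outlier_ratio < 1):
            raise ValueError("outlier_ratio must be in (0, 1)")
        if self.size**2 <= min_sample_size(self.degree):
            raise ValueError("window too small for the polynomial degree")


class SingularFitError(ValueError):
    """Raised when a minimal sample's design matrix is singular."""


def min_sample_size(d: int) -> int:
    """Points needed to determine a bivariate degree-d polynomial: (d+1)(d+2)/2."""
    if d < 0:
        raise ValueError(f"degree must be >= 0, got {d}")
    return (d + 1) * (d + 2) // 2


def ransac_iterations(p: float, eps: float, sm: int) -> int:
    """Number of minimal-sample draws guaranteeing confidence ``p``.

    ``ceil( ln(1-p) / ln(1 - (1-eps)^sm) )`` for outlier ratio ``eps``.
    """
    if not (0 < p < 1) or not (0 <= eps < 1):
        raise ValueError(f"need 0 < p < 1 and 0 <= eps < 1, got p={p}, eps={eps}")
    if eps == 0.0:
        return 1
    good = (1.0 - eps) ** sm
    if not (0.0 < good < 1.0):
        raise ValueError("degenerate arguments: (1-eps)^sm must lie in (0, 1)")
    return math.ceil(math.log(1.0 - p) / math.log(1.0 - good))


def _poly_exponents(d: int) -> list[tuple[int, int]]:
    """Monomial exponents (k, l) with k + l <= d, ordered constant, x, y, ..."""
    return [(k, t - k) for t in range(d + 1) for k in range(t, -1, -1)]


def _design_matrix(positions: np.ndarray, d: int) -> np.ndarray:
    x, y = positions[:, 0], positions[:, 1]
    return np.column_stack([x**k * y**l for k, l in _poly_exponents(d)])


def fit_polynomial_window(samples: np.ndarray, d: int) -> np.ndarray:
    """Least-squares bivariate polynomial fit.

    ``samples`` is an (N, 3) array of rows ``(x, y, value)`` in window-local
    coordinates.  Returns the coefficient vector ordered constant, x, y, x^2,
    xy, y^2, ...  With exactly the minimal number of points the fit
    interpolates; a singular (e.g. collinear) minimal design raises
    :class:`SingularFitError`.
    """
    samples = np.asarray(samples, dtype=float)
    sm = min_sample_size(d)
    if samples.shape[0] < sm:
        raise ValueError(f"need at least {sm} samples for degree {d}")
    A = _design_matrix(samples[:, :2], d)
    beta, _, rank, _ = np.linalg.lstsq(A, samples[:, 2])
    if rank < A.shape[1]:
        raise SingularFitError("singular design matrix (degenerate sample)")
    return beta


@dataclass
class LmsFit:
    """Best LMS-RANSAC model for one window (one channel).

    ``residuals`` are signed residuals of every window pixel under the best
    model; ``sample_mask`` flags the minimal-sample pixels of the winning
    draw (excluded from the median).
    """

    beta: np.ndarray
    dmed: float
    residuals: np.ndarray
    sample_mask: np.ndarray


def _candidate_samples(n: int, sm: int, rng: np.random.Generator, m: int):
    """Minimal-sample index sets: exhaustive for tiny windows, else random."""
    if n <= 9:
        yield from itertools.combinations(range(n), sm)
    else:
        for _ in range(m):
            yield tuple(rng.choice(n, size=sm, replace=False))


def lms_ransac(positions: np.ndarray, values: np.ndarray, params: LmsParams) -> LmsFit:
    """Least-median-of-squares polynomial fit of one window by RANSAC.

    ``positions`` (N, 2) are window-local pixel coordinates, ``values`` (N,)
    one channel's intensities.  Windows of at most 9 pixels are enumerated
    exhaustively over all minimal samples; larger windows draw
    :func:`ransac_iterations` seeded random samples.  The draw minimising the
    median squared residual of the non-sample pixels wins.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    n = positions.shape[0]
    sm = min_sample_size(params.degree)
    m = ransac_iterations(params.confidence, params.outlier_ratio, sm)
    A = _design_matrix(positions, params.degree)
    rng = np.random.default_rng(params.seed)

    best: LmsFit | None = None
    for idx in _candidate_samples(n, sm, rng, m):
        sample = np.asarray(idx)
        As = A[sample]
        if np.linalg.matrix_rank(As) < A.shape[1]:
            continue
        beta = np.linalg.solve(As, values[sample])
        resid = values - A @ beta
        mask = np.zeros(n, dtype=bool)
        mask[sample] = True
        dmed = _low_median(resid[~mask] ** 2) if (~mask).any() else 0.0
        if best is None or dmed < best.dmed:
            best = LmsFit(beta=beta, dmed=dmed, residuals=resid, sample_mask=mask)
    if best is None:
        raise SingularFitError("all candidate minimal samples were singular")
    return best


def _low_median(values: np.ndarray) -> float:
    """Lower median: the ``(n-1)//2``-th order statistic.

    The LMS criterion uses this (rather than the interpolated even-count
    median) so the estimator keeps its full breakdown point when exactly
    half of the scored pixels are contaminated.
    """
    values = np.asarray(values)
    return float(np.partition(values, (values.size - 1) // 2)[(values.size - 1) // 2])


def robust_threshold(residuals: np.ndarray) -> float:
    """Robust inlier scale ``1.4826 * median(|d_i - median(d_i)|)``."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("empty residual set")
    dmed = np.median(residuals)
    return float(MAD_SCALE * np.median(np.abs(residuals - dmed)))


def classify_inliers(residuals: np.ndarray, tr: float) -> np.ndarray:
    """Inlier mask ``|d_i| <= 2.5 * Tr`` (zero threshold keeps only exact fits)."""
    if tr < 0:
        raise ValueError(f"threshold must be >= 0, got {tr}")
    return np.abs(np.asarray(residuals, dtype=float)) <= INLIER_FACTOR * tr


def _lms_window_center(positions: np.ndarray, channel_values: np.ndarray, params: LmsParams, seed: int) -> np.ndarray:
    """Filtered centre value(s) for one (possibly clipped) window.

    ``channel_values`` has shape (N, C).  Channels are fitted independently;
    a pixel flagged as an outlier in any channel is excluded from every
    channel's refit (joint outlier mask).  Falls back to the per-channel
    window median when the inlier count is <= the minimal sample size.
    """
    n, n_channels = channel_values.shape
    sm = min_sample_size(params.degree)
    p = LmsParams(
        size=params.size, degree=params.degree, confidence=params.confidence,
        outlier_ratio=params.outlier_ratio, seed=seed,
    )
    # fit deviations from the centre pixel so constant windows reproduce
    # exactly; the constant polynomial term absorbs the shift
    center_idx = int(np.flatnonzero((positions == 0).all(axis=1))[0])
    center_val = channel_values[center_idx]
    shifted = channel_values - center_val
    inlier = np.ones(n, dtype=bool)
    for c in range(n_channels):
        fit = lms_ransac(positions, shifted[:, c], p)
        tr = robust_threshold(fit.residuals[~fit.sample_mask])
        ok = classify_inliers(fit.residuals, tr)
        ok[fit.sample_mask] = True  # the minimal sample defines the model
        inlier &= ok
    if inlier.sum() <= sm:
        return np.median(channel_values, axis=0)
    A = _design_matrix(positions, params.degree)
    out = np.empty(n_channels)
    for c in range(n_channels):
        beta, *_ = np.linalg.lstsq(A[inlier], shifted[inlier, c])
        out[c] = center_val[c] + beta[0]  # polynomial value at the centre (0, 0)
    return out


def lms_filter(image: ImageGrid, params: LmsParams) -> ImageGrid:
    """Robust LMS surface filter over every pixel.

    Interior windows share each RANSAC draw's sample positions across the
    image so the heavy lifting is vectorised; border windows (clipped
    supports) run the per-window routine.  Deterministic for a given seed.
    """
    s, h = params.size, params.size // 2
    vals = image.values
    H, W, C = vals.shape
    out = np.empty_like(vals)

    # --- interior, vectorised -------------------------------------------
    if H >= s and W >= s:
        out[h : H - h, h : W - h] = _lms_filter_interior(vals, params)

    # --- border band (and tiny images), per window ----------------------
    rng_border = np.random.default_rng((params.seed, 1))
    for v in range(H):
        for u in range(W):
            if h <= v < H - h and h <= u < W - h:
                continue
            u0, u1 = max(0, u - h), min(W - 1, u + h)
            v0, v1 = max(0, v - h), min(H - 1, v + h)
            uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
            positions = np.column_stack([(uu - u).ravel(), (vv - v).ravel()])
            win = vals[v0 : v1 + 1, u0 : u1 + 1].reshape(-1, C)
            seed = int(rng_border.integers(0, 2**31))
            out[v, u] = _lms_window_center(positions, win, params, seed)
    return ImageGrid(out)


def _lms_filter_interior(vals: np.ndarray, params: LmsParams) -> np.ndarray:
    """Batched LMS over all full (unclipped) windows.

    One set of minimal-sample positions is drawn per RANSAC iteration and
    applied to every window simultaneously; the per-window winner is still
    the draw with the least median squared residual, exactly as in the
    scalar routine.
    """
    s, h, d = params.size, params.size // 2, params.degree
    H, W, C = vals.shape
    n = s * s
    sm = min_sample_size(d)
    coords = np.arange(s) - h
    xs, ys = np.meshgrid(coords, coords)  # xs varies along columns
    positions = np.column_stack([xs.ravel(), ys.ravel()])
    A = _design_matrix(positions, d)
    nt = A.shape[1]

    rng = np.random.default_rng((params.seed, 0))
    if n <= 9:
        draws = [
            np.asarray(c)
            for c in itertools.combinations(range(n), sm)
            if np.linalg.matrix_rank(A[np.asarray(c)]) >= nt
        ]
    else:
        m = ransac_iterations(params.confidence, params.outlier_ratio, sm)
        draws = []
        guard = 0
        while len(draws) < m and guard < 50 * m:
            guard += 1
            c = rng.choice(n, size=sm, replace=False)
            if np.linalg.matrix_rank(A[c]) >= nt:
                draws.append(np.sort(c))

    windows = sliding_window_view(vals, (s, s), axis=(0, 1))  # (H', W', C, s, s)
    Hi, Wi = windows.shape[:2]
    win_raw = windows.reshape(Hi * Wi, C, n)
    npix = win_raw.shape[0]
    # work on deviations from each window's centre pixel (exact constant
    # fixed point); add the centre value back at the end
    center_idx = h * s + h
    center_vals = win_raw[:, :, center_idx]
    win = win_raw - center_vals[:, :, None]

    centers = np.empty((npix, C))
    joint_inlier = np.ones((npix, n), dtype=bool)
    best_draw_per_channel = []
    for c in range(C):
        v = win[:, c, :]  # (npix, n)
        best_dmed = np.full(npix, np.inf)
        best_beta = np.zeros((npix, nt))
        best_draw = np.full(npix, -1)
        for t, sample in enumerate(draws):
            rest = np.setdiff1d(np.arange(n), sample)
            beta = v[:, sample] @ np.linalg.inv(A[sample]).T  # (npix, nt)
            resid = v[:, rest] - beta @ A[rest].T
            k = (rest.size - 1) // 2
            dmed = np.partition(resid**2, k, axis=1)[:, k]  # lower median
            better = dmed < best_dmed
            best_dmed[better] = dmed[better]
            best_beta[better] = beta[better]
            best_draw[better] = t
        resid_all = v - best_beta @ A.T  # (npix, n)
        tr = np.empty(npix)
        sample_mask = np.zeros((npix, n), dtype=bool)
        for t, sample in enumerate(draws):
            sel = best_draw == t
            if not sel.any():
                continue
            rest = np.setdiff1d(np.arange(n), sample)
            r = resid_all[np.ix_(sel, rest)]
            med = np.median(r, axis=1, keepdims=True)
            tr[sel] = MAD_SCALE * np.median(np.abs(r - med), axis=1)
            sample_mask[np.ix_(sel, sample)] = True
        ok = np.abs(resid_all) <= INLIER_FACTOR * tr[:, None]
        ok |= sample_mask
        joint_inlier &= ok
        best_draw_per_channel.append(best_draw)

    counts = joint_inlier.sum(axis=1)
    fallback = counts <= sm
    for c in range(C):
        centers[fallback, c] = np.median(win_raw[fallback, c, :], axis=1)
    fit_idx = np.nonzero(~fallback)[0]
    if fit_idx.size:
        mask = joint_inlier[fit_idx].astype(float)  # (k, n)
        # batched weighted normal equations: M_k = A^T diag(mask_k) A
        M = np.einsum("ki,ij,il->kjl", mask, A, A)
        for c in range(C):
            v = win[fit_idx, c, :]
            b = np.einsum("ki,ij->kj", mask * v, A)
            try:
                beta = np.linalg.solve(M, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                beta = np.stack(
                    [
                        np.linalg.lstsq(A[mask[k] > 0], v[k][mask[k] > 0])[0]
                        for k in range(fit_idx.size)
                    ]
                )
            centers[fit_idx, c] = center_vals[fit_idx, c] + beta[:, 0]
    return centers.reshape(Hi, Wi, C)
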