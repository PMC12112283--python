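# Methods

## Image model and scale conventions

Images are dense 2-D rasters with 1 (grey) or 3 (RGB) channels, held as
float64 on the 0–255 scale regardless of file bit depth (16-bit files are
linearly rescaled on read).  Pixel coordinates are 0-based, `u` = column,
`v` = row, with unit pitch, so the spatial part of the manifold embedding is
simply `x = u`, `y = v`.  Keeping the 8-bit intensity scale rather than
normalising to [0, 1] is deliberate: the metric weight `α` and the filtering
extent `σ` only have their intended meanings when a one-grey-level signal
difference is commensurable with a one-pixel spatial step.  With `α = 1`
(the default), an edge of contrast 200 contributes a geodesic step of ≈ 200,
so a Gaussian weight `exp(−d²/2σ²)` at any practical σ (tens of units)
suppresses cross-edge averaging essentially completely.

Gamma is not modelled; stored intensities are filtered as-is.  Alpha
channels are dropped on read with a warning.

## Geodesic metric and window graphs

The metric between 8-neighbouring pixels is `sqrt(dS² + α²‖Δr‖²)` with
`dS = 1` (axial) or `√2` (diagonal) and `Δr` the joint Euclidean difference
over all channels (colour images use one joint distance map applied to all
channels, not per-channel paths).  Only 8-connectivity is supported; paths
are confined to the odd `w × w` window around the centre pixel, and windows
overlapping the image border are clipped with no padding — the filter's
normalisation handles the reduced pixel count.

## Minimal-path engines

* **Dijkstra** (reference): binary-heap priority queue, stale entries
  skipped via a visited flag rather than decrease-key.  Ties in the heap
  are broken by insertion order; distances are tie-independent.
* **Wave propagation**: vertices are grouped into concentric Chebyshev
  rings around the source; a sweep relaxes all 8-neighbours of every vertex
  ring by ring, and sweeps repeat until no distance changes.  Iterating to
  a fixed point makes the CPU implementation *exact* (equal to Dijkstra to
  double precision) rather than approximated to a fixed wave count.  The
  reported wave count is the number of ring relaxations that changed at
  least one distance — 4 for a uniform 7×7 window (centre + three rings).
* **Brute force oracle** (testing only): exact minimum over all simple
  paths by depth-first enumeration with a best-distance pruning bound;
  refuses graphs above 25 vertices.

The whole-image filter with `engine="wave"` runs the same relaxation
batched over every window simultaneously (a min-plus Jacobi iteration on an
`(H, W, w, w)` distance array built from eight shifted edge-weight fields).
Each window's state evolves independently, so blocked (tiled) execution is
bit-identical to whole-image filtering, and the σ-sweep can reuse one set of
distance maps for every σ on the grid (distances do not depend on σ).

Weighted means are accumulated as deviations from the centre pixel value,
which makes constant images exact (bit-level) fixed points of every filter.

## Tile geometry

For blocked execution with tile side `t` and window side `w`, the halo is
`⌊w/2⌋` pixels per side, a block loads `t + 2·halo` pixels per side, and the
interior whose windows fit inside a halo-free load is `t − 2·halo` per side
(16-px tiles with a 7×7 window: halo 3, loaded 22, effective 10).  Output
tiles partition the image exactly; border blocks clip their loaded region.

## Comparator filters

* **Gradient anisotropic diffusion**: explicit 4-neighbour Perona–Malik
  scheme, conductance `exp(−s²/C²)` or `1/(1+s²/C²)` evaluated per
  directional difference, time step τ ≤ 0.25 (default 0.25) for the
  discrete extremum principle.  Channels diffuse independently.
* **Curvature anisotropic diffusion**: explicit steps of
  `g(|κ|)·|∇I|·κ` with `κ = div(∇I/|∇I|)` by centred differences; the
  gradient magnitude in the normalisation is regularised by 1e−8.  The
  decreasing function `g` reuses the conductance forms with the scale
  applied to |κ|.  Because the speed is rescaled by |∇I|, useful curvature
  scales sit well above 1; the benchmark grid uses C ∈ {2, 10}.
* **Bilateral**: normalised product of spatial and range Gaussians over an
  odd `s × s` neighbourhood, joint Euclidean range distance across
  channels, clipped windows at the border.
* **LMS filter**: per window, a bivariate polynomial of degree 1 or 2 is
  fitted by RANSAC — minimal samples of `(d+1)(d+2)/2` pixels,
  `m = ⌈ln(1−p)/ln(1−(1−ε)^sm)⌉` draws (35 for p = 0.99, ε = 0.5, d = 1) —
  minimising the median squared residual of the non-sample pixels.  Windows
  of ≤ 9 pixels enumerate all minimal samples exhaustively.  Inliers are
  pixels with `|dᵢ| ≤ 2.5·Tr` where `Tr = 1.4826·median(|dᵢ − median(dᵢ)|)`
  (the MAD scale); the centre pixel is replaced by the value at the window
  origin of a least-squares refit on the inliers, or by the window median
  when ≤ sm inliers survive.  Colour channels are fitted independently with
  a joint outlier mask (a pixel rejected in any channel is excluded from
  every refit).

Two numerical conventions deserve note.  The LMS "median" is the lower
median (order statistic at index `(n−1)//2`): with an interpolated
even-count median the estimator loses its 50 % breakdown point exactly at
half contamination, which contradicts its defining property.  And the
whole-image LMS filter draws each minimal-sample *position set* once per
RANSAC iteration and shares it across all full interior windows (border
windows run per-window with their own seeded draws); the per-window
estimator is unchanged, only the random draws are coupled across windows,
and results remain deterministic for a given seed.

## Quality metrics

PSNR is `10·log₁₀(V²/MSE)` with V = 255 and the MSE pooled over channels;
identical images report `+inf`.  SSIM uses `c₁ = (0.01·V)²`,
`c₂ = (0.03·V)²` and is computed on the luma channel (0.299, 0.587, 0.114)
for colour pairs.  Two modes exist: a **global** single-statistic evaluation
of the SSIM formula over the whole image, and the conventional **windowed**
mean SSIM (11×11 Gaussian weights, σ = 1.5, population variances, border
band cropped) used by all benchmark reports; the windowed mode agrees with
scikit-image's implementation to ≤ 1e−6 and is cross-checked against it in
the tests.

## Synthetic data

The phantom generator supplies the study scenes: a three-region
piecewise-constant image (levels 40/120/220, so region contrasts ≥ 60 and
edges dominate noise at σₙ = 25), a 0/200 step, a 0→255 ramp, a 60/180
checkerboard, and seeded band-limited texture (Gaussian-filtered white
noise, σ = 3 px, ±40 around mid-grey).  Noise models: zero-mean additive
Gaussian with configurable σₙ (default 25, which puts the noisy-image PSNR
near 20 dB, the plausible range for 8-bit imagery being roughly σₙ ∈
[0, 35]), salt-and-pepper, and multiplicative speckle.  Noisy images are
clipped to [0, 255] by default (they represent 8-bit storage); clipping can
be disabled for analytic noise-statistics checks.

What the phantoms do *not* emulate is natural-image texture statistics:
they are piecewise-smooth scenes with exactly known references.  Passing
benchmarks on them demonstrates correct mechanics and edge-preservation
behaviour, not performance rankings on photographs.  One concrete
consequence: tuned Perona–Malik diffusion is a near-optimal prior for
purely piecewise-constant scenes and can match or exceed the geodesic
filter's SSIM there, whereas on textured natural imagery the geodesic
filter's structural-preservation advantage is what motivates the method.
The benchmark protocol (tune every method's coarse grid for best PSNR,
record the SSIM at the winning setting) is therefore reported per phantom,
and the aggregate ranking should be read with that caveat.

## Parameter defaults and problem sizes

Geodesic filter: `w = 11`, `α = 1` (the standard experimental setting),
`σ = 40` by default but normally taken from the natural-scale sweep; engine
`dijkstra` for single pixels (exact reference), `wave` for whole images.
Benchmarks and the acceptance script use 128×128 phantoms, a σ grid of
5…120 in steps of 5, and ≤ 8-point comparator grids — sizes chosen as
sensible desk-scale defaults; all are configurable.

## Known limitations

* No 3-D/4-D volumes, video, or range data; 2-D rasters only.
* No adaptive per-pixel selection of α, σ, or window size (globally fixed
  parameters only).
* 4-connectivity is deliberately unsupported.
* LMS fitted values may overshoot the window extrema (a polynomial fit is
  not a convex combination); the window-median fallback and constant-window
  cases are bounded.
* The wave engine's fixed-point iteration trades the fixed wave count of a
  streaming implementation for exactness; it is a CPU reference, not a
  performance claim.
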