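# geofilter

Edge-preserving image denoising by **geodesic filtering**: the image is
treated as a surface (a Riemannian manifold) embedded in a space that
combines pixel coordinates with intensity or colour, and pixel similarity is
measured by the length of the *minimal path* between pixels on that surface.
Spatially adjacent pixels separated by a strong edge are geodesically far —
every path between them has to climb the edge — so they exchange almost no
weight and edges survive aggressive smoothing.

The package is aimed at researchers in biological and medical image analysis
who need edge-preserving smoothing with a clean reference implementation,
the classical comparator filters, quality metrics, and an automatic
parameter search, all exercisable on synthetic data with no external image
downloads.

## The model

A grey-level image maps each pixel to `(x(u,v), y(u,v), I(u,v))` (RGB: to
R⁵).  The metric between 8-neighbouring pixels is

    w(p, q) = sqrt(dS² + α² ‖Δr‖²),     dS ∈ {1, √2},

with `α` weighting signal differences against spatial steps (intensities are
kept on the 0–255 scale, so `α = 1` makes one grey level comparable to one
pixel).  For an odd `w × w` window around a centre pixel, geodesic distances
`d` from the centre to every window pixel are single-source shortest paths
over the window's 8-connected graph, and the filter output is the normalised
Gaussian weighting

    r̂(u₀,v₀) = Σ r(u,v) · exp(−d²/2σ²) / Σ exp(−d²/2σ²).

Two distance engines are provided: a binary-heap **Dijkstra** (exact scalar
reference) and a synchronous ring-ordered **wave propagation** relaxation
(the parallel-friendly formulation, iterated to the same fixed point and
vectorised over all windows at once).  Comparators: gradient (Perona–Malik)
and curvature anisotropic diffusion, the bilateral filter, and a robust
least-median-of-squares (LMS/RANSAC) polynomial surface filter.  Quality is
scored by PSNR and SSIM, and the **natural scale** σ* of an image is found
by sweeping σ and maximising PSNR against a clean reference.

## Worked example

```python
import geofilter as gf

reference = gf.make_phantom("piecewise_constant", (128, 128), seed=0)
noisy = gf.add_noise(reference, gf.NoiseSpec(sigma_n=25.0, seed=0))
sweep = gf.natural_scale_search(reference, noisy, alpha=1.0, window=11,
                                sigma_grid=[float(s) for s in range(5, 125, 5)])
print("noisy PSNR:", round(gf.psnr(reference, noisy), 2), "dB")
print("natural scale sigma* =", sweep.sigma_star_psnr)
i = sweep.sigma_grid.index(sweep.sigma_star_psnr)
print("filtered PSNR:", round(sweep.psnr_curve[i], 2), "dB",
      " SSIM:", round(sweep.ssim_curve[i], 4))
```

prints

```
noisy PSNR: 20.51 dB
natural scale sigma* = 55.0
filtered PSNR: 35.01 dB  SSIM: 0.9295
```

i.e. on a flat-region phantom corrupted with σ=25 Gaussian noise, the sweep
finds an interior optimum σ* = 55 where geodesic filtering recovers ≈ 14.5 dB
of PSNR; the PSNR-vs-σ curve rises to this natural scale and then falls as
over-blurring sets in.

The same operations are available from a shell:

```sh
geofilter filter --input noisy.png --output clean.png --sigma 55 --window 11 --engine wave
geofilter metrics --reference ref.png --test clean.png
geofilter sweep --reference ref.png --noisy noisy.png --grid 5:120:5
geofilter benchmark --config bench.yaml --out report.csv
```

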