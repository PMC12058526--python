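"""Build and interrogate the (alpha, beta, gamma) conformational landscape.

Every paired particle contributes one point in the 3D space of relative
z-y-x rotation angles between the two rigid bodies.  Binning those points
gives the particle-distribution landscape; a light Gaussian smooth of the
counts (wrapped along the periodic alpha and gamma axes) gives a local
density that is normalized to sum 1 so landscapes of different particle
counts are directly comparable.  Hot areas and hotspots -- local density
maxima above a percentile threshold -- mark favoured relative orientations.

Defaults: 2-degree bins and a 1-bin smoothing sigma, fine enough that the
~14-degree selection radii used for subset reconstruction span several bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rotation_core import (
    canonicalize_stack,
    euler_zyz_to_matrix,
    matrix_to_euler_zyx,
    relative_rotation,
    wrap_angle,
)

#: axis ranges of the canonical orientation space, degrees
AXIS_RANGES = ((-180.0, 180.0), (-90.0, 90.0), (-180.0, 180.0))
#: smoothing boundary mode per axis: alpha and gamma wrap, beta clamps
_SMOOTH_MODES = ("wrap", "nearest", "wrap")

DEFAULT_BIN_WIDTH = 2.0
DEFAULT_SMOOTH_SIGMA = 1.0
DEFAULT_HOTSPOT_PERCENTILE = 97.5
DEFAULT_MIN_SEPARATION = 10.0


def compute_orientations(table, canonicalize_flag: bool = False) -> np.ndarray:
    """Per-particle relative orientations (n, 3) in degrees.

    Pipeline per record: ZYZ triples -> rotation matrices -> relative
    rotation (modifying body as reference) -> z-y-x decomposition, with
    optional collapse onto the canonical C2 representative.
    """
    r_mod = euler_zyz_to_matrix(table.euler_mod())
    r_cond = euler_zyz_to_matrix(table.euler_cond())
    orients = matrix_to_euler_zyx(relative_rotation(r_mod, r_cond))
    orients = np.atleast_2d(orients)
    if canonicalize_flag:
        orients = canonicalize_stack(orients)
    return orients


@dataclass
class LandscapeGrid:
    """Binned particle counts and smoothed density over (alpha, beta, gamma)."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    counts: np.ndarray          # 3D int array
    density: np.ndarray         # 3D float array, sums to 1
    bin_width: float
    n_particles: int
    smooth_sigma: float

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def marginal(self, axes=(0, 2)) -> np.ndarray:
        """2D marginal density over the given pair of axes (default alpha-gamma)."""
        drop = tuple(i for i in range(3) if i not in axes)
        return self.density.sum(axis=drop)

    def marginal_1d(self, axis: int = 0) -> np.ndarray:
        drop = tuple(i for i in range(3) if i != axis)
        return self.density.sum(axis=drop)

    def marginal_variance(self, axis: int = 0) -> float:
        """Variance of the 1D marginal density along one axis, degrees^2."""
        w = self.marginal_1d(axis)
        c = self.centers[axis]
        mean = float(np.sum(w * c))
        return float(np.sum(w * (c - mean) ** 2))

    def save(self, path) -> None:
        np.savez(
            path,
            edges_alpha=self.edges[0], edges_beta=self.edges[1],
            edges_gamma=self.edges[2], counts=self.counts,
            density=self.density,
            meta=np.array([self.bin_width, self.n_particles, self.smooth_sigma]),
        )

    @classmethod
    def load(cls, path) -> "LandscapeGrid":
        with np.load(path) as z:
            bw, n, sig = z["meta"]
            return cls(
                edges=(z["edges_alpha"], z["edges_beta"], z["edges_gamma"]),
                counts=z["counts"], density=z["density"],
                bin_width=float(bw), n_particles=int(n), smooth_sigma=float(sig),
            )


def build_landscape(orients, bin_width: float = DEFAULT_BIN_WIDTH,
                    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA) -> LandscapeGrid:
    """3D histogram of orientations with wrapped-Gaussian smoothing.

    alpha and gamma are wrapped into (-180, 180] before binning (the axes
    are periodic); beta is clamped into [-90, 90], which it satisfies by
    construction of the z-y-x decomposition.
    """
    orients = np.atleast_2d(np.asarray(orients, dtype=float))
    if orients.shape[0] == 0:
        raise ValueError("cannot build a landscape from zero orientations")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    pts = orients.copy()
    pts[:, 0] = wrap_angle(pts[:, 0])
    pts[:, 2] = wrap_angle(pts[:, 2])
    pts[:, 1] = np.clip(pts[:, 1], -90.0, 90.0)

    edges = []
    for lo, hi in AXIS_RANGES:
        nbins = max(1, int(round((hi - lo) / bin_width)))
        edges.append(np.linspace(lo, hi, nbins + 1))
    counts, _ = np.histogramdd(pts, bins=edges)
    # the wrap puts alpha/gamma in (-180, 180]; histogramdd treats only the
    # last bin as right-closed, so +180 lands correctly and -180 never occurs
    counts = counts.astype(int)

    if smooth_sigma > 0:
        density = ndimage.gaussian_filter(counts.astype(float), sigma=smooth_sigma,
                                          mode=_SMOOTH_MODES)
    else:
        density = counts.astype(float)
    total = density.sum()
    if total > 0:
        density = density / total
    return LandscapeGrid(edges=tuple(edges), counts=counts, density=density,
                         bin_width=bin_width, n_particles=int(counts.sum()),
                         smooth_sigma=smooth_sigma)


def _fractional_index(grid: LandscapeGrid, coord) -> np.ndarray:
    """Coordinate -> fractional bin-center index per axis."""
    coord = np.asarray(coord, dtype=float)
    idx = np.empty(3)
    for ax, (lo, _hi) in enumerate(AXIS_RANGES):
        value = coord[ax]
        if ax != 1:
            value = wrap_angle(value)
        idx[ax] = (value - lo) / grid.bin_width - 0.5
    return idx


def local_density(grid: LandscapeGrid, coord) -> float:
    """Trilinear interpolation of the smoothed density at a coordinate.

    alpha and gamma interpolate periodically across the seam; beta clamps
    to its edge bins.
    """
    frac = _fractional_index(grid, coord)
    shape = grid.density.shape
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    value = 0.0
    for corner in range(8):
        w, idx = 1.0, [0, 0, 0]
        for ax in range(3):
            bit = (corner >> ax) & 1
            j = i0[ax] + bit
            w *= t[ax] if bit else (1.0 - t[ax])
            if ax == 1:
                j = min(max(j, 0), shape[ax] - 1)   # clamp beta
            else:
                j %= shape[ax]                      # wrap alpha/gamma
            idx[ax] = j
        value += w * grid.density[tuple(idx)]
    return float(value)


@dataclass
class Hotspot:
    """A local density maximum of the landscape."""

    center: tuple[float, float, float]   # bin-center (alpha, beta, gamma)
    density: float
    n_within: int                        # raw counts in the peak bin


def wrapped_delta(a, b, axis: int) -> np.ndarray:
    """Signed angular difference a-b, wrapped for periodic axes (0 and 2)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if axis != 1:
        d = wrap_angle(d)
    return d


def orientation_distance(a, b) -> float:
    """Euclidean distance in degrees with wrap on alpha and gamma."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = np.array([wrapped_delta(a[i], b[i], i) for i in range(3)])
    return float(np.sqrt(np.sum(d ** 2)))


def find_hotspots(grid: LandscapeGrid,
                  percentile: float = DEFAULT_HOTSPOT_PERCENTILE,
                  min_separation: float = DEFAULT_MIN_SEPARATION) -> list[Hotspot]:
    """Strict local maxima of the density above a percentile threshold.

    The threshold is the given percentile of density over *nonzero* bins
    (empty space does not dilute it).  Maxima closer than ``min_separation``
    degrees (wrapped Euclidean) to a stronger maximum are pruned greedily.
    Returned sorted by descending density; may be empty (a perfectly flat
    landscape has no strict maximum).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    density = grid.density
    nonzero = density[density > 0]
    if nonzero.size == 0:
        return []
    threshold = np.percentile(nonzero, percentile)

    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    # pad manually: periodic alpha/gamma, clamped beta (scipy's maximum_filter
    # cannot mix boundary modes for a non-separable footprint)
    padded = np.pad(density, ((1, 1), (0, 0), (1, 1)), mode="wrap")
    padded = np.pad(padded, ((0, 0), (1, 1), (0, 0)), mode="edge")
    neighbour_max = ndimage.maximum_filter(
        padded, footprint=footprint, mode="constant", cval=-np.inf
    )[1:-1, 1:-1, 1:-1]
    peak_mask = (density > neighbour_max) & (density >= threshold) & (density > 0)
    idx = np.argwhere(peak_mask)
    if idx.size == 0:
        return []

    centers = grid.centers
    candidates = sorted(
        (Hotspot(center=(float(centers[0][i]), float(centers[1][j]), float(centers[2][k])),
                 density=float(density[i, j, k]),
                 n_within=int(grid.counts[i, j, k]))
         for i, j, k in idx),
        key=lambda h: -h.density,
    )
    kept: list[Hotspot] = []
    for cand in candidates:
        if all(orientation_distance(cand.center, k.center) >= min_separation for k in kept):
            kept.append(cand)
    return kept


def render_landscape(grid: LandscapeGrid, out_prefix,
                     overlay: LandscapeGrid | None = None,
                     overlay_levels=(0.25, 0.5, 0.75)) -> list[str]:
    """Write a 3D scatter view and 2D marginal projections as PNG files.

    The 3D panel shows occupied bins coloured by local density; the 2D
    panels are alpha-gamma and alpha-beta marginal densities.  An optional
    second grid is overlaid as red contours of its marginals at the given
    fractions of the marginal maximum (the standard way to compare, e.g., a
    crowding-restricted landscape against the reference one).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = str(out_prefix)
    written = []
    ca, cb, cg = grid.centers

    occupied = np.argwhere(grid.counts > 0)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    if occupied.size:
        dens = grid.density[tuple(occupied.T)]
        ax.scatter(ca[occupied[:, 0]], cb[occupied[:, 1]], cg[occupied[:, 2]],
                   c=dens, s=4, cmap="viridis")
    ax.set_xlabel(r"$\alpha$ (deg)")
    ax.set_ylabel(r"$\beta$ (deg)")
    ax.set_zlabel(r"$\gamma$ (deg)")
    ax.set_title("relative-orientation landscape")
    fig.savefig(out_prefix + "_3d.png", dpi=120)
    plt.close(fig)
    written.append(out_prefix + "_3d.png")

    panels = [((0, 2), cg, r"$\gamma$ (deg)", "_alpha_gamma.png"),
              ((0, 1), cb, r"$\beta$ (deg)", "_alpha_beta.png")]
    for axes, yc, ylabel, suffix in panels:
        marg = grid.marginal(axes).T
        fig, ax2 = plt.subplots(figsize=(6, 5))
        extent = (ca[0], ca[-1], yc[0], yc[-1])
        ax2.imshow(marg, origin="lower", extent=extent, aspect="auto", cmap="viridis")
        if overlay is not None:
            om = overlay.marginal(axes).T
            levels = sorted(set(float(f) * float(om.max()) for f in overlay_levels))
            oa, *_ = overlay.centers
            oyc = overlay.centers[axes[1]]
            if om.max() > 0 and len(levels) > 0:
                ax2.contour(oa, oyc, om, levels=levels, colors="red", linewidths=1.0)
        ax2.set_xlabel(r"$\alpha$ (deg)")
        ax2.set_ylabel(ylabel)
        fig.savefig(out_prefix + suffix, dpi=120)
        plt.close(fig)
        written.append(out_prefix + suffix)
    return written
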