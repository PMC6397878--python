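"""Lattice geometry, Gaussian lateral kernels and inter-nucleus projections.

Lateral connections within a nucleus are Gaussian neighborhoods
``w = A * exp(-d^2 / R^2)`` truncated to an ``nlat x nlat`` window and at the
lattice edges (no wraparound), with no self-connection.  Between nuclei the
STN<->GPe maps are one-to-one and STN->SNc is block-convergent (each SNc
neuron pools a 4x4 block of STN neurons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConnectivityConfig, NucleusSpec, default_nuclei


@dataclass
class LatticeLayout:
    """A rows x cols lattice of neurons, row-major indexed."""

    nucleus: str
    rows: int
    cols: int

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def coords(self) -> np.ndarray:
        """(n, 2) array of (i, j) lattice coordinates."""
        i, j = np.divmod(np.arange(self.n), self.cols)
        return np.stack([i, j], axis=1)


@dataclass
class LateralKernel:
    """Gaussian lateral weights for one nucleus.

    ``kernel1d`` holds the one-dimensional Gaussian profile of length
    ``nlat`` (the kernel is separable: w(di, dj) = A * k[di] * k[dj]); the
    center entry is excluded from all synaptic sums (no self-connection).
    """

    layout: LatticeLayout
    strength: float
    radius: float
    nlat: int
    kernel1d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("lateral strength A must be non-negative")
        if self.radius <= 0:
            raise ValueError("Gaussian radius R must be positive")
        if self.nlat < 1:
            raise ValueError("neighborhood extent nlat must be >= 1")
        if self.nlat > 2 * max(self.layout.rows, self.layout.cols) - 1:
            raise ValueError("lateral neighborhood larger than the lattice")
        half = (self.nlat - 1) // 2
        offs = np.arange(-half, half + 1, dtype=float)
        self.kernel1d = np.exp(-(offs**2) / self.radius**2)

    @property
    def half_width(self) -> int:
        return (self.nlat - 1) // 2

    def weight(self, d2: float) -> float:
        """Kernel value at squared lattice distance ``d2`` (window ignored)."""
        return self.strength * float(np.exp(-d2 / self.radius**2))

    def dense(self) -> np.ndarray:
        """Full (n, n) weight matrix (zero diagonal, window- and
        edge-truncated)."""
        xy = self.layout.coords()
        di = np.abs(xy[:, None, 0] - xy[None, :, 0])
        dj = np.abs(xy[:, None, 1] - xy[None, :, 1])
        d2 = di.astype(float) ** 2 + dj.astype(float) ** 2
        w = self.strength * np.exp(-d2 / self.radius**2)
        half = self.half_width
        w[(di > half) | (dj > half)] = 0.0
        np.fill_diagonal(w, 0.0)
        return w

    def lateral_sum(self, field2d: np.ndarray) -> np.ndarray:
        """Separable windowed convolution of a (rows, cols) field, minus the
        center term, times A.  Equivalent to ``dense() @ field.ravel()``."""
        k = self.kernel1d
        half = self.half_width
        padded = np.zeros((field2d.shape[0] + 2 * half, field2d.shape[1]))
        padded[half: half + field2d.shape[0]] = field2d
        tmp = np.zeros_like(field2d)
        for d in range(2 * half + 1):
            tmp += k[d] * padded[d: d + field2d.shape[0]]
        padded = np.zeros((field2d.shape[0], field2d.shape[1] + 2 * half))
        padded[:, half: half + field2d.shape[1]] = tmp
        out = np.zeros_like(field2d)
        for d in range(2 * half + 1):
            out += k[d] * padded[:, d: d + field2d.shape[1]]
        return self.strength * (out - field2d)


def build_lateral_kernel(
    layout: LatticeLayout, strength: float, radius: float, nlat: int
) -> LateralKernel:
    """Gaussian lateral kernel for ``layout`` (see :class:`LateralKernel`)."""
    return LateralKernel(layout=layout, strength=strength, radius=radius, nlat=nlat)


@dataclass
class ProjectionMap:
    """Edges from a source to a target nucleus with a common base weight.

    ``sources[t]`` lists the source indices feeding target neuron ``t``.
    """

    source: LatticeLayout
    target: LatticeLayout
    kind: str  # "one_to_one" | "convergent"
    sources: np.ndarray  # (n_target, in_degree) int
    w0: float

    @property
    def in_degree(self) -> int:
        return self.sources.shape[1]

    @property
    def n_edges(self) -> int:
        return self.sources.size


def build_projection(
    source: LatticeLayout, target: LatticeLayout, kind: str, w0: float
) -> ProjectionMap:
    """Build a one-to-one or block-convergent projection map.

    One-to-one requires equal lattice shapes and pairs equal (i, j)
    positions.  Convergent requires the source shape to be an integer
    multiple of the target shape; each target neuron pools the
    corresponding source block (a 4x4 block for the 32x32 -> 8x8 case,
    giving in-degree 16).
    """
    if kind == "one_to_one":
        if (source.rows, source.cols) != (target.rows, target.cols):
            raise ValueError("one-to-one projection requires equal lattice sizes")
        idx = np.arange(target.n, dtype=np.int64)[:, None]
        return ProjectionMap(source, target, kind, idx, w0)
    if kind == "convergent":
        if source.rows % target.rows or source.cols % target.cols:
            raise ValueError("convergent projection requires integer block sizes")
        bi, bj = source.rows // target.rows, source.cols // target.cols
        idx = np.empty((target.n, bi * bj), dtype=np.int64)
        for t in range(target.n):
            ti, tj = divmod(t, target.cols)
            rows = np.arange(ti * bi, (ti + 1) * bi)
            cols = np.arange(tj * bj, (tj + 1) * bj)
            idx[t] = (rows[:, None] * source.cols + cols[None, :]).ravel()
        return ProjectionMap(source, target, kind, idx, w0)
    raise ValueError(f"unknown projection kind: {kind!r}")


@dataclass
class ConnectivityBundle:
    """All kernels and projection maps of the STN-GPe-SNc network."""

    layouts: dict[str, LatticeLayout]
    kernels: dict[str, LateralKernel]
    stn_to_gpe: ProjectionMap
    gpe_to_stn: ProjectionMap
    stn_to_snc: ProjectionMap


def build_connectivity(
    nuclei: dict[str, NucleusSpec] | None = None,
    weights: ConnectivityConfig | None = None,
) -> ConnectivityBundle:
    """Assemble the full connectivity bundle from nucleus specs."""
    nuclei = nuclei or default_nuclei()
    weights = weights or ConnectivityConfig()
    layouts = {
        name: LatticeLayout(name, spec.rows, spec.cols) for name, spec in nuclei.items()
    }
    kernels = {
        name: build_lateral_kernel(layouts[name], spec.strength, spec.radius, spec.nlat)
        for name, spec in nuclei.items()
    }
    return ConnectivityBundle(
        layouts=layouts,
        kernels=kernels,
        stn_to_gpe=build_projection(layouts["stn"], layouts["gpe"], "one_to_one", weights.w_stn_gpe),
        gpe_to_stn=build_projection(layouts["gpe"], layouts["stn"], "one_to_one", weights.w_gpe_stn),
        stn_to_snc=build_projection(layouts["stn"], layouts["snc"], "convergent", weights.w_stn_snc),
    )


def load_connectivity(h5group) -> dict:
    """Read a dumped connectivity group back into plain arrays.

    Returns ``{"kernels": {name: dense matrix}, "projections":
    {name: (kind, w0, sources)}}`` for reproducibility checks.
    """
    out = {"kernels": {}, "projections": {}}
    for key in h5group:
        g = h5group[key]
        if key.startswith("kernel_"):
            out["kernels"][key[len("kernel_"):]] = g["dense"][...]
        else:
            out["projections"][key] = (g.attrs["kind"], float(g.attrs["w0"]),
                                       g["sources"][...])
    return out


def save_connectivity(bundle: ConnectivityBundle, h5group) -> None:
    """Dump kernels (dense) and projection index arrays into an HDF5 group."""
    for name, kern in bundle.kernels.items():
        g = h5group.create_group(f"kernel_{name}")
        g.attrs.update(strength=kern.strength, radius=kern.radius, nlat=kern.nlat,
                       rows=kern.layout.rows, cols=kern.layout.cols)
        g.create_dataset("dense", data=kern.dense())
    for name in ("stn_to_gpe", "gpe_to_stn", "stn_to_snc"):
        proj: ProjectionMap = getattr(bundle, name)
        g = h5group.create_group(name)
        g.attrs.update(kind=proj.kind, w0=proj.w0)
        g.create_dataset("sources", data=proj.sources)
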