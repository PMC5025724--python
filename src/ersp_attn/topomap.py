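"""Nearest-neighbor topographic rendering of electrode statistics on a mesh.

Each mesh vertex takes the value of its Euclidean-nearest electrode,
attenuated linearly with distance so the color fades to neutral at
``fade_radius_mm`` (default 15 mm, ≈1.5× typical subdural inter-electrode
spacing).  A generic low-polygon hemisphere mesh is generated in code; a real
template cortical surface can be supplied as any (vertices, triangles) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Mesh:
    """Triangular surface mesh: vertices (V, 3) mm and triangles (T, 3) indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, float)
        t = np.asarray(self.triangles, int)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (T, 3)")
        if not np.isfinite(v).all():
            raise ValueError("non-finite vertex coordinates")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        if t.size and any(len(set(tri)) < 3 for tri in t):
            raise ValueError("degenerate triangle (repeated vertex index)")


@dataclass(frozen=True)
class VertexField:
    """Per-vertex statistic with the electrode it was taken from."""

    values: np.ndarray
    source_electrode: np.ndarray  # index into the electrode array


def hemisphere_mesh(
    hemisphere: str = "R", n_polar: int = 14, n_azimuth: int = 18,
    radii_mm: tuple[float, float, float] = (65.0, 85.0, 70.0),
) -> Mesh:
    """Generic half-ellipsoid cortical stand-in (lateral convexity).

    Axes: x lateral, y anterior–posterior, z superior.  The polar range stops
    short of the poles so no degenerate triangles are produced.
    """
    rx, ry, rz = radii_mm
    theta = np.linspace(0.12 * np.pi, 0.95 * np.pi, n_polar)  # from vertex down
    phi = np.linspace(0.0, np.pi, n_azimuth)  # azimuth over one lateral half
    T, P = np.meshgrid(theta, phi, indexing="ij")
    x = rx * np.sin(T) * np.sin(P)
    y = ry * np.sin(T) * np.cos(P)
    z = rz * np.cos(T)
    if hemisphere == "L":
        x = -x
    vertices = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    tris = []
    for i in range(n_polar - 1):
        for j in range(n_azimuth - 1):
            a = i * n_azimuth + j
            b = a + 1
            c = a + n_azimuth
            d = c + 1
            tris.append((a, b, c))
            tris.append((b, d, c))
    return Mesh(vertices=vertices, triangles=np.array(tris))


def nearest_neighbor_field(
    mesh: Mesh,
    electrode_xyz: np.ndarray,
    values: np.ndarray,
    fade_radius_mm: float = 15.0,
) -> VertexField:
    """Assign each vertex its nearest electrode's value with a linear fade.

    vertex value = value[nearest] × max(0, 1 − d / fade_radius).  Distance
    ties go to the lowest electrode index, so electrodes should be passed in
    id order.
    """
    xyz = np.asarray(electrode_xyz, float)
    vals = np.asarray(values, float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or len(xyz) == 0:
        raise ValueError("electrode_xyz must be a non-empty (E, 3) array")
    if vals.shape != (len(xyz),):
        raise ValueError("values must have one entry per electrode")
    if not fade_radius_mm > 0:
        raise ValueError("fade_radius_mm must be positive")
    out = np.empty(len(mesh.vertices))
    src = np.empty(len(mesh.vertices), int)
    chunk = 4096
    for s in range(0, len(mesh.vertices), chunk):
        v = mesh.vertices[s : s + chunk]
        d2 = ((v[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
        j = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
        d = np.sqrt(d2[np.arange(len(v)), j])
        out[s : s + chunk] = vals[j] * np.maximum(0.0, 1.0 - d / fade_radius_mm)
        src[s : s + chunk] = j
    return VertexField(values=out, source_electrode=src)


def render_panel(
    mesh: Mesh,
    field: VertexField,
    out_path,
    vmax: float | None = None,
    cmap: str = "RdBu_r",
    title: str | None = None,
    dpi: int = 150,
) -> None:
    """Save a lateral-view panel of the vertex field as a PNG.

    Orthographic projection onto the sagittal (y, z) plane; triangles are
    painted far-to-near and colored by their mean vertex value on a diverging
    map (ERD negative = blue, ERS positive = red), symmetric about zero and
    clipped at ``vmax``.  Output is deterministic: identical inputs produce
    byte-identical files.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    tri_vals = field.values[mesh.triangles].mean(axis=1)
    if vmax is None:
        vmax = float(np.max(np.abs(field.values))) or 1.0
    # far-to-near along the viewing (x) axis
    depth = mesh.vertices[mesh.triangles, 0].mean(axis=1)
    view_sign = np.sign(depth.sum()) or 1.0
    order = np.argsort(view_sign * depth)
    polys = mesh.vertices[mesh.triangles][:, :, 1:]  # (y, z) projection

    fig, ax = plt.subplots(figsize=(4, 4))
    coll = PolyCollection(
        polys[order], array=tri_vals[order], cmap=cmap, edgecolors="none",
        antialiaseds=False,  # no seam blending: flat regions stay one color
    )
    coll.set_clim(-vmax, vmax)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(coll, ax=ax, shrink=0.7, label="ERSP (dB)")
    fig.savefig(out_path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
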