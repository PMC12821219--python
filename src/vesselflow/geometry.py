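"""Bottom-up domain reconstruction and surface-deviation validation.

The vessel graph is swept back into a voxel label field: the lumen is the
union of capsules (a cylinder per centerline segment plus spheres at the
segment ends, which removes seams at branch points), the endothelium is a
uniform-thickness shell around it, and everything else in the block is
porous interstitium. An implicit signed-distance construction replaces the
CAD Boolean sequence; the result is exactly what the flow solver consumes.

Reconstruction fidelity is validated by extracting iso-surfaces, rigidly
registering them (iterative closest point), and computing per-point
cloud-to-mesh distances with fraction-within-threshold summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure as _sk_measure

from .network import VesselGraph

# voxel labels
EXTERIOR, LUMEN, ENDOTHELIUM, INTERSTITIUM = 0, 1, 2, 3
LABEL_NAMES = {EXTERIOR: "exterior", LUMEN: "lumen",
               ENDOTHELIUM: "endothelium", INTERSTITIUM: "interstitium"}

# The endothelial monolayer thickness is taken uniform over the network;
# 5 um is a typical in vitro HUVEC monolayer figure and is configurable.
DEFAULT_ENDO_THICKNESS_UM = 5.0

FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass
class LabelField:
    """Voxel labels over a rectangular block plus boundary-face tags.

    ``labels`` is (nx, ny, nz) uint8 over {EXTERIOR, LUMEN, ENDOTHELIUM,
    INTERSTITIUM}; ``spacing`` is the isotropic voxel pitch in um;
    ``face_tags`` maps block faces ("x-", "x+", ...) to boundary-condition
    tag strings (e.g. "inlet"/"outlet").
    """
    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    face_tags: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def h(self) -> float:
        return float(self.spacing)

    def counts(self) -> dict:
        c = np.bincount(self.labels.ravel(), minlength=4)
        return {LABEL_NAMES[i]: int(c[i]) for i in range(4)}


@dataclass
class TriMesh:
    """Triangle surface mesh with vertices in micrometres."""
    vertices: np.ndarray
    faces: np.ndarray
    watertight: bool = False

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)


@dataclass
class RigidTransform:
    rotation: np.ndarray            # 3x3
    translation: np.ndarray         # (3,)
    scale: float                    # uniform pre-scale applied before R, t
    rms: float
    converged: bool

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (self.scale * points) @ self.rotation.T + self.translation


@dataclass
class DeviationReport:
    distances: np.ndarray           # per source point, um
    thresholds: np.ndarray
    fractions: np.ndarray           # fraction_within(threshold)
    transform: RigidTransform | None
    rms_registration: float

    def fraction_within(self, d: float) -> float:
        return float(np.mean(self.distances <= d))


# --------------------------------------------------------------------------
# Capsule rasterization
# --------------------------------------------------------------------------

def _segment_distance_field(p0, p1, centers_axes, lo, hi):
    """Distance from voxel centers in box [lo, hi) to segment p0-p1.

    ``centers_axes`` are the per-axis center coordinate vectors of the full
    grid; only the sub-box is evaluated. Returns (dist, slices).
    """
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    X, Y, Z = np.meshgrid(centers_axes[0][sl[0]], centers_axes[1][sl[1]],
                          centers_axes[2][sl[2]], indexing="ij", copy=False)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.sqrt((X - p0[0])**2 + (Y - p0[1])**2 + (Z - p0[2])**2)
        return dist, sl
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
    np.clip(t, 0.0, 1.0, out=t)
    dist = np.sqrt((X - (p0[0] + t * d[0]))**2
                   + (Y - (p0[1] + t * d[1]))**2
                   + (Z - (p0[2] + t * d[2]))**2)
    return dist, sl


def _paint_capsules(target: np.ndarray, graph: VesselGraph, radius_pad: float,
                    spacing: float, origin: np.ndarray, tapered: bool,
                    extended_polys=None) -> None:
    """OR into ``target`` all voxels within (link radius + pad) of any
    centerline segment. Spheres at segment ends are implicit in the
    point-to-segment distance."""
    shape = np.array(target.shape)
    centers = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing
               for a in range(3)]
    for lk in graph.links:
        poly = (extended_polys or {}).get(lk.id, lk.polyline)
        if tapered and lk.point_radii is not None and \
                len(lk.point_radii) == len(lk.polyline):
            radii = np.asarray(lk.point_radii, float)
        else:
            radii = np.full(len(poly), float(lk.radius))
        if len(radii) != len(poly):
            radii = np.full(len(poly), float(lk.radius))
        for i in range(len(poly) - 1):
            p0, p1 = poly[i], poly[i + 1]
            r = max(radii[i], radii[min(i + 1, len(radii) - 1)]) + radius_pad
            lo = np.minimum(p0, p1) - r - spacing
            hi = np.maximum(p0, p1) + r + spacing
            ilo = np.clip(np.floor((lo - origin) / spacing).astype(int),
                          0, shape)
            ihi = np.clip(np.ceil((hi - origin) / spacing).astype(int),
                          0, shape)
            if np.any(ihi <= ilo):
                continue
            dist, sl = _segment_distance_field(p0, p1, centers, ilo, ihi)
            target[sl] |= dist <= r


def rasterize_lumen(graph: VesselGraph, block_extent, resolution: float,
                    origin=(0, 0, 0), tapered: bool = False) -> np.ndarray:
    """Boolean occupancy of the capsule-union lumen on a fresh grid."""
    shape = np.maximum(1, np.round(np.asarray(block_extent, float)
                                   / resolution).astype(int))
    out = np.zeros(tuple(shape), bool)
    _paint_capsules(out, graph, 0.0, resolution, np.asarray(origin, float),
                    tapered)
    return out


def build_label_field(graph: VesselGraph, block_extent, t_endo: float =
                      DEFAULT_ENDO_THICKNESS_UM, resolution: float = 1.0,
                      face_tags: dict | None = None,
                      open_faces: tuple = (), tapered: bool = False,
                      origin=(0, 0, 0)) -> LabelField:
    """Rebuild the computational domain from the vessel graph.

    LUMEN is the union of capsules (cylinder of radius r per segment plus
    spheres at link ends); ENDOTHELIUM is the r + t_endo capsule union
    minus the lumen; the rest of the block is INTERSTITIUM. Links whose
    end node lies within one radius of a face listed in ``open_faces``
    (or any tagged face if ``open_faces`` is empty but ``face_tags`` is
    given) are extended through that face so the lumen opens without an
    endothelial cap.
    """
    if t_endo <= 0:
        raise ValueError("endothelial thickness must be positive")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    block_extent = np.asarray(block_extent, float)
    origin = np.asarray(origin, float)
    for lk in graph.links:
        if not (lk.radius > 0):
            raise ValueError(f"link {lk.id} has non-positive radius")
        if lk.radius < resolution:
            raise ValueError(
                f"resolution {resolution} um is coarser than the radius "
                f"{lk.radius:.3g} um of link {lk.id}; its lumen would vanish")
    face_tags = dict(face_tags or {})
    if not open_faces and face_tags:
        open_faces = tuple(face_tags)

    # extend polylines of links ending near an open face through that face
    ext = {}
    for lk in graph.links:
        poly = lk.polyline
        for end in (0, -1):
            pt = poly[0] if end == 0 else poly[-1]
            for f in open_faces:
                ax = "xyz".index(f[0])
                fpos = origin[ax] if f[1] == "-" else origin[ax] + \
                    block_extent[ax]
                if abs(pt[ax] - fpos) <= lk.radius + resolution:
                    tang = (poly[0] - poly[1]) if end == 0 \
                        else (poly[-1] - poly[-2])
                    n = np.linalg.norm(tang)
                    tang = tang / n if n > 0 else np.eye(3)[ax] * \
                        (-1 if f[1] == "-" else 1)
                    new_pt = pt + tang * (t_endo + lk.radius + 2 * resolution)
                    p = poly.copy()
                    if end == 0:
                        p = np.vstack([new_pt, p])
                    else:
                        p = np.vstack([p, new_pt])
                    poly = p
        if poly is not lk.polyline:
            ext[lk.id] = poly

    shape = tuple(np.maximum(1, np.round(block_extent /
                                         resolution).astype(int)))
    lumen = np.zeros(shape, bool)
    shell = np.zeros(shape, bool)
    _paint_capsules(lumen, graph, 0.0, resolution, origin, tapered, ext)
    _paint_capsules(shell, graph, float(t_endo), resolution, origin,
                    tapered, ext)
    labels = np.full(shape, INTERSTITIUM, np.uint8)
    labels[shell] = ENDOTHELIUM
    labels[lumen] = LUMEN
    return LabelField(labels, float(resolution), origin, face_tags)


# --------------------------------------------------------------------------
# Surfaces
# --------------------------------------------------------------------------

def extract_surface(field_or_mask, label: int | None = None,
                    spacing: float | None = None, origin=None,
                    smooth_sigma: float = 1.0) -> TriMesh:
    """Marching-cubes iso-surface (0.5 occupancy) of a label region.

    Accepts a :class:`LabelField` plus label, or a boolean array plus
    spacing. The occupancy is smoothed with a ``smooth_sigma``-voxel
    Gaussian before contouring, which removes the blocky 45-degree
    faceting of a raw binary iso-surface (a staircase sphere otherwise
    overestimates area by ~9%); if smoothing erases a very small label
    the raw binary surface is used instead. Vertices are in physical
    micrometres (voxel centers at ``(i + 0.5) * h``).
    """
    from scipy import ndimage as _ndi

    if isinstance(field_or_mask, LabelField):
        if label is None:
            raise ValueError("label required for a LabelField")
        occ = field_or_mask.labels == label
        h = field_or_mask.h
        org = field_or_mask.origin
        if not occ.any():
            raise ValueError(f"label {label} absent from field")
    else:
        occ = np.asarray(field_or_mask, bool)
        if not occ.any():
            raise ValueError("empty mask has no surface")
        h = float(spacing)
        org = np.zeros(3) if origin is None else np.asarray(origin, float)
    pad = max(2, int(np.ceil(2 * smooth_sigma)))
    vol = np.pad(occ, pad).astype(np.float32)
    if smooth_sigma > 0:
        smoothed = _ndi.gaussian_filter(vol, smooth_sigma)
        if smoothed.max() > 0.5:
            vol = smoothed
    verts, faces, _, _ = _sk_measure.marching_cubes(vol, level=0.5)
    verts = (verts - pad + 0.5) * h + org
    tm = trimesh.Trimesh(verts, faces, process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                   watertight=bool(tm.is_watertight))


def save_stl(mesh: TriMesh, path, unit: str = "um") -> None:
    """Export as STL; the length unit is recorded in the sidecar name."""
    mesh.as_trimesh().export(str(path))


def load_stl(path) -> TriMesh:
    tm = trimesh.load_mesh(str(path))
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                   watertight=bool(tm.is_watertight))


# --------------------------------------------------------------------------
# Registration (ICP) and deviation
# --------------------------------------------------------------------------

def _as_points(obj, n: int, seed: int) -> np.ndarray:
    if isinstance(obj, TriMesh):
        pts, _ = trimesh.sample.sample_surface(
            obj.as_trimesh(), n, seed=seed)
        return np.asarray(pts, float)
    return np.asarray(obj, float)


def register_rigid(source, reference: TriMesh, rms_tol: float = 1e-5,
                   prescale: float | None = None, max_iter: int = 100,
                   n_samples: int = 4000, seed: int = 0) -> RigidTransform:
    """Iterative-closest-point rigid alignment of source onto reference.

    An optional known uniform ``prescale`` (e.g. a pixel-to-um factor) is
    applied to the source first. Each iteration matches source points to
    their nearest reference-surface samples and solves the best rigid
    transform in closed form (SVD); iteration stops when the RMS distance
    improves by less than ``rms_tol``.
    """
    src = _as_points(source, n_samples, seed)
    if src.size == 0:
        raise ValueError("empty source")
    scale = float(prescale) if prescale else 1.0
    src = src * scale
    ref_pts = _as_points(reference, max(4 * n_samples, 20000), seed + 1)
    if ref_pts.size == 0:
        raise ValueError("empty reference")
    tree = cKDTree(ref_pts)

    R = np.eye(3)
    t = np.zeros(3)
    cur = src.copy()
    prev_rms = np.inf
    converged = False
    rms = np.inf
    for _ in range(max_iter):
        d, idx = tree.query(cur)
        rms = float(np.sqrt(np.mean(d**2)))
        if prev_rms - rms < rms_tol:
            converged = True
            break
        prev_rms = rms
        tgt = ref_pts[idx]
        mu_s, mu_t = cur.mean(0), tgt.mean(0)
        H = (cur - mu_s).T @ (tgt - mu_t)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R_step = Vt.T @ D @ U.T
        t_step = mu_t - R_step @ mu_s
        cur = cur @ R_step.T + t_step
        R = R_step @ R
        t = R_step @ t + t_step
    if not converged:
        import warnings
        warnings.warn("ICP did not converge within max_iter; returning "
                      "best transform")
    return RigidTransform(R, t, scale, rms, converged)


def _point_mesh_distances(points: np.ndarray, mesh: TriMesh,
                          k: int = 8) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface.

    Candidate triangles are found by a KD-tree over triangle centroids;
    the exact point-triangle distance is then evaluated on the candidates.
    """
    tm = mesh.as_trimesh()
    tris = tm.triangles                      # (m, 3, 3)
    centroids = tris.mean(axis=1)
    # guard k against tiny meshes
    k = int(min(k, len(tris)))
    tree = cKDTree(centroids)
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    if idx.ndim == 1:
        idx = idx[:, None]
    n, kk = idx.shape
    flat_tris = tris[idx.ravel()]
    flat_pts = np.repeat(points, kk, axis=0)
    closest = trimesh.triangles.closest_point(flat_tris, flat_pts)
    d = np.linalg.norm(closest - flat_pts, axis=1).reshape(n, kk)
    return d.min(axis=1)


def cloud_to_mesh_deviation(source_points, reference: TriMesh,
                            thresholds=(25.0,), register: bool = False,
                            rms_tol: float = 1e-5,
                            prescale: float | None = None) -> DeviationReport:
    """Per-point unsigned distance to the reference surface.

    With ``register=True`` the cloud is first rigidly aligned by ICP.
    Returns the distances (a per-point heat-map scalar), the
    fraction-within value for each threshold, and the transform used.
    """
    pts = np.asarray(source_points, float)
    if pts.size == 0:
        raise ValueError("empty point cloud")
    transform = None
    rms = np.nan
    if register:
        transform = register_rigid(pts, reference, rms_tol=rms_tol,
                                   prescale=prescale)
        pts = transform.apply(pts)
        rms = transform.rms
    d = _point_mesh_distances(pts, reference)
    thr = np.asarray(thresholds, float)
    fr = np.array([np.mean(d <= t) for t in thr])
    return DeviationReport(d, thr, fr, transform, rms)
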