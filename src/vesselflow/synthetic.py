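"""Synthetic fixtures with known ground truth for every pipeline stage.

Generates procedural branching vessel graphs spanning an inlet to an
outlet face, rasterizes them into blurred, noisy fluorescence-like image
stacks (emulating dextran-filled lumens with radii in the 5-40 um regime
of self-assembled microvascular networks), produces permeability
timelapses whose gel intensity rises at the slope implied by a known P_D,
and renders bead movies advected through a solved flow field. Every
generator is a pure function of its configuration and seed, and always
returns the ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .beads import Track, TrackSet
from .imaging import BinaryMask, ImageStack
from .network import Link, Node, VesselGraph, measure_links
from .geometry import rasterize_lumen
from .permeability import TimelapseStack


@dataclass
class SynthConfig:
    """Conditions for the synthetic network generator.

    Defaults emulate the imaged devices: a few-hundred-micron tissue
    chamber, ~20 vessel segments with radii 5-20 um (diameters up to the
    observed 20-40 um), mild tortuosity, 2 um optical blur, and 5 %
    additive intensity noise.
    """
    seed: int = 0
    extents: tuple = (400.0, 200.0, 200.0)   # um
    n_links: int = 20
    radius_range: tuple = (5.0, 20.0)        # um
    wavy_fraction: float = 0.3
    wave_amplitude_range: tuple = (0.05, 0.22)  # lateral amp / chord length
    blur_sigma: float = 2.0                  # um
    noise_sigma: float = 0.05                # fraction of vessel contrast
    shot_noise: bool = False
    branch_prob: float = 0.6
    segment_length_range: tuple = (60.0, 110.0)  # um
    clearance: float = 4.0                   # um kept between vessel walls

    def __post_init__(self):
        if self.radius_range[0] <= 0:
            raise ValueError("radii must be positive")


# --------------------------------------------------------------------------
# Procedural vessel graphs
# --------------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _lateral_basis(d):
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    b1 = _unit(np.cross(d, ref))
    b2 = _unit(np.cross(d, b1))
    return b1, b2


def _wavy_polyline(p0, p1, amp_frac, rng, n_pts=24):
    """Half-sine lateral offset between p0 and p1 (endpoints fixed)."""
    d = p1 - p0
    L = np.linalg.norm(d)
    b1, b2 = _lateral_basis(_unit(d))
    phi = rng.uniform(0, 2 * np.pi)
    lateral = np.cos(phi) * b1 + np.sin(phi) * b2
    t = np.linspace(0, 1, n_pts)
    return p0 + t[:, None] * d + (amp_frac * L * np.sin(np.pi * t))[:, None] \
        * lateral


def random_vessel_graph(config: SynthConfig) -> VesselGraph:
    """Grow a branching tree from the x- face toward the x+ face.

    Parent radii are always >= child radii; candidate segments keep a
    clearance to non-adjacent existing segments (rejection sampling with
    a bounded number of retries, after which the tip terminates). The
    main path is extended so the network spans inlet to outlet face.
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    ex = np.asarray(config.extents, float)
    rmin, rmax = config.radius_range
    margin = rmax + config.clearance

    nodes: dict[int, Node] = {}
    links: list[Link] = []
    occupied: list[tuple[np.ndarray, float, int, int]] = []
    # (sample points, radius, node_a, node_b) per accepted segment

    def add_node(pos):
        nid = len(nodes)
        nodes[nid] = Node(nid, np.asarray(pos, float), "terminal")
        return nid

    def clearance_ok(poly, radius, parent_node):
        for pts, r_o, na, nb in occupied:
            if parent_node in (na, nb):
                continue
            dmin = np.min(np.linalg.norm(
                poly[:, None, :] - pts[None, :, :], axis=2))
            if dmin < radius + r_o + config.clearance:
                return False
        return True

    def add_link(parent_node, poly, radius):
        nid = add_node(poly[-1])
        lk = Link(len(links), parent_node, nid, poly.copy(), radius=radius)
        links.append(lk)
        # resample for clearance checks
        seg = np.diff(poly, axis=0)
        slen = np.linalg.norm(seg, axis=1)
        samples = [poly[0]]
        for i in range(len(seg)):
            n = max(1, int(slen[i] // 5))
            tt = np.linspace(0, 1, n + 1)[1:]
            samples.extend(poly[i] + t * seg[i] for t in tt)
        occupied.append((np.array(samples), radius, parent_node, nid))
        return nid

    if config.n_links == 1:
        a = add_node([0.0, ex[1] / 2, ex[2] / 2])
        b = add_node([ex[0], ex[1] / 2, ex[2] / 2])
        r = float(np.mean(config.radius_range))
        links.append(Link(0, a, b, np.array([nodes[a].position,
                                             nodes[b].position]), radius=r))
    else:
        root = add_node([0.0, ex[1] / 2, ex[2] / 2])
        # (node_id, direction, radius, is_main_path)
        tips = [(root, np.array([1.0, 0.0, 0.0]), float(rmax), True)]
        revivals = 0
        while len(links) < config.n_links and (tips or revivals < 20):
            if not tips:
                # re-activate a random interior terminal to finish the budget
                revivals += 1
                ends = [lk for lk in links
                        if lk.polyline[-1][0] < ex[0] - margin]
                if not ends:
                    break
                src = ends[int(rng.integers(len(ends)))]
                r_par = src.radius
                d0 = _unit(src.polyline[-1] - src.polyline[-2])
                tips.append((src.node_b, d0,
                             max(rmin, r_par * rng.uniform(0.72, 0.95)),
                             False))
            tips.sort(key=lambda t: (not t[3], t[0]))
            node_id, direction, radius, main = tips.pop(0)
            pos = nodes[node_id].position
            placed = None
            for attempt in range(12):
                L = rng.uniform(*config.segment_length_range)
                jitter = rng.normal(0, 0.35, 3) if attempt else \
                    rng.normal(0, 0.2, 3)
                d = _unit(direction + jitter * (not main or attempt > 0))
                if d[0] < 0.15:          # keep marching toward the outlet
                    d = _unit(d + np.array([0.6, 0, 0]))
                end = pos + d * L
                end[1] = np.clip(end[1], margin, ex[1] - margin)
                end[2] = np.clip(end[2], margin, ex[2] - margin)
                reached_outlet = end[0] >= ex[0] - margin
                if reached_outlet:
                    end[0] = ex[0]
                if np.linalg.norm(end - pos) < 2 * radius:
                    continue
                if rng.uniform() < config.wavy_fraction and not reached_outlet:
                    amp = rng.uniform(*config.wave_amplitude_range)
                    poly = _wavy_polyline(pos, end, amp, rng)
                else:
                    poly = np.array([pos, end])
                if clearance_ok(poly[1:], radius, node_id):
                    placed = (poly, reached_outlet)
                    break
            if placed is None:
                continue                # tip dies; its node stays terminal
            poly, reached_outlet = placed
            child = add_link(node_id, poly, radius)
            if reached_outlet:
                continue
            budget = config.n_links - len(links)
            want_branch = (rng.uniform() < config.branch_prob
                           and budget >= 2 and len(tips) < budget)
            newd = _unit(poly[-1] - poly[-2])
            if want_branch:
                b1, b2 = _lateral_basis(newd)
                ang = rng.uniform(0.35, 0.8)
                phi = rng.uniform(0, 2 * np.pi)
                lat = np.cos(phi) * b1 + np.sin(phi) * b2
                for sgn, is_main in ((1.0, main), (-1.0, False)):
                    cd = _unit(newd + sgn * np.tan(ang) * lat)
                    cr = max(rmin, radius * rng.uniform(0.72, 0.95))
                    tips.append((child, cd, cr, is_main))
            else:
                cr = max(rmin, radius * rng.uniform(0.85, 1.0))
                tips.append((child, newd, cr, main))
        # guarantee the main path reaches the outlet face
        if not any(abs(lk.polyline[-1][0] - ex[0]) < 1e-6 for lk in links):
            far = max(links, key=lambda lk: lk.polyline[-1][0])
            endnode = nodes[far.node_b]
            tgt = endnode.position.copy()
            tgt[0] = ex[0]
            far.polyline = np.vstack([far.polyline, tgt])
            endnode.position = tgt

    # node kinds from degree
    deg = {nid: 0 for nid in nodes}
    for lk in links:
        deg[lk.node_a] += 1
        deg[lk.node_b] += 1
    for nid, n in nodes.items():
        n.kind = "branch" if deg[nid] >= 3 else "terminal"
    g = VesselGraph(nodes, links)
    measure_links(g)
    g.validate()
    return g


def poiseuille_tube_field(radius: float = 20.0, length: float = 400.0,
                          cells_per_diameter: int = 16, axis: int = 2,
                          pad_cells: int = 2):
    """Voxelized straight impermeable tube for closed-form flow checks.

    The tube is a circular lumen along ``axis`` in an EXTERIOR (solid)
    block; the two end faces are tagged inlet/outlet. The axial cell
    count is ``round(L/h) - 1`` so that the ghost-cell boundary pressures
    span exactly the physical length ``length``.
    """
    from .geometry import EXTERIOR, LUMEN, LabelField

    h = 2.0 * radius / cells_per_diameter
    n_ax = int(round(length / h)) - 1
    n_cross = int(np.ceil(2 * radius / h)) + 2 * pad_cells
    c = n_cross * h / 2.0
    x = (np.arange(n_cross) + 0.5) * h
    A, B = np.meshgrid(x, x, indexing="ij")
    disc = (A - c) ** 2 + (B - c) ** 2 <= radius**2
    shape = [n_cross, n_cross, n_cross]
    shape[axis] = n_ax
    labels = np.full(shape, EXTERIOR, np.uint8)
    sl = [slice(None)] * 3
    for i in range(n_ax):
        sl[axis] = i
        labels[tuple(sl)][disc] = LUMEN
    name = "xyz"[axis]
    return LabelField(labels, h,
                      face_tags={f"{name}-": "inlet", f"{name}+": "outlet"})


def darcy_slab_field(kappa: float = 1e-12, length: float = 1000.0,
                     cross_cells: int = 8, resolution: float = 50.0):
    """Homogeneous porous slab with pressure faces along x.

    Returns ``(LabelField, MaterialProps, BoundaryConditions)`` set up so
    the analytic superficial velocity is kappa dP / (mu L).
    """
    from .flow import (BoundaryConditions, MaterialProps, MU_MEDIA,
                       EPS_POROUS, RegionProps)
    from .geometry import INTERSTITIUM, LabelField

    nx = int(round(length / resolution)) - 1
    labels = np.full((nx, cross_cells, cross_cells), INTERSTITIUM, np.uint8)
    field = LabelField(labels, resolution,
                       face_tags={"x-": "inlet", "x+": "outlet"})
    props = MaterialProps(regions={
        INTERSTITIUM: RegionProps(EPS_POROUS, kappa, MU_MEDIA)})
    bcs = BoundaryConditions({"inlet": {INTERSTITIUM: 1.0},
                              "outlet": {INTERSTITIUM: 0.0}})
    return field, props, bcs


def two_channel_phantom(extent=(300.0, 150.0, 100.0), resolution: float = 5.0,
                        channel_radius: float = 25.0, rung_radius: float = 15.0,
                        n_rungs: int = 3, t_endo: float = 5.0):
    """Small two-parent-channel grid phantom for scenario comparisons.

    Two parent channels run the length of the block and are bridged by
    ``n_rungs`` smaller vessels, emulating the ladder-like device used to
    set inlet pressure conditions: media enters at the x- face (vessel
    and interstitial pressures), exits at x+. Returns
    ``(VesselGraph, LabelField)`` with endothelium and interstitium.
    """
    ex = np.asarray(extent, float)
    y_lo, y_hi = 0.25 * ex[1], 0.75 * ex[1]
    z_mid = ex[2] / 2
    nodes: dict[int, Node] = {}
    links: list[Link] = []

    def node(pos):
        nid = len(nodes)
        nodes[nid] = Node(nid, np.asarray(pos, float), "branch")
        return nid

    xs = np.linspace(0, ex[0], n_rungs + 2)
    top = [node([x, y_hi, z_mid]) for x in xs]
    bot = [node([x, y_lo, z_mid]) for x in xs]
    for row in (top, bot):
        for a, b in zip(row[:-1], row[1:]):
            links.append(Link(len(links), a, b,
                              np.array([nodes[a].position,
                                        nodes[b].position]),
                              radius=channel_radius))
    for i in range(1, n_rungs + 1):
        a, b = top[i], bot[i]
        links.append(Link(len(links), a, b,
                          np.array([nodes[a].position, nodes[b].position]),
                          radius=rung_radius))
    g = VesselGraph(nodes, links)
    measure_links(g)
    from .geometry import build_label_field
    field = build_label_field(g, ex, t_endo=t_endo, resolution=resolution,
                              face_tags={"x-": "inlet", "x+": "outlet"})
    return g, field


# --------------------------------------------------------------------------
# Ground-truth comparison helpers
# --------------------------------------------------------------------------

def _centerline_samples(graph: VesselGraph, step: float = 1.0):
    pts, lids = [], []
    for lk in graph.links:
        poly = lk.polyline
        seg = np.diff(poly, axis=0)
        slen = np.linalg.norm(seg, axis=1)
        for i in range(len(seg)):
            n = max(2, int(np.ceil(slen[i] / step)))
            t = np.linspace(0, 1, n)
            pts.append(poly[i] + t[:, None] * seg[i])
            lids.append(np.full(n, lk.id))
    return np.vstack(pts), np.concatenate(lids)


def radius_recovery(truth: VesselGraph, extracted: VesselGraph,
                    max_match_dist: float = 8.0,
                    min_points: int = 5):
    """Pair extracted per-point radii with the ground-truth link radii.

    Each interior centerline point of the extracted graph (end fifths
    trimmed, where junction geometry dominates) is assigned to the
    nearest ground-truth centerline sample within ``max_match_dist`` um;
    the per-truth-link estimate is the mean of its assigned point radii.
    Returns an (n, 2) array of (true radius, estimated radius) pairs --
    the desk analog of validating computed diameters against manual
    cross-section measurements.
    """
    from scipy.spatial import cKDTree

    tp, tl = _centerline_samples(truth)
    tree = cKDTree(tp)
    true_r = {lk.id: lk.radius for lk in truth.links}
    est: dict = {lk.id: [] for lk in truth.links}
    for lk in extracted.links:
        if lk.point_radii is None:
            continue
        poly = lk.polyline
        pr = lk.point_radii
        n = min(len(poly), len(pr))
        lo = int(0.2 * n)
        hi = max(lo + 1, int(0.8 * n))
        d, i = tree.query(poly[lo:hi])
        for dd, ii, rr in zip(d, i, pr[lo:hi]):
            if dd < max_match_dist:
                est[tl[ii]].append(rr)
    return np.array([(true_r[k], float(np.mean(v)))
                     for k, v in est.items() if len(v) >= min_points])


# --------------------------------------------------------------------------
# Rasterization into image stacks
# --------------------------------------------------------------------------

def rasterize_graph(graph: VesselGraph, spacing: float = 1.0,
                    blur_sigma: float | None = None,
                    noise_sigma: float | None = None,
                    shot_noise: bool | None = None,
                    config: SynthConfig | None = None,
                    extents=None, rng=None):
    """Render a graph as a noisy fluorescence stack plus ground truth.

    Occupancy of the capsule union (vessel 1, background 0) is blurred
    with a Gaussian of ``blur_sigma`` um and corrupted with additive
    Gaussian noise of ``noise_sigma`` x contrast (optionally Poisson shot
    noise). Returns ``(ImageStack, BinaryMask)``.
    """
    config = config or SynthConfig()
    if blur_sigma is None:
        blur_sigma = config.blur_sigma
    if noise_sigma is None:
        noise_sigma = config.noise_sigma
    if shot_noise is None:
        shot_noise = config.shot_noise
    if rng is None:
        rng = np.random.default_rng(config.seed)
    min_r = min(lk.radius for lk in graph.links)
    if spacing > min_r:
        raise ValueError(f"spacing {spacing} um exceeds the smallest link "
                         f"radius {min_r:.3g} um")
    if extents is None:
        pts = np.vstack([lk.polyline for lk in graph.links])
        rmax = max(lk.radius for lk in graph.links)
        extents = pts.max(axis=0) + rmax + 2 * spacing
    occ = rasterize_lumen(graph, extents, spacing)
    truth = BinaryMask(occ, np.full(3, spacing))
    img = occ.astype(float)
    if blur_sigma:
        img = ndimage.gaussian_filter(img, blur_sigma / spacing)
    if shot_noise and noise_sigma:
        gain = 1.0 / noise_sigma**2        # relative sigma at full contrast
        img = rng.poisson(np.clip(img, 0, None) * gain) / gain
    elif noise_sigma:
        img = img + rng.normal(0, noise_sigma, img.shape)
    return ImageStack(img, np.full(3, spacing)), truth


# --------------------------------------------------------------------------
# Permeability timelapses
# --------------------------------------------------------------------------

def synth_permeability_timelapse(Pd_true: float, r_vessel: float = 80.0,
                                 I_vessel: float = 1000.0,
                                 times=None, noise_sigma: float = 0.0,
                                 shot_noise: bool = False,
                                 shape=(120, 120), seed: int = 0
                                 ) -> TimelapseStack:
    """Frames whose gel intensity rises at the slope implied by ``Pd_true``.

    The left strip of each frame is the vessel at ``I_vessel``; the rest
    is gel whose mean intensity follows
    ``I_gel(t) = (2 P_D / r) I_vessel t`` (r in metres). Noise is
    additive Gaussian of ``noise_sigma * I_vessel`` per pixel, or Poisson
    with matched relative magnitude when ``shot_noise`` is set.
    """
    if Pd_true < 0:
        raise ValueError("Pd_true must be non-negative")
    if times is None:
        times = np.arange(0.0, 121.0, 10.0)   # imaged every 10 s for 2 min
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    rng = np.random.default_rng(seed)
    nx, ny = shape
    strip = nx // 4
    vessel_mask = np.zeros(shape, bool)
    vessel_mask[:strip] = True
    gel_mask = np.zeros(shape, bool)
    gel_mask[strip + 2:] = True

    r_m = r_vessel * 1e-6
    slope = 2.0 * Pd_true / r_m * I_vessel
    frames = np.empty((len(times),) + tuple(shape))
    for i, t in enumerate(times):
        f = np.zeros(shape)
        f[vessel_mask] = I_vessel
        f[gel_mask] = slope * t
        if shot_noise and noise_sigma:
            gain = 1.0 / (noise_sigma**2 * I_vessel)
            f = rng.poisson(np.clip(f, 0, None) * gain) / gain
        elif noise_sigma:
            f = f + rng.normal(0, noise_sigma * I_vessel, shape)
        frames[i] = f
    return TimelapseStack(frames, times, vessel_mask, gel_mask, r_vessel)


# --------------------------------------------------------------------------
# Bead movies
# --------------------------------------------------------------------------

def synth_bead_movie(flow, n_beads: int = 50, dt: float = 0.1,
                     n_frames: int = 10, loc_noise: float = 0.0,
                     bead_diameter: float = 10.0, image_spacing: float = 2.0,
                     seed: int = 0, speed_scale=None):
    """Advect beads through a solved field and render projection frames.

    Beads are seeded at random lumen voxels, advected with RK4 sub-steps
    of the interpolated velocity field, and rendered into 2D (x, y)
    maximum-projection frames as Gaussian blobs of ``bead_diameter``.
    ``loc_noise`` (um) jitters the rendered positions to emulate
    localization error. ``speed_scale`` optionally scales the field per
    frame (e.g. a decaying reservoir head). Returns
    ``(frames, TrackSet ground truth)``.
    """
    from .flow import velocity_interpolator
    from .geometry import LUMEN

    if n_beads <= 0:
        raise ValueError("n_beads must be positive")
    rng = np.random.default_rng(seed)
    labels = flow.labels
    h = labels.h
    lumen_idx = np.argwhere(labels.labels == LUMEN)
    if len(lumen_idx) == 0:
        raise ValueError("field has no lumen to seed beads in")
    pick = rng.choice(len(lumen_idx), size=n_beads, replace=True)
    pos = (lumen_idx[pick] + rng.uniform(0.3, 0.7, (n_beads, 3))) * h \
        + labels.origin
    vfun = velocity_interpolator(flow)
    extent = np.array(labels.shape) * h
    scale = np.ones(n_frames) if speed_scale is None \
        else np.asarray(speed_scale, float)

    nsub = 4
    traj = np.empty((n_frames, n_beads, 3))
    for fi in range(n_frames):
        traj[fi] = pos
        sub_dt = dt / nsub
        for _ in range(nsub):
            k1 = vfun(pos) * 1e6 * scale[fi]
            k2 = vfun(pos + 0.5 * sub_dt * k1) * 1e6 * scale[fi]
            k3 = vfun(pos + 0.5 * sub_dt * k2) * 1e6 * scale[fi]
            k4 = vfun(pos + sub_dt * k3) * 1e6 * scale[fi]
            pos = pos + sub_dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            pos = np.clip(pos, labels.origin, labels.origin + extent - 1e-9)

    # ground-truth 2D tracks
    tracks = []
    for b in range(n_beads):
        xy = traj[:, b, :2]
        tracks.append(Track(b, np.arange(n_frames), xy.copy(),
                            np.arange(n_frames) * dt))
    truth = TrackSet(tracks)

    # render projections: Gaussian blobs at true sub-pixel positions
    npx = np.ceil(extent[:2] / image_spacing).astype(int)
    sigma = bead_diameter / 4.0            # um
    win = int(np.ceil(3 * sigma / image_spacing))
    frames = np.zeros((n_frames, npx[0], npx[1]))
    for fi in range(n_frames):
        img = frames[fi]
        draw = traj[fi, :, :2] - labels.origin[:2]
        if loc_noise:
            draw = draw + rng.normal(0, loc_noise, draw.shape)
        for p in draw:
            c = (p / image_spacing - 0.5).astype(int)
            lo = np.maximum(c - win, 0)
            hi = np.minimum(c + win + 1, npx)
            if np.any(hi <= lo):
                continue
            gx = (np.arange(lo[0], hi[0]) + 0.5) * image_spacing
            gy = (np.arange(lo[1], hi[1]) + 0.5) * image_spacing
            X, Y = np.meshgrid(gx, gy, indexing="ij")
            img[lo[0]:hi[0], lo[1]:hi[1]] += 100.0 * np.exp(
                -((X - p[0]) ** 2 + (Y - p[1]) ** 2) / (2 * sigma**2))
    return frames, truth
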