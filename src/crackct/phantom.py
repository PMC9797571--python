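"""Synthetic tooth phantoms with known crack ground truth.

A phantom emulates a premolar crown in a micro-CT data-cube: a half-ellipsoid
enamel shell over a dentin core with a pulp cavity, carved by a star-shaped
network of thin planar cracks plus isolated near-surface cracks, rendered to
16-bit attenuation with partial-volume averaging, Gaussian noise, and optional
scan artifacts. Every phantom comes with voxelwise ground-truth labels, the
crack-free twin labelling, the crack plane normals, and the realised
connected-network volume fraction, so all downstream stages can be validated
against known truth.

Geometric conventions: arrays are (z, y, x), z is the vertical tooth axis,
the crown base sits at low z and the cusp at high z. Crown radii are unequal
in x and y so the cross-section has the convex-buccal / flatter-contact
asymmetry that sector detection relies on.

Densities follow measured tooth tissue (enamel 2.61-2.77 g/cm^3, dentin
1.79-2.12 g/cm^3); grey level is linear in density with mean enamel mapped
near 60% of the 16-bit range. Crack widths span ~0.3-30 um, i.e. mostly below
one voxel at the coarse synthetic pitch: sub-voxel cracks dim a voxel in
proportion to the volume they occupy rather than blacking it out, and a voxel
is ground-truth crack only when the crack occupies at least half of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_volumes import AIR, CRACK, DENTIN, ENAMEL, GreyVolume, LabelVolume

#: Grey-mapping constant: mean enamel density (2.69 g/cm^3) -> 60% of 16-bit range.
GREY_PER_DENSITY = 0.60 * 65535 / 2.69

#: Ground-truth rule: a voxel is labelled crack when crack occupancy >= 1/2.
CRACK_LABEL_OCCUPANCY = 0.5


@dataclass
class CrackNetworkSpec:
    """Parameters of the crack population.

    The *primary* planes are vertical planar slabs that all contain the tooth
    axis (``connect_to_axis``), forming one connected star-shaped network;
    the depth of the occlusal band they span is calibrated so the network
    occupies ``target_volume_fraction`` of the hard-tissue volume. Isolated
    cracks are small planar disks, biased toward the outer surface, with
    widths sampled from ``widths_um``.
    """

    n_primary_planes: int = 4
    orientation_mode: str = "radial_two_perpendicular"  # or "random"
    plane_normals: list | None = None  # explicit unit normals, (z, y, x)
    widths_um: tuple[float, float] = (0.3, 30.0)
    connect_to_axis: bool = True
    n_isolated_cracks: int = 6
    isolated_depth_bias: float = 0.8
    target_volume_fraction: float | None = 0.02
    #: Slab width of the primary planes, in voxels (26 um at 20 um pitch).
    primary_width_vox: float = 1.3

    def __post_init__(self) -> None:
        if self.widths_um[0] <= 0 or self.widths_um[1] <= 0:
            raise ValueError("crack widths must be positive")
        if not 0.0 <= self.isolated_depth_bias <= 1.0:
            raise ValueError("isolated_depth_bias must be in [0, 1]")
        if self.target_volume_fraction is not None and not (
            0.0 < self.target_volume_fraction < 1.0
        ):
            raise ValueError("target_volume_fraction must be in (0, 1)")
        if self.plane_normals is not None:
            normed = []
            for n in self.plane_normals:
                v = np.asarray(n, dtype=float)
                nrm = np.linalg.norm(v)
                if nrm == 0:
                    raise ValueError("plane normals must be nonzero")
                normed.append(v / nrm)
            self.plane_normals = normed


@dataclass
class PhantomSpec:
    """Full parameterisation of one synthetic tooth data-cube."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_pitch_um: float = 20.0
    crown_height_mm: float = 2.16
    crown_radii_mm: tuple[float, float] = (1.15, 0.95)  # (x, y) semi-axes
    enamel_thickness_mm: tuple[float, float] = (0.30, 0.60)  # (cervical, cuspal)
    pulp_scale: float = 0.35
    enamel_density_g_cm3: tuple[float, float] = (2.61, 2.77)
    dentin_density_g_cm3: tuple[float, float] = (1.79, 2.12)
    crack_network: CrackNetworkSpec = field(default_factory=CrackNetworkSpec)
    noise_sd: float = 800.0
    cylinder_void: bool = False
    top_rays: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 dims of at least 16 voxels")
        if not self.voxel_pitch_um > 0:
            raise ValueError("voxel_pitch_um must be positive")
        lo, hi = self.enamel_thickness_mm
        if not (0.3 <= lo <= 3.0 and 0.3 <= hi <= 3.0):
            raise ValueError("enamel thickness must lie within [0.3, 3.0] mm")
        for rng_ in (self.enamel_density_g_cm3, self.dentin_density_g_cm3):
            if not rng_[0] <= rng_[1]:
                raise ValueError("density ranges must be non-empty (lo <= hi)")
        if not 0.0 < self.pulp_scale < 1.0:
            raise ValueError("pulp_scale must be in (0, 1)")
        nz, ny, nx = self.grid_shape
        p = self.voxel_pitch_um
        if self.crown_height_mm * 1000 / p > nz - 8:
            raise ValueError("crown height does not fit the grid (need ~8 voxel margin)")
        if self.crown_radii_mm[0] * 1000 / p > nx / 2 - 4 or \
           self.crown_radii_mm[1] * 1000 / p > ny / 2 - 4:
            raise ValueError("crown radii do not fit the grid")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom."""

    labels: LabelVolume
    labels_nocrack: LabelVolume
    crack_plane_normals: list[np.ndarray]
    connected_network_voxel_fraction: float
    network_mask: np.ndarray  # bool, the connected star network only


# ---------------------------------------------------------------------------
# geometry

def _crown_geometry(spec: PhantomSpec):
    """Return (labels_nocrack array, tissue mask, axis info) for the crack-free tooth."""
    nz, ny, nx = spec.grid_shape
    p = spec.voxel_pitch_um
    z_base = 4.0
    height = spec.crown_height_mm * 1000 / p
    rx0 = spec.crown_radii_mm[0] * 1000 / p
    ry0 = spec.crown_radii_mm[1] * 1000 / p
    cx = (nx - 1) / 2
    cy = (ny - 1) / 2

    z = np.arange(nz, dtype=float)[:, None, None]
    y = np.arange(ny, dtype=float)[None, :, None]
    x = np.arange(nx, dtype=float)[None, None, :]

    t = (z - z_base) / height  # normalised crown height
    in_crown = (t >= 0) & (t <= 1)
    shrink = np.sqrt(np.clip(1.0 - t**2, 0.0, None))  # half-ellipsoid taper
    rx_z = np.maximum(rx0 * shrink, 1e-9)
    ry_z = np.maximum(ry0 * shrink, 1e-9)

    dx = x - cx
    dy = y - cy
    outer = in_crown & ((dx / rx_z) ** 2 + (dy / ry_z) ** 2 <= 1.0)

    th_lo, th_hi = (v * 1000 / p for v in spec.enamel_thickness_mm)
    th = th_lo + (th_hi - th_lo) * np.clip(t, 0, 1)
    inner = in_crown & (
        ((dx / np.maximum(rx_z - th, 1e-9)) ** 2
         + (dy / np.maximum(ry_z - th, 1e-9)) ** 2 <= 1.0)
        & (rx_z - th > 0.5) & (ry_z - th > 0.5)
    )

    # pulp chamber: fully enclosed by dentin (root canals are out of frame)
    pz = z_base + 0.35 * height
    pulp = (
        (dx / (spec.pulp_scale * rx0)) ** 2
        + (dy / (spec.pulp_scale * ry0)) ** 2
        + ((z - pz) / (0.30 * height)) ** 2
    ) <= 1.0
    pulp &= inner  # enforce nesting

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[outer] = ENAMEL
    labels[inner] = DENTIN
    labels[pulp] = AIR  # pulp is black, indistinguishable from air in this scheme
    tissue = (labels == ENAMEL) | (labels == DENTIN)
    axis = dict(cx=cx, cy=cy, z_base=z_base, height=height, rx0=rx0, ry0=ry0,
                rx_z=rx_z, ry_z=ry_z, t=t, dx=dx, dy=dy, z=z)
    return labels, tissue, axis


def _slab_occupancy(dist: np.ndarray, width_vox: float) -> np.ndarray:
    """Partial-volume fraction of a voxel cut by a planar slab.

    ``dist`` is the distance (in voxel units) from the voxel centre to the
    slab mid-plane; the voxel is modelled as a unit interval along the slab
    normal, so occupancy is the overlap of [d-1/2, d+1/2] with the slab
    [-w/2, w/2].
    """
    w2 = width_vox / 2.0
    return np.clip(np.minimum(w2, dist + 0.5) - np.maximum(-w2, dist - 0.5), 0.0, 1.0)


def _primary_normals(net: CrackNetworkSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Unit normals (z, y, x) of the primary radial planes."""
    if net.plane_normals is not None:
        return [np.asarray(n, dtype=float) for n in net.plane_normals]
    if net.n_primary_planes == 0:
        return []
    if net.orientation_mode == "radial_two_perpendicular":
        theta0 = rng.uniform(0, np.pi)
        normals = []
        for i in range(net.n_primary_planes):
            base = theta0 + (np.pi / 2) * (i % 2)  # alternate the two families
            theta = base + np.deg2rad(rng.uniform(-7, 7))
            normals.append(np.array([0.0, np.sin(theta), np.cos(theta)]))
        return normals
    if net.orientation_mode == "random":
        thetas = rng.uniform(0, np.pi, size=net.n_primary_planes)
        return [np.array([0.0, np.sin(t), np.cos(t)]) for t in thetas]
    raise ValueError(f"unknown orientation_mode {net.orientation_mode!r}")


def _primary_occupancy(axis: dict, tissue: np.ndarray, normals: list[np.ndarray],
                       band_frac: float, width_vox: float) -> np.ndarray:
    """Occupancy field of the connected star network.

    The primary planes contain the tooth axis, span the full cross-section,
    and extend downward from just below the cusp over a fraction
    ``band_frac`` of the crown height — cracks grow in from the occlusal
    surface, and the axis crossing above the pulp chamber keeps the network
    connected at any band depth.
    """
    occ = np.zeros(tissue.shape, dtype=np.float32)
    if not normals:
        return occ
    dx, dy, z = axis["dx"], axis["dy"], axis["z"]
    r_out = np.sqrt((dx / axis["rx_z"]) ** 2 + (dy / axis["ry_z"]) ** 2)  # 1 at surface
    z_hi = axis["z_base"] + 0.97 * axis["height"]
    z_lo = z_hi - band_frac * 0.94 * axis["height"]
    in_extent = (r_out <= 1.0) & (z >= z_lo) & (z <= z_hi)
    z_mid = axis["z_base"] + 0.5 * axis["height"]
    for n in normals:
        # plane through the tooth-axis midpoint; for the usual horizontal
        # normals (n_z = 0) it contains the whole vertical axis
        dist = np.abs((z - z_mid) * n[0] + dy * n[1] + dx * n[2])
        np.maximum(occ, _slab_occupancy(dist, width_vox), out=occ, where=in_extent)
    occ[~tissue] = 0.0
    return occ


def _isolated_occupancy(spec: PhantomSpec, axis: dict, tissue: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    net = spec.crack_network
    occ = np.zeros(tissue.shape, dtype=np.float32)
    if net.n_isolated_cracks <= 0:
        return occ
    nz, ny, nx = tissue.shape
    p = spec.voxel_pitch_um
    zc_all, yc_all, xc_all = np.nonzero(tissue)
    if zc_all.size == 0:
        return occ
    zg = np.arange(nz, dtype=float)
    yg = np.arange(ny, dtype=float)
    xg = np.arange(nx, dtype=float)
    for _ in range(net.n_isolated_cracks):
        # pick a tissue voxel as centre, biased toward the outer surface
        for _attempt in range(20):
            i = rng.integers(zc_all.size)
            cz, cyv, cxv = zc_all[i], yc_all[i], xc_all[i]
            r_norm = np.sqrt(((cxv - axis["cx"]) / axis["rx_z"][cz, 0, 0]) ** 2
                             + ((cyv - axis["cy"]) / axis["ry_z"][cz, 0, 0]) ** 2)
            near_surface = r_norm >= 0.7
            if near_surface or rng.random() > net.isolated_depth_bias:
                break
        radius = rng.uniform(4.0, 10.0)  # voxels
        lo, hi = net.widths_um
        width_vox = np.exp(rng.uniform(np.log(lo), np.log(hi))) / p
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        m = int(np.ceil(radius + width_vox + 1))
        z0, z1 = max(0, cz - m), min(nz, cz + m + 1)
        y0, y1 = max(0, cyv - m), min(ny, cyv + m + 1)
        x0, x1 = max(0, cxv - m), min(nx, cxv + m + 1)
        dz = (zg[z0:z1] - cz)[:, None, None]
        dy = (yg[y0:y1] - cyv)[None, :, None]
        dx = (xg[x0:x1] - cxv)[None, None, :]
        dist = np.abs(dz * v[0] + dy * v[1] + dx * v[2])
        r2_inplane = dz**2 + dy**2 + dx**2 - dist**2
        local = _slab_occupancy(dist, width_vox)
        local[r2_inplane > radius**2] = 0.0
        region = occ[z0:z1, y0:y1, x0:x1]
        np.maximum(region, local.astype(np.float32), out=region)
    occ[~tissue] = 0.0
    return occ


# ---------------------------------------------------------------------------
# rendering

def render_attenuation(labels: LabelVolume, spec: PhantomSpec,
                       crack_occupancy: np.ndarray | None = None) -> GreyVolume:
    """Render a label volume to 16-bit attenuation.

    Grey value is linear in tissue density; a voxel partially occupied by
    crack is dimmed in proportion (a crack thinner than one voxel lowers,
    not zeroes, its voxel's value). Gaussian noise and the flagged scan
    artifacts are then applied. Without an occupancy field, crack-labelled
    voxels are rendered fully open (occupancy 1).
    """
    ss = np.random.SeedSequence([spec.rng_seed, 2])  # stream 2: densities+noise
    rng_density, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    rho_e = rng_density.uniform(*spec.enamel_density_g_cm3)
    rho_d = rng_density.uniform(*spec.dentin_density_g_cm3)

    lab = labels.data
    grey = np.zeros(lab.shape, dtype=np.float32)
    grey[lab == ENAMEL] = rho_e * GREY_PER_DENSITY
    grey[lab == DENTIN] = rho_d * GREY_PER_DENSITY
    if crack_occupancy is None:
        crack_occupancy = (lab == CRACK).astype(np.float32)
    elif (lab == CRACK).any():
        # crack voxels were carved from enamel/dentin; restore the host
        # tissue grey (nearest tissue voxel) before applying occupancy dimming
        from scipy import ndimage

        tissue_mask = (lab == ENAMEL) | (lab == DENTIN)
        idx = ndimage.distance_transform_edt(~tissue_mask, return_distances=False,
                                             return_indices=True)
        grey = np.where(lab == CRACK, grey[tuple(idx)], grey)
    grey = grey * (1.0 - np.clip(crack_occupancy, 0.0, 1.0))

    nz, ny, nx = lab.shape
    if spec.cylinder_void:
        cx = (nx - 1) / 2 + 0.55 * spec.crown_radii_mm[0] * 1000 / spec.voxel_pitch_um
        cy = (ny - 1) / 2
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        cyl = (xx - cx) ** 2 + (yy - cy) ** 2 <= 6.0**2
        grey[:, cyl] = 0.0
    if spec.top_rays:
        ztop = int(4 + spec.crown_height_mm * 1000 / spec.voxel_pitch_um)
        yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2,
                             np.arange(nx) - (nx - 1) / 2, indexing="ij")
        theta = np.arctan2(yy, xx)
        rays = 1500.0 * (1 + np.sin(8 * theta)) / 2
        grey[min(ztop, nz - 1):, :, :] += rays.astype(np.float32)

    if spec.noise_sd > 0:
        grey = grey + rng_noise.normal(0.0, spec.noise_sd, size=grey.shape)
    grey = np.clip(grey, 0, 65535)
    return GreyVolume(data=np.rint(grey).astype(np.uint16),
                      voxel_pitch_um=spec.voxel_pitch_um)


# ---------------------------------------------------------------------------
# top-level generation

def generate_phantom(spec: PhantomSpec) -> tuple[GreyVolume, PhantomTruth]:
    """Generate a phantom data-cube and its ground truth.

    Deterministic for a fixed ``spec.rng_seed``; independent RNG streams are
    used for crack placement and for densities/noise, so disabling the crack
    network leaves the tooth geometry and rendering identical.

    Raises
    ------
    RuntimeError
        If the primary network cannot reach ``target_volume_fraction``
        within the tooth.
    """
    rng_cracks = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    labels_nocrack, tissue, axis = _crown_geometry(spec)
    net = spec.crack_network

    normals = _primary_normals(net, rng_cracks)
    width_vox = net.primary_width_vox
    band_frac = 0.4
    occ_primary = np.zeros(spec.grid_shape, dtype=np.float32)
    n_tissue = int(tissue.sum())

    if normals:
        target = net.target_volume_fraction
        if target is None:
            band_frac = 1.0
            occ_primary = _primary_occupancy(axis, tissue, normals, band_frac, width_vox)
        else:
            # calibrate the occlusal band depth so the labelled network hits
            # the target; fraction grows nonlinearly with depth (the crown
            # tapers), so use a log-log secant update, falling back to width
            # growth once the band spans the whole crown
            achieved = 0.0
            history: list[tuple[float, float]] = []  # (log depth, log fraction)
            for _ in range(12):
                occ_primary = _primary_occupancy(axis, tissue, normals,
                                                 band_frac, width_vox)
                n_crack = int((occ_primary >= CRACK_LABEL_OCCUPANCY).sum())
                achieved = n_crack / max(n_tissue, 1)
                if achieved > 0 and abs(achieved / target - 1.0) <= 0.03:
                    break
                if band_frac >= 1.0 and 0 < achieved < target:
                    width_vox = min(width_vox * target / achieved, 2.5)
                    continue
                if achieved > 0:
                    history.append((np.log(band_frac), np.log(achieved)))
                if len(history) >= 2 and history[-1][0] != history[-2][0]:
                    (x0, y0), (x1, y1) = history[-2], history[-1]
                    slope = (y1 - y0) / (x1 - x0)
                    step = (np.log(target) - y1) / np.clip(slope, 0.3, 5.0)
                else:
                    step = np.log((target / achieved) if achieved > 0 else 2.0) / 1.5
                band_frac = float(np.clip(np.exp(np.log(band_frac) + step),
                                          0.03, 1.0))
            if achieved == 0 or abs(achieved / target - 1.0) > 0.10:
                raise RuntimeError(
                    f"crack network cannot reach target volume fraction {target} "
                    f"(achieved {achieved:.4f})")

    occ_isolated = _isolated_occupancy(spec, axis, tissue, rng_cracks)
    occ = np.maximum(occ_primary, occ_isolated)

    labels = labels_nocrack.copy()
    crack_vox = (occ >= CRACK_LABEL_OCCUPANCY) & tissue
    labels[crack_vox] = CRACK
    network_mask = (occ_primary >= CRACK_LABEL_OCCUPANCY) & tissue

    n_tooth = int(((labels == ENAMEL) | (labels == DENTIN) | (labels == CRACK)).sum())
    fraction = float(network_mask.sum() / max(n_tooth, 1))

    lv = LabelVolume(data=labels, voxel_pitch_um=spec.voxel_pitch_um)
    lv_nc = LabelVolume(data=labels_nocrack, voxel_pitch_um=spec.voxel_pitch_um)
    # render from the crack-free labels: the occupancy field alone carves the
    # cracks, giving correct partial-volume grey for sub-voxel widths
    grey = render_attenuation(lv_nc, spec, crack_occupancy=occ)
    truth = PhantomTruth(labels=lv, labels_nocrack=lv_nc,
                         crack_plane_normals=normals,
                         connected_network_voxel_fraction=fraction,
                         network_mask=network_mask)
    return grey, truth


def generate_training_tiles(phantom: GreyVolume, truth, n_tiles: int,
                            tile_size: int, seed: int):
    """Sample aligned (grey, label) tile pairs from z-slices.

    ``truth`` may be a :class:`PhantomTruth` or a :class:`LabelVolume`.
    Reproducible for a fixed seed.
    """
    if n_tiles <= 0:
        raise ValueError("n_tiles must be positive")
    labels = truth.labels if isinstance(truth, PhantomTruth) else truth
    nz, ny, nx = phantom.shape
    if tile_size > ny or tile_size > nx:
        raise ValueError(f"tile_size {tile_size} exceeds slice shape {(ny, nx)}")
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(n_tiles):
        z = int(rng.integers(nz))
        r = int(rng.integers(ny - tile_size + 1))
        c = int(rng.integers(nx - tile_size + 1))
        tiles.append((phantom.data[z, r:r + tile_size, c:c + tile_size].copy(),
                      labels.data[z, r:r + tile_size, c:c + tile_size].copy()))
    return tiles


def nocrack_spec(spec: PhantomSpec) -> PhantomSpec:
    """The crack-free twin of a spec (same seed, geometry, rendering)."""
    return replace(spec, crack_network=replace(
        spec.crack_network, n_primary_planes=0, n_isolated_cracks=0,
        plane_normals=None, target_volume_fraction=None))
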