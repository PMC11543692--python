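"""Grid-based detection of internal cavities in a fibril stack.

A regular grid is laid over the structure; voxels within (r_vdw + probe) of
any heavy atom are blocked. Free voxels reachable from the lateral (x/y)
boundary of the box are exterior solvent; the z faces of the analysis slab
are treated as periodic fibril boundaries, not solvent, so channels running
along the fibril axis register as cavities. Remaining free voxels are
clustered into cavities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .contacts import HYDROPHOBIC_RESIDUES, vdw_radius
from .model import FibrilModel

#: 6-connectivity for the exterior flood fill (conservative: prevents leaks
#: through diagonal gaps); 26-connectivity for cavity clustering.
STRUCT_FLOOD = ndimage.generate_binary_structure(3, 1)
STRUCT_CLUSTER = ndimage.generate_binary_structure(3, 3)


@dataclass
class Cavity:
    voxels: np.ndarray  # (n, 3) voxel centers, A
    volume: float  # A^3
    lining_residues: set = field(default_factory=set)
    polarity: Optional[str] = None
    z_continuous: Optional[bool] = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class CavityGrid:
    """Bookkeeping for one voxelization run (exposed for oracle tests)."""

    origin: np.ndarray
    spacing: float
    blocked: np.ndarray  # boolean (nx, ny, nz)
    exterior: np.ndarray
    cavity_labels: np.ndarray  # int array, 0 = not a cavity

    @property
    def shape(self) -> tuple[int, ...]:
        return self.blocked.shape

    def partition_ok(self) -> bool:
        free_interior = (~self.blocked) & (~self.exterior)
        n = self.blocked.sum() + self.exterior.sum() + free_interior.sum()
        return int(n) == int(np.prod(self.shape))


def _voxelize(
    coords: np.ndarray,
    radii: np.ndarray,
    spacing: float,
    probe: float,
    zlim: Optional[tuple[float, float]] = None,
    pad: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Blocked-voxel mask over the bounding box (+pad in x/y); returns
    (origin, blocked)."""
    lo = coords.min(axis=0) - (radii.max() + probe + pad)
    hi = coords.max(axis=0) + (radii.max() + probe + pad)
    if zlim is not None:
        lo[2], hi[2] = zlim
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    blocked = np.zeros(shape, dtype=bool)
    # stamp each atom's inflated sphere onto its local sub-grid
    for (x, y, z), r in zip(coords, radii):
        rr = r + probe
        imin = np.floor(((x, y, z) - lo - rr) / spacing).astype(int)
        imax = np.ceil(((x, y, z) - lo + rr) / spacing).astype(int) + 1
        imin = np.maximum(imin, 0)
        imax = np.minimum(imax, shape)
        if np.any(imin >= imax):
            continue
        ax = lo[0] + spacing * np.arange(imin[0], imax[0]) - x
        ay = lo[1] + spacing * np.arange(imin[1], imax[1]) - y
        az = lo[2] + spacing * np.arange(imin[2], imax[2]) - z
        d2 = (
            ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        )
        blocked[imin[0]:imax[0], imin[1]:imax[1], imin[2]:imax[2]] |= d2 <= rr * rr
    return lo, blocked


def _exterior_mask(blocked: np.ndarray) -> np.ndarray:
    """Free voxels 6-connected to the lateral (x/y) box faces."""
    free = ~blocked
    labels, _ = ndimage.label(free, structure=STRUCT_FLOOD)
    edge_labels = set()
    for face in (labels[0, :, :], labels[-1, :, :], labels[:, 0, :], labels[:, -1, :]):
        edge_labels.update(np.unique(face[face > 0]).tolist())
    if not edge_labels:
        return np.zeros_like(blocked)
    return np.isin(labels, sorted(edge_labels)) & free


def detect_cavities(
    model: FibrilModel,
    probe: float = 1.4,
    spacing: float = 0.5,
    min_volume: float = 20.0,
    central_slab: bool = True,
    rise: Optional[float] = None,
    return_grid: bool = False,
):
    """Internal cavities of the stack, largest first.

    The probe (default 1.4 A, a water molecule) inflates atomic radii; free
    voxel clusters of at least ``min_volume`` A^3 that are not connected to
    the lateral exterior are reported. With ``central_slab`` the analysis is
    limited to a slab of thickness 3x rise centered on the stack midpoint,
    so that the open fibril ends do not merge cavities with the exterior.
    """
    if spacing <= 0 or probe < 0:
        raise ValueError("spacing must be > 0 and probe >= 0")
    atoms = model.heavy_atoms()
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    zlim = None
    if central_slab:
        if rise is None:
            rise = model.helical.rise if model.helical is not None else 4.8
        zmid = 0.5 * (coords[:, 2].min() + coords[:, 2].max())
        zlim = (zmid - 1.5 * rise, zmid + 1.5 * rise)
    origin, blocked = _voxelize(coords, radii, spacing, probe, zlim=zlim)
    exterior = _exterior_mask(blocked)
    interior_free = (~blocked) & (~exterior)
    labels, n = ndimage.label(interior_free, structure=STRUCT_CLUSTER)
    cavities = []
    vox_volume = spacing**3
    for k in range(1, n + 1):
        idx = np.argwhere(labels == k)
        vol = len(idx) * vox_volume
        if vol < min_volume:
            labels[labels == k] = 0
            continue
        centers = origin + (idx + 0.5) * spacing
        cavities.append(Cavity(voxels=centers, volume=vol))
    cavities.sort(key=lambda c: c.volume, reverse=True)
    grid = CavityGrid(origin=origin, spacing=spacing, blocked=blocked,
                      exterior=exterior, cavity_labels=labels)
    if return_grid:
        return cavities, grid
    return cavities


def cavity_lining(
    cavity: Cavity, model: FibrilModel, shell: float = 4.5
) -> list[tuple[str, int, str]]:
    """Residues with a heavy atom within ``shell`` of any cavity voxel."""
    tree = cKDTree(cavity.voxels)
    lining = set()
    for lay in model.layers:
        for res in lay.residues:
            pts = np.array([a.xyz for a in res.heavy_atoms()])
            if len(pts) and tree.query(pts, k=1)[0].min() <= shell:
                lining.add((lay.chain_id, res.seq, res.name))
    return sorted(lining)


def cavity_polarity(
    cavity: Cavity, model: FibrilModel, shell: float = 4.5
) -> str:
    """'hydrophobic' if most lining side-chain atoms are C/S from hydrophobic
    residues, else 'polar'. Also fills ``cavity.lining_residues``."""
    lining = cavity_lining(cavity, model, shell=shell)
    cavity.lining_residues = set(lining)
    tree = cKDTree(cavity.voxels)
    n_total = 0
    n_apolar = 0
    keyed = {(c, s): n for c, s, n in lining}
    for lay in model.layers:
        for res in lay.residues:
            if (lay.chain_id, res.seq) not in keyed:
                continue
            for a in res.side_chain_atoms():
                if tree.query(a.xyz.reshape(1, 3), k=1)[0][0] <= shell:
                    n_total += 1
                    if a.element in ("C", "S") and res.name in HYDROPHOBIC_RESIDUES:
                        n_apolar += 1
    if n_total == 0:
        cavity.polarity = "polar"
        return "polar"
    cavity.polarity = "hydrophobic" if n_apolar / n_total > 0.5 else "polar"
    return cavity.polarity


def z_continuity(cavity: Cavity, rise: float, spacing: float = 0.5) -> bool:
    """True when the cavity runs along the fibril axis: its voxels span at
    least two rises in z without a gap larger than twice the grid spacing."""
    zs = np.unique(cavity.voxels[:, 2])
    span = zs.max() - zs.min()
    if span < 2.0 * rise:
        cavity.z_continuous = False
        return False
    gaps = np.diff(np.sort(zs))
    ok = bool(len(gaps) == 0 or gaps.max() <= 2.0 * spacing + 1e-9)
    cavity.z_continuous = ok
    return ok
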