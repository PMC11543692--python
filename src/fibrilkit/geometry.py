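"""Helical symmetry operations and fibril geometry descriptors.

The fibril axis is the global z axis (the convention of deposited fibril
models). Twist is signed degrees per layer — negative means a left-handed
fibril — and rise is Angstroms per layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import CorrespondenceError, FibrilError
from .model import FibrilModel, Layer, chain_id_sequence
from .superpose import kabsch, rotation_angle_about_z

#: Tilt of the pair rotation axis away from z (degrees) above which we warn.
AXIS_TILT_WARN_DEG = 5.0


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry: rotation (degrees) and translation (A) per layer."""

    twist: float
    rise: float

    def __post_init__(self) -> None:
        if abs(self.twist) > 180.0:
            raise ValueError("twist must satisfy |twist| <= 180 degrees")

    @property
    def handedness(self) -> str:
        return "left" if self.twist < 0 else "right"


@dataclass
class GeometrySummary:
    crossover: float
    width: float
    z_extent_per_chain: float
    handedness: str

    def to_dict(self) -> dict:
        return asdict(self)


def _rot_z(deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def apply_symmetry(layer: Layer, params: HelicalParams, n_layers: int) -> FibrilModel:
    """Expand one layer into an ``n_layers`` helical stack (pdbsymm-style).

    Layer k is layer 0 rotated by ``k * twist`` about z and translated by
    ``k * rise`` along z. Chain ids are assigned deterministically (A, B, ...).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    ids = chain_id_sequence()
    layers = []
    for k in range(n_layers):
        R = _rot_z(k * params.twist)
        shift = np.array([0.0, 0.0, k * params.rise])
        new = layer.copy()
        new.chain_id = next(ids)
        new.layer_index = k
        for res in new.residues:
            for a in res.atoms:
                a.chain_id = new.chain_id
                a.xyz = R @ a.xyz + shift
        layers.append(new)
    return FibrilModel(layers, helical=params)


def estimate_params(model: FibrilModel) -> HelicalParams:
    """Estimate twist and rise from a stack by adjacent-layer superposition.

    For each adjacent layer pair the optimal rigid transform mapping layer i
    onto layer i+1 is found by least squares (Kabsch) on C-alpha atoms matched
    by residue number. The signed rotation angle about +z gives the twist
    (right-handed positive) and the z component of the translation gives the
    rise; per-pair values are averaged.
    """
    if model.n_layers < 2:
        raise FibrilError("need at least 2 layers to estimate helical parameters")
    twists, rises = [], []
    for lo, hi in zip(model.layers[:-1], model.layers[1:]):
        seq_lo = {r.seq for r in lo.residues if r.ca is not None}
        seq_hi = {r.seq for r in hi.residues if r.ca is not None}
        common = sorted(seq_lo & seq_hi)
        if seq_lo != seq_hi or not common:
            raise CorrespondenceError(
                f"layers {lo.chain_id} and {hi.chain_id} have mismatched residue sets"
            )
        a = np.array([lo.residue(s).ca.xyz for s in common])
        b = np.array([hi.residue(s).ca.xyz for s in common])
        R, t, _ = kabsch(a, b)
        angle, tilt = rotation_angle_about_z(R)
        if tilt > AXIS_TILT_WARN_DEG and abs(angle) > 1e-6:
            warnings.warn(
                f"rotation axis between layers {lo.layer_index} and {hi.layer_index} "
                f"deviates {tilt:.1f} deg from the fibril z axis"
            )
        twists.append(angle)
        rises.append(t[2])
    return HelicalParams(twist=float(np.mean(twists)), rise=float(np.mean(rises)))


def predict_crossover(params: HelicalParams) -> float:
    """Crossover distance (A): the half period of the helix, rise * 180/|twist|."""
    if params.twist == 0:
        raise FibrilError("crossover undefined for zero twist")
    return params.rise * 180.0 / abs(params.twist)


def z_extent(layer: Layer) -> float:
    """Distance between the highest and lowest C-alpha atom along z (A)."""
    ca = layer.coords("CA")
    if len(ca) == 0:
        raise FibrilError(f"chain {layer.chain_id} has no CA atoms")
    return float(ca[:, 2].max() - ca[:, 2].min())


def fibril_width(layer: Layer, margin: float = 1.5) -> float:
    """Maximal heavy-atom pairwise distance in xy projection plus 2*margin (A).

    The margin (default 1.5 A, about a carbon van der Waals radius) emulates
    the molecular envelope seen in projection rather than the bare skeleton.
    """
    pts = layer.coords(heavy_only=True)[:, :2]
    if len(pts) < 2:
        raise FibrilError("need at least 2 atoms for a width")
    if len(pts) > 10:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (collinear) point sets: fall back to all pairs
    return float(pdist(pts).max()) + 2.0 * margin


def align_axis_to_z(model: FibrilModel) -> FibrilModel:
    """Rotate the stack so its principal C-alpha axis coincides with global z.

    Optional pre-step for models not deposited in the fibril-axis frame.
    """
    ca = np.vstack([lay.coords("CA") for lay in model.layers])
    centered = ca - ca.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        return model.copy()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = model.copy()
    center = ca.mean(axis=0)
    for a in out.atoms():
        a.xyz = R @ (a.xyz - center) + center
    for a in out.hetero:
        a.xyz = R @ (a.xyz - center) + center
    return out


def summarize_geometry(
    model: FibrilModel,
    params: Optional[HelicalParams] = None,
    width_margin: float = 1.5,
) -> GeometrySummary:
    """Crossover, width, per-chain z extent and handedness for one stack."""
    if params is None:
        params = model.helical if model.helical is not None else estimate_params(model)
    mid = model.layers[model.n_layers // 2]
    return GeometrySummary(
        crossover=predict_crossover(params),
        width=fibril_width(mid, margin=width_margin),
        z_extent_per_chain=z_extent(mid),
        handedness=params.handedness,
    )
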