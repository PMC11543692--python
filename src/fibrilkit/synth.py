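"""Synthetic fibrils, trajectories and predictor tracks with known ground truth.

The generator emulates the study conditions at toy scale: a planar beta-arch
layer (two straight strands joined by a semicircular arc, C-alpha atoms at
3.8 A spacing) replicated into a helical stack with a chosen twist and rise
(defaults: the refined values -1.4 deg and 4.8 A) plus optional Gaussian
coordinate noise; trajectories of six 200 ns replicas with thermal jitter and
an optional programmed detachment of a terminal-chain segment; and
five-predictor score tracks with planted supra-threshold segments. Every
output is bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consensus import PAPER_RULES, ScoreTrack, ThresholdRule
from .errors import FibrilError
from .geometry import HelicalParams, apply_symmetry
from .model import (
    AA1_TO_3,
    AtomSite,
    FibrilModel,
    Layer,
    LYSOZYME_D87G,
    Residue,
)
from .separation import A_PER_NM, Trajectory

CA_SPACING = 3.8  # A, trans peptide C-alpha step


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic fibril.

    Defaults follow the study conditions: the 130-residue patient sequence,
    a six-layer stack (the MD system size) with twist -1.4 deg and rise
    4.8 A, and no coordinate noise.
    """

    sequence: str = LYSOZYME_D87G
    arc_radius: float = 8.0  # A, radius of the hairpin arc
    twist: float = -1.4  # deg per layer
    rise: float = 4.8  # A per layer
    n_layers: int = 6
    noise_sigma: float = 0.0  # A, iid Gaussian on every coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if isinstance(self.sequence, int):
            self.sequence = "A" * self.sequence

    @property
    def params(self) -> HelicalParams:
        return HelicalParams(self.twist, self.rise)


@dataclass
class DetachmentSpec:
    """Programmed detachment of a terminal-chain segment.

    The named residues of the named layer are displaced outward along +x,
    ramping linearly from zero at ``onset_ns`` to ``amplitude_nm`` at the end
    of the trajectory (emulating local loosening of the stack)."""

    layer: int
    residue_range: tuple[int, int]
    amplitude_nm: float
    onset_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_nm < 0:
            raise ValueError("amplitude must be >= 0")


def _arch_curve(n: int, arc_radius: float) -> np.ndarray:
    """C-alpha positions along a planar hairpin: strand, semicircle, strand."""
    arc_len = np.pi * arc_radius
    n_arc = max(int(round(arc_len / CA_SPACING)), 1)
    n_strand = (n - n_arc) // 2
    n_arc = n - 2 * n_strand  # absorb rounding
    pts = []
    # outgoing strand along +x at y = 0
    for i in range(n_strand):
        pts.append((i * CA_SPACING, 0.0))
    x0 = (n_strand - 1) * CA_SPACING if n_strand else 0.0
    # semicircular arc from (x0, 0) to (x0, 2R), angles swept to keep ~3.8 A steps
    dtheta = np.pi / (n_arc + 1)
    for k in range(1, n_arc + 1):
        th = -np.pi / 2 + k * dtheta
        pts.append((x0 + arc_radius * np.cos(th), arc_radius + arc_radius * np.sin(th)))
    # return strand along -x at y = 2R
    for i in range(n_strand):
        pts.append((x0 - i * CA_SPACING, 2.0 * arc_radius))
    xy = np.array(pts[:n])
    return np.column_stack([xy, np.zeros(len(xy))])


def make_layer(spec: GeneratorSpec) -> Layer:
    """One planar beta-arch layer with minimal backbone (N, CA, C, O, CB).

    C-alpha atoms sit on the hairpin curve at z = 0; N and C flank each
    C-alpha along the local chain direction, carbonyl O points +z, and CB
    (absent for Gly) alternates up/down as in a beta-strand.
    """
    seq = spec.sequence
    ca = _arch_curve(len(seq), spec.arc_radius)
    # center the layer on the helical (z) axis to keep the lever arm of the
    # twist realistic for a fibril cross-section
    ca[:, :2] -= ca[:, :2].mean(axis=0)
    # local tangent along the chain
    tang = np.zeros_like(ca)
    tang[1:-1] = ca[2:] - ca[:-2]
    tang[0] = ca[1] - ca[0]
    tang[-1] = ca[-1] - ca[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    residues = []
    serial = 0
    z = np.array([0.0, 0.0, 1.0])
    for i, aa in enumerate(seq):
        name3 = AA1_TO_3.get(aa, "ALA")
        atoms = []
        here = ca[i]
        for atom_name, element, pos in (
            ("N", "N", here - 1.2 * tang[i]),
            ("CA", "C", here),
            ("C", "C", here + 1.2 * tang[i]),
            ("O", "O", here + 1.2 * tang[i] + 1.23 * z),
        ):
            serial += 1
            atoms.append(AtomSite(serial, atom_name, element, name3, i + 1, "A",
                                  pos.astype(float).copy()))
        if name3 != "GLY":
            serial += 1
            cb = here + 1.53 * (z if i % 2 == 0 else -z)
            atoms.append(AtomSite(serial, "CB", "C", name3, i + 1, "A", cb))
        residues.append(Residue(name3, i + 1, atoms))
    return Layer("A", residues, layer_index=0)


def make_fibril(spec: GeneratorSpec) -> FibrilModel:
    """Helical stack from one synthetic layer, with optional coordinate noise.

    The generating parameters are recorded on the returned model
    (``model.helical``) as ground truth.
    """
    layer = make_layer(spec)
    model = apply_symmetry(layer, spec.params, spec.n_layers)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for a in model.atoms():
            a.xyz = a.xyz + rng.normal(0.0, spec.noise_sigma, size=3)
    model.helical = spec.params
    return model


def make_trajectory(
    model: FibrilModel,
    n_frames: int = 201,
    dt_ns: float = 1.0,
    jitter_sigma_nm: float = 0.03,
    detachment: Optional[DetachmentSpec] = None,
    seed: int = 0,
    replica_id: int = 0,
) -> Trajectory:
    """Synthetic trajectory: thermal jitter plus optional programmed detachment.

    Defaults emulate one 200 ns production run sampled every 1 ns. Each frame
    is the model plus iid Gaussian jitter; detached residues are additionally
    displaced along +x by ``amplitude_nm`` times a linear ramp that starts at
    ``onset_ns`` and reaches 1 at the final frame.
    """
    base = np.array([a.xyz for a in model.atoms()], dtype=float)
    rng = np.random.default_rng(seed)
    frames = base[None, :, :] + rng.normal(
        0.0, jitter_sigma_nm * A_PER_NM, size=(n_frames, len(base), 3)
    )
    times = np.arange(n_frames) * dt_ns
    if detachment is not None:
        lo, hi = detachment.residue_range
        sel = []
        i = 0
        found_layer = False
        for lay in model.layers:
            for res in lay.residues:
                for _ in res.atoms:
                    if lay.layer_index == detachment.layer and lo <= res.seq <= hi:
                        sel.append(i)
                    i += 1
            if lay.layer_index == detachment.layer:
                found_layer = True
                seqs = {r.seq for r in lay.residues}
                if not (lo in seqs and hi in seqs):
                    raise FibrilError(
                        f"detachment range {lo}-{hi} outside residues of layer {detachment.layer}"
                    )
        if not found_layer:
            raise FibrilError(f"no layer with index {detachment.layer}")
        t_end = times[-1] if times[-1] > detachment.onset_ns else detachment.onset_ns + 1.0
        ramp = np.clip((times - detachment.onset_ns) / (t_end - detachment.onset_ns), 0.0, 1.0)
        disp = detachment.amplitude_nm * A_PER_NM * ramp
        frames[:, sel, 0] += disp[:, None]
    return Trajectory(frames, dt_ns=dt_ns, topology=model, replica_id=replica_id)


def make_replica_set(
    model: FibrilModel,
    n_replicas: int = 6,
    detachment: Optional[DetachmentSpec] = None,
    seed: int = 0,
    **traj_kwargs,
) -> list[Trajectory]:
    """Independent replicas (default six, the study's replication) from one seed."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_replicas)
    return [
        make_trajectory(model, detachment=detachment, seed=int(s), replica_id=k, **traj_kwargs)
        for k, s in enumerate(seeds)
    ]


#: Background/planted value pairs that respect each predictor's rule direction
#: and sit safely on either side of its threshold.
_TRACK_LEVELS = {
    "tango": (0.02, 0.6, 0.02),
    "waltz": (20.0, 92.0, 8.0),
    "foldamyloid": (0.03, 0.10, 0.008),
    "aggrescan": (-0.6, 0.4, 0.1),
    "pasta": (-0.5, -5.0, 0.3),
}


def make_score_tracks(
    length: int = 130,
    planted_hits: Optional[dict[str, Sequence[tuple[int, int]]]] = None,
    seed: int = 0,
    rules: Optional[dict[str, ThresholdRule]] = None,
) -> list[ScoreTrack]:
    """Five predictor tracks with sub-threshold noise and planted hit segments.

    ``planted_hits`` maps predictor name to 1-based inclusive residue ranges
    that are driven past that predictor's threshold; everywhere else the
    background noise stays safely on the no-hit side.
    """
    rules = dict(PAPER_RULES if rules is None else rules)
    planted_hits = planted_hits or {}
    rng = np.random.default_rng(seed)
    tracks = []
    for name, rule in rules.items():
        bg, hit, sd = _TRACK_LEVELS.get(name, (0.0, 1.0, 0.1))
        vals = bg + rng.normal(0.0, sd, size=length)
        # clamp background to the no-hit side of the cutoff
        if rule.direction == "above":
            vals = np.minimum(vals, rule.cutoff - abs(sd) * 0.1)
        else:
            vals = np.maximum(vals, rule.cutoff + abs(sd) * 0.1)
        for lo, hi in planted_hits.get(name, ()):
            if not (1 <= lo <= hi <= length):
                raise ValueError(f"planted range {lo}-{hi} outside 1..{length}")
            vals[lo - 1: hi] = hit
        tracks.append(ScoreTrack(name, vals, rule))
    return tracks
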