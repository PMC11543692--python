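"""Per-residue inter-layer separation statistics over MD trajectories.

For a chosen pair of adjacent fibril layers, the distance between equivalent
residues (default: their C-alpha atoms) is followed through the trajectory.
The per-residue maximum after a burn-in period, averaged over independent
replicas with its standard error, quantifies local loosening of the stack:
residues whose mean maximum separation exceeds 0.7 nm are flagged, and
maximal contiguous runs of flagged residues are reported as loosened regions.
Distances are in nm (coordinates are stored in Angstroms and converted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import CorrespondenceError, FibrilError, StructureFormatError
from .model import FibrilModel, read_structure

A_PER_NM = 10.0


@dataclass
class Trajectory:
    """Frames of a fixed topology; atom order follows the topology model."""

    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    dt_ns: float
    topology: FibrilModel
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.dt_ns


def _atom_index(model: FibrilModel) -> dict[tuple[int, int, str], int]:
    """(layer_index, residue_seq, atom_name) -> flat atom position."""
    idx = {}
    i = 0
    for lay in model.layers:
        for res in lay.residues:
            for a in res.atoms:
                idx[(lay.layer_index, res.seq, a.name)] = i
                i += 1
    return idx


def read_multimodel_pdb(path: str | Path, dt_ns: float, replica_id: int = 0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (each MODEL is one frame)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    topo = read_structure(path)
    frames = []
    for gmodel in st:
        coords = []
        for chain in gmodel:
            for res in chain:
                tab = gemmi.find_tabulated_residue(res.name)
                if tab is None or not tab.is_amino_acid():
                    continue
                seen = {}
                for a in res:
                    prev = seen.get(a.name)
                    if prev is None or a.occ > prev.occ:
                        seen[a.name] = a
                for a in seen.values():
                    coords.append([a.pos.x, a.pos.y, a.pos.z])
        frames.append(coords)
    n_atoms = len(frames[0])
    if any(len(f) != n_atoms for f in frames):
        raise StructureFormatError(f"{path}: frames differ in atom count")
    # topology layers were reordered by z; rebuild frame arrays in that order
    order = _reading_order_to_topology(topo, st)
    arr = np.asarray(frames, dtype=float)[:, order, :]
    return Trajectory(arr, dt_ns=dt_ns, topology=topo, replica_id=replica_id)


def _reading_order_to_topology(topo: FibrilModel, st: gemmi.Structure) -> np.ndarray:
    flat = []
    for chain in st[0]:
        for res in chain:
            tab = gemmi.find_tabulated_residue(res.name)
            if tab is None or not tab.is_amino_acid():
                continue
            seen = {}
            for a in res:
                prev = seen.get(a.name)
                if prev is None or a.occ > prev.occ:
                    seen[a.name] = a
            for a in seen.values():
                flat.append((chain.name, res.seqid.num, a.name))
    pos = {key: i for i, key in enumerate(flat)}
    order = []
    for lay in topo.layers:
        for res in lay.residues:
            for a in res.atoms:
                order.append(pos[(lay.chain_id, res.seq, a.name)])
    return np.array(order, dtype=int)


def residue_distances(
    traj: Trajectory,
    layer_pair: tuple[int, int],
    atom: str = "CA",
) -> pd.DataFrame:
    """Time series of distances between equivalent residues of two layers.

    Returns a DataFrame indexed by residue_seq with one column per frame
    time (ns); values in nm. Residues lacking the representative atom in
    either layer are omitted.
    """
    i, j = layer_pair
    topo = traj.topology
    lay_i, lay_j = topo.layer(i), topo.layer(j)
    idx = _atom_index(topo)
    seqs, ai, aj = [], [], []
    for res in lay_i.residues:
        key_i = (i, res.seq, atom)
        key_j = (j, res.seq, atom)
        if key_i in idx and key_j in idx:
            seqs.append(res.seq)
            ai.append(idx[key_i])
            aj.append(idx[key_j])
    if not seqs:
        raise CorrespondenceError(f"no residues with atom {atom!r} shared by layers {i}, {j}")
    diff = traj.frames[:, ai, :] - traj.frames[:, aj, :]
    dist_nm = np.linalg.norm(diff, axis=2).T / A_PER_NM  # (n_res, n_frames)
    return pd.DataFrame(dist_nm, index=pd.Index(seqs, name="residue_seq"),
                        columns=traj.times_ns)


def max_after_burnin(series: pd.DataFrame | pd.Series, burnin_ns: float = 50.0):
    """Per-residue maximum over frames at times >= burn-in.

    The initial transient (the study discards the first 50 ns) is excluded.
    """
    if isinstance(series, pd.Series):
        times = np.asarray(series.index, dtype=float)
        if times.max() <= burnin_ns:
            raise FibrilError(f"trajectory ({times.max()} ns) does not exceed burn-in")
        return float(series[times >= burnin_ns].max())
    times = np.asarray(series.columns, dtype=float)
    if times.max() <= burnin_ns:
        raise FibrilError(f"trajectory ({times.max()} ns) does not exceed burn-in")
    return series.loc[:, times >= burnin_ns].max(axis=1)


@dataclass
class SeparationProfile:
    residue_seqs: np.ndarray
    replica_max: np.ndarray  # (n_replicas, n_residues), nm
    burnin_ns: float
    layer_pair: tuple[int, int]
    replica_mean: np.ndarray = field(init=False)
    replica_sem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.residue_seqs = np.asarray(self.residue_seqs, dtype=int)
        self.replica_max = np.atleast_2d(np.asarray(self.replica_max, dtype=float))
        self.replica_mean = self.replica_max.mean(axis=0)
        n = self.replica_max.shape[0]
        if n >= 2:
            self.replica_sem = self.replica_max.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            self.replica_sem = np.full(self.replica_max.shape[1], np.nan)

    @property
    def n_replicas(self) -> int:
        return self.replica_max.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_max_nm": self.replica_mean, "sem_nm": self.replica_sem},
            index=pd.Index(self.residue_seqs, name="residue_seq"),
        )


def aggregate_replicas(
    per_replica: Sequence[pd.Series],
) -> SeparationProfile:
    """Mean and SEM (sd/sqrt(n)) of per-residue maxima across replicas."""
    if not per_replica:
        raise FibrilError("no replicas given")
    base = per_replica[0].index
    for s in per_replica[1:]:
        if not base.equals(s.index):
            raise CorrespondenceError("replicas cover different residue sets")
    mat = np.vstack([np.asarray(s, dtype=float) for s in per_replica])
    return SeparationProfile(np.asarray(base), mat, burnin_ns=np.nan, layer_pair=(-1, -1))


def separation_profile(
    trajectories: Sequence[Trajectory],
    layer_pair: tuple[int, int],
    burnin_ns: float = 50.0,
    atom: str = "CA",
    pooled: bool = False,
) -> SeparationProfile:
    """Full pipeline: per-replica per-residue maxima after burn-in, aggregated.

    ``pooled=True`` takes the maximum over all replicas' frames pooled together
    (the alternative reading; SEM is then undefined).
    """
    maxima = []
    for tr in trajectories:
        d = residue_distances(tr, layer_pair, atom=atom)
        maxima.append(max_after_burnin(d, burnin_ns=burnin_ns))
    if pooled:
        mat = np.vstack([np.asarray(m) for m in maxima]).max(axis=0, keepdims=True)
        prof = SeparationProfile(np.asarray(maxima[0].index), mat,
                                 burnin_ns=burnin_ns, layer_pair=layer_pair)
        return prof
    prof = aggregate_replicas(maxima)
    prof.burnin_ns = burnin_ns
    prof.layer_pair = layer_pair
    return prof


def flag_loosened(
    profile: SeparationProfile, threshold_nm: float = 0.7
) -> tuple[set[int], list[tuple[int, int]]]:
    """Residues whose mean maximum separation exceeds the loosening threshold.

    Returns the flagged residue set and the maximal contiguous runs as
    (first_residue, last_residue) regions.
    """
    flagged = profile.residue_seqs[profile.replica_mean > threshold_nm]
    flagged_set = set(int(r) for r in flagged)
    regions = []
    for r in sorted(flagged_set):
        if regions and r == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], r)
        else:
            regions.append((r, r))
    return flagged_set, regions


def compare_variants(
    profile_a: SeparationProfile,
    profile_b: SeparationProfile,
    threshold_nm: float = 0.7,
) -> pd.DataFrame:
    """Per-residue difference report between two variants (a - b).

    Flags residues where one variant exceeds the loosening threshold and the
    other does not (``differential`` column).
    """
    if not np.array_equal(profile_a.residue_seqs, profile_b.residue_seqs):
        raise CorrespondenceError("profiles cover different residue ranges")
    a, b = profile_a.replica_mean, profile_b.replica_mean
    return pd.DataFrame(
        {
            "mean_a_nm": a,
            "mean_b_nm": b,
            "delta_nm": a - b,
            "loosened_a": a > threshold_nm,
            "loosened_b": b > threshold_nm,
            "differential": (a > threshold_nm) != (b > threshold_nm),
        },
        index=pd.Index(profile_a.residue_seqs, name="residue_seq"),
    )


def differential_regions(report: pd.DataFrame) -> list[tuple[int, int]]:
    """Maximal contiguous residue runs flagged as differential."""
    res = sorted(int(r) for r in report.index[report["differential"]])
    regions: list[tuple[int, int]] = []
    for r in res:
        if regions and r == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], r)
        else:
            regions.append((r, r))
    return regions


def plot_separation(profile: SeparationProfile, threshold_nm: float = 0.7, ax=None):
    """Mean max separation per residue with SEM band and loosening threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = profile.residue_seqs
    ax.plot(x, profile.replica_mean, lw=1.2, color="#2166ac")
    if np.isfinite(profile.replica_sem).all():
        ax.fill_between(x, profile.replica_mean - profile.replica_sem,
                        profile.replica_mean + profile.replica_sem,
                        alpha=0.3, color="#2166ac", lw=0)
    ax.axhline(threshold_nm, color="#b2182b", ls="--", lw=1)
    ax.set_xlabel("residue")
    ax.set_ylabel("max inter-layer distance (nm)")
    return ax
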