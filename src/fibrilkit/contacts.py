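"""Covalent and non-covalent interaction analysis of a fibril stack.

Disulfide detection, cross-layer contact counting, ion pairs, hydrophobic
clusters, and burial classification by solvent-accessible surface area.
All cutoffs are heavy-atom distances in Angstroms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import FibrilError
from .model import AtomSite, FibrilModel, Layer

#: Bondi van der Waals radii (A); fallback 1.70 for unlisted elements.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Conventional hydrophobic residue set (Kyte-Doolittle positive, plus Pro).
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

#: Side-chain atoms carrying formal charge, by residue.
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

#: Theoretical maximum accessible surface area of residue X in Gly-X-Gly (A^2),
#: Tien et al. 2013, used to normalize SASA into relative exposure.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


@dataclass(frozen=True)
class DisulfideBond:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    sg_distance: float

    @property
    def intra_chain(self) -> bool:
        return self.residue_a[0] == self.residue_b[0]


@dataclass(frozen=True)
class ContactEdge:
    layer_i: int
    layer_j: int
    n_atom_pairs: int
    min_distance: float


@dataclass(frozen=True)
class IonPair:
    acidic: tuple[str, int, str]  # (chain_id, residue_seq, residue_name)
    basic: tuple[str, int, str]
    distance: float
    same_layer: bool


def detect_disulfides(model: FibrilModel, cutoff: float = 2.5) -> list[DisulfideBond]:
    """All Cys pairs with an Sgamma-Sgamma distance within ``cutoff``.

    Both intra- and inter-chain bridges are reported, each pair once. Cysteines
    without a modeled SG atom are skipped with a warning.
    """
    sites: list[tuple[str, int, np.ndarray]] = []
    for lay in model.layers:
        for res in lay.residues:
            if res.name != "CYS":
                continue
            sg = res.atom("SG")
            if sg is None:
                warnings.warn(f"Cys {lay.chain_id}{res.seq} lacks an SG atom; skipped")
                continue
            sites.append((lay.chain_id, res.seq, sg.xyz))
    bonds = []
    if len(sites) >= 2:
        tree = cKDTree(np.array([s[2] for s in sites]))
        for i, j in sorted(tree.query_pairs(cutoff)):
            ca, sa, xa = sites[i]
            cb, sb, xb = sites[j]
            bonds.append(
                DisulfideBond((ca, sa), (cb, sb), float(np.linalg.norm(xa - xb)))
            )
    return bonds


def layer_contacts(
    model: FibrilModel, center_layer: int, cutoff: float = 4.5
) -> list[ContactEdge]:
    """Layers with at least one heavy-atom pair within ``cutoff`` of the center layer.

    This is the geometric analog of an interface census: the count of distinct
    molecules touching one molecule of the stack.
    """
    center = model.layer(center_layer)
    cpts = np.array([a.xyz for a in center.heavy_atoms()])
    ctree = cKDTree(cpts)
    edges = []
    for lay in model.layers:
        if lay.layer_index == center_layer:
            continue
        pts = np.array([a.xyz for a in lay.heavy_atoms()])
        pairs = ctree.query_ball_tree(cKDTree(pts), cutoff)
        n_pairs = sum(len(p) for p in pairs)
        if n_pairs:
            d = np.linalg.norm(
                cpts[:, None, :] - pts[None, :, :], axis=-1
            ) if len(cpts) * len(pts) <= 4_000_000 else None
            if d is not None:
                min_d = float(d.min())
            else:
                min_d = min(
                    float(np.linalg.norm(cpts[i] - pts[j]))
                    for i, js in enumerate(pairs)
                    for j in js
                )
            edges.append(ContactEdge(center_layer, lay.layer_index, n_pairs, min_d))
    if edges:
        reach = max(abs(e.layer_j - center_layer) for e in edges)
        n = model.n_layers
        if center_layer - 0 < reach or (n - 1) - center_layer < reach:
            warnings.warn(
                f"center layer {center_layer} is within {reach} layers of the stack "
                "edge; contact count may be truncated"
            )
    return sorted(edges, key=lambda e: e.layer_j)


def contact_count_vs_cutoff(
    model: FibrilModel, center_layer: int, cutoffs=(4.0, 4.5, 5.0)
) -> dict[float, int]:
    """Number of contacting layers as a function of the distance cutoff."""
    out = {}
    for c in cutoffs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[float(c)] = len(layer_contacts(model, center_layer, cutoff=c))
    return out


def find_ion_pairs(model: FibrilModel, cutoff: float = 4.0) -> list[IonPair]:
    """Salt bridges: acidic carboxylate O vs basic N within ``cutoff``.

    His imidazole nitrogens count as basic (buried His can pair with Asp in
    the fibril core). Pairs are annotated as intra- or inter-layer.
    """
    acidic: list[tuple[tuple[str, int, str], np.ndarray]] = []
    basic: list[tuple[tuple[str, int, str], np.ndarray]] = []
    for lay in model.layers:
        for res in lay.residues:
            for table, bucket in ((ACIDIC_ATOMS, acidic), (BASIC_ATOMS, basic)):
                for aname in table.get(res.name, ()):
                    a = res.atom(aname)
                    if a is not None:
                        bucket.append(((lay.chain_id, res.seq, res.name), a.xyz))
    if not acidic or not basic:
        return []
    atree = cKDTree(np.array([x for _, x in acidic]))
    btree = cKDTree(np.array([x for _, x in basic]))
    best: dict[tuple, IonPair] = {}
    for ia, jbs in enumerate(atree.query_ball_tree(btree, cutoff)):
        for jb in jbs:
            key_a, xa = acidic[ia]
            key_b, xb = basic[jb]
            if key_a[:2] == key_b[:2]:
                continue
            d = float(np.linalg.norm(xa - xb))
            key = (key_a, key_b)
            if key not in best or d < best[key].distance:
                best[key] = IonPair(key_a, key_b, d, same_layer=key_a[0] == key_b[0])
    return sorted(best.values(), key=lambda p: p.distance)


def hydrophobic_clusters(
    model: FibrilModel, cutoff: float = 5.0, min_size: int = 3
) -> list[set[tuple[str, int]]]:
    """Connected clusters of hydrophobic residues.

    Residues from {Ala, Val, Leu, Ile, Met, Phe, Trp, Pro} are nodes; an edge
    joins two residues whose side-chain heavy atoms approach within ``cutoff``.
    Connected components of size >= ``min_size`` are returned, largest first.
    """
    nodes: list[tuple[str, int]] = []
    atom_xyz: list[np.ndarray] = []
    atom_node: list[int] = []
    for lay in model.layers:
        for res in lay.residues:
            if res.name not in HYDROPHOBIC_RESIDUES:
                continue
            side = res.side_chain_atoms()
            if not side:
                continue
            idx = len(nodes)
            nodes.append((lay.chain_id, res.seq))
            for a in side:
                atom_xyz.append(a.xyz)
                atom_node.append(idx)
    if not nodes:
        return []
    tree = cKDTree(np.array(atom_xyz))
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(cutoff):
        ri, rj = find(atom_node[i]), find(atom_node[j])
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, set[tuple[str, int]]] = {}
    for i, node in enumerate(nodes):
        comps.setdefault(find(i), set()).add(node)
    return sorted(
        (c for c in comps.values() if len(c) >= min_size),
        key=len,
        reverse=True,
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley method.

    Each atom is covered with ``n_points`` quasi-uniform sphere points at
    radius r_vdw + probe; points inside any neighbor's expanded sphere are
    occluded and the exposed fraction scales the sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sphere = _fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    sasa = np.zeros(len(coords))
    max_r = expanded.max()
    for i in range(len(coords)):
        r = expanded[i]
        pts = coords[i] + r * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], r + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        sasa[i] = 4.0 * np.pi * r * r * exposed.mean()
    return sasa


@dataclass(frozen=True)
class ExposureResult:
    label: str  # "buried" | "exposed"
    relative_sasa: float
    sasa: float
    chain_id: str
    residue_seq: int
    residue_name: str


def classify_exposure(
    model: FibrilModel,
    position: int,
    threshold: float = 0.15,
    probe: float = 1.4,
    n_points: int = 960,
    neighborhood: float = 12.0,
) -> ExposureResult:
    """Buried/exposed classification of a residue in its fibril context.

    The SASA of the residue copy in the middle layer of the stack is computed
    (with all atoms within ``neighborhood`` as occluders) and normalized by
    the Gly-X-Gly reference area; relative SASA below ``threshold`` is buried.
    """
    mid = model.layers[model.n_layers // 2]
    res = mid.residue(position)
    if res is None:
        raise FibrilError(f"position {position} not in layer {mid.chain_id}")
    res_atoms = res.heavy_atoms()
    res_xyz = np.array([a.xyz for a in res_atoms])
    context: list[AtomSite] = []
    all_heavy = model.heavy_atoms()
    center = res_xyz.mean(axis=0)
    reach = neighborhood + float(np.max(np.linalg.norm(res_xyz - center, axis=1)))
    for a in all_heavy:
        if np.linalg.norm(a.xyz - center) <= reach:
            context.append(a)
    idx_of = {id(a): i for i, a in enumerate(context)}
    coords = np.array([a.xyz for a in context])
    radii = np.array([vdw_radius(a.element) for a in context])
    sasa = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    total = float(sum(sasa[idx_of[id(a)]] for a in res_atoms))
    ref = MAX_ASA.get(res.name)
    rel = total / ref if ref else float("nan")
    label = "buried" if rel < threshold else "exposed"
    return ExposureResult(label, rel, total, mid.chain_id, position, res.name)
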