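"""Data model and I/O for fibril structures.

A fibril is represented as an ordered stack of :class:`Layer` objects, one per
protein chain (this fibril has a single protofilament, so layer == chain).
Coordinates are in Angstroms throughout; residue numbering is 1-based mature
lysozyme numbering (1-130) and is taken verbatim from the input file.
"""

from __future__ import annotations

import copy
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

from .errors import (
    CorrespondenceError,
    EmptyModelError,
    StructureFormatError,
    UnsupportedResidueError,
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Mature human lysozyme, patient variant (Gly at position 87).
LYSOZYME_D87G = (
    "KVFERCELARTLKRLGMDGYRGISLANWMCLAKWESGYNTRATNYNAGDRSTDYGIFQINSRYWCNDGKTPGAVNACHLSCSALLQGNIADAVACAKRVVRDPQGIRAWVAWRNRCQNRDVRQYVQGCGV"
)
#: Wild-type mature human lysozyme (Asp at position 87).
LYSOZYME_WT = LYSOZYME_D87G[:86] + "D" + LYSOZYME_D87G[87:]


@dataclass
class AtomSite:
    """One atom of the model."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def copy(self) -> "AtomSite":
        a = copy.copy(self)
        a.xyz = self.xyz.copy()
        return a


@dataclass
class Residue:
    name: str
    seq: int
    atoms: list[AtomSite] = field(default_factory=list)

    def atom(self, name: str) -> Optional[AtomSite]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[AtomSite]:
        return self.atom("CA")

    def heavy_atoms(self) -> list[AtomSite]:
        return [a for a in self.atoms if a.element not in ("H", "D")]

    def side_chain_atoms(self) -> list[AtomSite]:
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS and a.name != "OXT"]

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq, [a.copy() for a in self.atoms])


@dataclass
class Layer:
    """One rung of the helical stack: a single fibril protein molecule."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    layer_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: r.seq)

    def atoms(self) -> Iterator[AtomSite]:
        for r in self.residues:
            yield from r.atoms

    def heavy_atoms(self) -> list[AtomSite]:
        return [a for r in self.residues for a in r.heavy_atoms()]

    def coords(self, atom_name: Optional[str] = None, heavy_only: bool = False) -> np.ndarray:
        if atom_name is not None:
            pts = [r.atom(atom_name).xyz for r in self.residues if r.atom(atom_name) is not None]
        elif heavy_only:
            pts = [a.xyz for a in self.heavy_atoms()]
        else:
            pts = [a.xyz for a in self.atoms()]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def mean_z(self) -> float:
        """Mean z of the C-alpha trace (used for layer ordering)."""
        ca = self.coords("CA")
        if len(ca) == 0:
            raise ValueError(f"chain {self.chain_id} has no CA atoms")
        return float(ca[:, 2].mean())

    def residue(self, seq: int) -> Optional[Residue]:
        for r in self.residues:
            if r.seq == seq:
                return r
        return None

    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.name, "X") for r in self.residues)

    def copy(self) -> "Layer":
        return Layer(self.chain_id, [r.copy() for r in self.residues], self.layer_index)


@dataclass
class SequenceRecord:
    residues: str
    variant_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FibrilModel:
    """An ordered stack of layers, optionally with known helical parameters."""

    layers: list[Layer] = field(default_factory=list)
    helical: Optional[object] = None  # HelicalParams; kept untyped to avoid a cycle
    source_format: Optional[str] = None
    hetero: list[AtomSite] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, index: int) -> Layer:
        for lay in self.layers:
            if lay.layer_index == index:
                return lay
        raise KeyError(f"no layer with index {index}")

    def atoms(self) -> Iterator[AtomSite]:
        for lay in self.layers:
            yield from lay.atoms()

    def heavy_atoms(self) -> list[AtomSite]:
        return [a for lay in self.layers for a in lay.heavy_atoms()]

    def copy(self) -> "FibrilModel":
        return FibrilModel(
            [lay.copy() for lay in self.layers],
            self.helical,
            self.source_format,
            [a.copy() for a in self.hetero],
        )

    def sequence(self, layer: int = 0, variant_label: str = "") -> SequenceRecord:
        seq = self.layers[layer].sequence()
        if not variant_label and len(seq) == 130:
            variant_label = "D87G" if seq[86] == "G" else "WT"
        return SequenceRecord(seq, variant_label)


def chain_id_sequence() -> Iterator[str]:
    """Deterministic chain id generator: A..Z, a..z, AA, AB, ..."""
    letters = string.ascii_uppercase + string.ascii_lowercase
    yield from letters
    for a in letters:
        for b in letters:
            yield a + b


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer of each alternate-location group."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or a.occ > prev.occ:
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(path: str | Path, format: Optional[str] = None) -> FibrilModel:
    """Read a PDB or mmCIF coordinate file into a :class:`FibrilModel`.

    Each polymer chain of the first model becomes one layer. Heteroatoms and
    waters are excluded from the layers but retained in ``model.hetero``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models")
    st.setup_entities()
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    gmodel = st[0]
    layers: list[Layer] = []
    hetero: list[AtomSite] = []
    serial = 0
    for chain in gmodel:
        residues: list[Residue] = []
        for gres in chain:
            tab = gemmi.find_tabulated_residue(gres.name)
            is_aa = tab is not None and tab.is_amino_acid()
            atoms: list[AtomSite] = []
            for ga in _pick_altloc(gres):
                serial += 1
                atoms.append(
                    AtomSite(
                        serial=serial,
                        name=ga.name,
                        element=ga.element.name,
                        residue_name=gres.name,
                        residue_seq=gres.seqid.num,
                        chain_id=chain.name,
                        xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        b_iso=ga.b_iso,
                    )
                )
            if is_aa:
                residues.append(Residue(gres.name, gres.seqid.num, atoms))
            else:
                hetero.extend(atoms)
        if residues:
            layers.append(Layer(chain.name, residues))
    if not layers:
        raise EmptyModelError(f"{path}: no polymer chain with amino-acid residues")
    model = FibrilModel(layers, source_format=format, hetero=hetero)
    return assign_layers(model)


def write_structure(model: FibrilModel, path: str | Path, format: Optional[str] = None) -> None:
    """Write the model as PDB or mmCIF (chosen by extension unless given)."""
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format: {format}")


def _to_gemmi(model: FibrilModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "fibril"
    gm = gemmi.Model("1")
    serial = 0
    for lay in model.layers:
        ch = gemmi.Chain(lay.chain_id)
        for res in lay.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seq, " ")
            gr.het_flag = "A"
            for a in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occupancy
                ga.b_iso = a.b_iso
                ga.serial = serial
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    # heteroatoms grouped back into their chains of origin
    het_by_chain: dict[str, dict[tuple[int, str], list[AtomSite]]] = {}
    for a in model.hetero:
        het_by_chain.setdefault(a.chain_id, {}).setdefault((a.residue_seq, a.residue_name), []).append(a)
    for cid, residues in het_by_chain.items():
        ch = gemmi.Chain(cid if all(l.chain_id != cid for l in model.layers) else cid + "h")
        for (seq, name), atoms in residues.items():
            gr = gemmi.Residue()
            gr.name = name
            gr.seqid = gemmi.SeqId(seq, " ")
            gr.het_flag = "H"
            for a in atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occupancy
                ga.b_iso = a.b_iso
                ga.serial = serial
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def assign_layers(model: FibrilModel) -> FibrilModel:
    """Order layers by ascending mean C-alpha z and assign layer indices.

    Ties are broken by lexicographic chain id. Chains lacking CA atoms are
    dropped with a warning.
    """
    keyed = []
    for lay in model.layers:
        try:
            keyed.append((lay.mean_z(), lay.chain_id, lay))
        except ValueError:
            warnings.warn(f"chain {lay.chain_id} has no CA atoms; skipped from layer stack")
    keyed.sort(key=lambda t: (t[0], t[1]))
    layers = []
    for i, (_, _, lay) in enumerate(keyed):
        lay.layer_index = i
        layers.append(lay)
    model.layers = layers
    return model


def _sidechain_template(target: str):
    """Idealized heavy-atom side chain for a standard residue (most common
    CCD ideal geometry), as (backbone N/CA/C coords, side-chain name/element/coords)."""
    from biotite.structure.info import residue as _ccd_residue

    try:
        tmpl = _ccd_residue(target)
    except KeyError as exc:
        raise UnsupportedResidueError(f"no template for residue {target!r}") from exc
    if tmpl is None:
        raise UnsupportedResidueError(f"no template for residue {target!r}")
    names = tmpl.atom_name
    elems = tmpl.element
    coords = tmpl.coord
    bb = {}
    side = []
    for n, e, c in zip(names, elems, coords):
        if e in ("H", "D"):
            continue
        if n in ("N", "CA", "C"):
            bb[n] = np.asarray(c, dtype=float)
        elif n not in ("O", "OXT"):
            side.append((str(n), str(e), np.asarray(c, dtype=float)))
    if set(bb) != {"N", "CA", "C"}:
        raise UnsupportedResidueError(f"template for {target!r} lacks a full backbone")
    return bb, side


def mutate_residue(model: FibrilModel, position: int, target: str) -> FibrilModel:
    """Backbone-preserving point mutation applied to every layer.

    The backbone atoms (N, CA, C, O) are kept bit-for-bit; the new side chain
    comes from an idealized template rigidly superposed on the local N/CA/C
    frame. Used to build the hypothetical wild-type fibril (G87 -> D87) from
    the patient model without touching backbone dihedrals.
    """
    target = target.upper()
    if target not in AA3_TO_1:
        raise UnsupportedResidueError(f"not a standard amino acid: {target!r}")
    out = model.copy()
    missing = [lay.chain_id for lay in out.layers if lay.residue(position) is None]
    if missing:
        raise CorrespondenceError(f"position {position} absent in chains {missing}")
    if all(lay.residue(position).name == target for lay in out.layers):
        return out  # identity mutation
    bb_t, side_t = _sidechain_template(target)
    from .superpose import kabsch

    for lay in out.layers:
        res = lay.residue(position)
        bb_atoms = {a.name: a for a in res.atoms if a.name in BACKBONE_ATOMS}
        if not all(n in bb_atoms for n in ("N", "CA", "C")):
            raise CorrespondenceError(
                f"chain {lay.chain_id} residue {position} lacks backbone atoms for mutation"
            )
        mobile = np.array([bb_t["N"], bb_t["CA"], bb_t["C"]])
        tgt = np.array([bb_atoms["N"].xyz, bb_atoms["CA"].xyz, bb_atoms["C"].xyz])
        R, t, _ = kabsch(mobile, tgt)
        new_atoms = [bb_atoms[n] for n in BACKBONE_ATOMS if n in bb_atoms]
        template_atom = res.atoms[0]
        for name, elem, c in side_t:
            a = template_atom.copy()
            a.name = name
            a.element = elem
            a.xyz = R @ c + t
            a.occupancy = 1.0
            new_atoms.append(a)
        res.name = target
        for a in new_atoms:
            a.residue_name = target
        res.atoms = new_atoms
    return out


def write_fasta(record: SequenceRecord, path: str | Path, line_width: int = 60) -> None:
    header = record.variant_label or "sequence"
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(record.residues), line_width):
            fh.write(record.residues[i : i + line_width] + "\n")
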