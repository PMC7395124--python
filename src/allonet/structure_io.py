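"""Read protein structures into a residue-node model.

Every downstream stage (contact counting, propagation, hotspot clustering)
operates on an ordered list of nodes, where a node is either an amino-acid
residue or a ligand group (one HETATM residue record).  This module owns the
atom-selection conventions: hydrogens/deuteriums are dropped, waters and
common ions are excluded by default, and altloc conflicts keep the
highest-occupancy conformer (ties broken by the alphabetically first altloc
code).  Coordinates are in Angstroms throughout.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "AtomRecord",
    "ResidueNode",
    "StructureModel",
    "StructureParseError",
    "SelectionError",
    "read_structure",
    "select_nodes",
    "write_aci_pdb",
    "node_table",
]

#: Backbone atom names on standard amino acids.  OXT is deliberately not
#: included: the chain-adjacency contact exclusion targets covalently bonded
#: backbone neighbours and the terminal carboxyl oxygen plays no part in that.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Residue names excluded from the node model by default: water and the
#: common crystallographic ions.  Ligands of interest (nucleotides, peptides,
#: phosphomimics such as BEF) are retained.
DEFAULT_EXCLUDE = frozenset(
    {"HOH", "DOD", "WAT", "NA", "CL", "K", "MG", "MN", "ZN", "CA", "CD", "NI",
     "CU", "FE", "CO", "HG", "BR", "IOD", "CS", "LI", "SR", "BA"}
)

_HYDROGEN_ELEMENTS = {"H", "D"}


class StructureParseError(ValueError):
    """Raised when PDB text cannot be turned into a structure model."""


class SelectionError(ValueError):
    """Raised when a node selection expression resolves to nothing."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: name, element, coordinates (A), occupancy, altloc."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_backbone: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)) or self.coords.shape != (3,):
            raise StructureParseError(f"atom {self.name}: non-finite or malformed coordinates")


@dataclass
class ResidueNode:
    """A network node: one amino-acid residue or one ligand group.

    ``node_id`` is (chain id, residue sequence number, insertion code) and is
    unique within a model; ``seq_index`` is the 0-based position in the node
    ordering (file order of each residue's first atom).
    """

    node_id: tuple[str, int, str]
    res_name: str
    kind: str  # "amino_acid" | "ligand"
    atoms: list[AtomRecord]
    seq_index: int

    @property
    def chain_id(self) -> str:
        return self.node_id[0]

    @property
    def resnum(self) -> int:
        return self.node_id[1]

    @property
    def icode(self) -> str:
        return self.node_id[2]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def label(self) -> str:
        """Human-readable node label, e.g. ``A/57`` or ``B/1301(BEF)``."""
        base = f"{self.chain_id}/{self.resnum}{self.icode.strip()}"
        return base if self.kind == "amino_acid" else f"{base}({self.res_name})"


@dataclass
class StructureModel:
    """Ordered node list backing the residue interaction network."""

    nodes: list[ResidueNode]
    title: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def atom_counts(self) -> np.ndarray:
        return np.array([node.n_atoms for node in self.nodes], dtype=int)

    def coords_by_node(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked atom coordinates, node index per atom, backbone flags."""
        coords, node_idx, backbone = [], [], []
        for i, node in enumerate(self.nodes):
            for atom in node.atoms:
                coords.append(atom.coords)
                node_idx.append(i)
                backbone.append(atom.is_backbone)
        return (np.asarray(coords, dtype=float),
                np.asarray(node_idx, dtype=int),
                np.asarray(backbone, dtype=bool))

    def index_of(self, chain: str, resnum: int, icode: str = " ") -> int:
        for node in self.nodes:
            if node.node_id == (chain, resnum, icode):
                return node.seq_index
        raise SelectionError(f"no node {chain}/{resnum}{icode.strip()} in model")

    def labels(self) -> list[str]:
        return [node.label() for node in self.nodes]

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise StructureParseError("duplicate node ids in model")
        for node in self.nodes:
            if not node.atoms:
                raise StructureParseError(f"node {node.label()} has no atoms")
            if node.kind == "ligand" and any(a.is_backbone for a in node.atoms):
                raise StructureParseError(f"ligand node {node.label()} has backbone-flagged atoms")


def _first_bad_line(pdb_text: str) -> str | None:
    """Return the first ATOM/HETATM line with unparsable mandatory fields."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        try:
            int(line[22:26])
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except (ValueError, IndexError):
            return f"line {lineno}: {line.rstrip()!r}"
    return None


def _pick_altloc(atoms: list) -> list:
    """Resolve altloc conflicts: highest occupancy, ties to first altloc code."""
    resolved = []
    for atom in atoms:
        if atom.is_disordered():
            children = sorted(
                atom.disordered_get_list(),
                key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
            )
            resolved.append(children[0])
        else:
            resolved.append(atom)
    return resolved


def read_structure(
    pdb_text: str,
    *,
    model_index: int = 0,
    keep_hetero: bool = True,
    exclude_resnames: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
    title: str = "",
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the requested model of a multi-model file is read (default: first).
    Waters and listed ions are excluded; hydrogens and deuteriums are dropped;
    each retained HETATM group becomes a single ligand node.
    """
    if not any(line.startswith(("ATOM  ", "HETATM")) for line in pdb_text.splitlines()):
        raise StructureParseError("no ATOM or HETATM records found in input")
    bad = _first_bad_line(pdb_text)
    if bad is not None:
        raise StructureParseError(f"unparsable PDB record at {bad}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(title or "model", io.StringIO(pdb_text))
    models = list(structure)
    if model_index >= len(models):
        raise StructureParseError(f"model index {model_index} out of range ({len(models)} models)")
    bio_model = models[model_index]

    nodes: list[ResidueNode] = []
    for chain in bio_model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            res_name = residue.get_resname().strip()
            is_het = hetflag.strip() != ""
            if is_het and (not keep_hetero or res_name in exclude_resnames):
                continue
            if not is_het and res_name in exclude_resnames:
                continue
            kind = "ligand" if is_het else "amino_acid"
            atoms = []
            for atom in _pick_altloc(list(residue)):
                element = (atom.element or "").strip().upper()
                if element in _HYDROGEN_ELEMENTS:
                    continue
                name = atom.get_name().strip()
                atoms.append(AtomRecord(
                    name=name,
                    element=element,
                    coords=atom.get_coord(),
                    occupancy=float(atom.get_occupancy() or 1.0),
                    altloc=atom.get_altloc().strip(),
                    is_backbone=(kind == "amino_acid" and name in BACKBONE_ATOMS),
                ))
            if not atoms:
                continue
            nodes.append(ResidueNode(
                node_id=(chain.id, resnum, icode),
                res_name=res_name,
                kind=kind,
                atoms=atoms,
                seq_index=len(nodes),
            ))
    if not nodes:
        raise StructureParseError("no nodes retained after filtering")
    model = StructureModel(nodes=nodes, title=title)
    model.validate()
    return model


def select_nodes(model: StructureModel, spec: str) -> list[int]:
    """Resolve a selection expression to node indices (model order, deduped).

    Grammar (comma-separated tokens):
      - ``chain B``        whole chain
      - ``A/57``           chain A, residue 57 (any insertion code)
      - ``A/50-58``        chain A, residues 50..58 inclusive
      - ``resname BEF``    all nodes with that residue/HET code
    """
    chains_available = sorted({n.chain_id for n in model.nodes})
    hits: list[int] = []
    for token in (t.strip() for t in spec.split(",") if t.strip()):
        low = token.lower()
        if low.startswith("chain "):
            chain = token.split(None, 1)[1].strip()
            hits.extend(n.seq_index for n in model.nodes if n.chain_id == chain)
        elif low.startswith("resname "):
            name = token.split(None, 1)[1].strip().upper()
            hits.extend(n.seq_index for n in model.nodes if n.res_name == name)
        elif "/" in token:
            chain, _, resspec = token.partition("/")
            chain = chain.strip()
            if "-" in resspec.lstrip("-"):
                lo_s, _, hi_s = resspec.rpartition("-")
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(resspec)
            hits.extend(
                n.seq_index for n in model.nodes
                if n.chain_id == chain and lo <= n.resnum <= hi
            )
        else:
            raise SelectionError(f"cannot parse selection token {token!r}")
    out = sorted(dict.fromkeys(hits))
    if not out:
        raise SelectionError(
            f"selection {spec!r} matched no nodes; available chains: {', '.join(chains_available)}"
        )
    return out


def _format_atom_line(serial: int, atom: AtomRecord, node: ResidueNode, bfactor: float) -> str:
    record = "ATOM  " if node.kind == "amino_acid" else "HETATM"
    name = atom.name
    # PDB atom-name column convention: names of <4 chars with 1-2 char
    # elements start in column 14.
    if len(name) < 4 and len(atom.element) < 2:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    x, y, z = atom.coords
    return (
        f"{record}{serial:5d} {name_field}{atom.altloc or ' ':1s}{node.res_name:>3s} "
        f"{node.chain_id:1s}{node.resnum:4d}{node.icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{bfactor:6.2f}"
        f"          {atom.element:>2s}  "
    )


def write_aci_pdb(model: StructureModel, profile) -> str:
    """Emit the structure with B-factors set to 100 x per-node coupling.

    ``profile`` is an :class:`~allonet.propagation_engine.ACIProfile` (or any
    object with an ``aci`` array covering all nodes).  Values are clamped to
    [0, 999.99] after scaling, preserving fixed-width PDB formatting.
    """
    aci = np.asarray(profile.aci, dtype=float)
    if aci.shape != (model.n_nodes,):
        raise ValueError(f"profile covers {aci.shape} values but model has {model.n_nodes} nodes")
    bvals = np.clip(100.0 * aci, 0.0, 999.99)
    lines = []
    serial = 0
    prev_chain = None
    for node in model.nodes:
        if prev_chain is not None and node.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = node.chain_id
        for atom in node.atoms:
            serial += 1
            lines.append(_format_atom_line(serial, atom, node, bvals[node.seq_index]))
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def node_table(model: StructureModel) -> pd.DataFrame:
    """Node inventory as a tidy table (chain, resnum, icode, resname, kind, n_atoms)."""
    return pd.DataFrame(
        {
            "chain": [n.chain_id for n in model.nodes],
            "resnum": [n.resnum for n in model.nodes],
            "icode": [n.icode.strip() for n in model.nodes],
            "resname": [n.res_name for n in model.nodes],
            "kind": [n.kind for n in model.nodes],
            "n_atoms": [n.n_atoms for n in model.nodes],
        }
    )
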