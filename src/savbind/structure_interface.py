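"""Interface-residue calling from 3D structures.

A residue of a protein chain is called *binding* for a substrate class
(protein / DNA / RNA) when the closest pair of atoms between that residue and
any chain of the class lies within a distance cutoff — 6.0 A by default, read
inclusively (<= 6.0). Waters and non-polymer heteroatom groups are excluded
on both sides; for alternate locations the highest-occupancy conformer of
each atom name is kept. Calls made in structure coordinates are translated to
sequence positions through an explicit residue-mapping table (SIFTS-like:
chain + author residue number -> protein accession + 1-based position), which
is the single source of truth — no heuristic renumbering.

Distances are evaluated with a k-d tree over substrate atoms; tests pin the
result to an exhaustive all-atom-pairs scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data_model import BINDING, BINDING_CLASSES, OTHER

__all__ = [
    "DEFAULT_CUTOFF",
    "PRONA_TRAINING_CUTOFF",
    "InterfaceCall",
    "read_structure",
    "classify_chain",
    "call_interfaces",
    "read_mapping_tsv",
    "map_calls",
    "annotate_structure",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 6.0
#: named preset matching the cutoff used to train per-residue binding predictors
PRONA_TRAINING_CUTOFF = 6.5

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DI"}
RNA_RESNAMES = {"A", "C", "G", "U", "I"}
WATER_RESNAMES = {"HOH", "DOD", "WAT"}


@dataclass(frozen=True)
class InterfaceCall:
    """A structure-coordinate binding call for one residue and one class."""

    chain_id: str
    res_id: str  # author residue number with any insertion code appended
    res_name: str
    binding_class: str  # protein | dna | rna
    min_distance: float


def read_structure(path) -> gemmi.Structure:
    """Read a PDB or mmCIF file (format detected from contents/extension)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _residue_id(res: gemmi.Residue) -> str:
    icode = res.seqid.icode.strip()
    return f"{res.seqid.num}{icode}"


def _polymer_category(res_name: str) -> str | None:
    if res_name in PROTEIN_RESNAMES:
        return "protein"
    if res_name in DNA_RESNAMES:
        return "dna"
    if res_name in RNA_RESNAMES:
        return "rna"
    return None


def classify_chain(chain: gemmi.Chain) -> str:
    """Type a chain by majority vote over recognized residue names.

    Returns 'protein', 'dna', 'rna', or 'other' when only heteroatoms /
    waters are present or no category wins a strict plurality.
    """
    if len(chain) == 0:
        raise ValueError(f"chain {chain.name!r} is empty")
    counts = {"protein": 0, "dna": 0, "rna": 0}
    for res in chain:
        cat = _polymer_category(res.name)
        if cat is not None:
            counts[cat] += 1
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        return "other"
    if sum(1 for c in counts.values() if c == counts[best]) > 1:
        return "other"
    return best


def _residue_coords(res: gemmi.Residue) -> np.ndarray:
    """Atom coordinates of one residue, keeping per atom-name the altloc of
    highest occupancy (ties: first in file order)."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = chosen.get(atom.name)
        # strict > : equal occupancy keeps the earlier atom in file order
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return np.array([[a.pos.x, a.pos.y, a.pos.z] for a in chosen.values()], dtype=float)


def _chain_polymer_residues(chain: gemmi.Chain) -> list[gemmi.Residue]:
    return [
        r for r in chain
        if r.name not in WATER_RESNAMES and _polymer_category(r.name) is not None
    ]


def call_interfaces(
    structure: gemmi.Structure,
    query_chain: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[InterfaceCall]:
    """Call binding residues of ``query_chain`` against every substrate class.

    For each residue r of the query chain and each class c, a call is emitted
    iff the minimum Euclidean distance between any kept atom of r and any kept
    atom of a chain of type c (other than the query chain itself) is
    ``<= cutoff``. The realized minimum distance is recorded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    model = structure[0]
    chains = {ch.name: ch for ch in model}
    if query_chain not in chains:
        raise KeyError(f"query chain {query_chain!r} not present in structure")
    qch = chains[query_chain]
    if classify_chain(qch) != "protein":
        raise ValueError(f"query chain {query_chain!r} is not a protein chain")

    # pool substrate atoms per class, excluding the query chain
    substrate_xyz: dict[str, list[np.ndarray]] = {c: [] for c in BINDING_CLASSES}
    for name, ch in chains.items():
        if name == query_chain:
            continue
        ctype = classify_chain(ch)
        if ctype not in substrate_xyz:
            continue
        for res in _chain_polymer_residues(ch):
            coords = _residue_coords(res)
            if coords.size:
                substrate_xyz[ctype].append(coords)
    trees = {
        c: cKDTree(np.vstack(blocks))
        for c, blocks in substrate_xyz.items()
        if blocks
    }

    calls: list[InterfaceCall] = []
    for res in _chain_polymer_residues(qch):
        coords = _residue_coords(res)
        if coords.size == 0:
            continue
        for cls, tree in trees.items():
            d, _ = tree.query(coords)
            dmin = float(np.min(d))
            if dmin <= cutoff:
                calls.append(
                    InterfaceCall(
                        chain_id=query_chain,
                        res_id=_residue_id(res),
                        res_name=res.name,
                        binding_class=cls,
                        min_distance=dmin,
                    )
                )
    return calls


def read_mapping_tsv(path) -> pd.DataFrame:
    """Residue-mapping table: chain_id, struct_resnum, protein_id, seq_pos."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"chain_id": str, "struct_resnum": str, "protein_id": str},
    )
    required = {"chain_id", "struct_resnum", "protein_id", "seq_pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping table missing columns {sorted(required - set(df.columns))}")
    df = df.copy()
    df["seq_pos"] = df["seq_pos"].astype(int)
    if (df["seq_pos"] < 1).any():
        raise ValueError("mapped sequence positions must be >= 1")
    return df


def map_calls(
    calls: list[InterfaceCall],
    mapping: pd.DataFrame,
    structure: gemmi.Structure,
    query_chain: str,
) -> tuple[pd.DataFrame, int]:
    """Translate structure-coordinate calls into per-residue annotations.

    Residues of the query chain resolved in the structure and covered by the
    mapping get status 'binding' for every called class and 'other'
    otherwise; structure residues absent from the mapping are dropped (count
    returned). Residues of the protein never resolved in the structure stay
    unannotated (downstream treats them as 'unknown'). A mapping collision
    (two structure residues onto one sequence position) is an error.

    Returns ``(annotations, n_dropped)`` with annotation columns
    protein_id, position, source='experimental', and per-class statuses.
    """
    mp = mapping[mapping["chain_id"] == query_chain]
    if mp.duplicated(subset=["struct_resnum"]).any():
        raise ValueError(f"mapping not injective for chain {query_chain!r}")
    if mp.duplicated(subset=["protein_id", "seq_pos"]).any():
        dup = mp[mp.duplicated(subset=["protein_id", "seq_pos"], keep=False)].iloc[0]
        raise ValueError(
            f"mapping collision: several structure residues map onto "
            f"{dup['protein_id']}:{dup['seq_pos']}"
        )
    lut = {row.struct_resnum: (row.protein_id, row.seq_pos) for row in mp.itertuples()}

    model = structure[0]
    qch = next(ch for ch in model if ch.name == query_chain)
    resolved = [_residue_id(r) for r in _chain_polymer_residues(qch)]

    called: dict[tuple[str, int], set[str]] = {}
    n_dropped = 0
    for call in calls:
        if call.chain_id != query_chain:
            continue
        target = lut.get(call.res_id)
        if target is None:
            n_dropped += 1
            continue
        called.setdefault(target, set()).add(call.binding_class)
    if n_dropped:
        log.info("map_calls: dropped %d calls at unmapped residues", n_dropped)

    rows = []
    for res_id in resolved:
        target = lut.get(res_id)
        if target is None:
            continue
        classes = called.get(target, set())
        rows.append(
            {
                "protein_id": target[0],
                "position": int(target[1]),
                "source": "experimental",
                **{f"{c}_status": (BINDING if c in classes else OTHER) for c in BINDING_CLASSES},
            }
        )
    cols = ["protein_id", "position", "source"] + [f"{c}_status" for c in BINDING_CLASSES]
    return pd.DataFrame(rows, columns=cols), n_dropped


def annotate_structure(
    structure_path,
    mapping_path,
    query_chain: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[pd.DataFrame, list[InterfaceCall], int]:
    """File-level convenience: read structure + mapping, call and map."""
    st = read_structure(structure_path)
    mapping = read_mapping_tsv(mapping_path) if not isinstance(mapping_path, pd.DataFrame) else mapping_path
    calls = call_interfaces(st, query_chain, cutoff=cutoff)
    annotations, n_dropped = map_calls(calls, mapping, st, query_chain)
    return annotations, calls, n_dropped
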