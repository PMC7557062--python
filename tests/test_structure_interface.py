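import gemmi
import numpy as np
import pandas as pd
import pytest

from savbind import structure_interface as si
from savbind import synthetic_data as sd


def make_structure(chain_specs):
    """Build a gemmi structure from {chain_id: [(resname, atomname, elem, xyz), ...]}
    with one residue per atom tuple."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain_id, residues in chain_specs.items():
        ch = gemmi.Chain(chain_id)
        for i, (resname, atomname, elem, xyz) in enumerate(residues):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = atomname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def random_complex(rng, n_per_chain=15, box=22.0):
    """Random-geometry complex: protein query chain plus protein/DNA/RNA
    substrate chains with uniformly scattered single-atom residues."""
    def coords():
        return tuple(rng.uniform(0, box, 3))

    return make_structure(
        {
            "A": [("ALA", "CA", "C", coords()) for _ in range(n_per_chain)],
            "B": [("GLY", "CA", "C", coords()) for _ in range(n_per_chain)],
            "C": [("DA", "P", "P", coords()) for _ in range(n_per_chain)],
            "D": [("U", "P", "P", coords()) for _ in range(n_per_chain)],
        }
    )


def brute_force_calls(structure, query_chain, cutoff):
    """O(n^2) oracle: per query residue and class, the minimum over every
    atom pair."""
    model = structure[0]
    chains = {ch.name: ch for ch in model}
    class_atoms = {}
    for name, ch in chains.items():
        if name == query_chain:
            continue
        ctype = si.classify_chain(ch)
        if ctype not in ("protein", "dna", "rna"):
            continue
        for res in ch:
            for atom in res:
                class_atoms.setdefault(ctype, []).append(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
    out = {}
    for res in chains[query_chain]:
        rx = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
        for cls, atoms in class_atoms.items():
            d = np.sqrt(((rx[:, None, :] - np.array(atoms)[None]) ** 2).sum(-1)).min()
            if d <= cutoff:
                out[(f"{res.seqid.num}", cls)] = d
    return out


class TestClassifyChain:
    @pytest.mark.parametrize(
        "residues, expected",
        [
            ([("ALA", "CA", "C", (0, 0, 0)), ("GLY", "CA", "C", (3, 0, 0)),
              ("LYS", "CA", "C", (6, 0, 0))], "protein"),
            ([("DA", "P", "P", (0, 0, 0)), ("DT", "P", "P", (3, 0, 0)),
              ("DG", "P", "P", (6, 0, 0)), ("DC", "P", "P", (9, 0, 0))], "dna"),
            ([("A", "P", "P", (0, 0, 0)), ("C", "P", "P", (3, 0, 0)),
              ("G", "P", "P", (6, 0, 0)), ("U", "P", "P", (9, 0, 0))], "rna"),
            ([("HOH", "O", "O", (0, 0, 0)), ("SO4", "S", "S", (3, 0, 0))], "other"),
        ],
    )
    def test_majority_vote(self, residues, expected):
        st = make_structure({"X": residues})
        assert si.classify_chain(st[0]["X"]) == expected

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            si.classify_chain(gemmi.Chain("Z"))


class TestCallInterfaces:
    def _two_atom(self, dz):
        return make_structure(
            {
                "A": [("ALA", "CA", "C", (0.0, 0.0, 0.0))],
                "B": [("DA", "P", "P", (0.0, 0.0, dz)),
                      ("DT", "P", "P", (0.0, 0.0, dz + 50))],
            }
        )

    def test_within_cutoff_called(self):
        calls = si.call_interfaces(self._two_atom(5.9), "A")
        assert [(c.res_id, c.binding_class) for c in calls] == [("1", "dna")]
        assert calls[0].min_distance == pytest.approx(5.9)

    def test_beyond_cutoff_not_called(self):
        assert si.call_interfaces(self._two_atom(6.1), "A") == []

    def test_boundary_inclusive(self):
        calls = si.call_interfaces(self._two_atom(6.0), "A")
        assert len(calls) == 1 and calls[0].min_distance == pytest.approx(6.0)

    def test_waters_and_het_excluded(self):
        st = make_structure(
            {
                "A": [("ALA", "CA", "C", (0, 0, 0))],
                "B": [("GLY", "CA", "C", (0, 0, 30)),
                      ("HOH", "O", "O", (0, 0, 2.0))],
            }
        )
        assert si.call_interfaces(st, "A") == []

    def test_non_protein_query_rejected(self):
        st = self._two_atom(5.0)
        with pytest.raises(ValueError):
            si.call_interfaces(st, "B")
        with pytest.raises(KeyError):
            si.call_interfaces(st, "Z")

    def test_matches_bruteforce_oracle(self, rng):
        st = random_complex(rng)
        for cutoff in (4.0, 6.0, 9.0):
            oracle = brute_force_calls(st, "A", cutoff)
            calls = {(c.res_id, c.binding_class): c.min_distance
                     for c in si.call_interfaces(st, "A", cutoff)}
            assert set(calls) == set(oracle)
            for key in calls:
                assert calls[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_monotone_in_cutoff(self, rng):
        st = random_complex(rng)
        previous = set()
        for cutoff in (3.0, 5.0, 7.0, 10.0):
            current = {(c.res_id, c.binding_class)
                       for c in si.call_interfaces(st, "A", cutoff)}
            assert previous <= current
            previous = current

    def test_altloc_keeps_highest_occupancy(self):
        st = make_structure(
            {
                "A": [("ALA", "CA", "C", (0, 0, 0))],
                "B": [("DA", "P", "P", (0, 0, 20)), ("DT", "P", "P", (0, 0, 24))],
            }
        )
        res = st[0]["A"][0]
        alt = gemmi.Atom()
        alt.name = "CA"
        alt.element = gemmi.Element("C")
        alt.pos = gemmi.Position(0, 0, 15)  # would be within 6 A of chain B
        alt.occ = 0.2
        alt.altloc = "B"
        res.add_atom(alt)  # lower occupancy than the 1.0 original
        assert si.call_interfaces(st, "A") == []


class TestMapCalls:
    def test_basic_translation(self):
        st = make_structure(
            {
                "A": [("ALA", "CA", "C", (0, 0, 0)) for _ in range(1)],
                "B": [("DA", "P", "P", (0, 0, 5.0)), ("DT", "P", "P", (0, 0, 40))],
            }
        )
        # give chain A ten residues at spaced positions
        st = make_structure(
            {
                "A": [("ALA", "CA", "C", (10.0 * i, 0, 0)) for i in range(10)],
                "B": [("DA", "P", "P", (90.0, 0, 5.0)), ("DT", "P", "P", (0, 0, 400))],
            }
        )
        mapping = pd.DataFrame(
            {
                "chain_id": "A",
                "struct_resnum": [str(i + 1) for i in range(10)],
                "protein_id": "P12345",
                "seq_pos": [101 + i for i in range(10)],
            }
        )
        calls = si.call_interfaces(st, "A")
        ann, dropped = si.map_calls(calls, mapping, st, "A")
        assert dropped == 0
        row = ann[ann["position"] == 110].iloc[0]
        assert row["dna_status"] == "binding"
        assert (ann[ann["position"] != 110]["dna_status"] == "other").all()
        assert (ann["protein_status"] == "other").all()

    def test_unmapped_call_dropped(self):
        st = make_structure(
            {
                "A": [("ALA", "CA", "C", (0, 0, 0))],
                "B": [("DA", "P", "P", (0, 0, 5.0)), ("DT", "P", "P", (0, 0, 40))],
            }
        )
        mapping = pd.DataFrame(
            {"chain_id": ["A"], "struct_resnum": ["99"], "protein_id": ["P1"],
             "seq_pos": [5]}
        )
        calls = si.call_interfaces(st, "A")
        ann, dropped = si.map_calls(calls, mapping, st, "A")
        assert dropped == 1 and len(ann) == 0

    def test_mapping_collision_rejected(self):
        st = make_structure({"A": [("ALA", "CA", "C", (0, 0, 0)),
                                   ("GLY", "CA", "C", (4, 0, 0))]})
        mapping = pd.DataFrame(
            {"chain_id": ["A", "A"], "struct_resnum": ["1", "2"],
             "protein_id": ["P1", "P1"], "seq_pos": [5, 5]}
        )
        with pytest.raises(ValueError, match="collision"):
            si.map_calls([], mapping, st, "A")


class TestPlantedComplex:
    def test_planted_interfaces_recovered_exactly(self):
        st, mapping, planted = sd.generate_complex()
        calls = si.call_interfaces(st, "A")
        ann, _ = si.map_calls(calls, mapping, st, "A")
        for cls in ("protein", "dna", "rna"):
            want = set(planted[planted["binding_class"] == cls]["seq_pos"])
            got = set(ann[ann[f"{cls}_status"] == "binding"]["position"])
            assert got == want

    def test_boundary_contact_called(self):
        cfg = sd.ComplexConfig(protein_contacts=(5,), dna_contacts=(), rna_contacts=(),
                               contact_distance=6.0)
        st, mapping, planted = sd.generate_complex(cfg)
        calls = si.call_interfaces(st, "A")
        assert [(c.res_id, c.binding_class) for c in calls] == [("5", "protein")]

    def test_no_contacts_no_calls(self):
        cfg = sd.ComplexConfig(protein_contacts=(), dna_contacts=(), rna_contacts=())
        st, _, planted = sd.generate_complex(cfg)
        assert si.call_interfaces(st, "A") == [] and len(planted) == 0

    def test_pdb_and_mmcif_roundtrip(self, tmp_path):
        st, _, _ = sd.generate_complex()
        want = sorted((c.res_id, c.binding_class) for c in si.call_interfaces(st, "A"))
        pdb = tmp_path / "c.pdb"
        st.write_pdb(str(pdb))
        cif = tmp_path / "c.cif"
        st.make_mmcif_document().write_file(str(cif))
        for path in (pdb, cif):
            got = sorted(
                (c.res_id, c.binding_class)
                for c in si.call_interfaces(si.read_structure(path), "A")
            )
            assert got == want
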