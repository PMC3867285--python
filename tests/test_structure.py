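"""PDB chain extraction, sequence-structure mapping, DSSP, PyMOL script."""

import pytest

from cube.structure import (
    ChainModel,
    emit_pymol_script,
    map_reference_to_chain,
    read_dssp,
    read_pdb_chain,
)


def atom_line(serial, name, resname, chain, resnum, x=0.0, y=0.0, z=0.0,
              record="ATOM"):
    return (f"{record:<6s}{serial:5d}  {name:<3s} {resname:>3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"           C")


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Chain A: MKVLW (5 CA), chain B: GAS (3 CA), a HEM ligand + water."""
    seq_a = ["MET", "LYS", "VAL", "LEU", "TRP"]
    seq_b = ["GLY", "ALA", "SER"]
    lines = []
    s = 1
    for i, rn in enumerate(seq_a, 1):
        lines.append(atom_line(s, "CA", rn, "A", i, z=1.5 * i))
        s += 1
    lines.append("TER")
    for i, rn in enumerate(seq_b, 1):
        lines.append(atom_line(s, "CA", rn, "B", i, x=10.0, z=1.5 * i))
        s += 1
    lines.append(atom_line(s, "FE", "HEM", "B", 90, x=20.0, record="HETATM"))
    lines.append(atom_line(s + 1, "O", "HOH", "B", 91, x=25.0, record="HETATM"))
    lines.append("END")
    p = tmp_path / "toy.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadPdbChain:
    def test_first_chain_default(self, two_chain_pdb):
        cm = read_pdb_chain(two_chain_pdb)
        assert cm.chain_id == "A" and cm.sequence == "MKVLW"
        assert cm.other_chains == ["B"]
        assert "HEM" in cm.het_records and "HOH" not in cm.het_records

    def test_explicit_chain(self, two_chain_pdb):
        cm = read_pdb_chain(two_chain_pdb, "B")
        assert cm.sequence == "GAS" and cm.other_chains == ["A"]

    def test_missing_chain_lists_available(self, two_chain_pdb):
        with pytest.raises(ValueError, match="available: A, B"):
            read_pdb_chain(two_chain_pdb, "Z")

    def test_hetatm_only_chain_rejected(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(atom_line(1, "FE", "HEM", "A", 1, record="HETATM")
                     + "\nEND\n")
        with pytest.raises(ValueError, match="no chain with standard residues"):
            read_pdb_chain(p)
        with pytest.raises(ValueError, match="no standard residues"):
            read_pdb_chain(p, "A")


class TestMapping:
    def test_identity_mapping(self, two_chain_pdb):
        cm = read_pdb_chain(two_chain_pdb)
        m = map_reference_to_chain("MKVLW", cm)
        assert m.coverage == 1.0
        assert m.pairs == [(i, (i, "")) for i in range(1, 6)]
        assert m.unmapped_reference == [] and m.unmapped_chain == []

    def test_truncated_n_terminus(self, two_chain_pdb):
        # reference has 2 extra N-terminal residues absent from the chain
        cm = read_pdb_chain(two_chain_pdb)
        m = map_reference_to_chain("GSMKVLW", cm)
        assert m.unmapped_reference == [1, 2]
        assert m.pairs == [(i + 2, (i, "")) for i in range(1, 6)]

    def test_monotone_mapping(self, two_chain_pdb):
        cm = read_pdb_chain(two_chain_pdb)
        m = map_reference_to_chain("MKVAAALW", cm)
        chain_order = [c for _, c in m.pairs]
        assert chain_order == sorted(chain_order)

    def test_low_coverage_warns(self, two_chain_pdb, caplog):
        cm = read_pdb_chain(two_chain_pdb)
        with caplog.at_level("WARNING"):
            m = map_reference_to_chain("PPPPPPPPPPPPPPPPPPPP", cm)
        assert m.coverage < 0.3
        assert any("may not match" in r.message for r in caplog.records)


def dssp_line(serial, resnum, chain, aa, acc, icode=" "):
    return f"{serial:5d}{resnum:5d}{icode}{chain} {aa}" + " " * 20 + f"{acc:4d}"


@pytest.fixture
def dssp_file(tmp_path):
    lines = [
        "==== Secondary Structure Definition, toy ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
        dssp_line(1, 1, "A", "M", 0),
        dssp_line(2, 2, "A", "G", 104),
        dssp_line(3, 3, "A", "W", 400),  # exceeds max ASA -> clip
        "  bad line",
        dssp_line(4, 1, "B", "G", 52),
    ]
    p = tmp_path / "toy.dssp"
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadDssp:
    def test_normalization_and_clipping(self, dssp_file, caplog):
        with caplog.at_level("WARNING"):
            acc = read_dssp(dssp_file, "A")
        assert acc[(1, "")] == 0.0
        assert acc[(2, "")] == 1.0  # glycine ACC at its max ASA
        assert acc[(3, "")] == 1.0  # clipped
        assert any("clipped" in r.message for r in caplog.records)
        assert (1, "") in acc and len(acc) == 3

    def test_other_chain(self, dssp_file):
        acc = read_dssp(dssp_file, "B")
        assert acc == {(1, ""): 0.5}

    def test_missing_file_yields_empty(self, tmp_path):
        assert read_dssp(tmp_path / "absent.dssp", "A") == {}
        assert read_dssp(None, "A") == {}


class TestPymolScript:
    def _emit(self, pdb, tmp_path, bins):
        cm = read_pdb_chain(pdb)
        m = map_reference_to_chain("MKVLW", cm)
        out = tmp_path / "out.pml"
        emit_pymol_script(cm, m, {"cons": bins}, out, pdb)
        return out.read_text()

    def test_single_bin_covers_all_mapped(self, two_chain_pdb, tmp_path):
        text = self._emit(two_chain_pdb, tmp_path,
                          {r: 1 for r in range(1, 6)})
        assert "select cube_bin01, cube_struct and chain A and resi 1+2+3+4+5" \
            in text
        assert "cube_bin02" not in text

    def test_context_chain_and_ligands_present(self, two_chain_pdb, tmp_path):
        text = self._emit(two_chain_pdb, tmp_path, {r: 1 for r in range(1, 6)})
        assert "select cube_context, cube_struct and (chain B)" in text
        assert "not resn HOH" in text

    def test_decile_selections_partition_mapped_set(self, two_chain_pdb,
                                                    tmp_path):
        bins = {1: 1, 2: 3, 3: 3, 4: 10, 5: 7}
        text = self._emit(two_chain_pdb, tmp_path, bins)
        seen = {}
        for line in text.splitlines():
            if line.startswith("select cube_bin"):
                name = line.split(",")[0].split()[1]
                resi = line.rsplit("resi ", 1)[1].split("+")
                for r in resi:
                    assert r not in seen, "residue in two decile selections"
                    seen[r] = name
        assert sorted(seen) == ["1", "2", "3", "4", "5"]

    def test_two_tracks_two_scenes(self, two_chain_pdb, tmp_path):
        cm = read_pdb_chain(two_chain_pdb)
        m = map_reference_to_chain("MKVLW", cm)
        out = tmp_path / "o.pml"
        bins = {r: 1 for r in range(1, 6)}
        emit_pymol_script(cm, m, {"conservation": bins,
                                  "specialization": bins}, out, two_chain_pdb)
        text = out.read_text()
        assert "scene conservation, store" in text
        assert "scene specialization, store" in text
        assert "select cube2_bin01" in text

    def test_byte_determinism(self, two_chain_pdb, tmp_path):
        a = self._emit(two_chain_pdb, tmp_path, {r: (r % 10) + 1
                                                 for r in range(1, 6)})
        b = self._emit(two_chain_pdb, tmp_path, {r: (r % 10) + 1
                                                 for r in range(1, 6)})
        assert a == b
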