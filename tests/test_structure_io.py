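"""Structure parsing, virtual dihedrals, and observation extraction."""

import math

import numpy as np
import pytest

from redalpha import (
    extract_backbone_observations,
    extract_contact_observations,
    read_structure,
    virtual_dihedral,
)
from redalpha.errors import FormatError, GeometryError
from redalpha.structure_io import Dataset, StructureRecord, load_dataset

from oracles import min_atom_distance_oracle, torsion_oracle

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# virtual dihedral


class TestVirtualDihedral:
    def test_planar_cis_is_zero(self):
        assert virtual_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == 0.0

    def test_planar_trans_is_pi(self):
        assert virtual_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(
            math.pi
        )

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3.0
            expect = torsion_oracle(*pts)
            assert virtual_dihedral(*pts) == pytest.approx(expect, abs=1e-10)

    def test_quarter_turn_example(self):
        # right-handed frame: +z displacement of the last point is a -pi/2
        # torsion, stored on the [0, 2*pi) branch as 3*pi/2
        val = virtual_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1))
        assert val == pytest.approx(
            torsion_oracle((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1))
        )
        assert val == pytest.approx(3 * math.pi / 2)

    def test_reversal_invariance_and_mirror_conjugation(self):
        # the torsion reads the same from either chain end; a mirror image
        # (which flips handedness) conjugates it to 2*pi - original
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 2.0
            fwd = virtual_dihedral(*pts)
            rev = virtual_dihedral(*pts[::-1])
            assert rev == pytest.approx(fwd, abs=1e-9)
            mirror = pts * np.array([1.0, 1.0, -1.0])
            mir = virtual_dihedral(*mirror)
            assert (fwd + mir) % TWO_PI == pytest.approx(
                0.0, abs=1e-9
            ) or fwd + mir == pytest.approx(TWO_PI, abs=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            virtual_dihedral((0, 0, 0), (0, 0, 0), (1, 1, 0), (2, 1, 0))
        with pytest.raises(GeometryError):
            virtual_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


# ---------------------------------------------------------------------------
# PDB reading


PDB_HEADER = "CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1\n"


def _atom_line(serial, name, resname, resseq, x, y, z, occ=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           C\n"
    )


def _write_chain(path, n=10, drop_ca_at=None):
    lines = [PDB_HEADER]
    serial = 1
    for i in range(n):
        if drop_ca_at != i:
            lines.append(_atom_line(serial, "CA", "ALA", i + 1, 3.8 * i, 0.1 * i * i, 0.0))
            serial += 1
        lines.append(_atom_line(serial, "CB", "ALA", i + 1, 3.8 * i, 0.1 * i * i, 1.5))
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


class TestReadStructure:
    def test_round_trip_length(self, tmp_path):
        p = _write_chain(tmp_path / "toy.pdb", n=10)
        rec = read_structure(p)
        assert len(rec.sequence) == 10
        assert rec.sequence == "A" * 10

    def test_residue_without_ca_dropped(self, tmp_path, caplog):
        p = _write_chain(tmp_path / "gap.pdb", n=10, drop_ca_at=4)
        with caplog.at_level("WARNING"):
            rec = read_structure(p)
        assert len(rec.sequence) == 9
        assert any("C-alpha" in m for m in caplog.messages)

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        lines = [PDB_HEADER]
        lines.append(_atom_line(1, "CA", "GLY", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A"))
        lines.append(_atom_line(2, "CA", "GLY", 1, 9.0, 9.0, 9.0, occ=0.6, altloc="B"))
        lines.append(_atom_line(3, "CA", "GLY", 2, 3.8, 0.0, 0.0))
        lines.append("END\n")
        p = tmp_path / "alt.pdb"
        p.write_text("".join(lines))
        rec = read_structure(p)
        # hand parse of the fixture: altloc B has occupancy 0.6 > 0.4
        np.testing.assert_allclose(rec.ca_coords[0], [9.0, 9.0, 9.0])

    def test_unreadable_file_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(FormatError):
            read_structure(p)


# ---------------------------------------------------------------------------
# observation extraction


def _zigzag_record(L, seq=None, break_at=None):
    """Non-planar chain with ~3.8 A consecutive CA distances."""
    rng = np.random.default_rng(3)
    ca = np.zeros((L, 3))
    for i in range(1, L):
        step = np.array([3.0, 2.0 * ((i % 2) - 0.5), 1.2 * ((i % 3) - 1.0)])
        step = step / np.linalg.norm(step) * 3.8
        ca[i] = ca[i - 1] + step
    if break_at is not None:
        ca[break_at:] += np.array([30.0, 0.0, 0.0])
    seq = seq or "ACDEFGHIKLMNPQRSTVWY"[:L] if L <= 20 else "A" * L
    heavy = [ca[i : i + 1] + np.array([0.0, 0.0, 1.0]) for i in range(L)]
    return StructureRecord(
        id="zig", sequence=seq[:L], ca_coords=ca, heavy_atoms=heavy
    )


class TestBackboneExtraction:
    @pytest.mark.parametrize("L", [5, 8, 15])
    def test_intact_chain_yields_L_minus_4(self, L):
        rec = _zigzag_record(L)
        assert len(extract_backbone_observations(rec)) == L - 4

    def test_chain_break_splits_windows(self):
        whole = _zigzag_record(20)
        broken = _zigzag_record(20, break_at=10)
        obs = extract_backbone_observations(broken)
        # two intact segments of length 10 each: 2 * (10 - 4)
        assert len(obs) == 2 * (10 - 4)
        assert len(extract_backbone_observations(whole)) == 16

    def test_x_trimer_members_excluded(self):
        rec = _zigzag_record(8, seq="AAAXAAAA")
        obs = extract_backbone_observations(rec)
        positions = {o.position for o in obs}
        # 'X' at 0-based index 3 kills trimers centered at indices 2, 3, 4;
        # of the windows 2..5 only i=5 (1-based 6) survives
        assert positions == {6}

    def test_gamma_matches_oracle_on_chain(self):
        rec = _zigzag_record(10)
        obs = extract_backbone_observations(rec)
        ca = rec.ca_coords
        for o in obs:
            i = o.position - 1
            g1 = torsion_oracle(ca[i - 2], ca[i - 1], ca[i], ca[i + 1])
            g2 = torsion_oracle(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
            assert o.gamma_pair[0] == pytest.approx(g1, abs=1e-9)
            assert o.gamma_pair[1] == pytest.approx(g2, abs=1e-9)


class TestContactExtraction:
    def _record_with_atoms(self, positions, atoms_per_res):
        ca = np.asarray(positions, dtype=float)
        L = len(ca)
        heavy = [np.asarray(a, dtype=float) for a in atoms_per_res]
        return StructureRecord(
            id="toy", sequence="A" * L, ca_coords=ca, heavy_atoms=heavy
        )

    def test_cap_excludes_beyond_12(self):
        L = 7
        ca = [[i * 3.8, 0, 0] for i in range(L)]
        ca[6] = [0.0, 12.5, 0.0]
        heavy = [[c] for c in ca]
        rec = self._record_with_atoms(ca, heavy)
        obs = extract_contact_observations(rec)
        assert not any(o.positions == (1, 7) for o in obs)

    def test_minimum_separation_is_five(self):
        # residues 1 and 5 (separation 4) at 4 A: excluded
        ca = [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0], [4.0, 0.5, 0], [19, 0, 0]]
        heavy = [[c] for c in ca]
        rec = self._record_with_atoms(ca, heavy)
        obs = extract_contact_observations(rec)
        assert not any(o.positions == (1, 5) for o in obs)
        assert all(o.separation >= 5 for o in obs)

    def test_distances_match_brute_force_oracle(self, corpus):
        rec = next(iter(corpus.records.values()))
        obs = extract_contact_observations(rec)
        assert obs, "fixture must produce contacts"
        for o in obs[:50]:
            i, j = o.positions[0] - 1, o.positions[1] - 1
            expect = min_atom_distance_oracle(rec.heavy_atoms[i], rec.heavy_atoms[j])
            assert o.distance == pytest.approx(expect, abs=1e-9)

    def test_symmetric_in_enumeration_order(self):
        rng = np.random.default_rng(8)
        ca = rng.normal(size=(12, 3)) * 4.0
        heavy = [[c] for c in ca]
        rec = self._record_with_atoms(ca, heavy)
        obs = extract_contact_observations(rec)
        pairs = {o.positions for o in obs}
        assert all(i < j for i, j in pairs)
        assert len(pairs) == len(obs)


# ---------------------------------------------------------------------------
# dataset assembly


class TestLoadDataset:
    def test_three_intact_chains_give_expected_n_d(self, tmp_path):
        from redalpha import default_model, generate_coordinate_files

        model = default_model(seed=3)
        paths, sidecar = generate_coordinate_files(model, 3, 50, tmp_path, seed=5)
        ds = load_dataset(paths, sidecar)
        assert ds.n_d == 3 * (50 - 4)

    def test_missing_sidecar_yields_unknown_classes(self, tmp_path):
        from redalpha import default_model, generate_coordinate_files

        model = default_model(seed=3)
        paths, _ = generate_coordinate_files(model, 3, 50, tmp_path, seed=5)
        ds = load_dataset(paths, sidecar=None)
        assert set(ds.class_index) == {"unknown"}
        assert len(ds.class_index["unknown"]) == 3

    def test_sidecar_classes_partition_records(self, tmp_path):
        from redalpha import default_model, generate_coordinate_files

        model = default_model(seed=3)
        paths, _ = generate_coordinate_files(model, 3, 50, tmp_path, seed=5)
        side = tmp_path / "side.tsv"
        ids = sorted(p.stem for p in paths)
        side.write_text(f"{ids[0]}\t3\n{ids[1]}\t3\n")
        ds = load_dataset(paths, side)
        assert set(ds.class_index["3"]) == {ids[0], ids[1]}
        sub = ds.subset(["3"])
        assert {o.source_id for o in sub.backbone_obs} == {ids[0], ids[1]}
        assert sub.n_d == 2 * (50 - 4)
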