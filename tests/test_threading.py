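"""Boltzmann-inverted potentials and gapless shuffle threading."""

import math

import numpy as np
import pytest

from redalpha import (
    AA_ORDER,
    ContactDiscretization,
    ReducedAlphabet,
    SubstitutionRule,
    fit_backbone,
    fit_contact,
    mi_backbone,
    mi_contact,
)
from redalpha.errors import ConfigurationError
from redalpha.structure_io import load_dataset
from redalpha.threading import (
    PotentialTables,
    ThreadingResult,
    build_potential,
    shuffle_threading,
    survey_threading,
    thread_energy,
)

IDENTITY = SubstitutionRule.identity()


@pytest.fixture(scope="module")
def potential_setup(corpus, table16):
    disc = ContactDiscretization(d_max=10.0, m=20)
    bb = fit_backbone(corpus, table16, IDENTITY, lam=1.0, loo=False)
    cc = fit_contact(corpus, disc, IDENTITY, lam=1.0, loo=False)
    return corpus, table16, disc, build_potential(bb, cc)


class TestBuildPotential:
    def test_entries_are_neg_log_ratios(self, corpus, table16):
        disc = ContactDiscretization(d_max=10.0, m=20)
        lam = 1.0
        bbm = fit_backbone(corpus, table16, IDENTITY, lam=lam, loo=False)
        ccm = fit_contact(corpus, disc, IDENTITY, lam=lam, loo=False)
        pot = build_potential(bbm, ccm, kT=1.0)
        assert np.isfinite(pot.bb).all() and np.isfinite(pot.contact).all()
        # hand recomputation for one occupied (trimer, cell) entry
        code = int(bbm.cond[0])
        cell = int(bbm.cells[0])
        n = bbm.n_d
        n_cell = bbm.n_cell()
        joint = ((bbm.cond == code) & (bbm.cells == cell)).sum()
        tot = (bbm.cond == code).sum()
        f_cond = (joint + lam * n_cell[cell] / n) / (tot + lam)
        f_marg = (n_cell[cell] + lam / table16.k) / (n + lam)
        assert pot.bb[code, cell] == pytest.approx(
            -math.log(f_cond / f_marg), abs=1e-12
        )

    def test_uniform_propensities_give_zero_potential(self):
        """Structure independent of sequence with exactly uniform counts."""
        from redalpha.structure_io import BackboneObservation, ContactObservation, Dataset
        from redalpha import VoronoiPartition

        part = VoronoiPartition(seeds=((1.0, 1.0), (5.0, 5.0)))
        disc = ContactDiscretization(d_max=10.0, m=2)
        bb = []
        for t in ("AAA", "GGG"):
            for g in ((1.0, 1.0), (5.0, 5.0)):
                bb.extend(
                    BackboneObservation(tuple(t), g, "u", i + 2) for i in range(5)
                )
        cc = []
        for p in (("A", "A"), ("G", "G")):
            for d in (3.0, 8.0):
                cc.extend(
                    ContactObservation(p, d, 5, "u", (1, 6 + i)) for i in range(5)
                )
        ds = Dataset(backbone_obs=bb, contact_obs=cc)
        bbm = fit_backbone(ds, part, IDENTITY, lam=0.0, loo=False)
        ccm = fit_contact(ds, disc, IDENTITY, lam=0.0, loo=False)
        pot = build_potential(bbm, ccm)
        occupied_bb = pot.bb[np.unique(bbm.cond)]
        occupied_c = pot.contact[np.unique(ccm.pairs)]
        np.testing.assert_allclose(occupied_bb, 0.0, atol=1e-12)
        np.testing.assert_allclose(occupied_c, 0.0, atol=1e-12)

    def test_mismatched_rules_rejected(self, corpus, table16):
        disc = ContactDiscretization(d_max=10.0, m=20)
        other = SubstitutionRule.from_string("AVDELGDIELIDPEESTVLL")
        bbm = fit_backbone(corpus, table16, IDENTITY, loo=False)
        ccm = fit_contact(corpus, disc, other, loo=False)
        with pytest.raises(ConfigurationError):
            build_potential(bbm, ccm)


class TestThreadEnergy:
    def test_zero_potential_gives_zero_energy(self, potential_setup):
        corpus, part, disc, pot = potential_setup
        zero = PotentialTables(
            bb=np.zeros_like(pot.bb), contact=np.zeros_like(pot.contact),
            kT=1.0, rule=IDENTITY, lam=pot.lam,
        )
        rec = next(iter(corpus.records.values()))
        assert thread_energy(rec, rec.sequence, zero, part, disc, IDENTITY) == 0.0

    def test_length_mismatch_rejected(self, potential_setup):
        corpus, part, disc, pot = potential_setup
        rec = next(iter(corpus.records.values()))
        with pytest.raises(ConfigurationError):
            thread_energy(rec, rec.sequence[:-1], pot, part, disc, IDENTITY)

    def test_native_energy_equals_mi_identity(self, corpus, table16):
        """Plug-in potential on a single-record dataset: the native energy
        equals -kT * n_d * (I_bb + I_c) when estimators share lam=0, loo off."""
        disc = ContactDiscretization(d_max=10.0, m=20)
        rid = sorted(corpus.records)[0]
        rec = corpus.records[rid]
        sub = corpus.subset([rec.fold_class])
        # single-record dataset built from scratch
        from redalpha.structure_io import (
            Dataset,
            extract_backbone_observations,
            extract_contact_observations,
        )

        ds1 = Dataset(
            backbone_obs=extract_backbone_observations(rec),
            contact_obs=extract_contact_observations(rec),
            records={rid: rec},
        )
        bbm = fit_backbone(ds1, table16, IDENTITY, lam=0.0, loo=False)
        ccm = fit_contact(ds1, disc, IDENTITY, lam=0.0, loo=False)
        pot = build_potential(bbm, ccm, kT=1.0)
        du = thread_energy(rec, rec.sequence, pot, table16, disc, IDENTITY)
        expect = -1.0 * ds1.n_d * (mi_backbone(bbm) + mi_contact(ccm))
        assert du == pytest.approx(expect, abs=1e-9)

    def test_two_residue_contact_hand_sum(self):
        """Hand-built record: energy equals the two table lookups summed."""
        from redalpha import VoronoiPartition
        from redalpha.structure_io import StructureRecord

        part = VoronoiPartition(seeds=((1.0, 1.0),))
        disc = ContactDiscretization(d_max=10.0, m=2)
        # 7 collinear-ish residues; only the (1, 7) pair is close in space
        ca = np.array(
            [[0, 0, 0], [3.8, 0.2, 0], [7.4, 1, 0], [10, 3, 0.5], [7.4, 5.5, 0],
             [3.8, 6, 0.3], [0.5, 4, 0]],
            dtype=float,
        )
        heavy = [ca[i : i + 1] for i in range(7)]
        rec = StructureRecord(
            id="h", sequence="ACDEFGH", ca_coords=ca, heavy_atoms=heavy
        )
        bb = np.zeros((8000, 1))
        contact = np.zeros((400, 2))
        a_idx, h_idx = AA_ORDER.index("A"), AA_ORDER.index("H")
        d17 = float(np.linalg.norm(ca[0] - ca[6]))
        assert d17 <= 10.0
        b = 0 if d17 <= 5.0 else 1
        contact[a_idx * 20 + h_idx, b] = -2.5
        pot = PotentialTables(bb=bb, contact=contact, kT=1.0, rule=IDENTITY, lam=1.0)
        du = thread_energy(rec, rec.sequence, pot, part, disc, IDENTITY)
        from redalpha.structure_io import extract_contact_observations

        contacts = extract_contact_observations(rec)
        expected_pairs = {o.positions for o in contacts}
        assert (1, 7) in expected_pairs
        # the A-H contact is double counted (both endpoint residues)
        others = len(expected_pairs) - 1
        assert du == pytest.approx(2 * -2.5 + others * 0.0, abs=1e-12)


class TestShuffleThreading:
    def test_zero_potential_zero_gap(self, potential_setup):
        corpus, part, disc, pot = potential_setup
        zero = PotentialTables(
            bb=np.zeros_like(pot.bb), contact=np.zeros_like(pot.contact),
            kT=1.0, rule=IDENTITY, lam=pot.lam,
        )
        rec = next(iter(corpus.records.values()))
        res = shuffle_threading(rec, zero, part, disc, IDENTITY, n_shuffles=10, seed=0)
        assert res.gap == 0.0

    def test_homopolymer_gap_exactly_zero(self, table16):
        from redalpha import default_model, generate_coordinate_files

        import tempfile

        disc = ContactDiscretization(d_max=10.0, m=20)
        with tempfile.TemporaryDirectory() as td:
            model = default_model(seed=14)
            paths, _ = generate_coordinate_files(model, 1, 40, td, seed=15)
            ds = load_dataset(paths)
            rid, rec = next(iter(ds.records.items()))
            rec.sequence = "A" * len(rec)  # homopolymer remount
            bbm = fit_backbone(ds, table16, IDENTITY, loo=False)
            ccm = fit_contact(ds, disc, IDENTITY, loo=False)
            pot = build_potential(bbm, ccm)
            res = shuffle_threading(rec, pot, table16, disc, IDENTITY, 20, seed=3)
            assert res.gap == pytest.approx(0.0, abs=1e-12)

    def test_shuffles_preserve_composition_and_reproduce(self, potential_setup):
        corpus, part, disc, pot = potential_setup
        rec = next(iter(corpus.records.values()))
        a = shuffle_threading(rec, pot, part, disc, IDENTITY, n_shuffles=25, seed=9)
        b = shuffle_threading(rec, pot, part, disc, IDENTITY, n_shuffles=25, seed=9)
        np.testing.assert_array_equal(a.per_shuffle, b.per_shuffle)
        assert a.n_shuffles == 25
        assert a.gap == pytest.approx(a.du_native - a.du_shuffled_mean)

    def test_planted_native_gap_negative(self, potential_setup):
        """Matched tables on planted chains favor the native sequence."""
        corpus, part, disc, pot = potential_setup
        gaps = [
            shuffle_threading(rec, pot.backbone_only(), part, disc, IDENTITY,
                              n_shuffles=60, seed=i).gap / len(rec)
            for i, (_, rec) in enumerate(sorted(corpus.records.items()))
        ]
        assert np.mean(gaps) < 0.0

    def test_gap_estimate_stabilizes_with_more_shuffles(self, potential_setup):
        corpus, part, disc, pot = potential_setup
        rec = next(iter(corpus.records.values()))
        r250 = shuffle_threading(rec, pot, part, disc, IDENTITY, 250, seed=2)
        r500 = shuffle_threading(rec, pot, part, disc, IDENTITY, 500, seed=3)
        se = r500.per_shuffle.std() / math.sqrt(250)
        assert abs(r250.du_shuffled_mean - r500.du_shuffled_mean) < 2 * se + 1e-9


class TestSurveyThreading:
    def test_single_alphabet_ranks_first(self, potential_setup, table16):
        corpus, part, disc, _ = potential_setup
        alphabet = ReducedAlphabet.from_string("ADEGILPSTV")
        rule = SubstitutionRule.from_string("AVDELGDIELIDPEESTVLL")
        sv = survey_threading(
            corpus, [alphabet], {alphabet.canonical: rule}, part, disc,
            n_shuffles=20, seed=1,
        )
        assert len(sv.table) == 1
        assert {"du_native_kT", "du_shuffled_mean_kT", "gap_kT"} <= set(sv.table)

    def test_group_aligned_alphabet_discriminates_better(self, table16, tmp_path):
        """An alphabet keeping one letter per planted group beats one that
        collapses distinct groups, over several chains."""
        from redalpha import informative_letters_model, generate_coordinate_files

        model = informative_letters_model("ADEGILPSTV", sigma=0.1, seed=33)
        paths, sidecar = generate_coordinate_files(model, 12, 70, tmp_path, seed=34)
        ds = load_dataset(paths, sidecar)
        part, _ = __import__("redalpha").optimize_voronoi(
            ds, 8, mc=__import__("redalpha").MCParams(patience=80, restarts=2), seed=1
        )
        disc = ContactDiscretization(d_max=10.0, m=10)
        aligned = ReducedAlphabet.from_string("ADEGILPSTV")
        # partner letters: mapping each onto its planted twin loses nothing
        aligned_rule = SubstitutionRule.from_string("AADEDGEIGLILPPSSTVTV")
        # adversarial: collapse everything onto two letters of one group
        adv = ReducedAlphabet.from_string("AC")
        adv_rule = SubstitutionRule(
            {a: ("A" if i % 2 else "C") for i, a in enumerate(AA_ORDER)}
            | {"A": "A", "C": "C"}
        )
        sv = survey_threading(
            ds,
            [aligned, adv],
            {aligned.canonical: aligned_rule, adv.canonical: adv_rule},
            part,
            disc,
            mode="backbone",
            n_shuffles=40,
            seed=5,
        )
        gaps = dict(zip(sv.table["alphabet"], sv.table["gap_kT"]))
        assert gaps[aligned.canonical] < gaps[adv.canonical]

    def test_result_requires_shuffles(self):
        with pytest.raises(ConfigurationError):
            ThreadingResult(
                du_native=0.0, du_shuffled_mean=0.0, n_shuffles=0,
                per_shuffle=np.empty(0),
            )
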