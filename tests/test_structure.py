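"""Structure parsing, renumbering, contact extraction and evaluation."""

import random
from io import StringIO

import pytest

from cmaptools.core import Contact, ContactMap, Sequence
from cmaptools.structure import (
    EvaluationResult,
    ResidueSite,
    contacts_from_structure,
    evaluate,
    read_structure,
    renumber_sites,
    apply_renumbering,
    resolved_indices,
)
from cmaptools.synthetic import chain_to_pdb, synth_chain, synth_prediction
from _oracles import structure_contacts_oracle


def pdb_atom(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:3s} {chain}{resnum:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{name[0]:>2s}"
    )


def collinear_sites(n, spacing=3.8):
    """Residues on a straight line: pair distances are multiples of spacing."""
    return [
        ResidueSite("A", k + 1, "ALA", k * spacing, 0.0, 0.0, "CB")
        for k in range(n)
    ]


class TestReadStructure:
    def test_cb_preferred_over_ca(self):
        text = "\n".join(
            [
                pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
                pdb_atom(2, "CB", "ALA", "A", 1, 1, 1, 1),
                "END",
            ]
        )
        (site,) = read_structure(StringIO(text))
        assert site.atom_used == "CB" and site.x == 1.0

    def test_glycine_falls_back_to_ca(self):
        text = pdb_atom(1, "CA", "GLY", "A", 1, 2, 2, 2) + "\nEND\n"
        (site,) = read_structure(StringIO(text))
        assert site.atom_used == "CA" and site.residue_name == "GLY"

    def test_first_model_only(self):
        text = "\n".join(
            [
                "MODEL        1",
                pdb_atom(1, "CB", "ALA", "A", 1, 0, 0, 0),
                "ENDMDL",
                "MODEL        2",
                pdb_atom(2, "CB", "ALA", "A", 1, 9, 9, 9),
                pdb_atom(3, "CB", "ALA", "A", 2, 9, 9, 12),
                "ENDMDL",
                "END",
            ]
        )
        sites = read_structure(StringIO(text))
        assert len(sites) == 1 and sites[0].x == 0.0

    def test_altloc_highest_occupancy_wins(self):
        text = "\n".join(
            [
                pdb_atom(1, "CB", "ALA", "A", 1, 0, 0, 0, occ=0.3, altloc="A"),
                pdb_atom(2, "CB", "ALA", "A", 1, 5, 5, 5, occ=0.7, altloc="B"),
                "END",
            ]
        )
        (site,) = read_structure(StringIO(text))
        assert site.x == 5.0

    def test_absent_chain_rejected(self):
        text = pdb_atom(1, "CB", "ALA", "A", 1, 0, 0, 0) + "\nEND\n"
        with pytest.raises(ValueError, match="chain 'B'"):
            read_structure(StringIO(text), chain="B")

    def test_multi_chain_requires_selection(self):
        text = "\n".join(
            [
                pdb_atom(1, "CB", "ALA", "A", 1, 0, 0, 0),
                pdb_atom(2, "CB", "ALA", "B", 1, 9, 9, 9),
                "END",
            ]
        )
        with pytest.raises(ValueError, match="specify"):
            read_structure(StringIO(text))
        assert len(read_structure(StringIO(text), chain="B")) == 1


class TestRenumbering:
    def test_window_scan_finds_offset(self):
        sites = [
            ResidueSite("A", 12 + k, code, 0.0, 0.0, k * 3.8, "CB")
            for k, code in enumerate(["MET", "LYS", "VAL", "LEU", "ALA"])
        ]
        mapping = renumber_sites(sites, Sequence("t", "GGMKVLAGG"))
        assert mapping == {12: 3, 13: 4, 14: 5, 15: 6, 16: 7}

    def test_identity_mapping(self):
        sites, seq = synth_chain(15, seed=2)
        mapping = renumber_sites(sites, seq)
        assert mapping == {k: k for k in range(1, 16)}

    def test_no_match_demands_manual_offset(self):
        sites = [ResidueSite("A", 1, "TRP", 0, 0, 0, "CB")]
        with pytest.raises(ValueError, match="manual offset"):
            renumber_sites(sites, Sequence("t", "AAAA"))

    def test_ambiguous_placement_rejected(self):
        sites = [ResidueSite("A", 1, "ALA", 0, 0, 0, "CB")]
        with pytest.raises(ValueError, match="ambiguous"):
            renumber_sites(sites, Sequence("t", "AAAA"))

    def test_apply_renumbering_shifts_sites(self):
        sites = [ResidueSite("A", 12, "MET", 0, 0, 0, "CB")]
        out = apply_renumbering(sites, {12: 3})
        assert out[0].residue_number == 3


class TestContactsFromStructure:
    def test_boundary_inclusive(self):
        sites = [
            ResidueSite("A", 1, "ALA", 0, 0, 0, "CB"),
            ResidueSite("A", 2, "ALA", 7.9, 0, 0, "CB"),
        ]
        assert len(contacts_from_structure(sites)) == 1

    def test_beyond_cutoff_excluded(self):
        sites = [
            ResidueSite("A", 1, "ALA", 0, 0, 0, "CB"),
            ResidueSite("A", 2, "ALA", 8.1, 0, 0, "CB"),
        ]
        assert len(contacts_from_structure(sites)) == 0

    def test_collinear_chain_yields_exactly_two_diagonals(self):
        # spacing 3.8: |i-j|=1 -> 3.8, =2 -> 7.6 (in), =3 -> 11.4 (out)
        cmap = contacts_from_structure(collinear_sites(10), 8.0, 1)
        expected = {(i, i + 1) for i in range(1, 10)} | {
            (i, i + 2) for i in range(1, 9)
        }
        assert cmap.pairs() == expected

    def test_matches_all_pairs_oracle(self, folded_chain):
        sites, _ = folded_chain
        for min_sep in (1, 5, 23):
            cmap = contacts_from_structure(sites, 8.0, min_sep)
            assert cmap.pairs() == structure_contacts_oracle(sites, 8.0, min_sep)

    def test_site_order_invariance(self, folded_chain):
        sites, _ = folded_chain
        shuffled = list(sites)
        random.Random(0).shuffle(shuffled)
        assert (
            contacts_from_structure(shuffled, 8.0, 5).pairs()
            == contacts_from_structure(sites, 8.0, 5).pairs()
        )


class TestEvaluate:
    def test_self_prediction_is_perfect(self, folded_chain):
        sites, _ = folded_chain
        reference = contacts_from_structure(sites, 8.0, 5)
        results = evaluate(reference, sites, L=60, factors=(0.5, 1.0))
        assert all(r.precision == 1.0 for r in results)

    def test_disjoint_prediction_scores_zero(self, folded_chain):
        sites, _ = folded_chain
        reference = contacts_from_structure(sites, 8.0, 5)
        decoys = ContactMap()
        k = 0
        for i in range(1, 55):
            for j in range(i + 5, 61):
                if (i, j) not in reference and k < 30:
                    decoys.add(Contact(i, j, raw_score=1.0 - k * 0.01))
                    k += 1
        results = evaluate(decoys, sites, L=60, factors=(0.5,))
        assert results[0].precision == 0.0

    def test_decoy_dilution_composition(self, folded_chain):
        sites, _ = folded_chain
        reference = contacts_from_structure(sites, 8.0, 5)
        pred = synth_prediction(reference, 40, 0.5, seed=3, min_separation=5)
        # factor small enough to select only the top-ranked (true) pairs
        (head,) = evaluate(pred, sites, L=60, factors=(1 / 6,))
        assert head.precision == 1.0 and head.n_selected == 10
        (full,) = evaluate(pred, sites, L=60, factors=(2 / 3,))
        assert full.n_selected == 40
        assert full.precision == 20 / 40

    def test_counts_always_partition_selection(self, folded_chain):
        sites, _ = folded_chain
        reference = contacts_from_structure(sites, 8.0, 5)
        rng = random.Random(17)
        for trial in range(5):
            pred = synth_prediction(
                reference, 30, rng.choice([0.0, 0.3, 0.7, 1.0]),
                seed=trial, min_separation=5,
            )
            resolved_subset = [s for s in sites if rng.random() < 0.8]
            for r in evaluate(pred, resolved_subset, L=60, factors=(0.25, 0.5)):
                assert r.n_selected == r.n_tp + r.n_fp + r.n_unknown

    def test_factors_must_increase(self, folded_chain):
        sites, _ = folded_chain
        with pytest.raises(ValueError, match="strictly increasing"):
            evaluate(ContactMap(length_hint=60), sites, factors=(0.5, 0.5))

    def test_inconsistent_result_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            EvaluationResult(1.0, 5, 2, 2, 2, 0.5)


class TestPdbRoundTrip:
    def test_synthetic_chain_survives_pdb(self):
        sites, seq = synth_chain(25, seed=6, compactness=0.6)
        back = read_structure(StringIO(chain_to_pdb(sites)))
        assert len(back) == len(sites)
        assert resolved_indices(back) == set(range(1, 26))
        for a, b in zip(sites, back):
            assert (a.x, a.y, a.z) == pytest.approx((b.x, b.y, b.z), abs=1e-3)
            assert b.atom_used == ("CA" if a.residue_name == "GLY" else "CB")
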