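"""Generation metrics on handcrafted fixtures with exactly known ratios."""

import numpy as np
import pytest

from tmcdiff.fixtures import make_corpus, make_toy_complex
from tmcdiff.metrics import (
    GenerationReport,
    Ratio,
    aggregate_reports,
    bond_length_profile,
    complex_validity,
    conformer_rmsd,
    ligand_connectivity,
    ligand_validity,
    novelty,
    uniqueness,
)

from conftest import random_rotation


def _sane_ligand():
    # ethanol-like chain C-C-O
    return (["C", "C", "O"], np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.1, 0]]))


def _pentavalent_carbon():
    # central C with five neighbours at bonding distance: sanitization must fail
    el = ["C", "C", "C", "C", "C", "C"]
    co = np.array([[0, 0, 0], [1.5, 0, 0], [-1.5, 0, 0], [0, 1.5, 0],
                   [0, -1.5, 0], [0, 0, 1.5]])
    return el, co


def _split_ligand():
    return (["C", "C"], np.array([[0, 0, 0], [8.0, 0, 0]]))


class TestLigandValidity:
    def test_all_sane_templates_are_valid(self):
        assert ligand_validity([_sane_ligand()] * 4).value == 1.0

    def test_pentavalent_carbon_halves_the_ratio(self):
        r = ligand_validity([_sane_ligand(), _pentavalent_carbon()])
        assert (r.numerator, r.denominator) == (1, 2)

    def test_concatenation_is_count_weighted_mean(self):
        a = [_sane_ligand()] * 3
        b = [_sane_ligand(), _pentavalent_carbon()]
        ra, rb, rab = ligand_validity(a), ligand_validity(b), ligand_validity(a + b)
        assert rab.numerator == ra.numerator + rb.numerator
        assert rab.denominator == ra.denominator + rb.denominator

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ligand_validity([])


class TestLigandConnectivity:
    def test_chelate_counts_connected(self):
        assert ligand_connectivity([_sane_ligand()]).value == 1.0

    def test_disjoint_fragments_not_connected(self):
        assert ligand_connectivity([_split_ligand()]).value == 0.0

    def test_three_of_four_connected(self):
        r = ligand_connectivity([_sane_ligand()] * 3 + [_split_ligand()])
        assert r.value == 0.75


class TestComplexValidity:
    def test_pristine_fixture_batch_is_fully_valid(self):
        cs, _ = make_corpus(6, seed=5)
        assert complex_validity(cs).value == 1.0

    def test_superposed_atoms_fail_clash_check(self):
        cx = make_toy_complex("Fe", ["aqua"] * 6, "octahedral", seed=1)
        bad = cx.copy()
        bad.coords[2] = bad.coords[1] + np.array([0.1, 0, 0])
        from tmcdiff.complexes import partition_ligands
        bad.ligands = None
        partition_ligands(bad)
        from tmcdiff.metrics import check_complex
        ok, detail = check_complex(bad, target_cn=6)
        assert not detail["clash"]

    def test_nine_of_ten_is_point_nine(self):
        cs, _ = make_corpus(9, seed=7)
        bad = cs[0].copy()
        bad.coords[2] = bad.coords[1] + np.array([0.05, 0, 0])
        bad.ligands = None
        r = complex_validity(cs + [bad])
        assert (r.numerator, r.denominator) == (9, 10)

    def test_monotone_in_checks(self):
        cs, _ = make_corpus(5, seed=11)
        bad = cs[0].copy()
        bad.coords[2] = bad.coords[1] + np.array([0.05, 0, 0])
        bad.ligands = None
        batch = cs + [bad]
        r_some = complex_validity(batch, checks=("cn",))
        r_all = complex_validity(batch, checks=("cn", "clash", "ligands", "donor"))
        assert r_all.numerator <= r_some.numerator


class TestNoveltyUniqueness:
    def test_subset_of_training_is_zero_novel(self):
        assert novelty(["CO", "CC"], ["CO", "CC", "CN"]).value == 0.0

    def test_disjoint_sets_fully_novel(self):
        assert novelty(["CF", "CBr"], ["CO", "CC"]).value == 1.0

    def test_three_of_four_novel(self):
        r = novelty(["X1", "X2", "X3", "CO"], ["CO", "CC"])
        assert r.value == 0.75

    def test_all_identical_uniqueness_is_one_over_n(self):
        assert uniqueness(["CO"] * 5).value == pytest.approx(0.2)

    def test_all_distinct_is_one(self):
        assert uniqueness(["A", "B", "C"]).value == 1.0

    def test_aabc_is_three_quarters(self):
        assert uniqueness(["A", "A", "B", "C"]).value == 0.75


class TestBondLengthProfile:
    def test_uniform_donors_give_that_distance(self):
        cx = make_toy_complex("Fe", ["aqua"] * 6, "octahedral", seed=1, jitter=0.0)
        assert bond_length_profile(cx) == pytest.approx(2.0, abs=1e-9)

    def test_mean_of_two_shells(self):
        from tmcdiff.complexes import TMComplex, partition_ligands

        cx = TMComplex(elements=["Fe", "O", "O"],
                       coords=[[0, 0, 0], [1.9, 0, 0], [0, 2.1, 0]])
        partition_ligands(cx)
        assert bond_length_profile(cx) == pytest.approx(2.0)

    def test_hs_geometry_shifted_by_point_two(self):
        """Uniformly stretching every metal-donor bond by 0.2 A (the typical
        low-spin -> high-spin relaxation) shifts the mean by exactly 0.2."""
        ls = make_toy_complex("Fe", ["aqua"] * 6, "octahedral", seed=3, jitter=0.0)
        hs = ls.copy()
        hs.coords[1:] *= (2.2 / 2.0)     # radial scaling of single-atom ligands
        hs.ligands = None
        from tmcdiff.complexes import partition_ligands
        partition_ligands(hs)
        diff = bond_length_profile(hs, "HS") - bond_length_profile(ls, "LS")
        assert diff == pytest.approx(0.2, abs=1e-9)

    def test_zero_donors_errors(self):
        from tmcdiff.complexes import TMComplex, partition_ligands

        cx = TMComplex(elements=["Fe", "C", "C"],
                       coords=[[0, 0, 0], [8, 0, 0], [9.4, 0, 0]])
        partition_ligands(cx)
        with pytest.raises(ValueError, match="zero donors"):
            bond_length_profile(cx)


class TestConformerRMSD:
    def test_identical_structures_zero(self, hexa_mono):
        assert conformer_rmsd(hexa_mono, hexa_mono) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_and_translation_zero(self, hexa_mono):
        rot = hexa_mono.copy()
        rot.coords = hexa_mono.coords @ random_rotation(5).T + np.array([3, -1, 2])
        assert conformer_rmsd(hexa_mono, rot) == pytest.approx(0.0, abs=1e-8)

    def test_matches_quaternion_oracle_and_rotation_grid(self):
        """Two independent checks on a 4-atom toy: Horn's closed-form
        quaternion solution agrees to 1e-9, and no rotation from a 15-degree
        exhaustive grid beats the reported optimum."""
        from tmcdiff.complexes import TMComplex

        rng = np.random.default_rng(17)
        a = TMComplex(elements=["Fe", "O", "N", "C"],
                      coords=rng.uniform(-2, 2, (4, 3)))
        b = TMComplex(elements=["Fe", "O", "N", "C"],
                      coords=a.coords + rng.normal(0, 0.3, (4, 3)))
        got = conformer_rmsd(a, b)

        ac = a.coords - a.coords.mean(0)
        bc = b.coords - b.coords.mean(0)

        # Horn (1987): optimal superposition from the largest eigenvalue of
        # the 4x4 quaternion cross-correlation matrix
        sxx = bc.T @ ac
        S = sxx
        K = np.array([
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ])
        lam = np.linalg.eigvalsh(K)[-1]
        e2 = (np.sum(ac**2) + np.sum(bc**2) - 2 * lam) / ac.shape[0]
        horn = np.sqrt(max(e2, 0.0))
        assert got == pytest.approx(horn, abs=1e-9)

        from scipy.spatial.transform import Rotation

        grid = np.linspace(0, 2 * np.pi, 25)[:-1]
        half = np.linspace(0, np.pi, 13)
        best = np.inf
        for za in grid:
            for ya in half:
                for zb in grid:
                    R = Rotation.from_euler("zyz", [za, ya, zb]).as_matrix()
                    rmsd = np.sqrt(np.mean(np.sum((bc @ R.T - ac) ** 2, axis=1)))
                    best = min(best, rmsd)
        assert got <= best + 1e-9        # optimal superposition is a lower bound
        assert best - got < 0.05         # a fine grid gets close

    def test_symmetry(self, hexa_mono, two_tridentate):
        a = hexa_mono
        b = a.copy()
        b.coords = a.coords + np.random.default_rng(2).normal(0, 0.2, a.coords.shape)
        assert conformer_rmsd(a, b) == pytest.approx(conformer_rmsd(b, a), abs=1e-10)

    def test_mismatch_raises(self, hexa_mono, two_tridentate):
        with pytest.raises(ValueError):
            conformer_rmsd(hexa_mono, two_tridentate)


class TestAggregation:
    def _report(self, num, den):
        r = Ratio(num, den)
        return GenerationReport(p_l_val=r, p_l_con=r, p_c_val=r)

    def test_ten_identical_runs_have_zero_std(self):
        agg = aggregate_reports([self._report(4, 5)] * 10)
        assert agg["p_l_val"]["mean"] == pytest.approx(0.8)
        assert agg["p_l_val"]["std"] == 0.0

    def test_two_run_mean(self):
        agg = aggregate_reports([self._report(4, 5), self._report(5, 5)])
        assert agg["p_c_val"]["mean"] == pytest.approx(0.9)
        assert agg["p_c_val"]["std"] == pytest.approx(0.1)

    def test_connectivity_denominator_tracks_validity_numerator(self):
        """p_l_con is a ratio over valid ligands only."""
        from tmcdiff.metrics import evaluate_generated

        cs, _ = make_corpus(4, seed=21)
        rep = evaluate_generated(cs, target_cn=None)
        assert rep.p_l_con.denominator == rep.p_l_val.numerator
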