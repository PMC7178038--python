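"""Structure geometry: superposition, distances, contacts, charge census."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from thermofold.geometry import (
    StructureModel,
    Ensemble,
    charge_census,
    closest_proton_contact,
    detect_salt_bridges,
    ensemble_rmsd_to_mean,
    entrance_distances,
    isoelectric_point,
    net_charge,
    rdc_q_factor,
    superpose,
)
from thermofold.simulate import simulate_helix_bundle_ensemble

COLS = ["name", "element", "resnum", "resname", "chain", "x", "y", "z"]


def model_from_xyz(xyz, names=None):
    xyz = np.asarray(xyz, float)
    rows = [
        (names[i] if names else "CA", "C", i + 1, "ALA", "A", *xyz[i])
        for i in range(len(xyz))
    ]
    return StructureModel(pd.DataFrame(rows, columns=COLS))


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        m = simulate_helix_bundle_ensemble(2, 0.0, seed=0).models[0]
        _, rmsd = superpose(m, m)
        assert rmsd < 1e-10

    def test_rigid_transform_invariance(self):
        ens = simulate_helix_bundle_ensemble(2, 0.0, seed=3)
        _, rmsd = superpose(ens.models[1], ens.models[0])
        assert rmsd < 1e-10

    def test_agrees_with_independent_rotation_optimizer(self):
        """Kabsch result must match scipy's independent align_vectors
        solution on two jittered 10-atom toys."""
        rng = np.random.default_rng(7)
        a = rng.uniform(-5, 5, (10, 3))
        b = a + rng.normal(0, 0.5, a.shape)
        ma, mb = model_from_xyz(a), model_from_xyz(b)
        _, rmsd = superpose(ma, mb)
        rot, oracle_rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0)
        )
        assert rmsd == pytest.approx(oracle_rssd / np.sqrt(len(a)), abs=1e-3)

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(8)
        a = model_from_xyz(rng.uniform(-5, 5, (12, 3)))
        b = model_from_xyz(rng.uniform(-5, 5, (12, 3)))
        _, r_ab = superpose(a, b)
        _, r_ba = superpose(b, a)
        assert r_ab == pytest.approx(r_ba, rel=1e-10)

    def test_too_few_atoms_rejected(self):
        m = model_from_xyz([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            superpose(m, m)


class TestEnsembleRmsd:
    def test_identical_models_give_zero(self):
        ens = simulate_helix_bundle_ensemble(5, 0.0, seed=1)
        assert ensemble_rmsd_to_mean(ens) < 1e-9

    def test_jittered_ensemble_matches_monte_carlo_expectation(self):
        """Isotropic jitter of sigma = 0.3 A on 20 models: the average
        RMSD to the mean must sit within 15% of the direct Monte-Carlo
        expectation sigma*sqrt(3*(M-1)/M) (superposition absorbs little
        for a 180-atom cloud)."""
        sigma, M = 0.3, 20
        ens = simulate_helix_bundle_ensemble(M, sigma, seed=12)
        avg = ensemble_rmsd_to_mean(ens)
        expect = sigma * np.sqrt(3.0 * (M - 1) / M)
        assert abs(avg - expect) / expect < 0.15

    def test_two_model_displaced_atom_closed_form(self):
        """Two identical models, one atom displaced by d along z with
        rotation suppressed by symmetry: RMSD-to-mean per model is
        (d/2) sqrt((1 - 1/N)/N) after translation removal."""
        rng = np.random.default_rng(3)
        base = rng.uniform(-4, 4, (40, 3))
        # place displaced atom at the centroid so the optimal rotation
        # stays the identity
        base[0] = base[1:].mean(axis=0)
        d = 0.8
        moved = base.copy()
        moved[0, 2] += d
        ens = Ensemble([model_from_xyz(base), model_from_xyz(moved)])
        avg = ensemble_rmsd_to_mean(ens)
        n = len(base)
        expect = (d / 2.0) * np.sqrt((1.0 - 1.0 / n) / n)
        assert avg == pytest.approx(expect, rel=1e-2)

    def test_single_model_rejected(self):
        ens = simulate_helix_bundle_ensemble(2, 0.0, seed=0)
        with pytest.raises(ValueError):
            ensemble_rmsd_to_mean(Ensemble(ens.models[:1]))


class TestEntranceDistances:
    def test_unit_triangle(self):
        m = model_from_xyz([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        d = entrance_distances(m, (1, 2, 3))
        assert all(v == pytest.approx(1.0) for v in d["pairs"].values())
        assert d["min"] == pytest.approx(1.0) and d["max"] == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 50))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        m = model_from_xyz(rng.uniform(-10, 10, (3, 3)))
        d = sorted(entrance_distances(m, (1, 2, 3))["pairs"].values())
        assert d[2] <= d[0] + d[1] + 1e-9

    def test_missing_calpha_rejected(self):
        m = model_from_xyz([[0, 0, 0], [1, 0, 0], [0, 1, 0]], names=["CA", "CB", "CA"])
        with pytest.raises(ValueError):
            entrance_distances(m, (1, 2, 3))


class TestClosestProtonContact:
    def _toy(self):
        rows = [
            ("HB1", "H", 1, "ILE", "A", 0.0, 0.0, 0.0),
            ("HB2", "H", 1, "ILE", "A", 0.5, 0.0, 0.0),
            ("CB", "C", 1, "ILE", "A", 0.2, 0.0, 0.0),
            ("HG1", "H", 2, "VAL", "A", 2.6, 0.0, 0.0),
            ("CB", "C", 2, "VAL", "A", 3.5, 0.0, 0.0),
        ]
        return StructureModel(pd.DataFrame(rows, columns=COLS))

    def test_minimum_hydrogen_pair_distance(self):
        assert closest_proton_contact(self._toy(), 1, 2) == pytest.approx(2.1)

    def test_same_residue_rejected(self):
        with pytest.raises(ValueError):
            closest_proton_contact(self._toy(), 1, 1)

    def test_heavy_atom_fallback_warns(self):
        rows = [
            ("CB", "C", 1, "ILE", "A", 0.0, 0.0, 0.0),
            ("CB", "C", 2, "VAL", "A", 3.7, 0.0, 0.0),
        ]
        m = StructureModel(pd.DataFrame(rows, columns=COLS))
        with pytest.warns(UserWarning):
            assert closest_proton_contact(m, 1, 2) == pytest.approx(3.7)


class TestSaltBridges:
    def _toy(self, d=3.0):
        rows = [
            ("NZ", "N", 10, "LYS", "A", 0.0, 0.0, 0.0),
            ("OD1", "O", 20, "ASP", "A", d, 0.0, 0.0),
            ("NH1", "N", 4, "ARG", "A", 0.0, 10.0, 0.0),
            ("OE1", "O", 28, "GLU", "A", 3.4, 10.0, 0.0),
        ]
        return StructureModel(pd.DataFrame(rows, columns=COLS))

    def test_basic_acidic_pairs_found(self):
        df = detect_salt_bridges(self._toy(), cutoff=4.0)
        pairs = {(r.basic_resnum, r.acidic_resnum) for r in df.itertuples()}
        assert pairs == {(10, 20), (4, 28)}
        assert set(df["cluster"]) == {0, 1}

    def test_tight_cutoff_empties_list(self):
        assert detect_salt_bridges(self._toy(), cutoff=2.5).empty

    @settings(deadline=None, derandomize=True)
    @given(c1=st.floats(2.0, 7.5), c2=st.floats(0.1, 2.0))
    def test_monotone_in_cutoff(self, c1, c2):
        m = self._toy()
        assert len(detect_salt_bridges(m, c1 + c2)) >= len(detect_salt_bridges(m, c1))

    def test_shared_residue_merges_clusters(self):
        rows = [
            ("NZ", "N", 65, "LYS", "A", 0.0, 0.0, 0.0),
            ("OD1", "O", 59, "ASP", "A", 3.0, 0.0, 0.0),
            ("OD1", "O", 62, "ASP", "A", -3.0, 0.0, 0.0),
            ("NZ", "N", 79, "LYS", "A", -6.0, 0.0, 0.0),
        ]
        df = detect_salt_bridges(StructureModel(pd.DataFrame(rows, columns=COLS)), 4.0)
        assert len(df) == 3
        assert set(df["cluster"]) == {0}


class TestChargeCensus:
    def test_single_acid_single_base(self):
        c = charge_census("EK")
        assert c.acidic_total == 1 and c.basic_total == 1

    def test_his_counted_separately_from_basic_total(self):
        c = charge_census("HHKR")
        assert c.basic_total == 2 and c.n_his == 2

    def test_polyglycine_pI_set_by_termini_only(self):
        """For side-chain-free polyglycine the pI is the mean of the two
        terminal pKa values (7.50 and 3.55 on this scale)."""
        assert isoelectric_point("GGGGGG") == pytest.approx((7.50 + 3.55) / 2, abs=1e-3)

    def test_bisection_agrees_with_grid_scan(self):
        """The bisection root must match an independent 1e-4-step grid
        scan of the net-charge function."""
        seq = "MDEKRHYAAKDDE"
        grid = np.arange(0.0, 14.0, 1e-4)
        charges = np.array([net_charge(seq, p) for p in grid])
        crossing = grid[np.argmin(np.abs(charges))]
        assert isoelectric_point(seq) == pytest.approx(crossing, abs=2e-4)

    def test_acidic_acp_composition_and_pI(self):
        """21 acidic (10E/11D) vs 9 basic (1R/8K) gives the strongly
        acidic pI of 4.13 characteristic of bacterial ACPs."""
        from thermofold.simulate import synthetic_acp_sequence

        c = charge_census(synthetic_acp_sequence())
        assert (c.n_glu, c.n_asp, c.n_arg, c.n_lys) == (10, 11, 1, 8)
        assert c.acidic_total == 21 and c.basic_total == 9
        assert round(c.pI, 2) == 4.13

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            charge_census("ACDEFGX")


class TestRdcQFactor:
    def test_perfect_agreement_is_zero(self):
        assert rdc_q_factor([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_zero_prediction_gives_one(self):
        assert rdc_q_factor([1.0, -2.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        """rms(0,1,0)/rms(1,2,3) = sqrt(1/3)/sqrt(14/3)."""
        assert rdc_q_factor([1, 2, 3], [1, 1, 3]) == pytest.approx(0.2673, abs=1e-4)

    def test_all_zero_measured_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rdc_q_factor([0.0, 0.0], [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rdc_q_factor([1.0, 2.0], [1.0])
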