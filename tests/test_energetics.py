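"""Pair energies, ensemble matrices, gap networks and charge scans."""

import numpy as np
import pytest

from relaxnet import (
    ChargedEnsemble,
    InteractionMatrix,
    MutationSpec,
    NoGapError,
    charge_scan,
    correlate_with_tm,
    difference_network,
    ensemble_matrix,
    find_gap,
    pair_energy,
)
from relaxnet.energetics import COULOMB_KJ_A
from relaxnet.synthetic import gen_charged_ensemble


def simple_ensemble(n_models=1, charges=(0, 1.0, 0, 0, 0, -1.0), sep=3.0,
                    lj_eps=0.0, jitter=0.0, seed=0):
    """Three residues; side chains of residues 1 and 3 sit `sep` Å apart,
    residue 2 is 200 Å away (isolated)."""
    rng = np.random.default_rng(seed)
    base = np.array(
        [
            [0.0, 0, 0], [1.5, 0, 0],        # res 1: CA, CB
            [200.0, 0, 0], [201.5, 0, 0],    # res 2 far away
            [1.5 + sep + 1.5, 0, 0], [1.5 + sep, 0, 0],  # res 3: CA, CB
        ]
    )
    coords = base[None] + (rng.normal(0, jitter, (n_models, 6, 3)) if jitter else 0.0)
    if coords.ndim == 2:
        coords = coords[None]
    return ChargedEnsemble(
        coords=np.broadcast_to(coords, (n_models, 6, 3)).copy(),
        charge=np.array(charges, dtype=float),
        lj_sigma=np.full(6, 3.2),
        lj_epsilon=np.full(6, lj_eps),
        res_index=np.array([1, 1, 2, 2, 3, 3]),
        res_name=np.array(["LYS", "LYS", "ALA", "ALA", "ASP", "ASP"], dtype=object),
        atom_name=np.array(["CA", "CB"] * 3, dtype=object),
    )


class TestPairEnergy:
    def test_coulomb_hand_value(self):
        ens = simple_ensemble()
        e = pair_energy(ens, 0, 1, 3)
        assert e == pytest.approx(-COULOMB_KJ_A / 3.0, rel=1e-12)

    def test_zero_charges_lj_off(self):
        ens = simple_ensemble(charges=(0, 0, 0, 0, 0, 0))
        assert pair_energy(ens, 0, 1, 3) == 0.0

    def test_beyond_cutoff_is_zero(self):
        ens = simple_ensemble(sep=300.0)  # partners moved past the cutoff
        assert pair_energy(ens, 0, 1, 3) == 0.0

    def test_sequence_neighbours_rejected(self):
        ens = simple_ensemble()
        with pytest.raises(ValueError):
            pair_energy(ens, 0, 1, 2 - 1)

    def test_dielectric_scales_coulomb(self):
        ens = simple_ensemble()
        assert pair_energy(ens, 0, 1, 3, dielectric=4.0) == pytest.approx(
            pair_energy(ens, 0, 1, 3) / 4.0, rel=1e-12
        )

    def test_overlapping_atoms_guarded(self):
        ens = simple_ensemble(sep=0.01)
        with pytest.raises(ValueError, match="overlap"):
            pair_energy(ens, 0, 1, 3)


class TestEnsembleMatrix:
    def test_single_model_equals_pair_energy(self):
        ens = simple_ensemble(lj_eps=0.25)
        mat = ensemble_matrix(ens)
        assert mat.matrix[0, 2] == pytest.approx(pair_energy(ens, 0, 1, 3), rel=1e-12)
        assert mat.matrix[2, 0] == mat.matrix[0, 2]
        assert np.all(np.diag(mat.matrix) == 0)
        assert mat.matrix[0, 1] == 0  # sequence neighbours excluded

    def test_degenerate_weights_select_single_model(self):
        ens = simple_ensemble(n_models=2, jitter=0.3, seed=4)
        ens.weights = np.array([1.0, 0.0])
        solo = ChargedEnsemble(
            coords=ens.coords[:1], charge=ens.charge, lj_sigma=ens.lj_sigma,
            lj_epsilon=ens.lj_epsilon, res_index=ens.res_index,
            res_name=ens.res_name, atom_name=ens.atom_name,
        )
        assert np.allclose(
            ensemble_matrix(ens).matrix, ensemble_matrix(solo).matrix, rtol=1e-12
        )

    def test_matches_naive_loop_oracle(self):
        ens, _, _ = gen_charged_ensemble(n_models=4, n_residues=12,
                                         planted_pairs=((3, 7, 3.0),), seed=8)
        mat = ensemble_matrix(ens)
        n = ens.n_residues
        oracle = np.zeros((n, n))
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                if abs(i - j) <= 1:
                    continue
                oracle[i - 1, j - 1] = sum(
                    w * pair_energy(ens, m, i, j)
                    for m, w in enumerate(ens.weights)
                )
        assert np.allclose(mat.matrix, oracle, rtol=1e-10, atol=1e-12)

    def test_invariant_under_model_reordering_and_rigid_motion(self):
        ens, _, _ = gen_charged_ensemble(n_models=3, n_residues=10,
                                         planted_pairs=((2, 6, 3.0),), seed=9)
        mat = ensemble_matrix(ens).matrix
        coords = ens.coords[::-1].copy()
        coords[0] = coords[0] + np.array([5.0, -3.0, 2.0])  # rigid translation
        moved = ChargedEnsemble(
            coords=coords, charge=ens.charge, lj_sigma=ens.lj_sigma,
            lj_epsilon=ens.lj_epsilon, res_index=ens.res_index,
            res_name=ens.res_name, atom_name=ens.atom_name,
            weights=ens.weights[::-1].copy(),
        )
        assert np.allclose(ensemble_matrix(moved).matrix, mat, rtol=1e-10)


class TestFindGap:
    def test_single_dominant_gap(self):
        thr = find_gap([10.0, 9.5, 1.0, 0.9, 0.8])
        assert 1.0 < thr < 9.5
        assert sum(v >= thr for v in [10.0, 9.5, 1.0, 0.9, 0.8]) == 2

    def test_uniform_spacing_tie_breaks_to_larger_threshold(self):
        assert find_gap([5.0, 4.0, 3.0, 2.0, 1.0]) == pytest.approx(4.5)

    def test_all_equal_raises(self):
        with pytest.raises(NoGapError):
            find_gap([2.0, 2.0, 2.0])

    def test_needs_two_nonzero_values(self):
        with pytest.raises(NoGapError):
            find_gap([3.0, 0.0])

    def test_sign_is_ignored(self):
        assert find_gap([-10.0, 9.5, -1.0, 0.9]) == find_gap([10.0, 9.5, 1.0, 0.9])


class TestDifferenceNetwork:
    def test_identical_matrices_empty_network_with_warning(self):
        ens = simple_ensemble()
        mat = ensemble_matrix(ens)
        with pytest.warns(UserWarning, match="no energy gap"):
            net = difference_network(mat, mat)
        assert net.edges == ()

    def test_single_perturbed_pair_single_edge(self):
        base = np.zeros((8, 8))
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.01, (8, 8))
        noise = np.triu(noise, k=2)
        noise = noise + noise.T
        changed = base + noise
        changed[0, 5] = changed[5, 0] = -20.0
        m0 = InteractionMatrix(base, 10.0, 1.0)
        m1 = InteractionMatrix(changed, 10.0, 1.0)
        net = difference_network(m0, m1)
        assert net.edge_set == {(1, 6)}
        assert net.edges[0][3] == "strengthened"  # energy decreased

    def test_antisymmetry_flips_signs(self):
        ref, mut, _ = gen_charged_ensemble(seed=1)
        m0, m1 = ensemble_matrix(ref), ensemble_matrix(mut)
        fwd = difference_network(m0, m1)
        rev = difference_network(m1, m0)
        assert fwd.edge_set == rev.edge_set
        signs_f = {e[:2]: e[3] for e in fwd.edges}
        signs_r = {e[:2]: e[3] for e in rev.edges}
        for k in signs_f:
            assert signs_f[k] != signs_r[k]

    def test_planted_salt_bridge_and_long_range_pair_recovered(self):
        """The charge edit severs one salt-bridge-like contact and one
        long-range charge pair; the network recovers exactly those."""
        ref, mut, mutation = gen_charged_ensemble(
            planted_pairs=((10, 4, 3.0), (10, 24, 4.5)), seed=6
        )
        net = difference_network(ensemble_matrix(ref), ensemble_matrix(mut))
        assert net.edge_set == {(4, 10), (10, 24)}
        assert all(sign == "weakened" for *_, sign in net.edges)


class TestChargeScan:
    def test_isolated_salt_bridge_analytic(self):
        ens = simple_ensemble()
        de = charge_scan(ens, [MutationSpec(1, "remove_side_chain_charge")])
        assert de[0] == pytest.approx(COULOMB_KJ_A / 3.0, rel=1e-12)

    def test_inversion_doubles_removal(self):
        ens = simple_ensemble()
        rem, inv = charge_scan(
            ens,
            [MutationSpec(1, "remove_side_chain_charge"),
             MutationSpec(1, "invert_side_chain_charge")],
        )
        assert inv == pytest.approx(2.0 * rem, rel=1e-12)

    def test_isolated_residue_null_effect(self):
        ens = simple_ensemble(charges=(0, 1.0, 0, 0.5, 0, -1.0))
        de = charge_scan(ens, [MutationSpec(2, "remove_side_chain_charge")])
        assert de[0] == 0.0

    def test_glycine_side_chain_rejected(self):
        ens = simple_ensemble()
        ens.res_name[2:4] = "GLY"
        with pytest.raises(ValueError, match="side-chain"):
            charge_scan(ens, [MutationSpec(2, "remove_side_chain_charge")])


class TestCorrelateWithTm:
    def test_perfect_anticorrelation(self):
        r = correlate_with_tm([1.0, 2.0, 3.0], [9.0, 6.0, 3.0])
        assert r.pearson == pytest.approx(-1.0)
        assert r.spearman == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        r = correlate_with_tm([1.0, 2.0, 4.0], [10.0, 7.0, 4.0])
        assert r.pearson == pytest.approx(-0.9819805060619655, rel=1e-12)

    def test_permuted_pairs_average_to_zero(self):
        rng = np.random.default_rng(31)
        de = np.arange(10.0)
        tm = 60.0 - 0.5 * de
        stats = [
            correlate_with_tm(de, rng.permutation(tm)).pearson for _ in range(500)
        ]
        assert abs(np.mean(stats)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_tm([1.0, 1.0, 1.0], [3.0, 4.0, 5.0])
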