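import numpy as np
import pandas as pd
import pytest

from ropbo.catalyst_space import Atom, MolecularGraph
from ropbo.errors import (
    EncodingMismatchError,
    SchemaError,
    ValidationError,
)
from ropbo.featurization import (
    DescriptorVector,
    aggregate_atomic,
    buried_volume,
    concatenate_fragments,
    coulomb_eigenvalues,
    derive_electronic,
    estate_indices,
    ingest_dft_table,
    one_hot_encode,
    preprocess,
)


def carbon(dv):
    """sp3 carbon with dv hydrogen-suppressed valence electrons (L=2)."""
    return Atom("C", 6, valence_electrons=dv, principal_quantum_number=2)


class TestOneHot:
    def test_indicator_position(self):
        v = one_hot_encode("A2", ["A1", "A2", "A3"])
        assert v.values.tolist() == [0.0, 1.0, 0.0]

    def test_singleton_vocabulary(self):
        assert one_hot_encode("A1", ["A1"]).values.tolist() == [1.0]

    def test_partition_property(self):
        vocab = [f"A{i}" for i in range(6)]
        rows = np.array([one_hot_encode(x, vocab).values for x in vocab])
        assert rows.sum(axis=1).tolist() == [1.0] * 6

    def test_unknown_id_named_in_error(self):
        with pytest.raises(ValidationError, match="A9"):
            one_hot_encode("A9", ["A1"])


class TestEstate:
    def test_single_atom_is_intrinsic_state(self):
        g = MolecularGraph(atoms=(carbon(1),), bonds=())
        # I = ((2/2)^2 * 1 + 1) / 1 with delta taken as 1 for a lone atom
        assert estate_indices(g)[0] == pytest.approx(2.0)

    def test_symmetric_diatomic_unperturbed(self):
        g = MolecularGraph(atoms=(carbon(1), carbon(1)), bonds=((0, 1),))
        s = estate_indices(g)
        assert s[0] == pytest.approx(s[1]) == pytest.approx(2.0)

    def test_propane_skeleton_matches_hand_oracle(self):
        # CH3-CH2-CH3 heavy-atom path: I = (2, 1.5, 2);
        # S1 = 2 + (2-1.5)/2^2 = 2.125, S2 = 1.5 + 2*(1.5-2)/2^2 = 1.25
        g = MolecularGraph(
            atoms=(carbon(1), carbon(2), carbon(1)), bonds=((0, 1), (1, 2))
        )
        assert estate_indices(g) == pytest.approx([2.125, 1.25, 2.125])

    def test_sum_invariance_on_random_trees(self, rng):
        # perturbations are antisymmetric over pairs: sum(S) == sum(I)
        for _ in range(10):
            n = int(rng.integers(2, 12))
            atoms = tuple(carbon(int(rng.integers(1, 5))) for _ in range(n))
            bonds = tuple(
                (int(rng.integers(0, i)), i) for i in range(1, n)
            )
            g = MolecularGraph(atoms=atoms, bonds=bonds)
            s = estate_indices(g)
            intrinsic_sum = sum(
                ((2 / a.principal_quantum_number) ** 2 * a.valence_electrons + 1)
                / g.degree(i)
                for i, a in enumerate(atoms)
            )
            assert s.sum() == pytest.approx(intrinsic_sum)

    def test_disconnected_graph_rejected(self):
        g = MolecularGraph(atoms=(carbon(1), carbon(1)), bonds=())
        with pytest.raises(ValidationError):
            estate_indices(g)


class TestCoulomb:
    def test_single_hydrogen(self):
        eig = coulomb_eigenvalues([1], np.zeros((1, 3)))
        assert eig == pytest.approx([0.5])

    def test_h2_at_unit_bohr_separation(self):
        # eigenvalues of [[0.5, 1], [1, 0.5]] are (1.5, -0.5)
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        eig = coulomb_eigenvalues([1, 1], coords, units="bohr")
        assert eig == pytest.approx([1.5, -0.5])

    def test_zero_padding(self):
        eig = coulomb_eigenvalues([1], np.zeros((1, 3)), pad_to=3)
        assert eig == pytest.approx([0.5, 0.0, 0.0])

    def test_rigid_motion_and_permutation_invariance(self, rng):
        n = 6
        z = rng.integers(1, 9, size=n)
        coords = rng.standard_normal((n, 3)) * 2
        ref = coulomb_eigenvalues(z, coords)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            shift = rng.standard_normal(3) * 5
            perm = rng.permutation(n)
            moved = coords @ q.T + shift
            eig = coulomb_eigenvalues(z[perm], moved[perm])
            np.testing.assert_allclose(eig, ref, atol=1e-8)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValidationError):
            coulomb_eigenvalues([1, 1], np.zeros((2, 3)))

    def test_pad_shorter_than_molecule_rejected(self):
        with pytest.raises(ValidationError):
            coulomb_eigenvalues([1, 1], [[0, 0, 0], [1, 0, 0]], pad_to=1)


def mc_buried_volume(elements, coords, center, sphere_radius, n=10**6, seed=0):
    """Monte-Carlo rejection-sampling oracle for %V_bur."""
    from ropbo.featurization import BONDI_RADII

    rng = np.random.default_rng(seed)
    pts = rng.uniform(-sphere_radius, sphere_radius, size=(n, 3))
    pts = pts[(pts**2).sum(axis=1) <= sphere_radius**2] + np.asarray(center)
    buried = np.zeros(len(pts), dtype=bool)
    for el, pos in zip(elements, np.asarray(coords, dtype=float)):
        buried |= ((pts - pos) ** 2).sum(axis=1) <= BONDI_RADII[el] ** 2
    return 100.0 * buried.mean()


class TestBuriedVolume:
    def test_empty_atom_list_is_zero(self):
        assert buried_volume([], np.empty((0, 3)), center=[0, 0, 0]) == 0.0

    def test_full_occlusion(self):
        # a carbon vdW sphere (1.70 A) swallows a 1.5 A probe sphere
        val = buried_volume(
            ["C"], [[0.0, 0, 0]], center=[0, 0, 0], sphere_radius=1.5
        )
        assert val == pytest.approx(100.0)

    def test_off_center_atom_matches_mc_oracle(self):
        coords = [[1.2, 0.4, -0.3]]
        grid = buried_volume(["C"], coords, center=[0, 0, 0], sphere_radius=3.5)
        mc = mc_buried_volume(["C"], coords, [0, 0, 0], 3.5)
        assert abs(grid - mc) < 0.5

    def test_multi_atom_case_matches_mc_oracle(self, rng):
        coords = rng.uniform(-2, 2, size=(4, 3))
        elements = ["C", "N", "O", "H"]
        grid = buried_volume(elements, coords, center=[0, 0, 0])
        mc = mc_buried_volume(elements, coords, [0, 0, 0], 3.5)
        assert abs(grid - mc) < 0.5

    def test_grid_refinement_converges(self):
        coords = [[0.9, -0.5, 0.2], [-1.1, 0.3, 0.8]]
        coarse = buried_volume(
            ["C", "N"], coords, center=[0, 0, 0], grid_spacing=0.10
        )
        fine = buried_volume(
            ["C", "N"], coords, center=[0, 0, 0], grid_spacing=0.05
        )
        assert abs(coarse - fine) < 0.5

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValidationError):
            buried_volume(["C"], [[0, 0, 0]], sphere_radius=0.0)


class TestAggregation:
    @pytest.mark.parametrize(
        "stat,expected", [("min", 1.0), ("max", 3.0), ("mean", 2.0)]
    )
    def test_statistics(self, stat, expected):
        assert aggregate_atomic([1, 2, 3], stat) == expected

    def test_constant_list_collapses(self):
        for stat in ("min", "max", "mean"):
            assert aggregate_atomic([4.2] * 5, stat) == 4.2

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_atomic([], "mean")


class TestElectronic:
    def test_en_and_hardness(self):
        assert derive_electronic(-6.0, -2.0) == (4.0, 2.0)

    def test_degenerate_orbitals_zero_hardness(self):
        assert derive_electronic(-4.0, -4.0)[1] == 0.0

    def test_lowering_homo_raises_en(self):
        en_hi, _ = derive_electronic(-7.0, -2.0)
        en_lo, _ = derive_electronic(-6.0, -2.0)
        assert en_hi > en_lo

    def test_inverted_ordering_rejected(self):
        with pytest.raises(ValidationError):
            derive_electronic(-2.0, -6.0)


def toy_table(**overrides):
    table = {
        "n_atoms": 2,
        "charge": 0,
        "spin_multiplicity": 1,
        "dipole": 1.5,
        "e_homo": -6.0,
        "e_lumo": -2.0,
        "vbur": [30.0, 40.0],
        "mulliken": [-0.2, 0.2],
        "apt_charge": [-0.1, 0.1],
        "freq": [100.0, 300.0],
    }
    table.update(overrides)
    return table


class TestDftIngestion:
    def test_frequency_aggregates(self):
        v = ingest_dft_table(toy_table())
        d = dict(zip(v.names, v.values))
        assert (d["freq_min"], d["freq_max"], d["freq_mean"]) == (100, 300, 200)

    def test_charge_aggregates(self):
        d = dict(zip(*[(v.names, v.values) for v in [ingest_dft_table(toy_table())]][0]))
        assert (d["mulliken_min"], d["mulliken_max"]) == (-0.2, 0.2)
        assert d["mulliken_mean"] == pytest.approx(0.0)

    def test_electronic_derivations_included(self):
        v = ingest_dft_table(toy_table())
        d = dict(zip(v.names, v.values))
        assert (d["en"], d["hardness"]) == (4.0, 2.0)

    def test_identical_tables_give_identical_vectors(self):
        a, b = ingest_dft_table(toy_table()), ingest_dft_table(toy_table())
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_field_named(self):
        table = toy_table()
        del table["dipole"]
        with pytest.raises(SchemaError, match="dipole"):
            ingest_dft_table(table)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            ingest_dft_table(toy_table(freq=[100.0, float("nan")]))


class TestConcatenation:
    def a_vec(self, n=5):
        return DescriptorVector(
            names=tuple(f"f{i}" for i in range(n)),
            values=np.arange(n, dtype=float),
            encoding="dft-ingest",
        )

    def test_lengths_add(self):
        a, bc = self.a_vec(5), self.a_vec(7)
        assert len(concatenate_fragments(a, bc)) == 12

    def test_prefixes_resolve_collisions(self):
        v = concatenate_fragments(self.a_vec(3), self.a_vec(3))
        assert len(set(v.names)) == 6
        assert v.names[0].startswith("A:") and v.names[3].startswith("BC:")

    def test_values_preserved_bit_exactly(self):
        a, bc = self.a_vec(4), self.a_vec(2)
        v = concatenate_fragments(a, bc)
        np.testing.assert_array_equal(v.values[:4], a.values)
        np.testing.assert_array_equal(v.values[4:], bc.values)

    def test_encoding_mismatch_rejected(self):
        one_hot = DescriptorVector(("x",), np.array([1.0]), "one-hot")
        with pytest.raises(EncodingMismatchError):
            concatenate_fragments(self.a_vec(), one_hot)


class TestPreprocess:
    def test_duplicate_column_dropped_once(self, rng):
        x = rng.standard_normal(20)
        frame = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(20)})
        fm = preprocess(frame)
        assert fm.columns == ["a", "c"]
        assert fm.preprocessor.dropped_correlated[0][0] == "b"

    def test_constant_column_dropped(self, rng):
        frame = pd.DataFrame(
            {"a": rng.standard_normal(10), "k": np.ones(10)}
        )
        fm = preprocess(frame)
        assert fm.columns == ["a"]
        assert fm.preprocessor.dropped_constant == ["k"]

    def test_correlated_triple_keeps_two(self, toy_linear_frame):
        r_ab = toy_linear_frame.corr().loc["a", "b"]
        assert abs(r_ab) > 0.95  # constructed near-duplicate
        fm = preprocess(toy_linear_frame)
        assert fm.columns == ["a", "c"]

    def test_retained_columns_standardized(self, rng):
        frame = pd.DataFrame(rng.standard_normal((30, 4)) * 7 + 3)
        frame.columns = list("wxyz")
        fm = preprocess(frame)
        np.testing.assert_allclose(fm.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(fm.values.std(axis=0), 1, atol=1e-8)

    def test_idempotence(self, rng):
        frame = pd.DataFrame(rng.standard_normal((25, 5)))
        frame.columns = list("abcde")
        once = preprocess(frame)
        twice = preprocess(once.frame)
        assert twice.columns == once.columns
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_transform_uses_training_statistics(self, rng):
        frame = pd.DataFrame({"a": rng.standard_normal(50) * 2 + 1})
        fm = preprocess(frame)
        new = pd.DataFrame({"a": [1.0]})
        z = fm.preprocessor.transform(new)
        expected = (1.0 - frame["a"].mean()) / frame["a"].std(ddof=0)
        assert z.iloc[0, 0] == pytest.approx(expected)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            preprocess(pd.DataFrame({"a": [1.0]}))
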