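"""Torsion extraction, per-residue entropies, folding references, contacts."""

import math

import numpy as np
import pytest

from confent.estimators import SampleSet, entropy_knn, relative_to_uniform
from confent.reference import (
    UNFOLDED_REFERENCE_TSV,
    unfolded_reference_entropy,
    unfolded_reference_table,
)
from confent.spaces import MetricSpace
from confent.synthetic import DensitySpec, make_backbone_ensemble, numeric_entropy_oracle, sample
from confent.torsions import (
    ResidueTorsions,
    TorsionTrajectory,
    compute_dihedral,
    contact_cluster_entropy,
    contact_map,
    extract_torsion_trajectory,
    folding_entropy,
    phi_psi_mutual_information,
    residue_entropy,
    torsion_names,
)

TWO_PI = 2.0 * np.pi


def _make_residue(angles, residue_type="ALA", variant="internal", index=1):
    angles = np.asarray(angles, dtype=float)
    names = tuple(f"t{i}" for i in range(angles.shape[1]))
    return ResidueTorsions(
        residue_index=index,
        chain_id="A",
        residue_type=residue_type,
        variant=variant,
        angle_names=names,
        angles=angles,
    )


class TestDihedral:
    @pytest.mark.parametrize(
        "p4, expected",
        [
            ((-1, 1, 0), math.pi),   # trans
            ((1, 1, 0), 0.0),        # cis
            ((0, 1, 1), -math.pi / 2),
        ],
    )
    def test_reference_geometries(self, p4, expected):
        angle = compute_dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
        assert angle == pytest.approx(expected, abs=1e-12)

    def test_matches_biotite_on_random_geometry(self, rng):
        import biotite.structure as struc

        for _ in range(20):
            p = rng.normal(size=(4, 3)) * 2.0
            expected = struc.dihedral(*(p[i] for i in range(4)))
            # biotite computes in float32
            assert compute_dihedral(*p) == pytest.approx(float(expected), abs=1e-6)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            compute_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestDefinitions:
    @pytest.mark.parametrize(
        "residue, count",
        [("ALA", 2), ("GLY", 2), ("VAL", 3), ("ILE", 4), ("TRP", 5), ("LYS", 6),
         ("ARG", 6), ("PRO", 2), ("CYS_SS", 3)],
    )
    def test_internal_torsion_counts(self, residue, count):
        assert len(torsion_names(residue)) == count

    def test_terminal_variants_drop_one_backbone_angle(self):
        assert "phi" not in torsion_names("LYS", "nterm")
        assert "psi" not in torsion_names("LYS", "cterm")
        assert len(torsion_names("LYS", "nterm")) == 5


class TestExtraction:
    @pytest.fixture()
    def poly_ala(self, rng):
        n_models, n_res = 4, 5
        phi = rng.uniform(-np.pi, np.pi, size=(n_models, n_res))
        psi = rng.uniform(-np.pi, np.pi, size=(n_models, n_res))
        return make_backbone_ensemble(phi, psi), phi, psi

    def test_counts_and_variants(self, poly_ala):
        stack, _, _ = poly_ala
        traj = extract_torsion_trajectory(stack)
        assert len(traj) == 5
        first = traj.get("A", 1)
        last = traj.get("A", 5)
        middle = traj.get("A", 3)
        assert first.variant == "nterm" and first.angle_names == ("psi",)
        assert last.variant == "cterm" and last.angle_names == ("phi",)
        assert middle.variant == "internal" and middle.angle_names == ("phi", "psi")
        assert middle.angles.shape == (4, 2)

    def test_angles_match_construction(self, poly_ala):
        stack, phi, psi = poly_ala
        traj = extract_torsion_trajectory(stack)
        middle = traj.get("A", 3)
        np.testing.assert_allclose(middle.angles[:, 0], phi[:, 2], atol=1e-5)
        np.testing.assert_allclose(middle.angles[:, 1], psi[:, 2], atol=1e-5)

    def test_missing_atom_flags_residue_only(self, poly_ala):
        stack, _, _ = poly_ala
        # drop residue 3's C atom: kills phi/psi of 3 and phi of 4
        keep = ~((stack.res_id == 3) & (stack.atom_name == "C"))
        trimmed = stack[:, keep]
        traj = extract_torsion_trajectory(trimmed)
        assert traj.get("A", 3) is None  # both its torsions need its C
        assert "missing-atoms-for-phi" in traj.get("A", 4).warnings
        assert traj.get("A", 2).warnings == ()  # unaffected neighbours
        assert traj.get("A", 5).angle_names == ("phi",)

    def test_unresolvable_input_rejected(self, poly_ala):
        stack, _, _ = poly_ala
        stack = stack.copy()
        stack.res_name[:] = "XXX"
        with pytest.raises(ValueError):
            extract_torsion_trajectory(stack)


class TestResidueEntropy:
    def test_uniform_angles_recover_reference(self, rng):
        angles = rng.uniform(-np.pi, np.pi, size=(300, 2))
        est = residue_entropy(_make_residue(angles))
        assert est.value <= 0.1
        assert est.value == pytest.approx(0.0, abs=0.35)

    def test_tight_rotamer_matches_oracle(self):
        spec = DensitySpec("vonmises", mu=(0.0, 0.0), kappa=(50.0, 50.0))
        angles = sample(spec, 300, seed=1).points
        est = residue_entropy(_make_residue(angles))
        expected = numeric_entropy_oracle(spec) - 2 * np.log(TWO_PI)
        assert est.value == pytest.approx(expected, abs=3 * 3.0 / np.sqrt(300))

    def test_three_rotamers_add_log_three(self):
        kappa = 80.0
        one = DensitySpec("vonmises_mixture", weights=(1.0,), mu=(0.0,), kappa=(kappa,))
        three = DensitySpec(
            "vonmises_mixture",
            weights=(1 / 3, 1 / 3, 1 / 3),
            mu=(-2.0, 0.0, 2.0),
            kappa=(kappa,) * 3,
        )
        vals = {}
        for name, spec in (("one", one), ("three", three)):
            reps = [
                residue_entropy(_make_residue(sample(spec, 300, seed=s).points)).value
                for s in range(6)
            ]
            vals[name] = np.mean(reps)
        assert vals["three"] - vals["one"] == pytest.approx(np.log(3.0), abs=0.25)

    def test_half_trajectory_stability(self):
        # the first-half/second-half convergence check on synthetic
        # rotamers; averaged over seeds since a single 150-snapshot half
        # carries ~0.15 kB of estimator noise
        spec = DensitySpec(
            "vonmises_mixture", weights=(0.5, 0.5), mu=(-1.5, 1.5), kappa=(60.0, 60.0)
        )
        diffs = []
        for seed in range(6):
            angles = sample(spec, 300, seed=seed).points
            full = residue_entropy(_make_residue(angles)).value
            diffs.append(abs(residue_entropy(_make_residue(angles[:150])).value - full))
            diffs.append(abs(residue_entropy(_make_residue(angles[150:])).value - full))
        assert np.mean(diffs) < 0.2

    def test_dropping_phi_costs_at_most_its_reference_share(self):
        spec = DensitySpec("vonmises", mu=(0.0, 0.0, 0.0), kappa=(8.0, 8.0, 8.0))
        angles = sample(spec, 400, seed=3).points
        internal = residue_entropy(_make_residue(angles)).value
        nterm = residue_entropy(_make_residue(angles[:, 1:])).value
        assert nterm >= internal - np.log(TWO_PI)

    def test_degenerate_snapshots_flagged(self):
        angles = np.zeros((10, 2))
        angles[0] = (0.3, 0.1)
        angles[1] = (0.1, -0.2)
        angles[2] = (-0.2, 0.2)
        est = residue_entropy(_make_residue(angles))
        assert any("duplicate" in w for w in est.warnings)


class TestFoldingEntropy:
    def _traj_with(self, residue_type, variant="internal"):
        res = _make_residue(np.zeros((2, 2)), residue_type=residue_type, variant=variant)
        return TorsionTrajectory({("A", 1): res})

    def test_alanine_arithmetic(self):
        from dataclasses import replace

        traj = self._traj_with("ALA")
        est = entropy_knn(SampleSet(np.array([[0.0], [1.0]]), MetricSpace.euclidean(1)))
        fake = replace(est, value=-4.4, reference_name="uniform-torus")
        folding = folding_entropy({("A", 1): fake}, traj)
        assert folding[("A", 1)] == pytest.approx(-4.4 - (-2.4))

    @pytest.mark.parametrize(
        "residue, variant, expected",
        [("LYS", "internal", -7.5), ("ALA", "internal", -2.4), ("GLY", "nterm", -0.4),
         ("TRP", "cterm", -4.1), ("CYS_SS", "internal", -3.6), ("PRO", "internal", -0.8)],
    )
    def test_reference_lookups(self, residue, variant, expected):
        assert unfolded_reference_entropy(residue, variant) == expected

    def test_entropy_equal_to_reference_gives_zero(self):
        from dataclasses import replace

        traj = self._traj_with("LYS")
        est = entropy_knn(SampleSet(np.array([[0.0], [1.0]]), MetricSpace.euclidean(1)))
        fake = replace(est, value=-7.5, reference_name="uniform-torus")
        folding = folding_entropy({("A", 1): fake}, traj)
        assert folding[("A", 1)] == pytest.approx(0.0)

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            unfolded_reference_entropy("XYZ")

    def test_table_round_trips_exactly(self):
        table = unfolded_reference_table()
        assert table.to_csv(sep="\t", lineterminator="\n") == UNFOLDED_REFERENCE_TSV
        assert table.loc["ALA", "entropy"] == -2.4
        assert table.loc["LYS", "av_dist"] == 16.8
        assert int(table.loc["GLY", "counts"]) == 43795


class TestContacts:
    def _two_atom_structure(self, separation):
        import biotite.structure as struc

        atoms = struc.AtomArray(2)
        atoms.coord = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
        atoms.chain_id = np.array(["A", "A"])
        atoms.res_id = np.array([1, 2])
        atoms.res_name = np.array(["ALA", "ALA"])
        atoms.atom_name = np.array(["CA", "CA"])
        atoms.element = np.array(["C", "C"])
        return atoms

    def test_contact_rule_threshold(self):
        # carbon radii 1.7 + 1.7 + 1.0 margin = 4.4 A
        close = contact_map(self._two_atom_structure(4.3))
        assert ("A", 2) in close[("A", 1)]
        far = contact_map(self._two_atom_structure(4.5))
        assert ("A", 2) not in far[("A", 1)]

    def test_self_contact_always_present(self):
        contacts = contact_map(self._two_atom_structure(10.0))
        assert contacts[("A", 1)] == {("A", 1)}

    def test_cluster_sums(self):
        contacts = {("A", 1): {("A", 1), ("A", 2)}, ("A", 2): {("A", 1), ("A", 2)},
                    ("A", 3): {("A", 3)}}
        folding = {("A", 1): -2.0, ("A", 2): -3.0, ("A", 3): -1.5}
        clusters = contact_cluster_entropy(contacts, folding)
        assert clusters[("A", 1)] == pytest.approx(-5.0)
        assert clusters[("A", 3)] == pytest.approx(-1.5)  # isolated: own entropy


class TestPhiPsiMutualInformation:
    def _traj_from_angles(self, psi_prev, phi_i):
        prev = ResidueTorsions(1, "A", "ALA", "nterm", ("psi",), psi_prev[:, None])
        cur = ResidueTorsions(2, "A", "ALA", "cterm", ("phi",), phi_i[:, None])
        return TorsionTrajectory({("A", 1): prev, ("A", 2): cur})

    def test_independent_angles_give_zero(self, rng):
        traj = self._traj_from_angles(
            rng.uniform(-np.pi, np.pi, 4000), rng.uniform(-np.pi, np.pi, 4000)
        )
        assert phi_psi_mutual_information(traj, "A", 2) == pytest.approx(0.0, abs=0.06)

    def test_constructed_correlation_is_large(self, rng):
        psi = rng.uniform(-np.pi, np.pi, 3000)
        phi = np.mod(-psi + rng.normal(0, 0.05, 3000) + np.pi, TWO_PI) - np.pi
        traj = self._traj_from_angles(psi, phi)
        assert phi_psi_mutual_information(traj, "A", 2) > 1.0

    def test_vonmises_coupling_matches_quadrature_oracle(self, rng):
        # psi uniform, phi = -psi + von Mises noise: both marginals are
        # uniform, so MI = log(2 pi) - S_vonMises(kappa) exactly
        kappa = 2.0
        psi = rng.uniform(-np.pi, np.pi, 5000)
        noise = rng.vonmises(0.0, kappa, 5000)
        phi = np.mod(-psi + noise + np.pi, TWO_PI) - np.pi
        traj = self._traj_from_angles(psi, phi)
        expected = np.log(TWO_PI) - numeric_entropy_oracle(
            DensitySpec("vonmises", kappa=(kappa,))
        )
        mi = phi_psi_mutual_information(traj, "A", 2)
        assert mi == pytest.approx(expected, abs=3 * 3.0 / np.sqrt(5000))

    def test_terminal_residue_rejected(self, rng):
        traj = self._traj_from_angles(rng.uniform(-1, 1, 10), rng.uniform(-1, 1, 10))
        with pytest.raises(ValueError):
            phi_psi_mutual_information(traj, "A", 1)
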