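import numpy as np
import pytest

from allopath import (
    Selection,
    build_enm,
    compute_modes,
    dcc,
    diagonalize,
    mode_fluctuations,
    population_shift,
    project_ensemble,
    variance_fraction,
)
from allopath import synthetic_data as sd
from allopath.errors import AllopathError, DisconnectedNetworkError
from allopath.modes import ModeSet
from allopath.structio import AtomRecord, Ensemble, Structure


def ca_structure(coords, chain="A"):
    atoms = [
        AtomRecord(chain, i + 1, "ALA", "CA", "C", np.asarray(c, float))
        for i, c in enumerate(coords)
    ]
    return Structure(atoms)


def assemble_hessian_oracle(coords, cutoff, gamma):
    """Independent elementwise Hessian assembly (scalar loops, no blocks)."""
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = coords[j] - coords[i]
            d = np.linalg.norm(rij)
            if d > cutoff:
                continue
            for a in range(3):
                for b in range(3):
                    val = -gamma * rij[a] * rij[b] / d ** 2
                    h[3 * i + a, 3 * j + b] += val
                    h[3 * i + a, 3 * i + b] -= val
    return h


@pytest.fixture(scope="module")
def helix_modes(helix40):
    return compute_modes(helix40, cutoff=15.0)


class TestBuildENM:
    def test_two_nodes_analytic(self):
        s = ca_structure([(0, 0, 0), (2, 0, 0)])
        h = build_enm(s, cutoff=5.0, gamma=1.0)
        eigenvalues = np.linalg.eigvalsh(h.matrix)
        np.testing.assert_allclose(sorted(eigenvalues)[:5], 0.0, atol=1e-12)
        assert abs(eigenvalues.max() - 2.0) < 1e-12
        # stretch is along x
        expected = np.zeros((6, 6))
        expected[0, 0] = expected[3, 3] = 1.0
        expected[0, 3] = expected[3, 0] = -1.0
        np.testing.assert_allclose(h.matrix, expected, atol=1e-12)

    def test_row_sums_zero(self, helix40):
        h = build_enm(helix40)
        np.testing.assert_allclose(h.matrix.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(h.matrix, h.matrix.T, atol=1e-12)

    def test_tetrahedron_matches_oracle(self):
        coords = np.array([
            (1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)
        ], dtype=float) * 2.0
        s = ca_structure(coords)
        h = build_enm(s, cutoff=10.0, gamma=1.3)
        oracle = assemble_hessian_oracle(coords, 10.0, 1.3)
        np.testing.assert_allclose(h.matrix, oracle, atol=1e-12)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(h.matrix), np.linalg.eigvalsh(oracle),
            atol=1e-10,
        )

    def test_disconnected_network_reports_components(self):
        coords = [(0, 0, 0), (2, 0, 0), (3, 1, 0), (100, 0, 0), (102, 0, 0),
                  (103, 1, 0), (104, 2, 0)]
        s = ca_structure(coords)
        with pytest.raises(DisconnectedNetworkError) as err:
            build_enm(s, cutoff=10.0)
        assert len(err.value.components) == 2


class TestDiagonalize:
    def test_six_zero_modes(self, helix_modes):
        assert helix_modes.n_zero == 6
        scale = abs(helix_modes.eigenvalues).max()
        assert np.all(helix_modes.eigenvalues[:6] < 1e-8 * scale)
        assert helix_modes.eigenvalues[6] > 1e-6

    def test_orthonormal_eigenvectors(self, helix_modes):
        v = helix_modes.eigenvectors
        gram = v.T @ v
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_ascending_eigenvalues(self, helix_modes):
        assert np.all(np.diff(helix_modes.eigenvalues) >= -1e-12)

    def test_n_modes_too_large(self, helix40):
        h = build_enm(helix40)
        with pytest.raises(ValueError):
            diagonalize(h, n_modes=3 * 40 + 1)

    def test_mode_numbering_from_seven(self, helix_modes):
        col = helix_modes.mode_column(7)
        assert col == 6
        assert helix_modes.eigenvalues[col] > 0


class TestVarianceFraction:
    def test_all_internal_is_one(self, helix_modes):
        k = len(helix_modes.eigenvalues) - helix_modes.n_zero
        assert variance_fraction(helix_modes, k) == pytest.approx(1.0)

    def test_zero_is_zero(self, helix_modes):
        assert variance_fraction(helix_modes, 0) == 0.0

    def test_monotone_in_k(self, helix_modes):
        n_internal = len(helix_modes.eigenvalues) - helix_modes.n_zero
        fractions = [variance_fraction(helix_modes, k)
                     for k in range(n_internal + 1)]
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))

    def test_equal_weighting_option(self, helix_modes):
        n_internal = len(helix_modes.eigenvalues) - helix_modes.n_zero
        assert variance_fraction(helix_modes, 5, weighting="equal") == (
            pytest.approx(5 / n_internal)
        )


class TestModeFluctuations:
    def test_rigid_body_modes_never_contribute(self, helix40):
        h = build_enm(helix40)
        full = diagonalize(h, n_modes=3 * 40)
        few = diagonalize(h, n_modes=30)
        msf_full = mode_fluctuations(full, n_modes=20)
        msf_few = mode_fluctuations(few, n_modes=20)
        np.testing.assert_allclose(msf_full, msf_few, atol=1e-10)

    def test_linear_chain_ends_move_more(self):
        # collinear chain has 7 zero modes; build the mode set manually
        coords = np.array([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        h = build_enm(ca_structure(coords), cutoff=5.0)
        eigenvalues, eigenvectors = np.linalg.eigh(h.matrix)
        nonzero = eigenvalues > 1e-8
        m = ModeSet(
            node_keys=[("A", i + 1, "") for i in range(3)],
            node_coords=coords,
            eigenvalues=eigenvalues[nonzero],
            eigenvectors=eigenvectors[:, nonzero],
            n_zero=0, cutoff=5.0, gamma=1.0,
        )
        msf = mode_fluctuations(m)
        assert msf[0] > msf[1]
        assert msf[2] > msf[1]

    def test_msf_scales_inverse_gamma(self, helix40):
        m1 = compute_modes(helix40, gamma=1.0)
        m2 = compute_modes(helix40, gamma=2.0)
        np.testing.assert_allclose(
            mode_fluctuations(m1), 2.0 * mode_fluctuations(m2), rtol=1e-8
        )

    def test_bfactor_roundtrip_correlation(self, helix40):
        m = compute_modes(helix40)
        msf = mode_fluctuations(m)
        rng = np.random.default_rng(5)
        b_like = msf * 50 + rng.normal(0, 0.05 * msf.std() * 50, msf.size)
        r = np.corrcoef(msf, b_like)[0, 1]
        assert r > 0.5


class TestProjection:
    def test_reference_copies_project_to_zero(self, helix40, helix_modes):
        e = Ensemble(helix40, [helix40.coords] * 5)
        proj = project_ensemble(e, helix_modes, [7, 8, 9])
        assert np.abs(proj.coordinates).max() < 1e-9

    def test_planted_amplitude_exact(self, helix40, helix_modes):
        amp = 1.7
        vec = helix_modes.eigenvector(8).reshape(-1, 3)
        node_of = {k: i for i, k in enumerate(helix_modes.node_keys)}
        disp = np.array([vec[node_of[a.residue_key]] for a in helix40.atoms])
        frame = helix40.coords + amp * disp
        e = Ensemble(helix40, [frame])
        proj = project_ensemble(e, helix_modes, [7, 8, 9], superpose=False)
        np.testing.assert_allclose(proj.coordinates[0, 1], amp, atol=1e-8)
        assert abs(proj.coordinates[0, 0]) < 1e-8
        assert abs(proj.coordinates[0, 2]) < 1e-8

    def test_projection_linearity(self, helix40, helix_modes):
        rng = np.random.default_rng(3)
        vec = helix_modes.eigenvector(9).reshape(-1, 3)
        node_of = {k: i for i, k in enumerate(helix_modes.node_keys)}
        disp = np.array([vec[node_of[a.residue_key]] for a in helix40.atoms])
        disp += rng.normal(0, 0.01, disp.shape)
        e = Ensemble(helix40, [helix40.coords + disp,
                               helix40.coords + 2.5 * disp])
        proj = project_ensemble(e, helix_modes, [7, 8, 9, 10], superpose=False)
        np.testing.assert_allclose(
            2.5 * proj.coordinates[0], proj.coordinates[1], atol=1e-9
        )

    def test_noisy_mean_recovery(self, helix40):
        amp, sigma, n = 2.0, 0.1, 300
        e, mode_set, truth = sd.make_mode_ensemble(
            helix40, mode_number=8, amplitude_mean=amp, amplitude_sd=0.0,
            n_frames=n, seed=9, noise_sd=sigma,
        )
        proj = project_ensemble(e, mode_set, [8])
        mean = proj.coordinates[:, 0].mean()
        assert abs(mean - amp) < 3 * sigma  # generous: 3 sigma per-frame
        assert abs(mean - amp) < 5 * sigma / np.sqrt(n) + 0.05

    def test_node_mismatch_rejected(self, helix40, helix_modes):
        short = sd.make_helix(20, seed=11)
        e = Ensemble(short, [short.coords])
        with pytest.raises(AllopathError):
            project_ensemble(e, helix_modes, [7])


class TestPopulationShift:
    def _projection(self, values):
        from allopath.modes import ProjectionSet

        return ProjectionSet(mode_numbers=[7], coordinates=np.asarray(values)[:, None])

    def test_identical_sets_zero_effect(self, rng):
        x = rng.standard_normal(100)
        shifts = population_shift(self._projection(x), self._projection(x))
        assert shifts[0].effect_size == 0.0
        assert shifts[0].p_value == 1.0

    def test_planted_two_sigma_shift(self):
        rng = np.random.default_rng(17)
        from allopath.modes import ProjectionSet

        n = 200
        apo = np.column_stack([rng.standard_normal(n) for _ in range(3)])
        holo = apo.copy() + rng.standard_normal((n, 3)) * 0.0
        holo = np.column_stack([
            rng.standard_normal(n),
            rng.standard_normal(n) + 2.0,   # planted on mode 8
            rng.standard_normal(n),
        ])
        p_apo = ProjectionSet([7, 8, 9], apo)
        p_holo = ProjectionSet([7, 8, 9], holo)
        shifts = population_shift(p_apo, p_holo)
        assert shifts[0].mode_number == 8
        assert abs(shifts[0].effect_size - 2.0) < 0.3

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(2024)
        false_positives = 0
        reps = 200
        for _ in range(reps):
            a = self._projection(rng.standard_normal(50))
            b = self._projection(rng.standard_normal(50))
            if population_shift(a, b)[0].p_value < 0.05:
                false_positives += 1
        assert false_positives / reps <= 0.05

    def test_few_frames_warns(self, rng):
        a = self._projection(rng.standard_normal(5))
        b = self._projection(rng.standard_normal(5))
        with pytest.warns(UserWarning, match="unstable"):
            population_shift(a, b)


class TestDCC:
    def test_unit_diagonal_symmetric_bounded(self, helix_modes):
        result = dcc(helix_modes, n_modes=30)
        np.testing.assert_allclose(np.diag(result.matrix), 1.0, atol=1e-12)
        np.testing.assert_allclose(result.matrix, result.matrix.T, atol=1e-12)
        assert result.matrix.min() >= -1.0
        assert result.matrix.max() <= 1.0

    def test_two_body_antiphase(self):
        # one stretch mode along x: v = (1,0,0,-1,0,0)/sqrt(2), lambda = 2
        v = np.array([[1, 0, 0, -1, 0, 0]], dtype=float).T / np.sqrt(2)
        m = ModeSet(
            node_keys=[("A", 1, ""), ("A", 2, "")],
            node_coords=np.array([(0, 0, 0), (2, 0, 0)], float),
            eigenvalues=np.array([2.0]),
            eigenvectors=v,
            n_zero=0, cutoff=5.0, gamma=1.0,
        )
        result = dcc(m, n_modes=1)
        assert result.matrix[0, 1] == pytest.approx(-1.0)

    def test_gamma_scaling_invariance(self, helix40):
        m1 = compute_modes(helix40, gamma=1.0)
        m2 = compute_modes(helix40, gamma=3.7)
        np.testing.assert_allclose(
            dcc(m1, 30).matrix, dcc(m2, 30).matrix, atol=1e-9
        )

    def test_matches_covariance_sampling_oracle(self):
        base = sd.make_helix(12, seed=2)
        m = compute_modes(base)
        k = len(m.eigenvalues) - m.n_zero
        analytic = dcc(m, n_modes=k)

        rng = np.random.default_rng(8)
        lam = m.eigenvalues[m.n_zero:]
        vec = m.eigenvectors[:, m.n_zero:]           # (3N, K)
        n_frames = 10_000
        amplitudes = rng.standard_normal((n_frames, k)) / np.sqrt(lam)
        disp = amplitudes @ vec.T                    # (F, 3N)
        disp = disp.reshape(n_frames, m.n_nodes, 3)
        cov = np.einsum("fia,fja->ij", disp, disp) / n_frames
        norm = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        sampled = cov / norm
        assert np.abs(sampled - analytic.matrix).max() < 0.05
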