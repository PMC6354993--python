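"""Mode extraction: POD/PCA/DMD/DMDC recipes, spectra, projections, estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from aeromode.decomposition import (
    DMD,
    DMDC,
    PCA,
    POD,
    ModeBasis,
    build_feature_table,
    continuous_frequencies,
    cumulative_energy,
    dmd,
    dmdc,
    load_basis,
    pca,
    pod,
    project,
    save_basis,
    spectrum_peaks,
)
from aeromode.io import assemble_snapshots, build_control_matrix, split_transitions

rng = np.random.default_rng(42)


def _lifted_trajectories(A, C=None, Y=None, n_traj=6, n_steps=4, n_pix=12, seed=0):
    """Pixel snapshots of a planted latent system, lifted by a fixed matrix."""
    r = A.shape[0]
    g = np.random.default_rng(seed)
    L = g.normal(size=(n_pix, r))
    Xp, Xdp = [], []
    for t in range(n_traj):
        z = g.normal(size=r)
        for k in range(n_steps):
            z_next = A @ z
            if C is not None:
                z_next = z_next + C @ Y[:, t * n_steps + k]
            Xp.append(L @ z)
            Xdp.append(L @ z_next)
            z = z_next
    return np.array(Xp).T, np.array(Xdp).T


# ---------------------------------------------------------------- POD / PCA

def test_pod_modes_are_orthonormal_and_detect_rank():
    X = rng.normal(size=(40, 25))
    basis = POD(n_modes=10).fit(X.T.T).basis_  # rows are samples
    M = basis.modes
    assert np.abs(M.T @ M - np.eye(M.shape[1])).max() < 1e-10
    u, v = rng.normal(size=30), rng.normal(size=8)
    with pytest.warns(UserWarning):
        rank1 = POD(n_modes=5).fit(np.outer(v, u)).basis_
    s = rank1.singular_values
    assert np.sum(s > 1e-10 * s[0]) == 1


def test_pod_reconstruction_error_matches_tail_singular_values():
    X = rng.normal(size=(30, 18))  # pixels x snapshots
    basis = pod_like(X, r=5)
    err = np.linalg.norm(X - basis.modes @ (basis.modes.T @ X))
    expected = np.sqrt(np.sum(basis.singular_values[5:] ** 2))
    assert abs(err - expected) < 1e-8


def pod_like(X, r):
    est = POD(n_modes=r).fit(X.T)
    return est.basis_


def test_pca_equals_pod_of_centered_data_up_to_sign():
    X = rng.normal(size=(25, 15)) + 3.0
    p = PCA(n_modes=4).fit(X)
    q = POD(n_modes=4).fit(X - X.mean(axis=0))
    dots = np.abs(np.sum(p.basis_.modes * q.basis_.modes, axis=0))
    assert np.allclose(dots, 1.0, atol=1e-8)
    # total PCA energy equals the centered Frobenius norm
    total = np.sum(p.basis_.singular_values**2)
    assert abs(total - np.linalg.norm(X - X.mean(axis=0)) ** 2) < 1e-8


def test_full_rank_reconstruction_recovers_the_data():
    X = rng.normal(size=(20, 12))
    basis = pod_like(X, r=12)
    recon = basis.modes @ (basis.modes.T @ X)
    assert np.linalg.norm(recon - X) / np.linalg.norm(X) < 1e-8


# ---------------------------------------------------------------------- DMD

def test_dmd_recovers_a_planted_two_state_map():
    A = np.diag([0.9, 0.5])
    Xp, Xdp = _lifted_trajectories(A, n_pix=10, seed=1)
    lam = np.sort_complex(dmd(Xp, Xdp, r=2).eigenvalues)
    assert np.abs(lam - np.array([0.5, 0.9])).max() < 1e-8


def test_dmd_identity_and_annihilation_dynamics():
    X = rng.normal(size=(15, 8))
    lam_id = dmd(X, X, r=4).eigenvalues
    assert np.abs(lam_id - 1.0).max() < 1e-10
    with pytest.warns(UserWarning):  # zero eigenvalues map to -inf frequency
        lam_zero = dmd(X, np.zeros_like(X), r=4).eigenvalues
    assert np.abs(lam_zero).max() < 1e-12


def test_dmd_one_step_prediction_on_noiseless_planted_data(noiseless_free_dataset):
    dataset, _ = noiseless_free_dataset
    snap = assemble_snapshots(dataset)
    Xp, Xdp = split_transitions(snap)
    basis = dmd(Xp, Xdp, r=9)
    Phi = basis.modes
    advance = Phi @ np.diag(basis.eigenvalues) @ np.linalg.pinv(Phi)
    pred = (advance @ Xp.values).real
    rel = np.linalg.norm(pred - Xdp.values) / np.linalg.norm(Xdp.values)
    assert rel < 1e-6


def test_dmd_rejects_zero_input_and_shape_mismatch():
    with pytest.raises(ValueError):
        dmd(np.zeros((5, 4)), rng.normal(size=(5, 4)), r=2)
    with pytest.raises(ValueError):
        dmd(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)), r=2)


# --------------------------------------------------------------------- DMDC

def test_dmdc_with_zero_control_reduces_to_dmd():
    A = np.diag([0.8, 0.3, -0.6])
    Xp, Xdp = _lifted_trajectories(A, n_pix=9, seed=2)
    Y = np.zeros((3, Xp.shape[1]))
    lam_dmd = np.sort_complex(dmd(Xp, Xdp, r=3).eigenvalues)
    basis, _ = dmdc(Xp, Xdp, Y, r=3)
    lam_dmdc = np.sort_complex(basis.eigenvalues)
    assert np.abs(lam_dmd - lam_dmdc).max() < 1e-8


def test_dmdc_matches_the_pseudoinverse_oracle_on_a_hand_sized_system():
    g = np.random.default_rng(3)
    A = np.array([[0.7, 0.2, 0.0], [0.0, 0.5, 0.1], [0.0, 0.0, 0.3]])
    C = np.array([[1.0], [0.5], [-0.4]])
    n_traj, n_steps = 4, 4
    Y = g.normal(size=(1, n_traj * n_steps))
    Xp, Xdp = [], []
    for t in range(n_traj):
        z = g.normal(size=3)
        for k in range(n_steps):
            z1 = A @ z + C @ Y[:, t * n_steps + k]
            Xp.append(z)
            Xdp.append(z1)
            z = z1
    Xp, Xdp = np.array(Xp).T, np.array(Xdp).T
    est = DMDC(n_modes=3, input_rank=4).fit_transitions(Xp, Xdp, Y)
    # oracle: the explicit min-norm solution G = X'' Omega^+
    G = Xdp @ np.linalg.pinv(np.vstack([Xp, Y]))
    Uhat = est.control_operator_.state_basis
    W = np.linalg.eig(Uhat.conj().T @ G[:, :3] @ Uhat)[0]
    assert np.abs(np.sort_complex(W) - np.sort_complex(est.eigenvalues_)).max() < 1e-10
    assert np.abs(est.control_operator_.values - Uhat.conj().T @ G[:, 3:]).max() < 1e-10


def test_dmdc_rejects_misaligned_controls():
    Xp = rng.normal(size=(6, 8))
    with pytest.raises(ValueError):
        dmdc(Xp, Xp, np.zeros((3, 5)), r=2)


def test_dmdc_recovers_planted_control_on_noiseless_default(noiseless_default_dataset):
    dataset, truth = noiseless_default_dataset
    snap = assemble_snapshots(dataset)
    Xp, Xdp = split_transitions(snap)
    Y = build_control_matrix(Xp.columns, standardize=True)
    assert np.allclose(Y.values, truth.control_inputs)
    basis, ctrl = dmdc(Xp, Xdp, Y, p=12, r=9)
    # oracle: lift the planted control through the stored spatial modes
    lifted = ctrl.state_basis.conj().T @ (truth.spatial_modes @ truth.planted_control)
    assert np.abs(ctrl.values - lifted).max() < 1e-6


# ------------------------------------------------- frequencies and spectra

def test_continuous_frequency_examples():
    om = continuous_frequencies(np.array([1.0, np.exp(-np.pi)]))
    assert abs(om[0]) < 1e-15
    assert abs(om[1].real + 0.5) < 1e-12 and abs(om[1].imag) < 1e-12
    with pytest.warns(UserWarning):
        om0 = continuous_frequencies(np.array([0.0]))
    assert om0[0].real == -np.inf


@settings(derandomize=True, max_examples=50)
@given(
    st.complex_numbers(min_magnitude=1e-6, max_magnitude=10.0,
                       allow_nan=False, allow_infinity=False)
)
def test_frequency_sign_tracks_eigenvalue_magnitude(lam):
    om = continuous_frequencies(np.array([lam]))[0]
    assert (abs(lam) < 1.0) == (om.real < 0.0) or abs(abs(lam) - 1.0) < 1e-12
    assert -0.5 < om.imag <= 0.5


def _basis_with(lams, amps):
    lams = np.asarray(lams, dtype=complex)
    return ModeBasis(
        method="DMD",
        modes=np.eye(len(lams), dtype=complex),
        singular_values=np.ones(len(lams)),
        rank_used=len(lams),
        eigenvalues=lams,
        continuous_eigenvalues=continuous_frequencies(lams),
        amplitudes=np.asarray(amps, dtype=complex),
    )


def test_spectrum_peaks_edge_cases():
    one = _basis_with([0.9 * np.exp(1j * 0.8)], [2.0])
    assert len(spectrum_peaks(one)) == 1
    # a dense flat spectrum (every bin equally loaded) has no strict maxima
    dense = [(i + 0.5) * 0.5 / 32 for i in range(32)]
    flat = _basis_with([0.9 * np.exp(2j * np.pi * f) for f in dense], [1.0] * 32)
    assert spectrum_peaks(flat) == []
    with pytest.raises(ValueError):
        spectrum_peaks(ModeBasis("POD", np.eye(3), np.ones(3), 3))


def test_spectrum_peaks_find_planted_oscillations():
    freqs = [0.05, 0.125, 0.18, 0.25, 0.31, 0.40, 0.47]
    amps = [0.2, 3.0, 0.1, 2.0, 0.15, 1.0, 0.1]
    basis = _basis_with([0.95 * np.exp(2j * np.pi * f) for f in freqs], amps)
    peaks = spectrum_peaks(basis)
    got = sorted(f for f, _ in peaks)
    assert np.allclose(got, [0.125, 0.25, 0.40], atol=1e-9)


def test_cumulative_energy_properties():
    s = np.array([4.0, 2.0, 1.0])
    fractions = [cumulative_energy(s, k) for k in (1, 2, 3)]
    assert fractions[-1] == 1.0
    assert all(b >= a for a, b in zip(fractions, fractions[1:]))
    assert cumulative_energy(np.array([7.0, 0.0]), 1) == 1.0
    with pytest.raises(ValueError):
        cumulative_energy(np.zeros(3), 1)
    with pytest.raises(ValueError):
        cumulative_energy(s, 4)


# --------------------------------------------------------------- projection

def test_projection_reproduces_orthonormal_coordinates():
    M = np.linalg.qr(rng.normal(size=(30, 4)))[0]
    basis = ModeBasis("POD", M, np.ones(4), 4)
    coeffs = project(basis, M[:, 0], r=4)
    assert np.allclose(coeffs, [1, 0, 0, 0], atol=1e-12)
    ortho = rng.normal(size=30)
    ortho -= M @ (M.T @ ortho)
    assert np.abs(project(basis, ortho, r=4)).max() < 1e-10


def test_projection_on_nonorthogonal_modes_matches_normal_equations():
    M = rng.normal(size=(25, 5)) + 1j * rng.normal(size=(25, 5))
    basis = ModeBasis("DMD", M, np.ones(5), 5,
                      eigenvalues=np.ones(5, dtype=complex),
                      continuous_eigenvalues=np.zeros(5, dtype=complex),
                      amplitudes=np.ones(5, dtype=complex))
    x = rng.normal(size=25)
    got = project(basis, x, r=5)
    oracle = np.linalg.solve(M.conj().T @ M, M.conj().T @ x)
    assert np.abs(got - oracle.real).max() < 1e-8


@settings(derandomize=True, max_examples=25)
@given(st.floats(-5, 5), st.floats(-5, 5))
def test_projection_is_linear(a, b):
    g = np.random.default_rng(7)
    M = np.linalg.qr(g.normal(size=(20, 3)))[0]
    basis = ModeBasis("POD", M, np.ones(3), 3)
    x, y = g.normal(size=20), g.normal(size=20)
    lhs = project(basis, a * x + b * y, r=3)
    rhs = a * project(basis, x, r=3) + b * project(basis, y, r=3)
    assert np.abs(lhs - rhs).max() < 1e-10


def test_projection_validates_shapes():
    M = np.linalg.qr(rng.normal(size=(20, 3)))[0]
    basis = ModeBasis("POD", M, np.ones(3), 3)
    with pytest.raises(ValueError):
        project(basis, np.zeros(19), r=3)
    with pytest.raises(ValueError):
        project(basis, np.zeros(20), r=4)


# ----------------------------------------------------------- feature tables

def test_feature_table_shape_and_nesting(small_dataset):
    dataset, _ = small_dataset
    snap = assemble_snapshots(dataset)
    basis = pod(snap, 25)
    table = build_feature_table(basis, dataset, 25)
    assert table.features.shape == (405, 25)
    assert list(table.labels) == dataset.manifest["class_label"].tolist()
    table3 = build_feature_table(basis, dataset, 3)
    assert np.allclose(table3.features, table.features[:, :3], atol=1e-10)


def test_zero_image_projects_to_zero_row(small_dataset):
    dataset, _ = small_dataset
    snap = assemble_snapshots(dataset)
    basis = pod(snap, 5)
    assert np.abs(project(basis, np.zeros(32 * 32), r=5)).max() == 0.0


# ----------------------------------------------- estimator API and persistence

def test_estimators_follow_sklearn_conventions(small_dataset):
    dataset, _ = small_dataset
    X = dataset.pixel_matrix()
    est = clone(PCA(n_modes=4)).fit(X)
    assert est.basis_.rank_used == 4
    feats = est.transform(X[:10])
    assert feats.shape == (10, 4)
    assert est.get_params()["n_modes"] == 4
    snap = assemble_snapshots(dataset)
    groups = snap.columns["group"].to_numpy()
    stages = snap.columns["stage"].to_numpy()
    d = DMD(n_modes=6).fit(snap.values.T, groups=groups, stages=stages)
    assert d.basis_.eigenvalues.shape == (6,)
    with pytest.raises(ValueError):
        DMD(n_modes=3).fit(X)  # grouping is mandatory for dynamics
    with pytest.raises(ValueError):
        POD(n_modes=3).transform(X)  # unfitted


def test_basis_round_trips_through_npz(small_dataset, tmp_path):
    dataset, _ = small_dataset
    snap = assemble_snapshots(dataset)
    Xp, Xdp = split_transitions(snap)
    basis = dmd(Xp, Xdp, r=8)
    path = tmp_path / "dmd.npz"
    save_basis(basis, path)
    back = load_basis(path)
    assert back.method == "DMD" and back.rank_used == 8
    assert np.array_equal(back.modes, basis.modes)
    assert np.array_equal(back.eigenvalues, basis.eigenvalues)
    assert np.array_equal(back.amplitudes, basis.amplitudes)
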