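"""SVD eigenmode extraction: POD, PCA, exact DMD, and DMD with control.

All four extractors are presented as scikit-learn estimators operating on an
``(n_samples, n_pixels)`` image matrix (rows are flattened images): ``fit``
learns a mode basis, ``transform`` projects images onto the leading modes to
produce real feature vectors.  POD is the SVD of the raw snapshot matrix;
PCA is POD after subtracting the ensemble-mean image.  DMD estimates the
linear operator of the stage-to-stage evolution X″ ≈ A·X′ and returns its
(complex) eigenvectors as modes; DMDC additionally separates the effect of
exogenous control inputs, X″ ≈ A·X′ + C·Y.

Discrete eigenvalues λ are reported together with continuous ones
ω = log(λ)/(2π): a mode decays over the progression sequence iff |λ| < 1
iff Re ω < 0, and |Im ω| is its oscillation frequency in progression-index
units (a period-T cycle appears at |Im ω| = 1/T).

Module-level functions (:func:`pod`, :func:`pca`, :func:`dmd`, :func:`dmdc`,
...) are thin wrappers over the estimators for snapshot-matrix workflows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .airway import STAGE_LABELS
from .io import AerosolDataset, ControlMatrix, SnapshotMatrix

__all__ = [
    "ModeBasis",
    "ControlOperator",
    "FeatureTable",
    "POD",
    "PCA",
    "DMD",
    "DMDC",
    "pod",
    "pca",
    "dmd",
    "dmdc",
    "continuous_frequencies",
    "spectrum_peaks",
    "cumulative_energy",
    "project",
    "build_feature_table",
    "save_basis",
    "load_basis",
]

#: Relative singular-value cutoff guarding every pseudo-inversion.
DEFAULT_SVD_TOL = 1e-10


# ----------------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------------

@dataclass
class ModeBasis:
    """The result of one eigenmode extraction.

    ``modes`` is (n_pixels, r); complex for DMD/DMDC.  ``singular_values``
    is the full descending σ spectrum of the decomposed matrix (used for
    cumulative energy), not truncated at r.  For DMD/DMDC the modes are
    stored ranked by amplitude |b| (ties by |λ|); for POD/PCA by σ.
    """

    method: str
    modes: np.ndarray
    singular_values: np.ndarray
    rank_used: int
    eigenvalues: np.ndarray | None = None
    continuous_eigenvalues: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be sorted descending")
        if np.any(self.singular_values < 0):
            raise ValueError("singular values must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return self.modes.shape[0]


@dataclass
class ControlOperator:
    """The reduced control operator C̃ of DMDC plus the state basis Û it lives in."""

    values: np.ndarray  # (r, q)
    state_basis: np.ndarray  # (n_pixels, r), the output-side POD basis Û

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureTable:
    """Per-image real feature vectors (projections onto r retained modes)."""

    features: np.ndarray  # (n_samples, r)
    labels: np.ndarray  # class label per row
    conditions: pd.DataFrame
    method: str
    r: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValueError("feature table contains non-finite entries")
        if len(self.features) != len(self.labels):
            raise ValueError("labels do not align with feature rows")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, columns=[f"{self.method.lower()}_{i + 1}" for i in range(self.r)]
        )
        df.insert(0, "class_label", self.labels)
        return pd.concat([df, self.conditions.reset_index(drop=True)], axis=1)


# ----------------------------------------------------------------------------
# numerical helpers
# ----------------------------------------------------------------------------

def _truncated_svd(M: np.ndarray, r: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Economy SVD truncated at min(r, numerical rank); returns (U_r, s_r, V_r, s_full)."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    num_rank = int(np.sum(s > tol * s[0])) if s.size and s[0] > 0 else 0
    if num_rank == 0:
        raise ValueError("matrix is numerically zero; nothing to decompose")
    if r > num_rank:
        warnings.warn(
            f"requested rank {r} exceeds numerical rank {num_rank}; truncating",
            stacklevel=3,
        )
        r = num_rank
    return U[:, :r], s[:r], Vt[:r].conj().T, s


def continuous_frequencies(eigenvalues: np.ndarray) -> np.ndarray:
    """Continuous eigenvalues ω = log(λ)/(2π), principal branch.

    Im ω ∈ (−1/2, 1/2]; |λ| < 1 ⇔ Re ω < 0.  λ = 0 maps to Re ω = −inf
    with a warning.
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    omega = np.empty_like(lam)
    zero = lam == 0
    if zero.any():
        warnings.warn("zero eigenvalue(s): continuous frequency set to -inf", stacklevel=2)
        omega[zero] = complex(-np.inf, 0.0)
    nz = ~zero
    omega[nz] = np.log(lam[nz]) / (2.0 * np.pi)
    # negative reals approached from below give Im = -1/2; normalize onto (-1/2, 1/2]
    flip = nz & (omega.imag <= -0.5)
    omega[flip] = omega[flip].real + 1j * (omega[flip].imag + 1.0)
    return omega


def cumulative_energy(singular_values: np.ndarray, k: int) -> float:
    """Fraction of squared-singular-value energy captured by the first k values."""
    s = np.asarray(singular_values, dtype=float)
    if not 1 <= k <= len(s):
        raise ValueError(f"k must be in [1, {len(s)}], got {k}")
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("all singular values are zero")
    return float(np.sum(s[:k] ** 2) / total)


def _rank_dynamic_modes(
    Phi: np.ndarray, lam: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize dynamic modes to unit norm and order by |b| desc, ties by |λ| desc.

    Exact-DMD modes come out unnormalized; folding the mode norm into the
    amplitude makes |b| measure the energy a mode actually contributes.
    """
    norms = np.linalg.norm(Phi, axis=0)
    norms[norms == 0] = 1.0
    Phi = Phi / norms[None, :]
    b = b * norms
    order = np.lexsort((-np.abs(lam), -np.abs(b)))
    return Phi[:, order], lam[order], b[order]


def _amplitudes(Phi: np.ndarray, X_prime: np.ndarray, group_starts: np.ndarray | None) -> np.ndarray:
    """Mode amplitudes |Φ† x₀|, magnitude-averaged over group-initial columns.

    With many groups the initial phases of oscillatory content vary from
    group to group, so complex averaging would cancel it; the magnitude mean
    measures how strongly a mode is excited across the ensemble.
    """
    starts = np.array([0]) if group_starts is None or len(group_starts) == 0 else group_starts
    pinv = np.linalg.pinv(Phi, rcond=DEFAULT_SVD_TOL)
    per_group = pinv @ X_prime[:, starts]
    if per_group.shape[1] == 1:
        return per_group[:, 0]
    # median rather than mean: an occasional outlier initial snapshot would
    # otherwise hand spurious modes a large apparent amplitude
    return np.median(np.abs(per_group), axis=1).astype(complex)


# ----------------------------------------------------------------------------
# estimators
# ----------------------------------------------------------------------------

class _ModeExtractor(TransformerMixin, BaseEstimator):
    """Shared fit/transform machinery for the four extractors."""

    method: str = ""

    def __init__(self, n_modes: int = 25, svd_tol: float = DEFAULT_SVD_TOL):
        self.n_modes = n_modes
        self.svd_tol = svd_tol

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_pixels)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        self.n_features_in_ = X.shape[1]
        return X

    def transform(self, X: np.ndarray, r: int | None = None) -> np.ndarray:
        """Least-squares projection of images (rows) onto the first r modes.

        Returns the real part of the coefficients; for PCA the stored mean
        image is subtracted first.
        """
        if not hasattr(self, "basis_"):
            raise ValueError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        one_dim = X.ndim == 1
        if one_dim:
            X = X[None, :]
        if X.shape[1] != self.basis_.n_pixels:
            raise ValueError(
                f"image length {X.shape[1]} does not match basis pixels {self.basis_.n_pixels}"
            )
        if self.basis_.mean is not None:
            X = X - self.basis_.mean[None, :]
        r = self.basis_.rank_used if r is None else r
        if r > self.basis_.rank_used:
            raise ValueError(f"r={r} exceeds the {self.basis_.rank_used} fitted modes")
        coeffs = (self._projector(r) @ X.T).T.real
        return coeffs[0] if one_dim else coeffs

    def _projector(self, r: int) -> np.ndarray:
        key = getattr(self, "_projector_cache_", (None, None))
        if key[0] != r:
            pinv = np.linalg.pinv(self.basis_.modes[:, :r], rcond=self.svd_tol)
            self._projector_cache_ = (r, pinv)
        return self._projector_cache_[1]

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [f"{self.method.lower()}_{i + 1}" for i in range(self.basis_.rank_used)]
        )


class POD(_ModeExtractor):
    """Proper orthogonal decomposition: left singular vectors of the raw snapshots."""

    method = "POD"

    def fit(self, X: np.ndarray, y=None) -> "POD":
        X = self._validate(X)
        U, s, _, s_full = _truncated_svd(X.T, self.n_modes, self.svd_tol)
        self.basis_ = ModeBasis(
            method=self.method, modes=U, singular_values=s_full, rank_used=U.shape[1]
        )
        self.modes_ = U
        self.singular_values_ = s_full
        return self


class PCA(_ModeExtractor):
    """POD of the mean-subtracted snapshots; the mean image is stored and reapplied."""

    method = "PCA"

    def fit(self, X: np.ndarray, y=None) -> "PCA":
        X = self._validate(X)
        mean = X.mean(axis=0)
        U, s, _, s_full = _truncated_svd((X - mean).T, self.n_modes, self.svd_tol)
        self.basis_ = ModeBasis(
            method=self.method, modes=U, singular_values=s_full, rank_used=U.shape[1],
            mean=mean,
        )
        self.modes_ = U
        self.mean_ = mean
        self.singular_values_ = s_full
        return self


class DMD(_ModeExtractor):
    """Exact dynamic mode decomposition of the stage-to-stage transitions.

    ``fit`` expects images in grouped progression order (see
    :meth:`fit_transitions` for the matrix-level recipe): X is split per
    group into before/after stacks X′ (stages 0–3) and X″ (stages 1–4).
    """

    method = "DMD"

    def fit(self, X: np.ndarray, y=None, *, groups=None, stages=None) -> "DMD":
        X = self._validate(X)
        Xp, Xdp, starts = _grouped_transitions(X, groups, stages)
        return self.fit_transitions(Xp, Xdp, group_starts=starts)

    def fit_transitions(
        self, X_prime: np.ndarray, X_dprime: np.ndarray, group_starts: np.ndarray | None = None
    ) -> "DMD":
        """Exact-DMD recipe on a paired (X′, X″): SVD-project, eigendecompose, lift.

        X′ = UΣV*, Ã = U*X″VΣ⁻¹, ÃW = WΛ, modes Φ = X″VΣ⁻¹W, b = Φ†x₀
        (averaged over group-initial columns).
        """
        if X_prime.shape != X_dprime.shape:
            raise ValueError("X_prime and X_dprime must have matching shapes")
        if not np.any(X_prime):
            raise ValueError("X_prime is identically zero")
        U, s, V, s_full = _truncated_svd(X_prime, self.n_modes, self.svd_tol)
        B = X_dprime @ (V / s[None, :])  # X″ V Σ⁻¹
        Atilde = U.conj().T @ B
        lam, W = np.linalg.eig(Atilde)
        Phi = B @ W
        b = _amplitudes(Phi, X_prime, group_starts)
        Phi, lam, b = _rank_dynamic_modes(Phi, lam, b)
        self.basis_ = ModeBasis(
            method=self.method,
            modes=Phi,
            singular_values=s_full,
            rank_used=Phi.shape[1],
            eigenvalues=lam,
            continuous_eigenvalues=continuous_frequencies(lam),
            amplitudes=b,
        )
        self.modes_ = Phi
        self.eigenvalues_ = lam
        self.operator_rank_ = len(s)
        return self


class DMDC(_ModeExtractor):
    """DMD with control: X″ ≈ A·X′ + C·Y via the two-SVD formulation.

    The augmented matrix Ω = [X′; Y] is truncated at ``input_rank`` p
    (default ``n_modes + q``), the output X″ at ``n_modes`` r.  After fitting,
    ``control_operator_`` holds the reduced C̃ mapping standardized controls
    to state change in the output basis Û.
    """

    method = "DMDC"

    def __init__(
        self, n_modes: int = 25, svd_tol: float = DEFAULT_SVD_TOL, input_rank: int | None = None
    ):
        super().__init__(n_modes=n_modes, svd_tol=svd_tol)
        self.input_rank = input_rank

    def fit(self, X: np.ndarray, y=None, *, groups=None, stages=None, controls=None) -> "DMDC":
        X = self._validate(X)
        if controls is None:
            raise ValueError("DMDC requires the control matrix via controls=")
        Xp, Xdp, starts = _grouped_transitions(X, groups, stages)
        Y = controls.values if isinstance(controls, ControlMatrix) else np.asarray(controls)
        return self.fit_transitions(Xp, Xdp, Y, group_starts=starts)

    def fit_transitions(
        self,
        X_prime: np.ndarray,
        X_dprime: np.ndarray,
        Y: np.ndarray,
        group_starts: np.ndarray | None = None,
    ) -> "DMDC":
        if X_prime.shape != X_dprime.shape:
            raise ValueError("X_prime and X_dprime must have matching shapes")
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != X_prime.shape[1]:
            raise ValueError(
                f"control matrix columns ({Y.shape}) must align with X_prime "
                f"columns ({X_prime.shape[1]})"
            )
        n = X_prime.shape[0]
        q = Y.shape[0]
        p = self.input_rank if self.input_rank is not None else self.n_modes + q
        Omega = np.vstack([X_prime, Y])
        Ut, st, Vt, _ = _truncated_svd(Omega, p, self.svd_tol)
        U1 = Ut[:n]  # pixel block of the input basis
        U2 = Ut[n:]  # control block
        Uhat, _, _, s_full = _truncated_svd(X_dprime, self.n_modes, self.svd_tol)
        B = X_dprime @ (Vt / st[None, :])  # X″ Ṽ Σ̃⁻¹
        Atilde = Uhat.conj().T @ B @ U1.conj().T @ Uhat
        Ctilde = Uhat.conj().T @ B @ U2.conj().T
        lam, W = np.linalg.eig(Atilde)
        Phi = B @ U1.conj().T @ Uhat @ W
        b = _amplitudes(Phi, X_prime, group_starts)
        Phi, lam, b = _rank_dynamic_modes(Phi, lam, b)
        self.basis_ = ModeBasis(
            method=self.method,
            modes=Phi,
            singular_values=s_full,
            rank_used=Phi.shape[1],
            eigenvalues=lam,
            continuous_eigenvalues=continuous_frequencies(lam),
            amplitudes=b,
        )
        self.modes_ = Phi
        self.eigenvalues_ = lam
        self.control_operator_ = ControlOperator(values=Ctilde, state_basis=Uhat)
        return self


def _grouped_transitions(
    X: np.ndarray, groups, stages
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (X′, X″, group-start indices) from row-wise images + group/stage tags."""
    if groups is None or stages is None:
        raise ValueError("DMD-family fits require groups= and stages= per sample")
    groups = np.asarray(groups)
    stages = np.asarray(stages)
    n_stages = len(STAGE_LABELS)
    prime_cols, dprime_cols, starts = [], [], []
    col = 0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) != n_stages or sorted(stages[idx]) != list(range(n_stages)):
            raise ValueError(f"group {g!r} must contain exactly stages 0..{n_stages - 1}")
        idx = idx[np.argsort(stages[idx], kind="mergesort")]
        prime_cols.extend(idx[:-1])
        dprime_cols.extend(idx[1:])
        starts.append(col)
        col += n_stages - 1
    return X[prime_cols].T, X[dprime_cols].T, np.asarray(starts)


# ----------------------------------------------------------------------------
# snapshot-matrix wrappers (the functional surface)
# ----------------------------------------------------------------------------

def pod(X: SnapshotMatrix, r: int) -> ModeBasis:
    """POD of a snapshot matrix: first r left singular vectors of X."""
    return POD(n_modes=r).fit(X.values.T).basis_


def pca(X: SnapshotMatrix, r: int) -> ModeBasis:
    """PCA of a snapshot matrix: POD of the centered X, mean stored in the basis."""
    return PCA(n_modes=r).fit(X.values.T).basis_


def dmd(X_prime: SnapshotMatrix | np.ndarray, X_dprime: SnapshotMatrix | np.ndarray, r: int) -> ModeBasis:
    """Exact DMD of a transition pair (snapshot matrices or plain arrays)."""
    Xp, starts = _as_transition_array(X_prime)
    Xdp, _ = _as_transition_array(X_dprime)
    return DMD(n_modes=r).fit_transitions(Xp, Xdp, group_starts=starts).basis_


def dmdc(
    X_prime: SnapshotMatrix | np.ndarray,
    X_dprime: SnapshotMatrix | np.ndarray,
    Y: ControlMatrix | np.ndarray,
    p: int | None = None,
    r: int = 25,
) -> tuple[ModeBasis, ControlOperator]:
    """DMDC of a transition pair with control inputs Y; returns (basis, C̃)."""
    Xp, starts = _as_transition_array(X_prime)
    Xdp, _ = _as_transition_array(X_dprime)
    Yv = Y.values if isinstance(Y, ControlMatrix) else np.asarray(Y)
    est = DMDC(n_modes=r, input_rank=p).fit_transitions(Xp, Xdp, Yv, group_starts=starts)
    return est.basis_, est.control_operator_


def _as_transition_array(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, SnapshotMatrix):
        return X.values, X.group_start_indices()
    return np.asarray(X, dtype=float), None


def spectrum_peaks(
    basis: ModeBasis, n_peaks: int = 3, n_bins: int = 32
) -> list[tuple[float, float]]:
    """Dominant (frequency, amplitude) peaks of the mode-amplitude spectrum.

    Mode amplitudes |b| are folded onto the nonnegative frequency axis
    f = |Im ω| ∈ [0, 1/2] (conjugate pairs coincide) and aggregated into
    ``n_bins`` equal frequency bins.  A peak is a bin whose summed amplitude
    strictly exceeds both neighbouring bins; the first bin — which holds the
    zero-frequency mean/background component — has no left neighbour and is
    therefore never a peak.  Peaks are returned sorted by amplitude, largest
    first, at most ``n_peaks``; each is reported at the frequency of its
    bin's strongest mode.  A flat spectrum has no strict maxima and yields
    an empty list; with fewer than three occupied bins, whatever qualifies
    is returned.
    """
    if basis.amplitudes is None or basis.continuous_eigenvalues is None:
        raise ValueError("spectrum peaks require a DMD/DMDC basis with amplitudes")
    freq = np.abs(np.imag(basis.continuous_eigenvalues))
    amp = np.abs(basis.amplitudes)
    finite = np.isfinite(freq)
    freq, amp = freq[finite], amp[finite]
    if freq.size == 0:
        return []
    if freq.size == 1:
        return [(float(freq[0]), float(amp[0]))]
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    which = np.clip(np.digitize(freq, edges) - 1, 0, n_bins - 1)
    totals = np.bincount(which, weights=amp, minlength=n_bins)
    peaks = []
    for i in range(1, n_bins - 1):
        if totals[i] > totals[i - 1] and totals[i] > totals[i + 1]:
            in_bin = np.flatnonzero(which == i)
            top = in_bin[np.argmax(amp[in_bin])]
            peaks.append((float(freq[top]), float(totals[i])))
    peaks.sort(key=lambda p: -p[1])
    return peaks[:n_peaks]


def project(basis: ModeBasis, image: np.ndarray, r: int) -> np.ndarray:
    """Least-squares coefficients of one image on the first r modes (real part)."""
    image = np.asarray(image, dtype=float).reshape(-1)
    if image.shape[0] != basis.n_pixels:
        raise ValueError(
            f"image length {image.shape[0]} does not match basis pixels {basis.n_pixels}"
        )
    if r > basis.rank_used:
        raise ValueError(f"r={r} exceeds the {basis.rank_used} modes in the basis")
    x = image - basis.mean if basis.mean is not None else image
    coeffs = np.linalg.pinv(basis.modes[:, :r], rcond=DEFAULT_SVD_TOL) @ x
    return coeffs.real


def build_feature_table(basis: ModeBasis, dataset: AerosolDataset, r: int) -> FeatureTable:
    """Project every image of a dataset onto the first r modes, manifest order."""
    if r > basis.rank_used:
        raise ValueError(f"r={r} exceeds the {basis.rank_used} modes in the basis")
    X = dataset.pixel_matrix()
    if X.shape[1] != basis.n_pixels:
        raise ValueError("dataset pixel count does not match the basis")
    if basis.mean is not None:
        X = X - basis.mean[None, :]
    pinv = np.linalg.pinv(basis.modes[:, :r], rcond=DEFAULT_SVD_TOL)
    feats = (pinv @ X.T).T.real
    if not np.isfinite(feats).all():
        bad = np.flatnonzero(~np.isfinite(feats).all(axis=1))
        names = dataset.manifest["filename"].iloc[bad].tolist()
        raise ValueError(f"non-finite projections for images {names}")
    cond_cols = ["flow_rate_L_min", "particle_size_um", "replicate"]
    return FeatureTable(
        features=feats,
        labels=dataset.manifest["class_label"].to_numpy(),
        conditions=dataset.manifest[cond_cols].copy(),
        method=basis.method,
        r=r,
    )


# ----------------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------------

def save_basis(basis: ModeBasis, path: str | Path) -> Path:
    """Persist a ModeBasis as a single ``.npz`` archive with JSON metadata."""
    path = Path(path)
    arrays = {"modes": basis.modes, "singular_values": basis.singular_values}
    for name in ("eigenvalues", "continuous_eigenvalues", "amplitudes", "mean"):
        val = getattr(basis, name)
        if val is not None:
            arrays[name] = val
    meta = json.dumps({"method": basis.method, "rank_used": basis.rank_used})
    np.savez_compressed(path, _meta=np.array(meta), **arrays)
    return path


def load_basis(path: str | Path) -> ModeBasis:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["_meta"]))
        kwargs = {name: z[name] for name in
                  ("eigenvalues", "continuous_eigenvalues", "amplitudes", "mean")
                  if name in z.files}
        return ModeBasis(
            method=meta["method"],
            modes=z["modes"],
            singular_values=z["singular_values"],
            rank_used=int(meta["rank_used"]),
            **kwargs,
        )
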