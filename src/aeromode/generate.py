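"""Synthetic exhaled-aerosol image generator with planted linear dynamics.

The generator emulates the structure of the breath-test image database: 405
images = 5 disease stages × 3 flow rates × 9 particle sizes × 3 replicates,
a shared background pattern (vortex-like blobs and streaks), and
severity-ordered perturbations.  Within each (flow, size, replicate) group
the five stage images are snapshots of a linear latent system

    z_{k+1} = A z_k + C y_k,        x_k = clip(m + Phi z_k + noise, 0)

where ``A`` (``planted_dynamics``) contains three damped rotation pairs at
angles 2π/3, 2π/5 and 2π/9 — so the dynamic-mode amplitude spectrum of the
default dataset shows peaks at frequencies 1/3 (flow-associated), 1/5
(disease stage) and 1/9 (particle size) — plus two decaying coordinates,
``C`` (``planted_control``) maps the standardized controls (particle size,
flow rate, severity of the target stage) into the latent space, ``m`` is the
background mean pattern and ``Phi`` holds fixed, mutually non-orthogonal
spatial mode patterns.  Because the mean pattern rides along every snapshot
as a fixed point, the effective pixel-space operator has eigenvalues
{1} ∪ eig(A), all inside or on the unit circle.

Everything is a deterministic function of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .airway import SEVERITY_BY_LABEL, STAGE_LABELS
from .design import all_conditions
from .io import AerosolDataset, ControlMatrix, build_control_matrix

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_dynamics",
    "default_control",
    "generate_dataset",
    "save_ground_truth",
    "load_ground_truth",
]

#: Latent rotation periods (flow-, stage- and size-associated).
ROTATION_PERIODS = (3, 5, 9)

_LATENT_RANK = 8
_N_STAGES = len(STAGE_LABELS)


def default_dynamics(damping: float = 0.98, decays: tuple[float, float] = (0.7, 0.45)) -> np.ndarray:
    """Default planted latent operator: three damped rotation pairs + two decays.

    Rotation angles are 2π/3, 2π/5 and 2π/9, giving discrete eigenvalues
    ``damping * exp(±2πi/T)`` for T in (3, 5, 9); spectral radius < 1.
    """
    A = np.zeros((_LATENT_RANK, _LATENT_RANK))
    for i, period in enumerate(ROTATION_PERIODS):
        theta = 2.0 * np.pi / period
        c, s = np.cos(theta), np.sin(theta)
        A[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = damping * np.array([[c, -s], [s, c]])
    A[6, 6], A[7, 7] = decays
    return A


def default_control() -> np.ndarray:
    """Default planted control operator (latent_rank × 3).

    Columns act on the standardized controls in the order (particle size,
    flow rate, severity of the target stage).  Only the severity column is
    active: it drives the fast-decay coordinate (so the instantaneous
    severity of a stage is approximately read off one latent coordinate)
    plus, weakly, the period-5 rotation pair.  Particle size and flow rate
    are constant within a progression group, so their columns are zero and
    their effects enter through the group's initial latent state instead —
    a constant forcing would only shift the group fixed point while biasing
    the autonomous eigenvalues any control-blind decomposition estimates.
    """
    C = np.zeros((_LATENT_RANK, 3))
    C[7, 2] = 0.25             # severity -> fast decay (memoryless-ish)
    C[2:4, 2] = (0.0625, 0.02)  # severity -> period-5 pair
    return C


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic image generator.

    Parameters
    ----------
    seed : int
        Master RNG seed; required so that every run is reproducible.
    image_height, image_width : int
        Image resolution in pixels (each ≥ 8).  The analysis depends only on
        the column space, so any resolution supports the same invariants.
    latent_rank : int
        Number of planted latent coordinates.
    planted_dynamics : (latent_rank, latent_rank) array, optional
        The latent transition operator A; defaults to :func:`default_dynamics`.
        Spectral radius must not exceed 1 (stable system).
    planted_control : (latent_rank, 3) array, optional
        The latent control operator C; defaults to :func:`default_control`.
    effect_sizes : dict
        Per-factor perturbation magnitudes with keys ``severity``, ``flow``,
        ``size``; they scale the corresponding columns of C and the
        condition loading of the initial state.
    noise_sd : float
        Pixel-wise Gaussian noise standard deviation (intensity units).
    group_jitter_sd : float
        Standard deviation of the per-group random initial latent state
        (the replicate-to-replicate "stochastic inlet profile" variability).
    burst_prob, burst_scale : float
        The initial-state jitter is a Gaussian mixture: with probability
        ``burst_prob`` a group's jitter is drawn ``burst_scale`` times wider
        (an occasional erratic inlet profile).
    noisy_image_prob, noisy_image_scale : float
        Per-image noise level is likewise heavy-tailed: with probability
        ``noisy_image_prob`` an image's pixel noise is ``noisy_image_scale``
        times ``noise_sd`` (an occasional poor acquisition).
    """

    seed: int
    image_height: int = 128
    image_width: int = 128
    latent_rank: int = _LATENT_RANK
    planted_dynamics: np.ndarray | None = None
    planted_control: np.ndarray | None = None
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"severity": 1.0, "flow": 1.0, "size": 1.0}
    )
    noise_sd: float = 0.02
    group_jitter_sd: float = 0.6
    burst_prob: float = 0.1
    burst_scale: float = 6.0
    noisy_image_prob: float = 0.12
    noisy_image_scale: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required: all generator runs must be reproducible")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image dimensions must be at least 8 pixels")
        if self.planted_dynamics is None:
            if self.latent_rank != _LATENT_RANK:
                raise ValueError(
                    "a custom planted_dynamics is required when latent_rank != "
                    f"{_LATENT_RANK}"
                )
            self.planted_dynamics = default_dynamics()
        self.planted_dynamics = np.asarray(self.planted_dynamics, dtype=float)
        if self.planted_dynamics.shape != (self.latent_rank, self.latent_rank):
            raise ValueError("planted_dynamics must be (latent_rank, latent_rank)")
        radius = np.abs(np.linalg.eigvals(self.planted_dynamics)).max()
        if radius > 1.0 + 1e-9:
            raise ValueError(f"planted_dynamics spectral radius {radius:.4f} exceeds 1")
        if self.planted_control is None:
            self.planted_control = (
                default_control() if self.latent_rank == _LATENT_RANK
                else np.zeros((self.latent_rank, 3))
            )
        self.planted_control = np.asarray(self.planted_control, dtype=float)
        if self.planted_control.shape != (self.latent_rank, 3):
            raise ValueError("planted_control must be (latent_rank, 3)")
        for key in ("severity", "flow", "size"):
            if key not in self.effect_sizes:
                raise ValueError(f"effect_sizes must provide {key!r}")
            if not np.isfinite(self.effect_sizes[key]):
                raise ValueError(f"effect size {key!r} must be finite")
        if self.noise_sd < 0 or self.group_jitter_sd < 0:
            raise ValueError("noise_sd and group_jitter_sd must be nonnegative")
        if not 0.0 <= self.burst_prob <= 1.0 or self.burst_scale < 1.0:
            raise ValueError("burst_prob must be in [0, 1] and burst_scale >= 1")

    def scaled_control(self) -> np.ndarray:
        """Planted control with effect sizes applied to its (size, flow, severity) columns."""
        scale = np.array(
            [self.effect_sizes["size"], self.effect_sizes["flow"], self.effect_sizes["severity"]]
        )
        return self.planted_control * scale[None, :]


@dataclass
class GroundTruth:
    """Planted quantities of one generator run, for verification of recovery.

    ``effective_eigenvalues`` are the eigenvalues of the pixel-space operator
    the data actually follow: eig(planted_dynamics) plus the eigenvalue 1
    carried by the invariant mean pattern.
    """

    planted_eigenvalues: np.ndarray
    effective_eigenvalues: np.ndarray
    planted_dynamics: np.ndarray
    planted_control: np.ndarray  # effect-scaled C actually used
    latent_trajectories: np.ndarray  # (n_groups, 5, latent_rank)
    control_inputs: np.ndarray  # standardized, (3, 4 * n_groups)
    mean_pattern: np.ndarray  # (H, W), noiseless
    spatial_modes: np.ndarray  # (H * W, latent_rank), unit columns
    seed: int


# ----------------------------------------------------------------------------
# fixed spatial patterns (deterministic, resolution-parametric)
# ----------------------------------------------------------------------------

def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    return y, x


def _blob(y, x, cy, cx, sy, sx):
    return np.exp(-(((y - cy) ** 2) / (2 * sy**2) + ((x - cx) ** 2) / (2 * sx**2)))


def _gabor(y, x, cy, cx, sigma, freq, theta, phase):
    carrier = np.cos(2 * np.pi * freq * (x * np.cos(theta) + y * np.sin(theta)) + phase)
    return _blob(y, x, cy, cx, sigma, sigma) * carrier


def _streak(y, x, cy, cx, radius, width, arc):
    """Curved (circular-arc) aerosol streak centred at (cy, cx)."""
    r = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    ang = np.arctan2(y - cy, x - cx)
    return np.exp(-((r - radius) ** 2) / (2 * width**2)) * np.exp(
        -((ang - arc) ** 2) / (2 * 0.8**2)
    )


def background_pattern(h: int, w: int) -> np.ndarray:
    """The shared background: base intensity, 5 vortex-like blobs, 2 curved streaks."""
    y, x = _grid(h, w)
    img = 0.70 * np.ones((h, w))
    blobs = [
        (0.25, 0.30, 0.10, 0.12, 0.22),
        (0.70, 0.25, 0.12, 0.09, 0.18),
        (0.75, 0.75, 0.09, 0.11, 0.20),
        (0.45, 0.55, 0.16, 0.16, 0.16),  # central sprout
        (0.30, 0.72, 0.07, 0.08, 0.15),
    ]
    for cy, cx, sy, sx, amp in blobs:
        img += amp * _blob(y, x, cy, cx, sy, sx)
    img += 0.20 * _streak(y, x, 0.15, 0.5, 0.22, 0.035, 0.0)  # hairpin-like, top
    img += 0.18 * _streak(y, x, 0.6, 0.45, 0.30, 0.03, 2.2)
    return img


def spatial_modes(h: int, w: int, rank: int = _LATENT_RANK) -> np.ndarray:
    """Fixed unit-norm spatial mode patterns, deliberately non-orthogonal.

    Each latent coordinate owns a localized oscillatory or blob-like pattern;
    a shared broad component is mixed into every pattern so the modes overlap
    (mutual coherence well away from zero).  Orthogonal decompositions
    therefore cannot align single modes with single latent coordinates,
    whereas operator-eigenvector methods can.
    """
    y, x = _grid(h, w)
    common = _blob(y, x, 0.5, 0.5, 0.35, 0.35)
    common /= np.linalg.norm(common)
    base = [
        _gabor(y, x, 0.32, 0.68, 0.13, 5.0, 0.4, 0.0),
        _gabor(y, x, 0.32, 0.68, 0.13, 5.0, 0.4, np.pi / 2),
        _gabor(y, x, 0.62, 0.35, 0.15, 7.0, 1.2, 0.0),
        _gabor(y, x, 0.62, 0.35, 0.15, 7.0, 1.2, np.pi / 2),
        _gabor(y, x, 0.72, 0.70, 0.12, 9.0, 2.1, 0.0),
        _gabor(y, x, 0.72, 0.70, 0.12, 9.0, 2.1, np.pi / 2),
        _blob(y, x, 0.28, 0.30, 0.10, 0.16) - _blob(y, x, 0.55, 0.62, 0.14, 0.10),
        _streak(y, x, 0.48, 0.52, 0.26, 0.05, 1.0) - 0.6 * _blob(y, x, 0.2, 0.2, 0.12, 0.12),
    ]
    cols = []
    for p in base[:rank]:
        flat = p.reshape(-1)
        flat = flat / np.linalg.norm(flat)
        mixed = flat + 0.35 * common.reshape(-1)
        cols.append(mixed / np.linalg.norm(mixed))
    Phi = np.column_stack(cols)
    if np.linalg.matrix_rank(Phi) < rank:  # pragma: no cover - fixed patterns
        raise RuntimeError("spatial mode patterns are rank deficient at this resolution")
    return Phi


#: Baseline excitation amplitude per latent coordinate, scaled by the
#: associated factor's effect size (flow, severity, size for the three
#: rotation pairs).  Each rotation pair starts at its amplitude with a
#: uniformly random per-group phase (the replicate-to-replicate "stochastic
#: inlet profile"): the pairs power the three spectrum peaks while their
#: phases carry no disease-stage information, so the class signal flows
#: through the severity-driven coordinates only.  The decay coordinates
#: start from the group jitter alone; with all effect sizes, noise and
#: jitter at zero, every image equals the mean pattern exactly.
_BASE_EXCITATION = np.array([3.0, 0.0, 2.4, 0.0, 2.7, 0.0, 0.0, 0.0])
_ROTATION_PAIRS = ((0, 1), (2, 3), (4, 5))
_PAIR_FACTORS = ("flow", "severity", "size")

#: Loading of the (standardized) flow and size conditions on the initial state.
_FLOW_LOADING = np.array([0.9, 0.3, 0, 0, 0, 0, 0, 0])
_SIZE_LOADING = np.array([0, 0, 0, 0, 0.9, 0.3, 0, 0])


def _transition_metadata() -> pd.DataFrame:
    """Column metadata of X′ for the full factorial design, canonical order."""
    records = []
    for g, cond in enumerate(all_conditions()):
        for s in range(_N_STAGES - 1):
            records.append(
                {
                    "group": g,
                    "stage": s,
                    "class_label": STAGE_LABELS[s],
                    "flow_rate_L_min": cond.flow_rate,
                    "particle_size_um": cond.particle_size,
                    "replicate": cond.replicate,
                }
            )
    return pd.DataFrame.from_records(records)


def generate_dataset(config: GeneratorConfig) -> tuple[AerosolDataset, GroundTruth]:
    """Generate the factorial image database plus its planted ground truth.

    One image per (stage, flow, size, replicate) combination — 405 with the
    default design — in (flow, size, replicate, stage)-ascending manifest
    order, which matches the snapshot-matrix column order of
    :func:`aeromode.io.assemble_snapshots`.
    """
    h, w = config.image_height, config.image_width
    A = config.planted_dynamics
    C = config.scaled_control()
    rank = config.latent_rank

    conditions = all_conditions()
    n_groups = len(conditions)

    # Standardized controls for every transition, identical to what
    # build_control_matrix produces on the assembled snapshot metadata.
    controls: ControlMatrix = build_control_matrix(_transition_metadata(), standardize=True)
    Y = controls.values  # (3, 4 * n_groups), rows (size, flow, severity)

    mean_pattern = background_pattern(h, w)
    Phi = spatial_modes(h, w, rank)
    if rank == _LATENT_RANK:
        z_base = _BASE_EXCITATION.copy()
        flow_load = config.effect_sizes["flow"] * _FLOW_LOADING
        size_load = config.effect_sizes["size"] * _SIZE_LOADING
    else:
        z_base = np.zeros(rank)
        flow_load = np.zeros(rank)
        size_load = np.zeros(rank)

    seed_seq = np.random.SeedSequence(config.seed)
    group_seeds = seed_seq.spawn(n_groups)

    trajectories = np.empty((n_groups, _N_STAGES, rank))
    images = np.empty((n_groups * _N_STAGES, h, w))
    records = []
    mean_flat = mean_pattern.reshape(-1)
    for g, cond in enumerate(conditions):
        rng = np.random.default_rng(group_seeds[g])
        z = z_base.copy()
        if rank == _LATENT_RANK:
            for (a, bcoord), factor in zip(_ROTATION_PAIRS, _PAIR_FACTORS):
                phase = rng.uniform(0.0, 2.0 * np.pi)
                amp = z_base[a] * config.effect_sizes[factor]
                z[a], z[bcoord] = amp * np.cos(phase), amp * np.sin(phase)
        # Bursty inlet variability: most groups get Gaussian jitter, an
        # occasional group a much larger kick (heavy-tailed mixture).
        burst = config.burst_scale if rng.uniform() < config.burst_prob else 1.0
        jitter = rng.normal(0.0, burst * config.group_jitter_sd, size=rank)
        y_g = Y[:, 4 * g : 4 * (g + 1)]  # (3, 4)
        size_s, flow_s = y_g[0, 0], y_g[1, 0]  # constant within the group
        z = z + flow_s * flow_load + size_s * size_load + jitter
        trajectories[g, 0] = z
        for k in range(_N_STAGES - 1):
            z = A @ z + C @ y_g[:, k]
            trajectories[g, k + 1] = z
        if config.noise_sd > 0:
            # Per-image noise level is itself heavy-tailed: an occasional
            # acquisition is far noisier than the rest (bursty tracer counts).
            scales = np.where(
                rng.uniform(size=_N_STAGES) < config.noisy_image_prob,
                config.noisy_image_scale,
                1.0,
            )
            noise = rng.normal(0.0, config.noise_sd, size=(_N_STAGES, h, w))
            noise *= scales[:, None, None]
        else:
            noise = np.zeros((_N_STAGES, h, w))
        for k in range(_N_STAGES):
            flat = mean_flat + Phi @ trajectories[g, k]
            img = flat.reshape(h, w) + noise[k]
            images[g * _N_STAGES + k] = np.maximum(img, 0.0)
            records.append(
                {
                    "class_label": STAGE_LABELS[k],
                    "flow_rate_L_min": cond.flow_rate,
                    "particle_size_um": cond.particle_size,
                    "replicate": cond.replicate,
                    "seed": config.seed,
                }
            )

    manifest = pd.DataFrame.from_records(records)
    manifest.insert(
        0,
        "filename",
        [
            f"aerosol_q{r['flow_rate_L_min']:g}_"
            f"d{str(r['particle_size_um']).replace('.', 'p')}um_"
            f"rep{r['replicate']}_{r['class_label']}.png"
            for _, r in manifest.iterrows()
        ],
    )
    dataset = AerosolDataset(images=images, manifest=manifest)
    truth = GroundTruth(
        planted_eigenvalues=np.linalg.eigvals(A),
        effective_eigenvalues=np.concatenate([[1.0 + 0.0j], np.linalg.eigvals(A)]),
        planted_dynamics=A.copy(),
        planted_control=C,
        latent_trajectories=trajectories,
        control_inputs=Y,
        mean_pattern=mean_pattern,
        spatial_modes=Phi,
        seed=config.seed,
    )
    return dataset, truth


def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Serialize a :class:`GroundTruth` as a single ``.npz`` archive."""
    path = Path(path)
    np.savez_compressed(
        path,
        planted_eigenvalues=truth.planted_eigenvalues,
        effective_eigenvalues=truth.effective_eigenvalues,
        planted_dynamics=truth.planted_dynamics,
        planted_control=truth.planted_control,
        latent_trajectories=truth.latent_trajectories,
        control_inputs=truth.control_inputs,
        mean_pattern=truth.mean_pattern,
        spatial_modes=truth.spatial_modes,
        seed=np.array(truth.seed),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_ground_truth(path: str | Path) -> GroundTruth:
    with np.load(path) as z:
        return GroundTruth(
            planted_eigenvalues=z["planted_eigenvalues"],
            effective_eigenvalues=z["effective_eigenvalues"],
            planted_dynamics=z["planted_dynamics"],
            planted_control=z["planted_control"],
            latent_trajectories=z["latent_trajectories"],
            control_inputs=z["control_inputs"],
            mean_pattern=z["mean_pattern"],
            spatial_modes=z["spatial_modes"],
            seed=int(z["seed"]),
        )
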