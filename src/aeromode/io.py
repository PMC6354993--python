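"""Dataset containers, PNG/CSV persistence, and snapshot-matrix assembly.

Images are grayscale intensity grids; a dataset couples an image stack with a
tabular manifest assigning each image a disease stage (A0–A4) and a test
condition (flow rate, particle size, replicate).  The decompositions operate
on a *snapshot matrix*: every image flattened row-major to one column, columns
arranged in groups of five — one (flow, size, replicate) condition per group,
stages ordered A0→A4 within it — so that consecutive columns of a group form
the disease-progression trajectory the dynamic decompositions fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .airway import SEVERITY_BY_LABEL, STAGE_LABELS
from .design import TestCondition

__all__ = [
    "INTENSITY_SCALE",
    "MANIFEST_COLUMNS",
    "AerosolImage",
    "AerosolDataset",
    "SnapshotMatrix",
    "ControlMatrix",
    "read_dataset",
    "write_dataset",
    "assemble_snapshots",
    "mean_image",
    "center",
    "split_transitions",
    "build_control_matrix",
]

logger = logging.getLogger(__name__)

#: Full-scale intensity mapped to the maximum 16-bit PNG value on export.
#: Wide enough that heavy-tailed replicate bursts stay on scale even at low
#: resolutions (where unit-norm spatial modes concentrate on few pixels).
INTENSITY_SCALE = 8.0

MANIFEST_COLUMNS = (
    "filename",
    "class_label",
    "flow_rate_L_min",
    "particle_size_um",
    "replicate",
    "seed",
)

_GROUP_KEYS = ["flow_rate_L_min", "particle_size_um", "replicate"]


@dataclass(frozen=True)
class AerosolImage:
    """A single aerosol-deposition image with its condition and stage label."""

    pixels: np.ndarray
    condition: TestCondition
    class_label: str

    def __post_init__(self) -> None:
        if self.class_label not in STAGE_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel intensities must be finite")


@dataclass
class AerosolDataset:
    """An image stack ``(n_images, H, W)`` plus its manifest, in manifest order."""

    images: np.ndarray
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must have shape (n_images, H, W)")
        if len(self.images) != len(self.manifest):
            raise ValueError("manifest length does not match the image stack")
        unknown = set(self.manifest["class_label"]) - set(STAGE_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in manifest: {sorted(unknown)}")
        dup = self.manifest.duplicated(subset=["class_label", *_GROUP_KEYS])
        if dup.any():
            rows = self.manifest.loc[dup, ["class_label", *_GROUP_KEYS]]
            raise ValueError(f"duplicate (class, condition) keys in manifest:\n{rows}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def pixel_matrix(self) -> np.ndarray:
        """Images flattened row-major, one row per image, manifest order."""
        return self.images.reshape(len(self.images), -1)

    def __getitem__(self, i: int) -> AerosolImage:
        row = self.manifest.iloc[i]
        return AerosolImage(
            pixels=self.images[i],
            condition=TestCondition(
                flow_rate=float(row["flow_rate_L_min"]),
                particle_size=float(row["particle_size_um"]),
                replicate=int(row["replicate"]),
            ),
            class_label=str(row["class_label"]),
        )


@dataclass
class SnapshotMatrix:
    """Pixels × snapshots array with per-column metadata.

    ``columns`` carries, for each column: ``group`` (0-based group index),
    ``stage`` (0–4, the A0→A4 position within the group), ``class_label`` and
    the condition fields.  Columns of one group are contiguous and
    stage-ordered.
    """

    values: np.ndarray
    columns: pd.DataFrame
    image_shape: tuple[int, int]
    ordering: str = "by-condition-then-stage"

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_pixels, n_snapshots)")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match the value matrix")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return int(self.columns["group"].nunique())

    def group_start_indices(self) -> np.ndarray:
        """Index of the first (stage-0) column of every group."""
        return np.flatnonzero(self.columns["stage"].to_numpy() == 0)


@dataclass
class ControlMatrix:
    """Exogenous control inputs aligned with the transition columns of X′.

    One column per transition; rows are (particle size, flow rate, severity of
    the target stage).  When standardized, each non-constant row has mean 0
    and unit (population) standard deviation; the parameters are retained so
    the same scaling can be reapplied.
    """

    values: np.ndarray
    row_names: tuple[str, ...] = ("particle_size_um", "flow_rate_L_min", "severity")
    row_means: np.ndarray = field(default_factory=lambda: np.zeros(3))
    row_sds: np.ndarray = field(default_factory=lambda: np.ones(3))
    standardized: bool = False

    @property
    def q(self) -> int:
        return self.values.shape[0]

    @property
    def n_transitions(self) -> int:
        return self.values.shape[1]


def _filename(row: pd.Series) -> str:
    size = f"{row['particle_size_um']:g}".replace(".", "p")
    return (
        f"aerosol_q{row['flow_rate_L_min']:g}_d{size}um_"
        f"rep{int(row['replicate'])}_{row['class_label']}.png"
    )


def write_dataset(dataset: AerosolDataset, directory: str | Path) -> Path:
    """Write a dataset as 16-bit grayscale PNGs plus a CSV manifest.

    Intensities are quantized onto the 16-bit grid with full scale
    ``INTENSITY_SCALE``; values outside [0, INTENSITY_SCALE] are clipped.
    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    if "filename" not in manifest.columns:
        manifest.insert(0, "filename", [_filename(r) for _, r in manifest.iterrows()])
    for img, name in zip(dataset.images, manifest["filename"]):
        scaled = np.clip(img / INTENSITY_SCALE, 0.0, 1.0)
        iio.imwrite(directory / name, np.round(scaled * 65535.0).astype(np.uint16))
    manifest_path = directory / "manifest.csv"
    manifest[list(MANIFEST_COLUMNS)].to_csv(manifest_path, index=False)
    return manifest_path


def read_dataset(directory: str | Path) -> AerosolDataset:
    """Read a PNG/CSV dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest found at {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    images = []
    for name in manifest["filename"]:
        path = directory / str(name)
        if not path.exists():
            raise FileNotFoundError(f"manifest references a missing image file: {path}")
        raw = np.asarray(iio.imread(path))
        images.append(raw.astype(np.float64) / 65535.0 * INTENSITY_SCALE)
    return AerosolDataset(images=np.stack(images), manifest=manifest)


def assemble_snapshots(dataset: AerosolDataset) -> SnapshotMatrix:
    """Arrange a dataset into the grouped, stage-ordered snapshot matrix.

    Groups are the (flow, size, replicate) triples in ascending order; within
    each group the five stages are stacked A0→A4.  Every group must be
    complete (exactly one image per stage); incomplete groups are rejected
    with the missing (class, condition) pairs listed.
    """
    manifest = dataset.manifest.reset_index(drop=True)
    stage_index = {label: i for i, label in enumerate(STAGE_LABELS)}
    order = manifest.assign(
        _stage=manifest["class_label"].map(stage_index), _row=np.arange(len(manifest))
    ).sort_values([*_GROUP_KEYS, "_stage"], kind="mergesort")

    missing: list[tuple[str, tuple]] = []
    for key, grp in order.groupby(_GROUP_KEYS, sort=True):
        present = set(grp["class_label"])
        for label in STAGE_LABELS:
            if label not in present:
                missing.append((label, key))
    if missing:
        raise ValueError(
            "incomplete disease-progression groups; missing (class, condition): "
            + ", ".join(f"({m[0]}, {m[1]})" for m in missing[:20])
        )

    rows = order["_row"].to_numpy()
    pixels = dataset.pixel_matrix()[rows].T  # (n_pixels, n_snapshots)
    n_groups = len(order) // len(STAGE_LABELS)
    columns = pd.DataFrame(
        {
            "group": np.repeat(np.arange(n_groups), len(STAGE_LABELS)),
            "stage": order["_stage"].to_numpy(),
            "class_label": order["class_label"].to_numpy(),
            "flow_rate_L_min": order["flow_rate_L_min"].to_numpy(dtype=float),
            "particle_size_um": order["particle_size_um"].to_numpy(dtype=float),
            "replicate": order["replicate"].to_numpy(dtype=int),
        }
    )
    return SnapshotMatrix(
        values=np.ascontiguousarray(pixels),
        columns=columns,
        image_shape=dataset.image_shape,
    )


def mean_image(X: SnapshotMatrix) -> np.ndarray:
    """Arithmetic mean across snapshot columns (the background pattern)."""
    if X.n_snapshots == 0:
        raise ValueError("cannot average an empty snapshot matrix")
    return X.values.mean(axis=1)


def center(X: SnapshotMatrix) -> SnapshotMatrix:
    """Subtract the mean image from every column (the PCA preprocessing)."""
    mu = mean_image(X)
    return replace(X, values=X.values - mu[:, None], ordering=X.ordering + "|centered")


def split_transitions(X: SnapshotMatrix) -> tuple[SnapshotMatrix, SnapshotMatrix]:
    """Split grouped snapshots into the transition pair (X′, X″).

    Per group, X′ takes stages 0–3 and X″ stages 1–4, so column k of X″ is
    the one-stage-later partner of column k of X′.  Both keep group-contiguous
    columns and have ``4 * n_groups`` columns.
    """
    stages = X.columns["stage"].to_numpy()
    groups = X.columns["group"].to_numpy()
    n_stages = len(STAGE_LABELS)
    for g in np.unique(groups):
        got = np.sort(stages[groups == g])
        if not np.array_equal(got, np.arange(n_stages)):
            raise ValueError(f"group {g} does not contain exactly stages 0..{n_stages - 1}")
    prime_idx = np.flatnonzero(stages < n_stages - 1)
    dprime_idx = np.flatnonzero(stages > 0)
    X_prime = SnapshotMatrix(
        values=X.values[:, prime_idx],
        columns=X.columns.iloc[prime_idx].reset_index(drop=True),
        image_shape=X.image_shape,
        ordering=X.ordering + "|stages0-3",
    )
    X_dprime = SnapshotMatrix(
        values=X.values[:, dprime_idx],
        columns=X.columns.iloc[dprime_idx].reset_index(drop=True),
        image_shape=X.image_shape,
        ordering=X.ordering + "|stages1-4",
    )
    return X_prime, X_dprime


def build_control_matrix(columns: pd.DataFrame, standardize: bool = True) -> ControlMatrix:
    """Control inputs (particle size, flow rate, target-stage severity) per transition.

    ``columns`` is the column metadata of X′; the control column for the
    transition starting at stage s carries the severity of stage s+1 (the
    input that produced the new state).  Standardization is per row with
    population statistics; a constant row is left at zero after centering.
    """
    required = {"stage", "class_label", *_GROUP_KEYS}
    if not required.issubset(columns.columns):
        raise ValueError(f"column metadata must contain {sorted(required)}")
    stages = columns["stage"].to_numpy()
    target_severity = np.array(
        [SEVERITY_BY_LABEL[STAGE_LABELS[s + 1]] for s in stages], dtype=float
    )
    raw = np.vstack(
        [
            columns["particle_size_um"].to_numpy(dtype=float),
            columns["flow_rate_L_min"].to_numpy(dtype=float),
            target_severity,
        ]
    )
    if not standardize:
        return ControlMatrix(values=raw)
    means = raw.mean(axis=1)
    sds = raw.std(axis=1)  # population sd, ddof=0
    values = raw - means[:, None]
    for i, sd in enumerate(sds):
        if sd > 0:
            values[i] /= sd
        else:
            logger.info("control row %d is constant; left at zero after centering", i)
            sds[i] = 1.0
    return ControlMatrix(
        values=values, row_means=means, row_sds=sds, standardized=True
    )
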