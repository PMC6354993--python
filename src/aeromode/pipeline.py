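"""Generate → assemble → decompose → classify → report as a reproducible run.

A run is a pure function of (config, master seed): every stage writes its
artifacts into the run directory, consumes only the previous stage's on-disk
artifacts, and can be deleted and re-run in isolation with identical results.

Run-directory layout::

    dataset/            PNG images + manifest.csv (generated runs)
    ground_truth.npz    planted quantities (generated runs)
    bases/<method>.npz  persisted ModeBasis per extraction method
    features/           per-method feature tables (CSV)
    cv/                 pooled confusion matrices (CSV)
    sweep.csv/.json     the (method, classifier, r) accuracy sweep
    figures/            singular values, eigenvalue planes, spectra, sweep
    run_manifest.json   config + seeds + package versions
    pipeline.log        timestamped log
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    CLASSIFIERS,
    DEFAULT_R_LIST,
    METHODS,
    CVConfig,
    one_way_anova,
    sweep_feature_tables,
)
from .decomposition import (
    build_feature_table,
    dmd,
    dmdc,
    load_basis,
    pca,
    pod,
    save_basis,
)
from .generate import GeneratorConfig, generate_dataset, save_ground_truth
from .io import (
    assemble_snapshots,
    build_control_matrix,
    read_dataset,
    split_transitions,
    write_dataset,
)

__all__ = ["PROFILES", "PipelineConfig", "run_pipeline",
           "stage_generate", "stage_decompose", "stage_classify", "stage_report"]

logger = logging.getLogger(__name__)

#: Desk-scale vs paper-scale evaluation settings.
PROFILES = {
    "quick": {"repeats": 20, "rf_trees": 200},
    "fidelity": {"repeats": 100, "rf_trees": 1000},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one YAML file)."""

    seed: int
    output_dir: str
    profile: str = "quick"
    generator: dict | None = None
    input_dir: str | None = None
    methods: tuple[str, ...] = METHODS
    r_list: tuple[int, ...] = DEFAULT_R_LIST
    classifiers: tuple[str, ...] = CLASSIFIERS
    cv: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of 'generator' and 'input_dir' must be configured"
            )
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")
        bad = set(m.upper() for m in self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        self.methods = tuple(m.upper() for m in self.methods)
        bad = set(c.upper() for c in self.classifiers) - set(CLASSIFIERS)
        if bad:
            raise ValueError(f"unknown classifiers: {sorted(bad)}")
        self.classifiers = tuple(c.upper() for c in self.classifiers)
        self.r_list = tuple(int(r) for r in self.r_list)
        if any(r < 1 for r in self.r_list):
            raise ValueError("r_list entries must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  output_dir: str | None = None, profile: str | None = None
                  ) -> "PipelineConfig":
        """Load and validate a YAML config; CLI options override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if seed is not None:
            raw["seed"] = seed
        if output_dir is not None:
            raw["output_dir"] = output_dir
        if profile is not None:
            raw["profile"] = profile
        if "seed" not in raw:
            raise ValueError("a master seed is required (config 'seed' or --seed)")
        if "output_dir" not in raw:
            raise ValueError("an output directory is required (config 'output_dir' or --out)")
        return cls(**raw)

    def cv_config(self) -> CVConfig:
        merged = {**PROFILES[self.profile], **self.cv, "seed": self.seed}
        return CVConfig(**merged)

    def run_dir(self) -> Path:
        return Path(self.output_dir)


def _setup_logging(config: PipelineConfig, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("aeromode")
    root.setLevel(config.log_level.upper())
    have = {getattr(h, "_aeromode_tag", None) for h in root.handlers}
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    if "console" not in have:
        h = logging.StreamHandler()
        h.setFormatter(fmt)
        h._aeromode_tag = "console"
        root.addHandler(h)
    logfile = str(run_dir / "pipeline.log")
    for h in list(root.handlers):
        if getattr(h, "_aeromode_tag", None) == "file" and h.baseFilename != logfile:
            root.removeHandler(h)
            h.close()
    if not any(getattr(h, "_aeromode_tag", None) == "file" for h in root.handlers):
        h = logging.FileHandler(logfile)
        h.setFormatter(fmt)
        h._aeromode_tag = "file"
        root.addHandler(h)


def _write_manifest(config: PipelineConfig, run_dir: Path) -> None:
    import sklearn

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "aeromode": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (run_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _dataset_dir(config: PipelineConfig, run_dir: Path) -> Path:
    return Path(config.input_dir) if config.input_dir else run_dir / "dataset"


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs the upstream artifact {path}; "
            "run the preceding stage first"
        )
    return path


def stage_generate(config: PipelineConfig, run_dir: Path | None = None) -> Path:
    """Generate the synthetic dataset and write images, manifest and ground truth."""
    run_dir = run_dir or config.run_dir()
    _setup_logging(config, run_dir)
    if config.generator is None:
        raise ValueError("this run uses an input directory; nothing to generate")
    gen_cfg = GeneratorConfig(seed=config.seed, **config.generator)
    dataset, truth = generate_dataset(gen_cfg)
    out = run_dir / "dataset"
    write_dataset(dataset, out)
    save_ground_truth(truth, run_dir / "ground_truth.npz")
    logger.info("generated %d images into %s", len(dataset), out)
    _write_manifest(config, run_dir)
    return out


def stage_decompose(config: PipelineConfig, run_dir: Path | None = None) -> Path:
    """Fit every configured extraction method and persist the mode bases."""
    run_dir = run_dir or config.run_dir()
    _setup_logging(config, run_dir)
    data_dir = _require(_dataset_dir(config, run_dir), "decompose")
    dataset = read_dataset(data_dir)
    snap = assemble_snapshots(dataset)
    r_max = max(config.r_list)
    bases_dir = run_dir / "bases"
    bases_dir.mkdir(parents=True, exist_ok=True)
    Xp, Xdp = split_transitions(snap)
    for method in config.methods:
        if method == "POD":
            basis = pod(snap, r_max)
        elif method == "PCA":
            basis = pca(snap, r_max)
        elif method == "DMD":
            basis = dmd(Xp, Xdp, r_max)
        else:
            Y = build_control_matrix(Xp.columns, standardize=True)
            basis, _ = dmdc(Xp, Xdp, Y, r=r_max)
        save_basis(basis, bases_dir / f"{method.lower()}.npz")
        logger.info("decomposed %s: rank %d of requested %d", method, basis.rank_used, r_max)
    return bases_dir


def stage_classify(config: PipelineConfig, run_dir: Path | None = None) -> Path:
    """Project images onto each persisted basis and run the CV sweep."""
    run_dir = run_dir or config.run_dir()
    _setup_logging(config, run_dir)
    dataset = read_dataset(_require(_dataset_dir(config, run_dir), "classify"))
    bases_dir = _require(run_dir / "bases", "classify")
    feat_dir = run_dir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for method in config.methods:
        basis = load_basis(_require(bases_dir / f"{method.lower()}.npz", "classify"))
        r = min(max(config.r_list), basis.rank_used)
        tables[method] = build_feature_table(basis, dataset, r)
        tables[method].to_frame().to_csv(feat_dir / f"{method.lower()}_r{r}.csv", index=False)
    cv_cfg = config.cv_config()
    sweep = sweep_feature_tables(tables, config.classifiers, config.r_list, cv_cfg)
    sweep.to_csv(run_dir / "sweep.csv", index=False)
    logger.info("classified %d sweep cells", len(sweep))
    return run_dir / "sweep.csv"


def stage_report(config: PipelineConfig, run_dir: Path | None = None) -> Path:
    """Aggregate the sweep into JSON + figures and an ANOVA of method variability."""
    from . import plotting

    run_dir = run_dir or config.run_dir()
    _setup_logging(config, run_dir)
    sweep = pd.read_csv(_require(run_dir / "sweep.csv", "report"))
    bases_dir = _require(run_dir / "bases", "report")
    fig_dir = run_dir / "figures"
    outputs = [plotting.plot_sweep(sweep, fig_dir / "sweep.png")]
    for method in config.methods:
        basis = load_basis(bases_dir / f"{method.lower()}.npz")
        outputs.append(
            plotting.plot_singular_values(basis, fig_dir / f"{method.lower()}_sigma.png")
        )
        if basis.eigenvalues is not None:
            outputs.append(
                plotting.plot_eigenvalues(basis, fig_dir / f"{method.lower()}_lambda.png")
            )
            outputs.append(
                plotting.plot_continuous_eigenvalues(
                    basis, fig_dir / f"{method.lower()}_omega.png"
                )
            )
            outputs.append(
                plotting.plot_spectrum(basis, fig_dir / f"{method.lower()}_spectrum.png")
            )
    r_top = max(sweep["r"])
    top = sweep[sweep["r"] == r_top]
    summary: dict = {
        "best_cell": sweep.loc[sweep["mean_acc"].idxmax()].to_dict(),
        "mean_acc_at_r_max": {
            f"{row.method}-{row.classifier}": row.mean_acc for row in top.itertuples()
        },
    }
    # variability of per-cell mean accuracy across methods, per classifier
    for clf in config.classifiers:
        groups = [
            grp["mean_acc"].to_numpy()
            for _, grp in sweep[sweep["classifier"] == clf].groupby("method")
        ]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            F, p = one_way_anova(*groups)
            summary[f"anova_{clf.lower()}"] = {"F": F, "p": p}
    (run_dir / "sweep.json").write_text(json.dumps(summary, indent=2, default=str))
    logger.info("report artifacts: %s", ", ".join(str(p) for p in outputs))
    return run_dir / "sweep.json"


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages end-to-end; returns the run directory."""
    run_dir = config.run_dir()
    _setup_logging(config, run_dir)
    _write_manifest(config, run_dir)
    if config.generator is not None:
        stage_generate(config, run_dir)
    stage_decompose(config, run_dir)
    stage_classify(config, run_dir)
    stage_report(config, run_dir)
    return run_dir
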