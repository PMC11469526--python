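"""Experiment runner, dataset I/O and the command-line interface.

Every experiment is described by a small serializable config; re-running a
saved config with the same seed regenerates byte-identical metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import click

from . import evaluation, model as model_mod, synthetic_data
from .signal_pipeline import SignalPipeline, SignalPipelineConfig

__all__ = ["ExperimentConfig", "run_experiment", "load_image_dataset", "cli"]

log = logging.getLogger("eswcnn")

_COMMANDS = ("simulate", "train", "crossval", "evaluate", "signal-pipeline")


@dataclass
class ExperimentConfig:
    command: str
    dataset: str = "texture3"  # benchmark name or a dataset directory
    out_dir: str = "results"
    seed: int = 0
    n_folds: int = 5
    gamma: float = 0.5
    epochs: int = 6
    n_per_class: int = 400
    checkpoint: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(f"command must be one of {_COMMANDS}, got {self.command!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**json.loads(Path(path).read_text()))


def load_image_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a directory-per-class image folder or a CSV manifest.

    Images are decoded with Pillow, converted to RGB, bilinearly resized to
    28x28 and scaled to [0, 1]; samples are ordered by sorted path so
    reloading is deterministic.  Corrupt files are skipped with a log entry.
    """
    from PIL import Image
    import pandas as pd

    path = Path(path)
    entries: list[tuple[Path, str]] = []
    manifest = path / "manifest.csv" if path.is_dir() else path
    if manifest.suffix == ".csv" and manifest.exists():
        df = pd.read_csv(manifest)
        root = manifest.parent
        entries = [(root / p, str(lab)) for p, lab in zip(df["path"], df["label"])]
    else:
        for cls_dir in sorted(p for p in path.iterdir() if p.is_dir()):
            files = sorted(
                f for f in cls_dir.iterdir() if f.suffix.lower() in (".png", ".jpg", ".jpeg")
            )
            if not files:
                raise ValueError(f"empty class directory: {cls_dir}")
            entries.extend((f, cls_dir.name) for f in files)
    if not entries:
        raise ValueError(f"no images found under {path}")
    entries.sort(key=lambda e: str(e[0]))
    class_names = sorted({lab for _, lab in entries})
    index = {c: i for i, c in enumerate(class_names)}
    images, labels = [], []
    skipped = 0
    for file, lab in entries:
        try:
            with Image.open(file) as im:
                arr = np.asarray(
                    im.convert("RGB").resize((28, 28), Image.BILINEAR), dtype=float
                )
        except Exception:  # noqa: BLE001 - corrupt image: skip with log
            log.warning("skipping unreadable image %s", file)
            skipped += 1
            continue
        images.append(arr.transpose(2, 0, 1) / 255.0)
        labels.append(index[lab])
    if skipped:
        log.warning("skipped %d unreadable images", skipped)
    return np.stack(images), np.asarray(labels), class_names


def _load_dataset(cfg: ExperimentConfig):
    benches = {"texture3", "texture2", "signal2"}
    if cfg.dataset in benches:
        data = synthetic_data.default_benchmarks(seed=2024 + cfg.seed)[cfg.dataset]
        return data
    return load_image_dataset(cfg.dataset)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment and write its result bundle to disk.

    The bundle contains ``metrics.json``, ``confusion.csv`` (when labels are
    predicted), ``fold_table.txt`` for cross-validation, a model checkpoint
    for training commands, and ``run.log`` recording the seed, gamma and
    parameter count.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    result: dict = {"config": asdict(config)}

    if config.command == "simulate":
        images, labels, names = _load_dataset(config)
        if config.dataset.startswith("signal"):
            import pandas as pd

            df = pd.DataFrame(images)
            df.insert(0, "label", [names[int(l)] for l in labels])
            df.to_csv(out / "signals.csv", index=False)
        else:
            synthetic_data.write_image_dataset(images, labels, names, out / "images")
        result["n_samples"] = int(labels.size)

    elif config.command in ("train", "evaluate"):
        images, labels, names = _load_dataset(config)
        mcfg = model_mod.ESWCNNConfig(
            n_classes=len(names), gamma=config.gamma, seed=config.seed, epochs=config.epochs
        )
        if config.command == "train" or config.checkpoint is None:
            net = model_mod.build_eswcnn(mcfg)
            history = model_mod.train(net, images, labels)
            model_mod.save_checkpoint(net, out / "checkpoint.npz")
            result["history"] = history
        else:
            net = model_mod.load_checkpoint(config.checkpoint)
        pred, _ = model_mod.predict(net, images)
        cm = evaluation.confusion_matrix(labels, pred, list(range(len(names))))
        cm.to_csv(out / "confusion.csv")
        report = evaluation.compute_metrics(cm)
        result["metrics"] = report.to_dict()
        result["n_params"] = net.n_params()

    elif config.command == "crossval":
        images, labels, names = _load_dataset(config)
        plan = evaluation.nfold_split(labels, config.n_folds, seed=config.seed)

        def builder(fold_seed: int):
            return model_mod.build_eswcnn(
                model_mod.ESWCNNConfig(
                    n_classes=len(names),
                    gamma=config.gamma,
                    seed=fold_seed,
                    epochs=config.epochs,
                )
            )

        cv = evaluation.cross_validate(
            builder,
            lambda m, x, y: model_mod.train(m, x, y),
            lambda m, x: model_mod.predict(m, x)[0],
            images,
            labels,
            plan,
            classes=list(range(len(names))),
        )
        (out / "fold_table.txt").write_text(evaluation.format_fold_table(cv))
        cv.pop("fold_reports")
        result["crossval"] = cv

    elif config.command == "signal-pipeline":
        signals, labels, names = _load_dataset(config)
        rng = np.random.default_rng(config.seed)
        idx = rng.permutation(labels.size)
        n_train = int(0.8 * labels.size)
        tr, te = idx[:n_train], idx[n_train:]
        pipe = SignalPipeline(SignalPipelineConfig(seed=config.seed))
        pipe.fit(signals[tr], labels[tr])
        pred = pipe.predict(signals[te])
        cm = evaluation.confusion_matrix(labels[te], pred, sorted(set(labels.tolist())))
        cm.to_csv(out / "confusion.csv")
        result["metrics"] = evaluation.compute_metrics(cm).to_dict()
        result["selected_features"] = pipe.screened_features

    (out / "metrics.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    (out / "run.log").write_text(
        f"command={config.command} seed={config.seed} gamma={config.gamma} "
        f"n_params={result.get('n_params', 'n/a')}\n"
    )
    (out / "config.json").write_text(config.to_json())
    return result


@click.group()
def cli() -> None:
    """Hybrid scattering-wavelet CNN experiments."""


def _common(f):
    f = click.option("--config", "config_path", type=click.Path(exists=True), default=None)(f)
    f = click.option("--dataset", default="texture3", show_default=True)(f)
    f = click.option("--seed", default=0, show_default=True)(f)
    f = click.option("--out", "out_dir", default="results", show_default=True)(f)
    return f


def _run(command: str, config_path, dataset, seed, out_dir, **kw) -> None:
    if config_path:
        cfg = ExperimentConfig.from_file(config_path)
    else:
        cfg = ExperimentConfig(command=command, dataset=dataset, seed=seed, out_dir=out_dir, **kw)
    run_experiment(cfg)
    click.echo(f"wrote results to {cfg.out_dir}")


@cli.command()
@_common
def simulate(config_path, dataset, seed, out_dir):
    """Generate a synthetic benchmark dataset on disk."""
    _run("simulate", config_path, dataset, seed, out_dir)


@cli.command()
@_common
@click.option("--gamma", default=0.5, show_default=True)
def train(config_path, dataset, seed, out_dir, gamma):
    """Train the reference model on a benchmark or image folder."""
    _run("train", config_path, dataset, seed, out_dir, gamma=gamma)


@cli.command()
@_common
@click.option("--n-folds", default=5, show_default=True)
def crossval(config_path, dataset, seed, out_dir, n_folds):
    """n-fold cross-validation with per-fold metrics."""
    _run("crossval", config_path, dataset, seed, out_dir, n_folds=n_folds)


@cli.command()
@_common
@click.option("--checkpoint", type=click.Path(exists=True), required=True)
def evaluate(config_path, dataset, seed, out_dir, checkpoint):
    """Evaluate a saved checkpoint on a dataset."""
    _run("evaluate", config_path, dataset, seed, out_dir, checkpoint=checkpoint)


@cli.command(name="signal-pipeline")
@_common
def signal_pipeline(config_path, dataset, seed, out_dir):
    """Run the wavelet-feature LSTM pipeline on a signal benchmark."""
    _run("signal-pipeline", config_path, dataset, seed, out_dir)
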