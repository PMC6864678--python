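"""End-to-end model comparison: nine PCA+kNN configurations versus the CNN.

`run_full_comparison` simulates a dataset, preprocesses it, makes one
stratified 50/50 split shared by every model, evaluates the seven per-LED
baselines, the two fused baselines and the CNN on that split, and repeats
the whole experiment over several seeds.  The headline claim it probes is
qualitative: on overlapping classes the CNN should beat every PCA+kNN
variant, while naive concatenation of the seven channels should buy the
baselines essentially nothing over their best single channel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .baselines import (
    CONCAT_SPECTRA_PC_NUMBER,
    PER_LED_PC_NUMBERS,
    BaselineResult,
    KNNConfig,
    run_concatenated_pcs,
    run_concatenated_spectra,
    run_per_led,
)
from .cnn import CNNSpec, TrainingTrace, build_model, train
from .errors import ParameterError
from .preprocess import preprocess_measurement, split_dataset
from .synthetic import CLASS_LABELS, generate_dataset

__all__ = [
    "accuracy",
    "confusion_matrix",
    "ComparisonConfig",
    "EvaluationReport",
    "run_single_comparison",
    "run_full_comparison",
]


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of exact label matches."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ParameterError(
            f"label vectors differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    if not true_labels:
        raise ParameterError("empty label vectors")
    return float(np.mean([t == p for t, p in zip(true_labels, predicted_labels)]))


def confusion_matrix(true_labels, predicted_labels, labels=CLASS_LABELS) -> np.ndarray:
    """Counts matrix: entry (i, j) = items of class labels[i] predicted labels[j]."""
    known = set(labels)
    for l in list(true_labels) + list(predicted_labels):
        if l not in known:
            raise ParameterError(f"unknown label {l!r}")
    return _sk_confusion(list(true_labels), list(predicted_labels), labels=list(labels))


@dataclass
class ComparisonConfig:
    """Study conditions of one full comparison run."""

    n_per_class: int = 60
    overlap: float = 1.0
    split_fraction: float = 0.5
    seeds: tuple[int, ...] = (0, 1, 2)
    sg_window: int = 11
    sg_polyorder: int = 2
    knn: KNNConfig = field(default_factory=KNNConfig)
    per_led_pc_numbers: tuple[int, ...] = PER_LED_PC_NUMBERS
    concat_pc_number: int = CONCAT_SPECTRA_PC_NUMBER
    cnn_epochs: int = 200
    cnn_hidden: tuple[int, ...] = (128,)
    cnn_batch_size: int = 18
    cnn_learning_rate: float = 0.1


@dataclass
class EvaluationReport:
    """Accuracies, confusion matrices and traces of every model, per seed and averaged."""

    config: dict
    per_seed: list[dict]
    mean_accuracies: dict[str, float]
    class_labels: tuple[str, ...] = CLASS_LABELS

    # -- derived ------------------------------------------------------------

    @property
    def best_baseline_mean(self) -> float:
        return max(v for k, v in self.mean_accuracies.items() if k != "cnn")

    @property
    def best_single_led_mean(self) -> float:
        return max(v for k, v in self.mean_accuracies.items() if k.startswith("per-LED"))

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self._as_dict(), indent=2, sort_keys=True))

    def _as_dict(self) -> dict:
        return {
            "config": self.config,
            "per_seed": self.per_seed,
            "mean_accuracies": self.mean_accuracies,
            "class_labels": list(self.class_labels),
        }

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        return cls(
            config=d["config"],
            per_seed=d["per_seed"],
            mean_accuracies=d["mean_accuracies"],
            class_labels=tuple(d["class_labels"]),
        )

    def table_mirror(self) -> pd.DataFrame:
        """One-row accuracy table over the nine baseline configurations plus the CNN."""
        cols = [f"per-LED {i}" for i in range(1, 8)] + [
            "concatenated-spectra",
            "concatenated-PCs",
            "cnn",
        ]
        return pd.DataFrame([{c: self.mean_accuracies[c] for c in cols}])


def _baseline_entry(result: BaselineResult) -> dict:
    return {
        "accuracy": result.accuracy,
        "pc_numbers": list(result.pc_numbers),
        "confusion": confusion_matrix(result.true_labels, result.predictions).tolist(),
    }


def run_single_comparison(cfg: ComparisonConfig, seed: int) -> dict:
    """Generate, preprocess, split once, and evaluate all ten models on that split."""
    raws = generate_dataset(cfg.n_per_class, seed=seed, overlap=cfg.overlap)
    mats = [
        preprocess_measurement(r, cfg.sg_window, cfg.sg_polyorder, measurement_id=str(i))
        for i, r in enumerate(raws)
    ]
    train_set, test_set = split_dataset(mats, fraction=cfg.split_fraction, seed=seed)

    results: dict[str, dict] = {}
    for led in range(1, 8):
        res = run_per_led(train_set, test_set, led, cfg.per_led_pc_numbers[led - 1], cfg.knn)
        results[f"per-LED {led}"] = _baseline_entry(res)
    results["concatenated-spectra"] = _baseline_entry(
        run_concatenated_spectra(train_set, test_set, cfg.concat_pc_number, cfg.knn)
    )
    results["concatenated-PCs"] = _baseline_entry(
        run_concatenated_pcs(train_set, test_set, cfg.per_led_pc_numbers, cfg.knn)
    )

    spec = CNNSpec(
        hidden_fc_sizes=cfg.cnn_hidden,
        epochs=cfg.cnn_epochs,
        batch_size=cfg.cnn_batch_size,
        learning_rate=cfg.cnn_learning_rate,
        seed=seed,
    )
    model = build_model(spec)
    trace = train(model, train_set, test_set, spec)
    predictions, _ = model.predict(test_set)
    true_labels = [m.label for m in test_set]
    results["cnn"] = {
        "accuracy": accuracy(true_labels, predictions),
        "confusion": confusion_matrix(true_labels, predictions).tolist(),
        "trace": {
            "train_accuracy": trace.train_accuracy,
            "test_accuracy": trace.test_accuracy,
            "loss": trace.loss,
        },
    }
    return {"seed": seed, "results": results}


def export_score_plots(cfg: ComparisonConfig, seed: int, out_dir) -> list[Path]:
    """Write PC1xPC2 score CSVs (per LED and concatenated spectra) for one seed.

    PCA is fitted on the training half of the same split the classifiers
    used; the CSVs hold the projected test scores with their true labels.
    """
    from .baselines import fit_pca, flatten_features, led_features

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raws = generate_dataset(cfg.n_per_class, seed=seed, overlap=cfg.overlap)
    mats = [preprocess_measurement(r, cfg.sg_window, cfg.sg_polyorder) for r in raws]
    train_set, test_set = split_dataset(mats, fraction=cfg.split_fraction, seed=seed)
    labels = [m.label for m in test_set]
    written = []
    feature_sets = {f"led{i}": (lambda i=i: (led_features(train_set, i), led_features(test_set, i)))
                    for i in range(1, 8)}
    feature_sets["concat"] = lambda: (flatten_features(train_set), flatten_features(test_set))
    for name, get in feature_sets.items():
        Xtr, Xte = get()
        scores = fit_pca(Xtr, 2).transform(Xte)
        path = out_dir / f"scores_{name}.csv"
        pd.DataFrame({"PC1": scores[:, 0], "PC2": scores[:, 1], "label": labels}).to_csv(
            path, index=False
        )
        written.append(path)
    return written


def run_full_comparison(cfg: ComparisonConfig | None = None) -> EvaluationReport:
    """Repeat the comparison over the configured seeds and average the accuracies."""
    cfg = cfg or ComparisonConfig()
    per_seed = [run_single_comparison(cfg, s) for s in cfg.seeds]
    names = list(per_seed[0]["results"].keys())
    mean_acc = {
        name: float(np.mean([ps["results"][name]["accuracy"] for ps in per_seed]))
        for name in names
    }
    cfg_dict = asdict(cfg)
    cfg_dict["knn"] = asdict(cfg.knn)
    return EvaluationReport(config=cfg_dict, per_seed=per_seed, mean_accuracies=mean_acc)
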