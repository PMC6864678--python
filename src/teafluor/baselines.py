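"""PCA + k-nearest-neighbor baselines.

Three training-data configurations are supported, mirroring standard
chemometric practice on multi-channel fluorescence data:

* *per-LED*: PCA on the 837-point spectrum of a single excitation LED;
* *concatenated spectra* ("1~7"): the seven rows flattened into one
  5859-feature vector before a single PCA;
* *concatenated PCs* ("1+...+7"): a separate PCA per LED, whose score
  vectors are concatenated (default 11+6+3+3+3+4+11 = 41 features).

PCA is mean-centred only (no variance scaling: all channels share units);
classification is a majority vote among the k nearest training scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as _SkPCA

from .errors import ParameterError
from .preprocess import ProcessedMatrix

__all__ = [
    "PER_LED_PC_NUMBERS",
    "CONCAT_SPECTRA_PC_NUMBER",
    "PCAModel",
    "KNNConfig",
    "BaselineResult",
    "fit_pca",
    "knn_predict",
    "led_features",
    "flatten_features",
    "run_per_led",
    "run_concatenated_spectra",
    "run_concatenated_pcs",
]

# retained components per excitation LED (1..7), and for the flattened variant
PER_LED_PC_NUMBERS = (11, 6, 3, 3, 3, 4, 11)
CONCAT_SPECTRA_PC_NUMBER = 9


@dataclass(frozen=True)
class PCAModel:
    """Mean-centred principal-component decomposition."""

    mean_vector: np.ndarray  # (p,)
    loadings: np.ndarray  # (k, p), orthonormal rows
    explained_variance: np.ndarray  # (k,), non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_vector) @ self.loadings.T


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")


@dataclass
class BaselineResult:
    """Outcome of one PCA+kNN configuration."""

    mode: str
    pc_numbers: tuple[int, ...]
    accuracy: float
    predictions: list[str]
    true_labels: list[str]
    scores: np.ndarray = field(repr=False)  # (n_test, 2) PC1 x PC2 projection


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Principal components of mean-centred data, ordered by decreasing variance.

    Sign convention: each loading vector is flipped, if necessary, so that its
    largest-magnitude element is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components={n_components} must be in [1, min(n_obs-1, n_features)={min(n - 1, p)}]"
        )
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(X)
    loadings = sk.components_.copy()
    for comp in loadings:
        if comp[np.argmax(np.abs(comp))] < 0:
            comp *= -1.0
    return PCAModel(
        mean_vector=sk.mean_,
        loadings=loadings,
        explained_variance=sk.explained_variance_,
    )


def knn_predict(
    train_scores: np.ndarray,
    train_labels: list[str],
    query_scores: np.ndarray,
    config: KNNConfig = KNNConfig(),
) -> list[str]:
    """Majority vote among the k nearest training points.

    Ties are broken by the smallest mean distance from the query to the tied
    class's voting neighbors, then by lexicographic label order.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, float))
    query_scores = np.atleast_2d(np.asarray(query_scores, float))
    if train_scores.shape[0] == 0:
        raise ParameterError("empty training set")
    if config.k > train_scores.shape[0]:
        raise ParameterError(f"k={config.k} exceeds training size {train_scores.shape[0]}")
    labels = np.asarray(train_labels)
    dist = cdist(query_scores, train_scores, metric=config.metric)
    predictions: list[str] = []
    for row in dist:
        nearest = np.argsort(row, kind="stable")[: config.k]
        votes: dict[str, list[float]] = {}
        for i in nearest:
            votes.setdefault(str(labels[i]), []).append(float(row[i]))
        best = max(
            votes.items(),
            key=lambda kv: (len(kv[1]), -float(np.mean(kv[1])), _lex_key(kv[0])),
        )
        predictions.append(best[0])
    return predictions


def _lex_key(label: str) -> tuple[int, ...]:
    # max() picks the largest key; invert character codes so that the
    # lexicographically smallest label wins among remaining ties
    return tuple(-ord(c) for c in label)


def led_features(matrices: list[ProcessedMatrix], led_index: int) -> np.ndarray:
    """Feature matrix holding the spectrum of one LED (1-based index) per row."""
    if not 1 <= led_index <= 7:
        raise ParameterError(f"led_index must be in 1..7, got {led_index}")
    return np.stack([m.values[led_index - 1] for m in matrices])


def flatten_features(matrices: list[ProcessedMatrix]) -> np.ndarray:
    """Row-major flattening of each 7 x 837 matrix (LED1 block first) -> 5859 features."""
    return np.stack([m.values.reshape(-1) for m in matrices])


def _labels(matrices: list[ProcessedMatrix]) -> list[str]:
    return [m.label for m in matrices]


def _evaluate(
    mode: str,
    pc_numbers: tuple[int, ...],
    train_scores: np.ndarray,
    train_labels: list[str],
    test_scores: np.ndarray,
    test_labels: list[str],
    knn: KNNConfig,
) -> BaselineResult:
    predictions = knn_predict(train_scores, train_labels, test_scores, knn)
    accuracy = float(np.mean([p == t for p, t in zip(predictions, test_labels)]))
    return BaselineResult(
        mode=mode,
        pc_numbers=pc_numbers,
        accuracy=accuracy,
        predictions=predictions,
        true_labels=list(test_labels),
        scores=test_scores[:, :2],
    )


def run_per_led(
    train: list[ProcessedMatrix],
    test: list[ProcessedMatrix],
    led_index: int,
    pc_number: int | None = None,
    knn: KNNConfig = KNNConfig(),
) -> BaselineResult:
    """PCA+kNN on the spectra of a single excitation LED."""
    if pc_number is None:
        pc_number = PER_LED_PC_NUMBERS[led_index - 1]
    Xtr = led_features(train, led_index)
    Xte = led_features(test, led_index)
    pca = fit_pca(Xtr, pc_number)
    return _evaluate(
        f"per-LED {led_index}", (pc_number,),
        pca.transform(Xtr), _labels(train), pca.transform(Xte), _labels(test), knn,
    )


def run_concatenated_spectra(
    train: list[ProcessedMatrix],
    test: list[ProcessedMatrix],
    pc_number: int = CONCAT_SPECTRA_PC_NUMBER,
    knn: KNNConfig = KNNConfig(),
) -> BaselineResult:
    """PCA+kNN on all seven spectra flattened into one vector ("1~7")."""
    Xtr = flatten_features(train)
    Xte = flatten_features(test)
    pca = fit_pca(Xtr, pc_number)
    return _evaluate(
        "concatenated-spectra", (pc_number,),
        pca.transform(Xtr), _labels(train), pca.transform(Xte), _labels(test), knn,
    )


def run_concatenated_pcs(
    train: list[ProcessedMatrix],
    test: list[ProcessedMatrix],
    per_led_pc_numbers: tuple[int, ...] = PER_LED_PC_NUMBERS,
    knn: KNNConfig = KNNConfig(),
) -> BaselineResult:
    """Per-LED PCAs whose score vectors are concatenated before kNN ("1+...+7")."""
    if len(per_led_pc_numbers) != 7:
        raise ParameterError("per_led_pc_numbers must hold 7 counts")
    tr_blocks, te_blocks = [], []
    for led in range(1, 8):
        pca = fit_pca(led_features(train, led), per_led_pc_numbers[led - 1])
        tr_blocks.append(pca.transform(led_features(train, led)))
        te_blocks.append(pca.transform(led_features(test, led)))
    return _evaluate(
        "concatenated-PCs", tuple(per_led_pc_numbers),
        np.hstack(tr_blocks), _labels(train), np.hstack(te_blocks), _labels(test), knn,
    )
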