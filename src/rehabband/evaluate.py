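"""Model-selection and evaluation machinery.

Three pieces: a (hidden_dim, code_dim) grid searched with stratified
10-fold cross-validation; a generalized k-fold linear-separability test
that trains a linear SVM on *one* subset pair and tests on everything
else; and confusion-matrix metrics with an explicit "not recognized"
column, macro-averaged precision/recall and an f1 computed as the harmonic
mean of the aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .autoencoder import AEConfig, train_autoencoder, _forward_mse
from .ensemble import ACTION_LABELS, predict, train_pairwise
from .errors import InputError


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    hidden_grid=(10, 20, 30, 40, 50, 60),
    code_grid=(5, 10, 15, 20, 25, 30, 35, 40),
    k: int = 10,
    seed: int = 0,
    epochs: int = 150,
    learning_rate: float = 1e-3,
    leakage_free: bool = False,
) -> pd.DataFrame:
    """Mean k-fold AE validation MSE and pipeline error rate per grid point.

    For each (hidden_dim, code_dim): (a) the autoencoder is trained on the
    k-1 training folds and scored by reconstruction MSE on the held-out
    fold; (b) the pipeline error rate trains the autoencoder once on *all*
    samples, encodes everything, and cross-validates only the SVM ensemble
    on the codes.  That single-encoder protocol leaks the held-out fold
    into the encoder; ``leakage_free=True`` instead re-trains the encoder
    inside every fold.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    if not hidden_grid or not code_grid:
        raise InputError("grids must be non-empty")
    counts = np.bincount(y)[1:]
    if np.any(counts < k):
        raise InputError(f"every class needs >= k={k} samples for {k}-fold CV")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for hd in hidden_grid:
        for cd in code_grid:
            ae_mses = []
            for f_idx, (tr, va) in enumerate(folds):
                cfg = _child_cfg(hd, cd, epochs, learning_rate, seed, f_idx)
                model = train_autoencoder(X[tr], cfg)
                ae_mses.append(_forward_mse(model.params, X[va]))

            errors = []
            if not leakage_free:
                full = train_autoencoder(X, _child_cfg(hd, cd, epochs, learning_rate, seed, 97))
                codes = full.encode(X)
            for f_idx, (tr, va) in enumerate(folds):
                if leakage_free:
                    enc = train_autoencoder(X[tr], _child_cfg(hd, cd, epochs, learning_rate, seed, 200 + f_idx))
                    tr_codes, va_codes = enc.encode(X[tr]), enc.encode(X[va])
                else:
                    tr_codes, va_codes = codes[tr], codes[va]
                ens = train_pairwise(tr_codes, y[tr])
                errors.append(float(np.mean(predict(ens, va_codes) != y[va])))

            rows.append(
                {
                    "hidden_dim": hd,
                    "code_dim": cd,
                    "ae_val_mse": float(np.mean(ae_mses)),
                    "pipeline_error_rate": float(np.mean(errors)),
                    "k": k,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def _child_cfg(hidden, code, epochs, lr, seed, salt) -> AEConfig:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # wide-bottleneck grid points warn by design
        return AEConfig(
            hidden_dim=int(hidden),
            code_dim=int(code),
            epochs=epochs,
            learning_rate=lr,
            seed=int((seed * 1009 + salt) % (2**31 - 1)),
        )


# ---------------------------------------------------------------------------
# generalized k-fold separability
# ---------------------------------------------------------------------------

@dataclass
class SeparabilityResult:
    """Per-fold misclassification rates for one class pair and their mean."""

    rates: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any((self.rates < 0) | (self.rates > 1)):
            raise InputError("rates must lie in [0, 1]")
        self.mean = float(self.rates.mean())


def generalized_kfold(A: np.ndarray, B: np.ndarray, k: int = 5, seed: int = 0,
                      C: float = 1.0) -> SeparabilityResult:
    """Linear-separability index for two code sets.

    A and B are each shuffled (seeded) and split into k subsets.  Fold i
    trains a linear SVM (C = 1) on the *pair* (A_i, B_i) alone and tests on
    all remaining samples; the k misclassification rates and their mean
    quantify how linearly separable the two classes are — near 0 for far
    apart sets, near 0.5 for indistinguishable ones.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) < k or len(B) < k:
        raise InputError(f"both classes need at least k={k} samples")
    rng = np.random.default_rng(seed)
    A = A[rng.permutation(len(A))]
    B = B[rng.permutation(len(B))]
    A_parts = np.array_split(A, k)
    B_parts = np.array_split(B, k)

    rates = []
    for i in range(k):
        X_tr = np.vstack([A_parts[i], B_parts[i]])
        y_tr = np.concatenate([np.ones(len(A_parts[i])), np.zeros(len(B_parts[i]))])
        rest_A = [A_parts[j] for j in range(k) if j != i]
        rest_B = [B_parts[j] for j in range(k) if j != i]
        if rest_A or rest_B:
            X_te = np.vstack([*rest_A, *rest_B])
            y_te = np.concatenate(
                [np.ones(sum(len(a) for a in rest_A)), np.zeros(sum(len(b) for b in rest_B))]
            )
        else:  # k equals both class sizes: test on the training pair itself
            X_te, y_te = X_tr, y_tr
        clf = SVC(kernel="linear", C=C)
        clf.fit(X_tr, y_tr)
        rates.append(float(np.mean(clf.predict(X_te) != y_te)))
    return SeparabilityResult(rates=np.asarray(rates))


def pairwise_separability(codes: np.ndarray, labels: np.ndarray, k: int = 5,
                          seed: int = 0) -> pd.DataFrame:
    """Run the generalized k-fold test for all six action pairs."""
    X = np.asarray(codes, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    rows = []
    from .ensemble import CLASS_PAIRS

    for i, j in CLASS_PAIRS:
        res = generalized_kfold(X[y == i], X[y == j], k=k, seed=seed)
        rows.append({"class_a": i, "class_b": j, "mean_rate": res.mean,
                     **{f"fold{f + 1}": r for f, r in enumerate(res.rates)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    """Per-class and macro precision/recall/f1 (percent) from a confusion table."""

    confusion: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    error_rate: float
    undefined_precision: list
    undefined_recall: list


def compute_metrics(confusion) -> Metrics:
    """Metrics from a 4x4 confusion matrix, optionally with a 5th column.

    Rows are true actions, the first four columns are predicted actions and
    the optional fifth column counts windows not recognized as any action
    (those enter FN but never FP).  Precision, recall and per-class f1 are
    percentages; the aggregate precision/recall are unweighted (macro)
    means over the four actions, and the aggregate f1 is the harmonic mean
    of the two aggregates.
    """
    M = np.asarray(confusion, dtype=float)
    if M.shape not in ((4, 4), (4, 5)):
        raise InputError(f"confusion matrix must be 4x4 or 4x5, got {M.shape}")
    if np.any(M < 0):
        raise InputError("confusion counts must be non-negative")

    tp = np.diag(M[:, :4]).astype(float)
    fp = M[:, :4].sum(axis=0) - tp
    fn = M.sum(axis=1) - tp  # misclassified-as-other plus not-recognized

    undefined_p, undefined_r = [], []
    precision = np.full(4, np.nan)
    recall = np.full(4, np.nan)
    for c in range(4):
        if tp[c] + fp[c] > 0:
            precision[c] = tp[c] / (tp[c] + fp[c]) * 100.0
        else:
            undefined_p.append(c + 1)
        if tp[c] + fn[c] > 0:
            recall[c] = tp[c] / (tp[c] + fn[c]) * 100.0
        else:
            undefined_r.append(c + 1)

    f1 = np.full(4, np.nan)
    ok = ~np.isnan(precision) & ~np.isnan(recall) & ((precision + recall) > 0)
    f1[ok] = 2 * precision[ok] * recall[ok] / (precision[ok] + recall[ok])

    macro_p, macro_r, macro_f1 = aggregate_scores(precision, recall)
    total = M.sum()
    acc = float(tp.sum() / total) if total > 0 else float("nan")
    return Metrics(
        confusion=M,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        accuracy=acc,
        error_rate=1.0 - acc if np.isfinite(acc) else float("nan"),
        undefined_precision=undefined_p,
        undefined_recall=undefined_r,
    )


def aggregate_scores(per_class_precision, per_class_recall) -> tuple[float, float, float]:
    """Macro precision/recall over the four actions plus their harmonic-mean f1.

    Inputs are percentages; any NaN entry (undefined class) propagates.
    """
    p = float(np.mean(np.asarray(per_class_precision, dtype=float)))
    r = float(np.mean(np.asarray(per_class_recall, dtype=float)))
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else float("nan")
    return p, r, f1


def confusion_from_predictions(true_labels, predicted_labels) -> np.ndarray:
    """4x5 confusion table; prediction None / 0 counts as "not recognized"."""
    M = np.zeros((4, 5), dtype=int)
    for t, p in zip(true_labels, predicted_labels, strict=True):
        t = int(t)
        if t not in ACTION_LABELS:
            raise InputError(f"true label {t} outside 1..4")
        col = 4 if p is None or int(p) == 0 else int(p) - 1
        M[t - 1, col] += 1
    return M
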