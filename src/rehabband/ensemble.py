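"""One-vs-one linear-SVM voting ensemble over autoencoder codes.

Four rehabilitation actions (1 stretching-and-making-a-fist,
2 separating-and-merging-fingers, 3 palm-flexion-and-dorsiflexion,
4 ulnar-deviation) are discriminated by six soft-margin linear SVMs
``S_ij``, one per unordered class pair, each trained only on samples of
its two classes with C = 1 and no kernel.  At prediction time every member
casts one vote by the sign of its decision value and the class with the
most votes wins.  Because a class that wins all three of its pairwise
contests reaches the maximum attainable tally of 3 while every other class
is capped at 2, pairwise dominance always implies victory.

Tie-breaking among equal tallies: the tied class with the greatest sum of
signed decision values over the members involving it wins; if that still
ties, the lowest class index does.  A decision value of exactly zero votes
for the lower class index of the pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import InputError, StateError
from . import detect as _detect
from . import signals as _signals

ACTION_LABELS = (1, 2, 3, 4)
ACTION_NAMES = {
    1: "stretching-and-making-a-fist",
    2: "separating-and-merging-fingers",
    3: "palm-flexion-and-dorsiflexion",
    4: "ulnar-deviation",
}
CLASS_PAIRS = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))


@dataclass
class PairwiseSVM:
    """One linear binary member ``S_ij``: decision w.x + b > 0 votes for the higher class."""

    pair: tuple[int, int]
    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.pair = (int(self.pair[0]), int(self.pair[1]))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)

    def decision(self, code: np.ndarray) -> float:
        return float(self.weights @ code + self.bias)

    def vote(self, code: np.ndarray) -> int:
        # exactly-zero decision goes to the lower class index (deterministic)
        return self.pair[1] if self.decision(code) > 0 else self.pair[0]


@dataclass
class VoteResult:
    """Per-class tallies from the six members plus the winning action label."""

    tallies: np.ndarray
    winner: int
    decisions: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tallies = np.asarray(self.tallies, dtype=int)


class SVMEnsemble:
    """The six pairwise members, trained or deserialized."""

    def __init__(self, members: list[PairwiseSVM]):
        pairs = tuple(m.pair for m in members)
        if pairs != CLASS_PAIRS:
            raise InputError(f"ensemble must hold members for pairs {CLASS_PAIRS} in order, got {pairs}")
        dims = {m.weights.size for m in members}
        if len(dims) != 1:
            raise InputError("all members must share one code dimension")
        self.members = list(members)

    @property
    def code_dim(self) -> int:
        return self.members[0].weights.size

    def to_dict(self) -> dict:
        return {
            "members": [
                {"pair": list(m.pair), "weights": m.weights.tolist(), "bias": m.bias}
                for m in self.members
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMEnsemble":
        return cls(
            [
                PairwiseSVM(pair=tuple(m["pair"]), weights=np.asarray(m["weights"]), bias=m["bias"])
                for m in d["members"]
            ]
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SVMEnsemble":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def train_pairwise(codes: np.ndarray, labels: np.ndarray, C: float = 1.0, tol: float = 1e-4) -> SVMEnsemble:
    """Train the six pairwise linear SVMs on encoded samples.

    Each member ``S_ij`` sees only the samples of classes i and j.  The
    stored orientation makes a positive decision value vote for class j
    (the higher index of the pair).
    """
    X = np.asarray(codes, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InputError("codes must be (n, d) with one label per row")
    present = set(np.unique(y))
    missing = [c for c in ACTION_LABELS if c not in present]
    if missing:
        raise InputError(f"every class needs at least one sample; missing {missing}")

    members = []
    for i, j in CLASS_PAIRS:
        mask = (y == i) | (y == j)
        clf = SVC(kernel="linear", C=C, tol=tol)
        clf.fit(X[mask], y[mask])
        # sklearn sorts classes ascending, so decision > 0 already means class j
        members.append(PairwiseSVM(pair=(i, j), weights=clf.coef_[0], bias=clf.intercept_[0]))
    return SVMEnsemble(members)


def vote(ens: SVMEnsemble, code: np.ndarray) -> VoteResult:
    """Tally the six members' votes for one code and resolve the winner."""
    c = np.asarray(code, dtype=float).ravel()
    if c.size != ens.code_dim:
        raise InputError(f"code length {c.size} does not match ensemble dimension {ens.code_dim}")
    tallies = np.zeros(4, dtype=int)
    decisions: dict[tuple[int, int], float] = {}
    for m in ens.members:
        d = m.decision(c)
        decisions[m.pair] = d
        tallies[m.vote(c) - 1] += 1

    best = int(tallies.max())
    tied = [cls for cls in ACTION_LABELS if tallies[cls - 1] == best]
    if len(tied) == 1:
        winner = tied[0]
    else:
        # signed evidence toward a class: +d when it is the pair's higher
        # index, -d when the lower; highest total wins, lowest index breaks
        # the residual tie
        def evidence(cls: int) -> float:
            s = 0.0
            for (i, j), d in decisions.items():
                if cls == j:
                    s += d
                elif cls == i:
                    s -= d
            return s

        winner = min(tied, key=lambda cls: (-evidence(cls), cls))
    return VoteResult(tallies=tallies, winner=winner, decisions=decisions)


def predict(ens: SVMEnsemble, codes: np.ndarray) -> np.ndarray:
    """Vectorized convenience: winning label for each row of ``codes``."""
    X = np.atleast_2d(np.asarray(codes, dtype=float))
    return np.array([vote(ens, row).winner for row in X], dtype=int)


def predict_window(ae_model, ens: SVMEnsemble, window: np.ndarray,
                   cfg: _detect.DetectionConfig | None = None) -> VoteResult | None:
    """Gate a normalized window, then classify it: None when the gate rejects.

    ``window`` is the 3x30 normalized sliding-window contents; the raw
    stream must already have been divided by the session reference.
    """
    if ae_model is None or ens is None:
        raise StateError("both the autoencoder and the ensemble must be fitted")
    cfg = cfg or _detect.DetectionConfig()
    if not _detect.is_action(window, cfg):
        return None
    x = _signals.flatten(np.asarray(window, dtype=float))
    code = ae_model.encode(x)
    return vote(ens, code)
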