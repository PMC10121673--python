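"""Zero-inflated exponential naive Bayes for durable-benefit prediction.

Signature attributions are semicontinuous: many patients have exactly
zero activity for a signature, the rest a positive right-skewed amount.
Each feature is therefore modelled, per class, as a point mass pi at zero
plus an exponential density with rate lambda on the positive part:

    p(x | c) = pi_c           if x = 0
             = (1 - pi_c) * lambda_c * exp(-lambda_c * x)   if x > 0

Features combine under the naive conditional-independence assumption;
posteriors are computed in log space. The decision threshold defaults to
0.438, the estimated population prevalence of durable benefit used as the
classification probability cutoff.

Zero-inflation masses are smoothed, pi_hat = (n_zero + 1) / (n + 2), so
no likelihood is ever exactly zero; the rate is the maximum-likelihood
estimate n_pos / sum(positive values), with a 1/max(observed) fallback
when a class has no positive value at all.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_formats import logger

DEFAULT_THRESHOLD = 0.438
CLASSES = ("yes", "no")  # durable benefit / no durable benefit


@dataclasses.dataclass
class ZienbModel:
    """Fitted zero-inflated exponential naive Bayes model."""

    feature_names: list[str]
    priors: dict[str, float]                 # class -> P(c)
    pi: dict[str, np.ndarray]                # class -> zero mass per feature
    rate: dict[str, np.ndarray]              # class -> exponential rate per feature
    threshold: float = DEFAULT_THRESHOLD
    priors_only: bool = False                # degenerate single-class fold

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        for c in self.priors:
            if ((self.pi[c] < 0) | (self.pi[c] > 1)).any():
                raise ValueError("pi outside [0, 1]")
            if (self.rate[c] <= 0).any():
                raise ValueError("rates must be > 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "priors": self.priors,
            "pi": {c: list(v) for c, v in self.pi.items()},
            "rate": {c: list(v) for c, v in self.rate.items()},
            "threshold": self.threshold,
            "priors_only": self.priors_only,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ZienbModel":
        d = json.loads(Path(path).read_text())
        return cls(feature_names=d["feature_names"], priors=d["priors"],
                   pi={c: np.asarray(v) for c, v in d["pi"].items()},
                   rate={c: np.asarray(v) for c, v in d["rate"].items()},
                   threshold=d["threshold"], priors_only=d.get("priors_only", False))


def _as_matrix(features) -> tuple[np.ndarray, list[str], list]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns), list(features.index)
    arr = np.atleast_2d(np.asarray(features, dtype=float))
    return arr, [f"f{j}" for j in range(arr.shape[1])], list(range(arr.shape[0]))


def fit(features, labels, threshold: float = DEFAULT_THRESHOLD) -> ZienbModel:
    """Fit the model; `labels` are 'yes'/'no' durable-benefit labels.

    Priors are the empirical class frequencies (the external prevalence
    enters only through the decision threshold).
    """
    X, names, _ = _as_matrix(features)
    y = np.asarray(labels)
    if (X < 0).any():
        raise ValueError("features must be non-negative")
    for c in CLASSES:
        if (y == c).sum() == 0:
            raise ValueError(f"class {c!r} absent from training data")
    col_max = X.max(axis=0)
    priors, pi, rate = {}, {}, {}
    for c in CLASSES:
        block = X[y == c]
        n = block.shape[0]
        n_zero = (block == 0).sum(axis=0)
        n_pos = n - n_zero
        pi[c] = (n_zero + 1.0) / (n + 2.0)
        pos_sum = np.where(block > 0, block, 0.0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(n_pos > 0, n_pos / np.where(pos_sum > 0, pos_sum, np.nan),
                           np.nan)
        fallback = np.where(col_max > 0, 1.0 / np.where(col_max > 0, col_max, 1.0), 1.0)
        rate[c] = np.where(np.isnan(lam), fallback, lam)
        priors[c] = n / len(y)
    return ZienbModel(feature_names=names, priors=priors, pi=pi, rate=rate,
                      threshold=threshold)


def _log_likelihood(model: ZienbModel, x: np.ndarray, c: str) -> float:
    pi, lam = model.pi[c], model.rate[c]
    zero = x == 0
    ll = np.where(zero, np.log(pi),
                  np.log1p(-pi) + np.log(lam) - lam * x)
    return float(ll.sum())


def posterior(model: ZienbModel, x) -> float:
    """P(durable benefit | x) under conditional independence, in log space."""
    x = np.asarray(x, dtype=float).ravel()
    if (x < 0).any():
        raise ValueError("features must be non-negative")
    if model.priors_only:
        return model.priors["yes"]
    log_joint = {c: np.log(model.priors[c]) + _log_likelihood(model, x, c)
                 for c in CLASSES}
    vals = np.array([log_joint["yes"], log_joint["no"]])
    return float(np.exp(vals[0] - logsumexp(vals)))


def predict(model: ZienbModel, x) -> str:
    """'yes' iff the benefit posterior reaches the threshold (inclusive)."""
    return "yes" if posterior(model, x) >= model.threshold else "no"


def loocv(features, labels, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Leave-one-out cross-validation over the labelled samples.

    Each labelled sample is scored by a model fitted on the other m-1;
    samples with an unknown label are scored by the full-data model (they
    enter only the survival analysis). A training fold that loses its
    last sample of one class falls back to a priors-only model (logged).

    Returns a frame with out-of-fold posterior, predicted label and fold id.
    """
    X, names, index = _as_matrix(features)
    y = np.asarray(labels)
    known = np.isin(y, CLASSES)
    if known.sum() < 3:
        raise ValueError("LOOCV requires at least 3 labelled samples")
    full_model = fit(X[known], y[known], threshold=threshold)

    rows = []
    fold = 0
    for i in range(len(y)):
        if not known[i]:
            post = posterior(full_model, X[i])
            rows.append((index[i], post, "yes" if post >= threshold else "no", -1))
            continue
        mask = known.copy()
        mask[i] = False
        try:
            model = fit(X[mask], y[mask], threshold=threshold)
        except ValueError:
            logger.warning("LOOCV fold %d has a single class; priors-only fallback", fold)
            counts = pd.Series(y[mask]).value_counts()
            pr = {c: counts.get(c, 0) / counts.sum() for c in CLASSES}
            model = ZienbModel(feature_names=names, priors=pr,
                               pi={c: np.full(X.shape[1], 0.5) for c in CLASSES},
                               rate={c: np.ones(X.shape[1]) for c in CLASSES},
                               threshold=threshold, priors_only=True)
        post = posterior(model, X[i])
        rows.append((index[i], post, "yes" if post >= threshold else "no", fold))
        fold += 1
    return pd.DataFrame(rows, columns=["sample_id", "posterior", "predicted", "fold"]
                        ).set_index("sample_id")
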