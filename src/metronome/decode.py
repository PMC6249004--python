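"""Logistic decoding of correct vs error trials from binned gamma amplitude.

Features are mean gamma amplitude in 10 equal bins per maintenance
interval (35 bins to a go-cue at the middle of the 4th interval); the
classifier is logistic regression with a small ridge penalty on the slopes
(not the intercept) for separation robustness.  Accuracy curves are
estimated on 100 random held-out sets of 50 correct + 50 error trials,
either cumulatively (bins 1..k) or with a 5-bin sliding window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .session import TrialRecord
from .spectral import GammaEnvelope, InputError


@dataclass
class FeatureMatrix:
    features: np.ndarray        # trials x bins, NaN where past the go-cue
    labels: np.ndarray          # 1 = correct, 0 = error
    trial_ids: np.ndarray
    bins_per_interval: int
    tempo_ms: float

    @property
    def n_bins(self) -> int:
        return self.features.shape[1]

    def bin_centers_s(self) -> np.ndarray:
        """Maintenance-elapsed time at each bin center (seconds)."""
        width = self.tempo_ms / self.bins_per_interval / 1000.0
        return (np.arange(self.n_bins) + 0.5) * width


@dataclass
class LogisticModel:
    coef: np.ndarray
    intercept: float
    bins: np.ndarray            # column indices of the fitted bins
    ridge: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.coef + self.intercept
        return (z > 0).astype(int)


def bin_gamma(envelopes: list[GammaEnvelope], trials: list[TrialRecord],
              bins_per_interval: int = 10) -> FeatureMatrix:
    """Mean gamma amplitude in equal-width bins of the maintenance epoch.

    All trials must share one tempo (bin separately per tempo otherwise).
    Each trial contributes bins up to its go-cue; later bins are NaN.
    """
    by_id = {tr.trial_id: tr for tr in trials}
    tempos = {by_id[e.trial_id].tempo_ms for e in envelopes}
    if len(tempos) != 1:
        raise InputError("trials mix tempos; bin each tempo separately")
    tempo = tempos.pop()
    width = tempo / bins_per_interval
    max_bins = 0
    rows, labels, ids = [], [], []
    for env in envelopes:
        tr = by_id[env.trial_id]
        if tr.correct is None:
            continue
        on = tr.maintenance_onset_ms
        n_avail = int(np.floor((tr.go_cue_ms - on) / width + 1e-9))
        max_bins = max(max_bins, n_avail)
        vals = np.full(n_avail, np.nan)
        for k in range(n_avail):
            sel = (env.time_ms >= on + k * width) \
                & (env.time_ms < on + (k + 1) * width)
            if sel.any():
                vals[k] = env.amplitude[sel].mean()
        rows.append(vals)
        labels.append(int(tr.correct))
        ids.append(tr.trial_id)
    if not rows:
        raise InputError("no labelled trials")
    feats = np.full((len(rows), max_bins), np.nan)
    for i, vals in enumerate(rows):
        feats[i, :vals.size] = vals
    return FeatureMatrix(features=feats, labels=np.array(labels),
                         trial_ids=np.array(ids),
                         bins_per_interval=bins_per_interval, tempo_ms=tempo)


def fit_logistic(features: np.ndarray, labels: np.ndarray,
                 ridge: float = 1e-4) -> LogisticModel:
    """Penalized ML logistic fit (quadratic penalty on slopes only)."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise InputError("both classes must be present")
    if np.any(~np.isfinite(features)):
        raise InputError("features contain missing values")
    clf = LogisticRegression(C=1.0 / (2.0 * ridge), solver="lbfgs",
                             max_iter=1000, tol=1e-6)
    clf.fit(features, labels)
    return LogisticModel(coef=clf.coef_.ravel(),
                         intercept=float(clf.intercept_[0]),
                         bins=np.arange(features.shape[1]), ridge=ridge)


def classifier_accuracy_curves(fm: FeatureMatrix,
                               scheme: str = "cumulative",
                               holdout_per_class: int = 50,
                               n_iter: int = 100, seed: int = 0,
                               sliding_bins: int = 5, ridge: float = 1e-4
                               ) -> dict:
    """Held-out accuracy as a function of time bin.

    Per iteration a random 50 + 50 held-out set is drawn (scaled down with
    a warning when a class is small); the classifier is refit on bins
    ``1..k`` (cumulative) or ``k..k+4`` (sliding) and scored on the
    held-out trials.  Trials that do not reach the analysed bins are
    excluded from that bin (attrition).  Returns per-bin mean accuracy and
    s.e. across iterations.
    """
    if scheme not in ("cumulative", "sliding"):
        raise InputError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n_bins = fm.n_bins
    ks = np.arange(n_bins) if scheme == "cumulative" \
        else np.arange(n_bins - sliding_bins + 1)
    acc = np.full((n_iter, ks.size), np.nan)
    for it in range(n_iter):
        for j, k in enumerate(ks):
            cols = np.arange(0, k + 1) if scheme == "cumulative" \
                else np.arange(k, k + sliding_bins)
            ok = ~np.isnan(fm.features[:, cols]).any(axis=1)
            X, y = fm.features[np.ix_(ok, cols)], fm.labels[ok]
            i_pos = np.flatnonzero(y == 1)
            i_neg = np.flatnonzero(y == 0)
            h = min(holdout_per_class, i_pos.size // 2, i_neg.size // 2)
            if h < holdout_per_class:
                warnings.warn("holdout scaled down to "
                              f"{h} per class", stacklevel=2)
            if h < 1:
                continue
            test = np.concatenate([rng.choice(i_pos, h, replace=False),
                                   rng.choice(i_neg, h, replace=False)])
            train = np.setdiff1d(np.arange(y.size), test)
            model = fit_logistic(X[train], y[train], ridge)
            acc[it, j] = (model.predict(X[test]) == y[test]).mean()
    mean = np.nanmean(acc, axis=0)
    se = np.nanstd(acc, axis=0, ddof=1) / np.sqrt(n_iter)
    centers = fm.bin_centers_s()
    t = centers[ks] if scheme == "cumulative" \
        else centers[ks + sliding_bins - 1]
    return {"scheme": scheme, "bin": ks + 1, "time_s": t,
            "accuracy": mean, "se": se, "n_iter": n_iter}
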