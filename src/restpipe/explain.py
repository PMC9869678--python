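"""Shapley-value attribution for fitted classifiers.

Coalition values are interventional: v(S) is the mean model output over
the background sample with the explained row's features substituted on S.
With up to ``max_exact`` features every coalition is enumerated and the
classical Shapley weights applied, which is exact and satisfies local
accuracy, dummy and symmetry by construction; larger models fall back to
seeded permutation sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd


@dataclass
class ShapSummary:
    """Per-sample signed contributions plus the ranking they induce."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float  # expected model output over the background
    model_output: np.ndarray  # (n_samples,) f(x) for each explained row
    feature_names: list[str]
    feature_values: np.ndarray = None  # (n_samples, n_features) explained rows

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def local_accuracy_error(self) -> np.ndarray:
        """|base + sum(contributions) - f(x)| per sample."""
        return np.abs(self.base_value + self.values.sum(axis=1) - self.model_output)


def _coalition_values(predict, background, X, n_features):
    """V[s, e] = mean_b f(x_e on S, b off S) for every coalition bitmask s."""
    B = background.shape[0]
    E = X.shape[0]
    V = np.empty((2**n_features, E))
    for s in range(2**n_features):
        on = [i for i in range(n_features) if s >> i & 1]
        rows = np.repeat(background[None, :, :], E, axis=0)  # (E, B, M)
        if on:
            rows[:, :, on] = X[:, None, on]
        out = predict(rows.reshape(E * B, n_features))
        V[s] = out.reshape(E, B).mean(axis=1)
    return V


def _exact_shapley(predict, background, X):
    M = X.shape[1]
    V = _coalition_values(predict, background, X, M)
    w = np.array(
        [factorial(s) * factorial(M - s - 1) / factorial(M) for s in range(M)]
    )
    phi = np.zeros((X.shape[0], M))
    for i in range(M):
        bit = 1 << i
        for s in range(2**M):
            if s & bit:
                continue
            size = bin(s).count("1")
            phi[:, i] += w[size] * (V[s | bit] - V[s])
    return phi, V[0], V[-1]


def _sampled_shapley(predict, background, X, n_permutations, rng):
    """Permutation-sampling estimator (used when enumeration is too big)."""
    E, M = X.shape
    B = background.shape[0]
    phi = np.zeros((E, M))
    base = predict(background).mean()
    full = predict(X)
    for _ in range(n_permutations):
        order = rng.permutation(M)
        rows = np.repeat(background[None, :, :], E, axis=0)
        prev = np.full(E, base)
        for i in order:
            rows[:, :, i] = X[:, None, i]
            cur = predict(rows.reshape(E * B, M)).reshape(E, B).mean(axis=1)
            phi[:, i] += cur - prev
            prev = cur
    return phi / n_permutations, base, full


def shap_contributions(
    model,
    background,
    explain_set,
    feature_names: list[str] | None = None,
    max_exact: int = 12,
    n_permutations: int = 256,
    seed: int = 0,
) -> ShapSummary:
    """Shapley contributions of each feature to the model's decision score.

    ``model`` needs a ``decision_function`` (fallback ``predict``);
    DataFrames are accepted and must share columns with the background.
    """
    if isinstance(background, pd.DataFrame) and isinstance(explain_set, pd.DataFrame):
        if list(background.columns) != list(explain_set.columns):
            raise ValueError(
                f"feature mismatch: background {list(background.columns)} vs "
                f"explain {list(explain_set.columns)}"
            )
        feature_names = feature_names or list(background.columns)
    bg = np.asarray(background, dtype=float)
    X = np.asarray(explain_set, dtype=float)
    if bg.size == 0:
        raise ValueError("background sample is empty")
    if bg.shape[1] != X.shape[1]:
        raise ValueError(
            f"feature mismatch: background has {bg.shape[1]} features, "
            f"explain set has {X.shape[1]}"
        )
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]

    predict = getattr(model, "decision_function", None) or model.predict
    if X.shape[1] <= max_exact:
        phi, base, full = _exact_shapley(predict, bg, X)
        # the empty-coalition value is the same for every explained row
        base = float(np.asarray(base).mean())
        full = np.asarray(full)
    else:
        rng = np.random.default_rng(seed)
        phi, base, full = _sampled_shapley(predict, bg, X, n_permutations, rng)
        base = float(base)
    return ShapSummary(
        values=phi,
        base_value=base,
        model_output=np.asarray(full),
        feature_names=names,
        feature_values=X,
    )


def top_features(summary: ShapSummary, k: int = 20) -> pd.DataFrame:
    """First k features by mean |contribution|, ties broken lexicographically.

    ``direction`` is the sign of the correlation between a feature's value
    deviation and its contribution (positive: high values push toward the
    patient class).
    """
    n = len(summary.feature_names)
    if k > n:
        warnings.warn(f"k={k} > {n} features; returning all", stacklevel=2)
        k = n
    mean_abs = summary.mean_abs
    order = sorted(range(n), key=lambda i: (-mean_abs[i], summary.feature_names[i]))
    rows = []
    for rank, i in enumerate(order[:k], start=1):
        contrib = summary.values[:, i]
        sign = np.nanmean(contrib)
        if summary.feature_values is not None and contrib.std() > 0:
            fv = summary.feature_values[:, i]
            if fv.std() > 0:
                sign = np.corrcoef(fv, contrib)[0, 1]
        direction = "patient_up" if sign >= 0 else "patient_down"
        rows.append(
            {
                "rank": rank,
                "feature": summary.feature_names[i],
                "mean_abs_contribution": float(mean_abs[i]),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows, columns=["rank", "feature", "mean_abs_contribution", "direction"])


def plot_summary(summary: ShapSummary, path, k: int = 20) -> None:
    """Bar + strip summary figure of the top-k features."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = top_features(summary, k)
    idx = [summary.feature_names.index(f) for f in top["feature"]]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 0.4 * len(idx) + 2), sharey=True)
    ypos = np.arange(len(idx))[::-1]
    ax1.barh(ypos, top["mean_abs_contribution"], color="steelblue")
    ax1.set_yticks(ypos, top["feature"])
    ax1.set_xlabel("mean |contribution|")
    for y, i in zip(ypos, idx):
        vals = summary.values[:, i]
        jitter = (np.arange(len(vals)) % 7 - 3) * 0.04
        ax2.plot(vals, y + jitter, ".", ms=4, alpha=0.6, color="crimson")
    ax2.axvline(0.0, color="gray", lw=0.8)
    ax2.set_xlabel("contribution per sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
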