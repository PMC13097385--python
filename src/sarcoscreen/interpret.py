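"""Shapley-value feature attribution by permutation sampling.

For a model f over feature vectors, the Shapley value of feature j at a
sample x is its average marginal contribution over feature orderings,
with absent features imputed from a background set.  The permutation-
sampling estimator draws random orderings (and one background row per
ordering) and averages f's change as each feature is switched from its
background value to the sample's value — an unbiased estimator of the
exact Shapley value that satisfies local accuracy in expectation:
attributions plus the baseline (mean background prediction) sum to the
model output for the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = [
    "AttributionSet",
    "shapley_attributions",
    "exact_shapley",
    "summary_ranking",
]


@dataclass
class AttributionSet:
    per_sample_shap: np.ndarray   # (samples, features), signed
    per_sample_se: np.ndarray     # Monte-Carlo standard errors, same shape
    baseline_value: float         # mean model output over the background
    feature_names: list[str]
    model_outputs: np.ndarray     # f(x) per sample


def shapley_attributions(
    model_fn,
    samples: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionSet:
    """Permutation-sampling Shapley attributions for each sample.

    Parameters
    ----------
    model_fn
        Maps an (n, d) feature matrix to n scalar scores.
    samples, background
        (n, d) rows to explain and (m, d) background rows used to impute
        absent features.
    n_permutations
        Random feature orderings per sample; the Monte-Carlo SE of each
        attribution is reported alongside the estimate.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n, d = samples.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(d)]

    rng = np.random.default_rng(seed)
    baseline = float(np.mean(model_fn(background)))
    outputs = np.asarray(model_fn(samples), dtype=float)

    shap = np.zeros((n, d))
    se = np.zeros((n, d))
    for i in range(n):
        x = samples[i]
        contribs = np.zeros((n_permutations, d))
        # evaluate all permutations in one batched model call per step
        orders = np.array([rng.permutation(d) for _ in range(n_permutations)])
        bg_rows = background[rng.integers(background.shape[0], size=n_permutations)]
        current = bg_rows.copy()
        prev_vals = np.asarray(model_fn(current), dtype=float)
        for step in range(d):
            feats = orders[:, step]
            current[np.arange(n_permutations), feats] = x[feats]
            new_vals = np.asarray(model_fn(current), dtype=float)
            contribs[np.arange(n_permutations), feats] = new_vals - prev_vals
            prev_vals = new_vals
        shap[i] = contribs.mean(axis=0)
        se[i] = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)

    return AttributionSet(
        per_sample_shap=shap,
        per_sample_se=se,
        baseline_value=baseline,
        feature_names=list(feature_names),
        model_outputs=outputs,
    )


def exact_shapley(model_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full d! enumeration (small d only).

    Marginalizes absent features over the *whole* background set, so it
    is the exact value the sampling estimator converges to.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if d > 8:
        raise ValueError("exact enumeration is limited to d <= 8")

    def value(subset: frozenset) -> float:
        rows = background.copy()
        for j in subset:
            rows[:, j] = x[j]
        return float(np.mean(model_fn(rows)))

    cache: dict[frozenset, float] = {}

    def cached_value(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = value(subset)
        return cache[subset]

    phi = np.zeros(d)
    perms = list(permutations(range(d)))
    for order in perms:
        present: frozenset = frozenset()
        prev = cached_value(present)
        for j in order:
            present = present | {j}
            new = cached_value(present)
            phi[j] += new - prev
            prev = new
    return phi / len(perms)


def summary_ranking(attribution_set: AttributionSet) -> list[tuple[str, float]]:
    """Features sorted by mean |attribution|, descending; ties alphabetical."""
    shap = attribution_set.per_sample_shap
    if shap.size == 0:
        raise ValueError("empty attribution set")
    mean_abs = np.abs(shap).mean(axis=0)
    pairs = list(zip(attribution_set.feature_names, mean_abs.tolist()))
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))
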