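"""Sampling-based Shapley attribution of classifier predictions.

The Shapley value of feature ``j`` for an explained sample ``x`` is its
average marginal contribution to the model output over all orderings of the
features, with absent features imputed from a background dataset.  The
estimator here is the classic permutation Monte Carlo: draw a random feature
ordering and a random background row, walk through the ordering switching
features from the background value to the explained value, and credit each
feature with the resulting change in model output.

Per explained sample the per-permutation contributions telescope, so the
estimate satisfies the efficiency axiom exactly against the mean output of
the drawn background rows; symmetry and the dummy axiom hold in expectation
with Monte-Carlo error tracked via per-feature standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ShapleyReport:
    """Per-sample attributions and their Monte-Carlo uncertainty."""

    phi: np.ndarray  # (n_explained, n_features)
    se: np.ndarray  # (n_explained, n_features) standard errors
    base_values: np.ndarray  # (n_explained,) mean output over drawn backgrounds
    outputs: np.ndarray  # (n_explained,) model output at each explained sample
    feature_names: list[str]
    n_permutations: int


def _proba_output(model, class_index: int):
    def fn(X: np.ndarray) -> np.ndarray:
        return model.predict_proba(X)[:, class_index]

    return fn


def shapley_values(
    model,
    X_background: np.ndarray,
    X_explain: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    class_index: int | None = None,
    output_fn=None,
    feature_names: list[str] | None = None,
) -> ShapleyReport:
    """Permutation-sampling Shapley values for each row of ``X_explain``.

    ``output_fn`` maps a 2-D array to a scalar output per row; by default the
    predicted probability of ``class_index`` is explained (``class_index``
    defaults to each sample's own predicted class).  Deterministic per seed.
    """
    X_background = np.asarray(X_background, dtype=float)
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if X_background.ndim != 2 or X_background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D array")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    n_explain, d = X_explain.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(d)]

    rng = np.random.default_rng(seed)
    phi = np.empty((n_explain, d))
    se = np.empty((n_explain, d))
    base = np.empty(n_explain)
    outs_full = np.empty(n_explain)

    for i in range(n_explain):
        x = X_explain[i]
        if output_fn is not None:
            fn = output_fn
        else:
            ci = class_index
            if ci is None:
                ci = int(np.argmax(model.predict_proba(x[None, :])[0]))
            fn = _proba_output(model, ci)

        contribs = np.empty((n_permutations, d))
        base_draws = np.empty(n_permutations)
        full_outs = np.empty(n_permutations)
        for p in range(n_permutations):
            z = X_background[rng.integers(X_background.shape[0])]
            order = rng.permutation(d)
            # rows: background, then features switched to x one at a time
            rows = np.tile(z, (d + 1, 1))
            for t, j in enumerate(order, start=1):
                rows[t:, j] = x[j]
            outs = np.asarray(fn(rows), dtype=float)
            contribs[p, order] = np.diff(outs)
            base_draws[p] = outs[0]
            full_outs[p] = outs[-1]
        phi[i] = contribs.mean(axis=0)
        if n_permutations > 1:
            se[i] = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
        else:
            se[i] = np.inf
        base[i] = base_draws.mean()
        outs_full[i] = full_outs.mean()  # identical across permutations

    if np.allclose(phi, 0.0) and np.allclose(se[np.isfinite(se)], 0.0):
        logger.info("model output is constant over the explained set; all phi = 0")

    return ShapleyReport(
        phi=phi,
        se=se,
        base_values=base,
        outputs=outs_full,
        feature_names=list(feature_names),
        n_permutations=n_permutations,
    )


def rank_features(report: ShapleyReport, top: int = 20) -> pd.DataFrame:
    """Features ordered by mean absolute attribution, descending.

    Ties break toward the lower feature index.  ``top`` beyond the feature
    count truncates with a warning.
    """
    d = report.phi.shape[1]
    if report.phi.size == 0:
        raise ValueError("empty Shapley report")
    if top > d:
        logger.warning("requested top %d of %d features; truncating", top, d)
        top = d
    mean_abs = np.abs(report.phi).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")[:top]
    return pd.DataFrame(
        {
            "feature_index": order,
            "feature": [report.feature_names[j] for j in order],
            "mean_abs_phi": mean_abs[order],
        }
    ).reset_index(drop=True)


def block_share(report: ShapleyReport, suffix: str = "_f1") -> float:
    """Fraction of total mean |phi| carried by features whose name ends with
    ``suffix`` — a diagnostic for how much the zero-order-moment block drives
    the classifier."""
    mean_abs = np.abs(report.phi).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        return 0.0
    mask = np.array([name.endswith(suffix) for name in report.feature_names])
    return float(mean_abs[mask].sum() / total)
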