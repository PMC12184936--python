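"""Model interpretation: Gini importance and multiclass partial dependence.

Variable importance is the mean-decrease-impurity (Gini) importance: each
feature's total, tree-averaged reduction in node impurity, normalised across
features so the values sum to one.

Partial dependence is computed on the log-of-votes (multiclass logit) scale.
For a probe point x with per-class vote fractions p_j(x), two variants of
the per-class value are available:

    printed    f_k(x) = log p_k(x) - sum_j log p_j(x)
    centered   f_k(x) = log p_k(x) - (1/K) * sum_j log p_j(x)

The centered variant is the conventional multiclass logit (the per-class
values sum to zero at every probe point) and is the default; the printed
variant omits the 1/K factor, which rescales and shifts the curves but does
not change their shape.  Probe rows hold every non-target feature at its
column mean; vote fractions are smoothed by eps = 1/(2 * n_trees) so the
logs stay finite when a class receives zero votes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, NumericalGuardError, StateError
from .modeling import ModeChoiceForest, feature_columns

__all__ = [
    "gini_importance",
    "multiclass_logit",
    "smooth_vote_fractions",
    "PDPResult",
    "partial_dependence",
    "plot_importance",
    "plot_pdp",
]

VARIANTS = ("printed", "centered")


def gini_importance(model: ModeChoiceForest) -> pd.DataFrame:
    """Normalised mean-decrease-impurity importance with a deterministic rank.

    Returns a DataFrame (feature, importance, rank) sorted by descending
    importance; exact ties are ordered by feature name.
    """
    if not hasattr(model, "forest_"):
        raise StateError("model is not fitted")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    table = pd.DataFrame({"feature": model.feature_names_, "importance": imp})
    table = table.sort_values(
        ["importance", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def multiclass_logit(p: np.ndarray, variant: str = "centered") -> np.ndarray:
    """Per-class log-of-votes value for vote-fraction vector(s) ``p``.

    ``p`` has classes on the last axis; entries must be strictly positive.
    """
    if variant not in VARIANTS:
        raise InvalidConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise NumericalGuardError("vote fractions must be strictly positive for the log")
    logp = np.log(p)
    k = p.shape[-1]
    s = logp.sum(axis=-1, keepdims=True)
    if variant == "printed":
        return logp - s
    return logp - s / k


def smooth_vote_fractions(votes: np.ndarray, n_trees: int) -> np.ndarray:
    """Laplace-style smoothing p = (v + eps) / (1 + K*eps), eps = 1/(2*n_trees)."""
    votes = np.asarray(votes, dtype=float)
    eps = 1.0 / (2.0 * n_trees)
    k = votes.shape[-1]
    p = (votes + eps) / (votes.sum(axis=-1, keepdims=True) + k * eps)
    if np.any(p <= 0):
        raise NumericalGuardError("vote fraction non-positive after smoothing")
    return p


@dataclass
class PDPResult:
    """Per-class partial-dependence curves for one feature.

    ``values`` is (n_classes, n_grid) in the order of ``classes``; the grid
    spans the feature's 1st-99th percentile in ``n_grid`` even steps.
    """

    feature: str
    grid: np.ndarray
    classes: list[str]
    values: np.ndarray
    variant: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, klass in enumerate(self.classes):
            for gi, x in enumerate(self.grid):
                rows.append(
                    {
                        "feature": self.feature,
                        "grid_value": float(x),
                        "class": klass,
                        "f": float(self.values[ci, gi]),
                        "variant": self.variant,
                    }
                )
        return pd.DataFrame(rows)


def partial_dependence(
    model: ModeChoiceForest,
    X: pd.DataFrame,
    feature: str,
    n_grid: int = 50,
    variant: str = "centered",
) -> PDPResult:
    """Held-at-means partial dependence of the class logits on one feature.

    For each grid value the probe row sets the target feature to that value
    and every other feature to its mean over ``X``; the model's (smoothed)
    vote fractions at the probe are mapped through :func:`multiclass_logit`.
    """
    feats = [c for c in feature_columns(X) if c in model.feature_names_]
    if feature not in model.feature_names_:
        raise InvalidConfigError(f"{feature!r} is not a training feature")
    lo, hi = np.percentile(X[feature].to_numpy(dtype=float), [1, 99])
    if hi <= lo:
        hi = lo + 1e-9
    grid = np.linspace(lo, hi, n_grid)

    means = X[model.feature_names_].mean()
    probes = pd.DataFrame([means.to_dict()] * n_grid)[model.feature_names_]
    probes[feature] = grid
    votes = model.vote_fractions(probes)
    p = smooth_vote_fractions(votes, model.n_trees)
    values = multiclass_logit(p, variant=variant).T  # (K, n_grid)
    return PDPResult(
        feature=feature,
        grid=grid,
        classes=[str(c) for c in model.classes_],
        values=values,
        variant=variant,
    )


# --------------------------------------------------------------------------
# optional figure output


def plot_importance(table: pd.DataFrame, path) -> None:
    """Horizontal bar chart of the importance table, most important on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.35 * len(table) + 1))
    t = table.sort_values("importance")
    ax.barh(t["feature"], t["importance"], color="#4477aa")
    ax.set_xlabel("Gini importance (mean decrease impurity)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pdp(results: list[PDPResult], path, ncols: int = 3) -> None:
    """Panel of per-feature partial-dependence curves, one line per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for i, res in enumerate(results):
        ax = axes[i // ncols][i % ncols]
        for ci, klass in enumerate(res.classes):
            ax.plot(res.grid, res.values[ci], label=klass)
        ax.set_title(res.feature, fontsize=9)
        ax.axhline(0.0, color="grey", lw=0.5)
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
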