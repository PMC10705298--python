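"""Predicted probability of male-biased power at named ancestral nodes.

The fitted logistic coefficients map a reconstructed ratio-scale trait
value m at an ancestral node to the odds of male-biased power:

    odds = exp(b0 + log10(m) * b1),   probability = odds / (1 + odds)

i.e. the predictor enters on the log10 scale, unstandardized, with the
bootstrapped coefficient means.  (A fully standardized variant — z-scoring
log10(m) with the mean/SD of the fitted species sample — is available via
``standardization=`` for users fitting their own data.)  Probability CIs
are the mapped trait-CI endpoints; the map is monotone, so endpoint order
is preserved, reversed when b1 < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "predicted_odds",
    "predicted_probability",
    "CladePrediction",
    "build_ancestral_power_table",
    "resolve_clade_nodes",
]


def predicted_odds(b0: float, b1: float, node_mle: float,
                   standardization=None) -> float:
    """Odds of male-biased power at a ratio-scale ancestral trait value."""
    if node_mle <= 0:
        raise ValueError(f"node MLE must be > 0, got {node_mle}")
    z = math.log10(node_mle)
    if standardization is not None:
        z = (z - standardization.mean) / standardization.sd
    return math.exp(b0 + z * b1)


def predicted_probability(odds: float) -> float:
    """Convert odds to probability: odds / (1 + odds)."""
    if odds < 0:
        raise ValueError(f"odds must be >= 0, got {odds}")
    return odds / (1.0 + odds)


def probability_at(b0: float, b1: float, node_mle: float,
                   standardization=None) -> float:
    return predicted_probability(predicted_odds(b0, b1, node_mle, standardization))


def crossing_point(b0: float, b1: float) -> float:
    """Ratio-scale trait value at which the predicted probability is 50%."""
    if b1 == 0:
        raise ValueError("b1 = 0: the curve never crosses 50%")
    return 10.0 ** (-b0 / b1)


def resolve_clade_nodes(tree, clade_map) -> dict:
    """Map clade name -> internal node index in (a pruned copy of) the tree.

    Clade tips absent from the tree are ignored.  When two clades collapse
    onto the same MRCA node (e.g. a haplorhine clade whose only
    non-anthropoid members are missing from a predictor's dataset), only
    the most exclusive clade keeps the node; the others are reported as
    absent (None).  Clades with fewer than 2 tips present are absent.
    """
    tips = set(tree.tip_labels)
    raw = {}
    sizes = {}
    for name, members in clade_map.items():
        present = [m for m in members if m in tips]
        if len(present) < 2:
            raw[name] = None
            continue
        raw[name] = tree.mrca(present)
        # tie-break on the full clade definition: when a larger clade's node
        # collapses onto a nested clade's MRCA (members missing from this
        # dataset), the more exclusive clade keeps the node
        sizes[name] = len(members)
    by_node = {}
    for name, node in raw.items():
        if node is not None:
            by_node.setdefault(node, []).append(name)
    resolved = {}
    for name, node in raw.items():
        if node is None:
            resolved[name] = None
        else:
            keep = min(by_node[node], key=lambda nm: sizes[nm])
            resolved[name] = node if name == keep else None
    return resolved


@dataclass
class CladePrediction:
    clade: str
    scaled_lik_md: float | None
    per_predictor: dict  # predictor -> dict(mle, ci, prob, prob_ci) or None


def build_ancestral_power_table(
    discrete, continuous, coefficients, clade_map, clade_order=None,
) -> pd.DataFrame:
    """Assemble the per-clade ancestral power table.

    Parameters
    ----------
    discrete : ``(tree, NodeStateLikelihoods)`` for the power category, or None
    continuous : dict predictor -> ``(tree, NodeEstimates)``; each predictor
        may use its own pruned tree
    coefficients : dict predictor -> ``(b0, b1)`` bootstrapped means
    clade_map : dict clade name -> list of defining tip labels
    clade_order : optional row order (defaults to clade_map order)

    Cells are NaN when a clade's node does not exist in a predictor's
    pruned tree.  Probability CI endpoints are the mapped trait CI
    endpoints in trait order (reversed when b1 < 0).
    """
    order = list(clade_order or clade_map)
    unknown = set(order) - set(clade_map)
    if unknown:
        raise ValueError(f"clades without a tip list: {sorted(unknown)}")
    rows = []
    disc_nodes = None
    if discrete is not None:
        dtree, dlik = discrete
        disc_nodes = resolve_clade_nodes(dtree, clade_map)
    cont_nodes = {
        pred: resolve_clade_nodes(tree, clade_map)
        for pred, (tree, _est) in continuous.items()
    }
    for clade in order:
        row = {"clade": clade}
        if discrete is not None:
            node = disc_nodes[clade]
            row["scaled_lik_md"] = (
                dlik.probability(node, "MD") if node is not None else np.nan
            )
        for pred, (tree, est) in continuous.items():
            b0, b1 = coefficients[pred]
            node = cont_nodes[pred][clade]
            if node is None or node not in est.node_mle:
                row[f"{pred}_mle"] = np.nan
                row[f"{pred}_ci_lo"] = np.nan
                row[f"{pred}_ci_hi"] = np.nan
                row[f"{pred}_prob"] = np.nan
                row[f"{pred}_prob_ci_lo"] = np.nan
                row[f"{pred}_prob_ci_hi"] = np.nan
                continue
            m = est.ratio_mle(node)
            lo, hi = est.ratio_ci(node)
            row[f"{pred}_mle"] = m
            row[f"{pred}_ci_lo"] = lo
            row[f"{pred}_ci_hi"] = hi
            row[f"{pred}_prob"] = probability_at(b0, b1, m)
            row[f"{pred}_prob_ci_lo"] = probability_at(b0, b1, lo)
            row[f"{pred}_prob_ci_hi"] = probability_at(b0, b1, hi)
        rows.append(row)
    return pd.DataFrame(rows)


# -- figures ---------------------------------------------------------------

def plot_probability_curves(coefficients, ranges, path, n_grid: int = 200):
    """Predicted-probability curves over a ratio-scale predictor grid.

    ``ranges`` maps predictor -> (lo, hi) on the ratio scale.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preds = list(coefficients)
    fig, axes = plt.subplots(1, len(preds), figsize=(4 * len(preds), 3.2))
    if len(preds) == 1:
        axes = [axes]
    for ax, pred in zip(axes, preds):
        b0, b1 = coefficients[pred]
        lo, hi = ranges[pred]
        grid = np.linspace(lo, hi, n_grid)
        probs = [probability_at(b0, b1, g) for g in grid]
        ax.plot(grid, probs)
        ax.axhline(0.5, color="grey", lw=0.8)
        ax.set_xlabel(pred.upper())
        ax.set_ylabel("P(male-biased power)")
        ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dimorphism_by_power(table, path, predictors=("bmr", "cr")):
    """Box summaries of dimorphism by power category."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.frame
    fig, axes = plt.subplots(1, len(predictors), figsize=(4 * len(predictors), 3.2))
    if len(predictors) == 1:
        axes = [axes]
    cats = ["MD", "CD", "FD"]
    for ax, pred in zip(axes, predictors):
        data = [df.loc[df["power"] == c, pred].dropna() for c in cats]
        ax.boxplot(data, tick_labels=cats, whis=(10, 90))
        ax.axhline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_ylabel(pred.upper())
        ax.set_xlabel("power category")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
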