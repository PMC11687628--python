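"""Akaike-weight comparison of the seven trait-evolution models.

Fits BM1, BMS, OU1, OUM, OUMV, OUMA and OUMVA to the same data, ranks them
by AICc (or AIC), converts differences to Akaike weights
``w_m = exp(-Delta_m/2) / sum exp(-Delta/2)``, and applies the evidence-ratio
rule: the selected set is the best model plus every model whose evidence
ratio ``w_best / w_m`` is below 3.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DrivephyError, ValidationError
from .ou import MODEL_ORDER, MODELS, FitConfig, OUModel, OUResults
from .phylo import Phylogeny, RegimeMap

logger = logging.getLogger(__name__)

__all__ = ["compare_models", "ModelComparison"]

EVIDENCE_RATIO_THRESHOLD = 3.0


@dataclass
class ModelComparison:
    """Ranked model table with Akaike weights and the evidence-ratio selection."""

    table: pd.DataFrame
    results: dict[str, OUResults]
    criterion: str
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    @property
    def best_result(self) -> OUResults:
        return self.results[self.best]

    @property
    def selected(self) -> list[str]:
        return list(self.table[self.table["selected"]]["model"])

    def weights(self) -> dict[str, float]:
        return dict(zip(self.table["model"], self.table["weight"]))

    def summary(self) -> str:
        lines = [
            f"Model comparison ({self.criterion.upper()}, n = "
            f"{next(iter(self.results.values())).nobs}):",
            self.table.to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        if self.excluded:
            lines.append(f"excluded: {self.excluded}")
        lines.append(f"selected set (evidence ratio < {EVIDENCE_RATIO_THRESHOLD}): "
                     f"{self.selected}")
        return "\n".join(lines)


def akaike_weights(criterion_values: np.ndarray) -> np.ndarray:
    delta = criterion_values - np.min(criterion_values)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def compare_models(
    tree: Phylogeny,
    tip_values,
    regimes: RegimeMap,
    criterion: str = "aicc",
    root_mode: str = "fixed",
    models: list[str] | None = None,
    config: FitConfig | None = None,
) -> ModelComparison:
    """Fit the model suite and rank by Akaike weight.

    Models whose AICc is undefined at this sample size (n <= k + 1) are
    excluded with a logged reason.  Ties in the criterion break toward the
    smaller parameter count, then the fixed model-name order.
    """
    if criterion not in ("aic", "aicc"):
        raise ValidationError("criterion must be 'aic' or 'aicc'")
    models = models or MODEL_ORDER
    results: dict[str, OUResults] = {}
    excluded: dict[str, str] = {}
    n_tips = tree.n_tips
    for name in models:
        k = MODELS[name].k(len(regimes.alphabet))
        if n_tips <= k + 1:
            excluded[name] = f"AICc undefined: n = {n_tips} <= k+1 = {k + 1}"
            logger.warning("%s excluded: %s", name, excluded[name])
            continue
        try:
            results[name] = OUModel(
                tree, tip_values, regimes=regimes, model=name, root_mode=root_mode
            ).fit(config)
        except DrivephyError as exc:
            excluded[name] = str(exc)
            logger.warning("%s excluded: %s", name, excluded[name])
    if not results:
        raise ValidationError("no model could be fitted")

    rows = []
    for name, res in results.items():
        crit = res.aicc if criterion == "aicc" else res.aic
        rows.append(
            {
                "model": name,
                "logL": res.llf,
                "k": res.k,
                criterion: crit,
                "_order": MODEL_ORDER.index(name),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values([criterion, "k", "_order"], kind="stable").reset_index(drop=True)
    df[f"d{criterion}"] = df[criterion] - df[criterion].iloc[0]
    w = akaike_weights(df[criterion].to_numpy())
    df["weight"] = w
    df["evidence_ratio"] = w[0] / w
    df["selected"] = df["evidence_ratio"] < EVIDENCE_RATIO_THRESHOLD
    df = df.drop(columns="_order")
    return ModelComparison(df, results, criterion, excluded)
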