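"""Composite frequency of positive selection on CENH3 per clade.

Consumes tabulated outputs of branch-level (aBSREL-style) and codon-level
(MEME-style) episodic positive-selection tests.  The branch frequency is the
fraction of significant branches among branches of orthologous groups
(paralogous-duplication subtrees excluded from numerator and denominator);
the codon frequency is the fraction of significant codons among aligned
codons; their product is the clade's single composite frequency F.
Significance uses uncorrected P-values with strict thresholds (branches
P < 0.05, codons P < 0.1 by default), matching exploratory-analysis practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "branch_frequency",
    "codon_frequency",
    "selection_frequency",
    "selection_frequencies",
    "compare_dnds_groups",
    "SelectionFrequencyResult",
]

DEFAULT_ALPHA_BRANCH = 0.05
DEFAULT_ALPHA_CODON = 0.1


@dataclass
class SelectionFrequencyResult:
    clade: str
    region: str
    f_branch: float
    f_codon: float
    F: float
    n_branch_denom: int
    n_codons: int


def _check_pvalues(p: pd.Series, what: str) -> None:
    p = p.astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError(f"{what} P-values outside [0, 1]")


def branch_frequency(records: pd.DataFrame, alpha_branch: float = DEFAULT_ALPHA_BRANCH) -> float:
    """Fraction of orthologous-group branches with uncorrected P < alpha."""
    if not 0 < alpha_branch < 1:
        raise ValidationError("alpha_branch must be in (0, 1)")
    _check_pvalues(records["p_value"], "branch")
    ortho = records[records["orthologous"].astype(bool)]
    if ortho.empty:
        raise ValidationError("no orthologous branches: branch frequency undefined")
    return float((ortho["p_value"].astype(float) < alpha_branch).sum() / len(ortho))


def codon_frequency(
    records: pd.DataFrame, n_codons: int, alpha_codon: float = DEFAULT_ALPHA_CODON
) -> float:
    """Fraction of aligned codons with P < alpha.  ``records`` may list only
    tested codons; ``n_codons`` is the full alignment length in codons."""
    if n_codons < 1:
        raise ValidationError("n_codons must be >= 1")
    _check_pvalues(records["p_value"], "codon")
    idx = records["codon_index"].astype(int)
    if (idx > n_codons).any() or (idx < 1).any():
        bad = sorted(idx[(idx > n_codons) | (idx < 1)])
        raise ValidationError(f"codon indices outside 1..{n_codons}: {bad}")
    if idx.duplicated().any():
        raise ValidationError("duplicate codon indices within a (clade, region) table")
    return float((records["p_value"].astype(float) < alpha_codon).sum() / n_codons)


def selection_frequency(f_branch: float, f_codon: float) -> float:
    """Composite frequency: product of branch and codon frequencies."""
    for f in (f_branch, f_codon):
        if not 0 <= f <= 1:
            raise ValidationError("component frequencies must lie in [0, 1]")
    return f_branch * f_codon


def selection_frequencies(
    branch_tests: pd.DataFrame,
    codon_tests: pd.DataFrame,
    alignment_lengths: pd.DataFrame,
    alpha_branch: float = DEFAULT_ALPHA_BRANCH,
    alpha_codon: float = DEFAULT_ALPHA_CODON,
) -> pd.DataFrame:
    """Composite selection frequency per (clade, region).

    ``branch_tests``: columns ``clade, branch_id, omega, p_value, orthologous``
    (one table per clade gene tree; regions share it).
    ``codon_tests``: columns ``clade, region, codon_index, p_value[, omega]``.
    ``alignment_lengths``: columns ``clade, region, n_codons``.
    """
    fb: dict[str, tuple[float, int]] = {}
    for clade, sub in branch_tests.groupby("clade", sort=True):
        n_denom = int(sub["orthologous"].astype(bool).sum())
        fb[str(clade)] = (branch_frequency(sub, alpha_branch), n_denom)

    lengths = alignment_lengths.set_index(["clade", "region"])["n_codons"]
    rows = []
    for (clade, region), sub in codon_tests.groupby(["clade", "region"], sort=True):
        key = (clade, region)
        if key not in lengths.index:
            raise ValidationError(f"no alignment length for {key}")
        if str(clade) not in fb:
            raise ValidationError(f"no branch tests for clade {clade!r}")
        n_codons = int(lengths.loc[key])
        f_c = codon_frequency(sub, n_codons, alpha_codon)
        f_b, n_denom = fb[str(clade)]
        rows.append(
            {
                "clade": str(clade),
                "region": str(region),
                "f_branch": f_b,
                "f_codon": f_c,
                "F": selection_frequency(f_b, f_c),
                "n_branch_denom": n_denom,
                "n_codons": n_codons,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clade", "region", "f_branch", "f_codon", "F", "n_branch_denom", "n_codons"],
    )


def compare_dnds_groups(omegas_a, omegas_b):
    """Two-sided Mann-Whitney comparison of dN/dS samples (e.g. pooled by
    meiosis regime).  Returns a :class:`drivephy.hypotests.MannWhitneyResult`."""
    from .hypotests import mann_whitney

    return mann_whitney(np.asarray(omegas_a, float), np.asarray(omegas_b, float))
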