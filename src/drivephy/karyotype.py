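"""Chromosome-size trait construction and the per-clade rate-of-evolution statistic.

A species' mean chromosome size is its diploid genome size (2C, Mb) divided by
its diploid chromosome count (2n).  Within each clade the sizes are
z-standardized so the trait is comparable across clades of very different
genome sizes, then phylogenetic independent contrasts are computed on the
clade's ultrametric species tree, and the median of their absolute values is
the clade's single rate-of-chromosome-size-evolution statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .phylo import Phylogeny, independent_contrasts

logger = logging.getLogger(__name__)

PG_TO_MB = 978.0  # 1 pg of DNA ~ 978 Mb

__all__ = [
    "mean_chromosome_size",
    "z_standardize",
    "clade_rate",
    "clade_rates",
    "load_karyotypes",
    "CladeRateResult",
]


def mean_chromosome_size(two_c, two_n, species=None):
    """Mean chromosome size = 2C / 2n (Mb).  Vectorized over arrays/Series."""
    two_c = np.asarray(two_c, dtype=float)
    two_n = np.asarray(two_n, dtype=float)
    bad = (two_c <= 0) | (two_n < 2)
    if np.any(bad):
        if species is not None:
            names = list(np.asarray(species)[bad])
            raise ValidationError(f"non-positive 2C or 2n < 2 for species: {names}")
        raise ValidationError("non-positive 2C or 2n < 2")
    out = two_c / two_n
    return float(out) if out.ndim == 0 else out


def z_standardize(values) -> np.ndarray:
    """(x - mean) / sd with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("z-standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("z-standardization undefined: zero variance")
    return (x - x.mean()) / sd


@dataclass
class CladeRateResult:
    """Per-clade rate of chromosome-size evolution (median |PIC|)."""

    clade: str
    regime: str
    n_species: int
    rate: float
    dropped_species: list[str] = field(default_factory=list)


def clade_rate(
    tree: Phylogeny,
    karyotypes: pd.DataFrame,
    clade: str | None = None,
    min_species: int = 3,
) -> CladeRateResult:
    """Rate statistic for one clade.

    ``karyotypes`` must carry columns ``species, clade, regime, 2C_Mb, 2n``
    (one row per species).  The tree is pruned to the species present in both
    the tree and the table; dropped species are recorded on the result.
    """
    df = karyotypes
    if clade is not None:
        df = df[df["clade"] == clade]
    if df.empty:
        raise ValidationError(f"no karyotype rows for clade {clade!r}")
    clade = str(df["clade"].iloc[0])
    regime = str(df["regime"].iloc[0])

    in_tree = set(tree.tip_labels)
    in_table = set(df["species"])
    common = sorted(in_tree & in_table)
    dropped = sorted((in_tree | in_table) - set(common))
    if dropped:
        logger.info("clade %s: dropped at tree/table intersection: %s", clade, dropped)
    if len(common) < min_species:
        raise ValidationError(
            f"clade {clade!r}: only {len(common)} species shared between tree and "
            f"table (minimum {min_species})"
        )

    sub = df[df["species"].isin(common)].set_index("species")
    sizes = mean_chromosome_size(
        sub.loc[common, "2C_Mb"], sub.loc[common, "2n"], species=common
    )
    z = z_standardize(sizes)
    pruned = tree.prune_to_taxa(common)
    contrasts = independent_contrasts(pruned, dict(zip(common, z)))
    rate = float(np.median(np.abs(contrasts.contrasts)))
    return CladeRateResult(clade, regime, len(common), rate, dropped)


def clade_rates(
    trees: dict[str, Phylogeny],
    karyotypes: pd.DataFrame,
    min_species: int = 3,
) -> tuple[pd.DataFrame, list[dict]]:
    """Rate statistics for every clade; clades that fail are skipped with a record.

    Returns ``(table, skipped)`` where table has columns
    ``clade, regime, n_species, rate`` and ``skipped`` is a list of
    ``{"clade": ..., "reason": ...}`` records.
    """
    rows, skipped = [], []
    for clade, sub in karyotypes.groupby("clade", sort=True):
        tree = trees.get(str(clade))
        if tree is None:
            skipped.append({"clade": str(clade), "reason": "no species tree supplied"})
            continue
        try:
            res = clade_rate(tree, sub, min_species=min_species)
        except ValidationError as exc:
            skipped.append({"clade": str(clade), "reason": str(exc)})
            logger.warning("clade %s skipped: %s", clade, exc)
            continue
        rows.append(
            {
                "clade": res.clade,
                "regime": res.regime,
                "n_species": res.n_species,
                "rate": res.rate,
            }
        )
    return pd.DataFrame(rows, columns=["clade", "regime", "n_species", "rate"]), skipped


def load_karyotypes(path_or_df) -> pd.DataFrame:
    """Load and validate a karyotype table.

    Expected columns ``species, clade, regime, 2C_Mb, 2n`` (TSV/CSV detected
    by extension).  A ``2C_pg`` column is converted to Mb at 978 Mb/pg.
    Multiple records per species collapse to the median 2C and the modal 2n
    (smallest mode on ties).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        sep = "," if str(path_or_df).endswith(".csv") else "\t"
        df = pd.read_csv(path_or_df, sep=sep)
    if "2C_Mb" not in df.columns and "2C_pg" in df.columns:
        df["2C_Mb"] = df["2C_pg"].astype(float) * PG_TO_MB
        logger.info("converted 2C from pg to Mb (1 pg = %g Mb)", PG_TO_MB)
    required = {"species", "clade", "regime", "2C_Mb", "2n"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"karyotype table missing columns: {sorted(missing)}")
    bad_regime = set(df["regime"]) - {"asymmetric", "symmetric"}
    if bad_regime:
        raise ValidationError(f"unknown regimes in karyotype table: {sorted(bad_regime)}")

    if df["species"].duplicated().any():
        def collapse(g: pd.DataFrame) -> pd.Series:
            modes = g["2n"].mode()
            return pd.Series(
                {
                    "clade": g["clade"].iloc[0],
                    "regime": g["regime"].iloc[0],
                    "2C_Mb": float(g["2C_Mb"].median()),
                    "2n": int(modes.min()),
                }
            )

        n_before = len(df)
        df = df.groupby("species", sort=False).apply(collapse, include_groups=False)
        df = df.reset_index()
        logger.info("collapsed %d duplicate karyotype records", n_before - len(df))

    df["2C_Mb"] = df["2C_Mb"].astype(float)
    df["2n"] = df["2n"].astype(int)
    if (df["2C_Mb"] <= 0).any() or (df["2n"] < 2).any():
        bad = df[(df["2C_Mb"] <= 0) | (df["2n"] < 2)]["species"].tolist()
        raise ValidationError(f"invalid 2C/2n for species: {bad}")
    return df[["species", "clade", "regime", "2C_Mb", "2n"]]
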