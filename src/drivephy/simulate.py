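"""Seeded generators for every input the comparative pipeline consumes.

The default scenario emulates the study design this package targets: 27
plant clades (21 with asymmetric female meiosis, 6 with only symmetric
meiosis, symmetric ancestral at the root), 384 taxa with CENH3 sequences of
which 290 carry karyotype data, and 475 sequences once within-clade
paralogues are counted.  Asymmetric clades are young (genus/family level,
tens of Myr) and symmetric clades old (class level, hundreds of Myr); that
age difference is what drives the regime difference in the clade rate
statistic, since the median-|PIC| of z-scored traits scales like
1/sqrt(clade age) and is invariant to the Brownian rate itself.

Every draw descends from a single master seed through counter-based
sub-seeds (``SeedSequence(seed, spawn_key=(clade, stream))``), so adding
clades or streams never perturbs earlier clades' data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .ou import simulate_tips
from .phylo import Phylogeny, RegimeMap, paint_regimes

__all__ = [
    "ScenarioConfig",
    "SyntheticStudy",
    "yule_tree",
    "simulate_clade_system",
    "simulate_clade_response",
    "scenario_presets",
]

ASYM, SYM = "asymmetric", "symmetric"


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic study; all randomness flows from
    ``seed``.  Clade-level OU parameters are given as ``alpha_rel`` (alpha
    times the clade-tree depth, dimensionless pull) and regime optima
    ``theta`` on the response scale; ``sigma2`` follows from the stationary
    SD: ``sigma2 = 2 * alpha * stationary_sd**2``."""

    seed: int = 0
    name: str = "custom"
    # clade-level tree and painting
    n_clades: int = 27
    n_symmetric: int = 6
    clade_tree_depth: float = 475.0  # Myr (land-plant crown order of magnitude)
    root_regime: str = SYM
    # clade-level generating model for the response
    response_model: str = "OUM"
    theta: dict = field(default_factory=lambda: {ASYM: 0.118, SYM: 0.058})
    alpha_rel: float = 3.0
    stationary_sd: float = 0.02
    # species-level karyotype generation
    n_taxa_total: int = 384
    n_karyotyped_total: int = 290
    n_sequences_total: int = 475
    clade_age_range: dict = field(
        default_factory=lambda: {ASYM: (42.0, 65.0), SYM: (187.0, 281.0)}
    )
    logsize_root_mean: float = float(np.log(150.0))  # log Mb
    logsize_root_sd: float = 0.5
    bm_sigma2_log: dict = field(default_factory=lambda: {ASYM: 0.004, SYM: 0.001})
    base_2n_support: tuple = tuple(range(4, 50, 2))
    polyploidy_rate: float = 0.05
    # selection-test generation (true Bernoulli significance rates)
    p_branch: dict = field(default_factory=lambda: {ASYM: 0.35, SYM: 0.30})
    p_codon: dict = field(
        default_factory=lambda: {
            ASYM: {"full": 0.020, "N": 0.470, "C": 0.00829},
            SYM: {"full": 0.010, "N": 0.543, "C": 0.00033},
        }
    )
    n_codons: dict = field(default_factory=lambda: {"full": 150, "N": 90, "C": 60})
    alpha_branch: float = 0.05
    alpha_codon: float = 0.1

    def __post_init__(self):
        if self.n_clades < 2 or not (0 < self.n_symmetric < self.n_clades):
            raise ValidationError("need n_clades >= 2 and 0 < n_symmetric < n_clades")
        for p in self.p_branch.values():
            if not 0 <= p <= 1:
                raise ValidationError("p_branch outside [0, 1]")
        for d in self.p_codon.values():
            for p in d.values():
                if not 0 <= p <= 1:
                    raise ValidationError("p_codon outside [0, 1]")
        if self.n_karyotyped_total > self.n_taxa_total:
            raise ValidationError("cannot karyotype more taxa than exist")
        if self.n_sequences_total < self.n_taxa_total:
            raise ValidationError("every taxon contributes at least one sequence")

    @property
    def alpha(self) -> float:
        return self.alpha_rel / self.clade_tree_depth

    @property
    def sigma2(self) -> float:
        return 2.0 * self.alpha * self.stationary_sd**2


def _rng(seed: int, clade: int = 0, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(clade, stream)))


# -------------------------------------------------------------------- Yule
def yule_tree(n_tips: int, seed, depth: float = 1.0) -> Phylogeny:
    """Pure-birth tree rescaled to the requested root-to-tip depth.

    Deterministic per seed; ultrametric by construction (all tips end at the
    same final time).
    """
    if n_tips < 2:
        raise ValidationError("a Yule tree needs at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parent = [-1]
    start = {0: 0.0}
    split_time: dict[int, float] = {}
    tips = [0]
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(int(rng.integers(len(tips))))
        split_time[node] = t
        for _ in range(2):
            j = len(parent)
            parent.append(node)
            start[j] = t
            tips.append(j)
    t_end = t + rng.exponential(1.0 / n_tips)
    parent = np.array(parent, dtype=np.int64)
    blen = np.zeros(len(parent))
    labels = {}
    n_label = 0
    for j in range(len(parent)):
        end = split_time.get(j, t_end)
        if parent[j] >= 0:
            blen[j] = end - start[j]
    scale = depth / (t_end - split_time[0])  # root-to-tip span, root edge excluded
    blen *= scale
    # label tips in preorder encounter order for reproducible naming
    tree = Phylogeny(parent, blen, {j: f"_tmp{j}" for j in range(len(parent)) if j not in split_time})
    labels = {}
    for node in tree.preorder():
        if tree.is_tip(node):
            n_label += 1
            labels[node] = f"t{n_label}"
    return Phylogeny(parent, blen, labels)


# ------------------------------------------------------------ clade system
@dataclass
class SyntheticStudy:
    """Complete synthetic input bundle plus its generating truth."""

    config: ScenarioConfig
    clade_tree: Phylogeny
    regime_map: RegimeMap
    clades: pd.DataFrame  # clade, regime, n_taxa, n_karyotyped, n_sequences, age
    species_trees: dict[str, Phylogeny]
    karyotypes: pd.DataFrame
    branch_tests: pd.DataFrame
    codon_tests: pd.DataFrame
    alignment_lengths: pd.DataFrame
    truth: dict

    def tip_regimes(self) -> dict[str, str]:
        return dict(zip(self.clades["clade"], self.clades["regime"]))

    def to_dir(self, path) -> None:
        """Emit the TSV/Newick dialects the pipeline consumes, plus truth.json."""
        path = Path(path)
        (path / "species_trees").mkdir(parents=True, exist_ok=True)
        (path / "clade_tree.nwk").write_text(self.clade_tree.to_newick() + "\n")
        self.clades.to_csv(path / "clades.tsv", sep="\t", index=False)
        for clade, tree in self.species_trees.items():
            (path / "species_trees" / f"{clade}.nwk").write_text(tree.to_newick() + "\n")
        self.karyotypes.to_csv(path / "karyotypes.tsv", sep="\t", index=False)
        self.branch_tests.to_csv(path / "branch_tests.tsv", sep="\t", index=False)
        self.codon_tests.to_csv(path / "codon_tests.tsv", sep="\t", index=False)
        self.alignment_lengths.to_csv(path / "alignment_lengths.tsv", sep="\t", index=False)
        (path / "truth.json").write_text(json.dumps(self.truth, indent=2, default=str))


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items; deterministic."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_clade_system(config: ScenarioConfig) -> SyntheticStudy:
    """Generate the full study: painted clade tree, per-clade species trees,
    karyotypes and selection-test tables, with ground truth attached."""
    cfg = config
    rng_tree = _rng(cfg.seed, 0, 0)
    clade_tree = yule_tree(cfg.n_clades, rng_tree, depth=cfg.clade_tree_depth)
    # symmetric regime = the first n_symmetric tips in preorder: a basal,
    # possibly paraphyletic group, as in the land-plant tree
    tip_order = [n for n in clade_tree.preorder() if clade_tree.is_tip(n)]
    names = {node: f"clade{k + 1:02d}" for k, node in enumerate(tip_order)}
    clade_tree = Phylogeny(clade_tree.parent, clade_tree.blen, names)
    clade_names = [names[n] for n in tip_order]
    regimes = {
        name: (SYM if k < cfg.n_symmetric else ASYM)
        for k, name in enumerate(clade_names)
    }
    regime_map = paint_regimes(clade_tree, regimes, cfg.root_regime, (ASYM, SYM))

    n_cl = cfg.n_clades
    taxa_alloc = _allocate(cfg.n_taxa_total, np.ones(n_cl))
    karyo_alloc = _allocate(cfg.n_karyotyped_total, taxa_alloc.astype(float))
    karyo_alloc = np.maximum(karyo_alloc, 4)  # keep every clade analysable
    extra_seq = cfg.n_sequences_total - cfg.n_taxa_total
    asym_idx = [k for k, c in enumerate(clade_names) if regimes[c] == ASYM]
    extra_alloc = np.zeros(n_cl, dtype=int)
    if extra_seq > 0 and asym_idx:
        per, rem = divmod(extra_seq, len(asym_idx))
        for j, k in enumerate(asym_idx):
            extra_alloc[k] = per + (1 if j < rem else 0)

    clade_rows = []
    species_trees: dict[str, Phylogeny] = {}
    karyo_rows = []
    branch_rows = []
    codon_rows = []
    length_rows = []
    truth_clades = {}

    for k, clade in enumerate(clade_names):
        regime = regimes[clade]
        n_taxa = int(taxa_alloc[k])
        n_karyo = int(min(karyo_alloc[k], n_taxa))
        n_seq = n_taxa + int(extra_alloc[k])

        lo, hi = cfg.clade_age_range[regime]
        age = float(_rng(cfg.seed, k + 1, 1).uniform(lo, hi))
        tree = yule_tree(n_taxa, _rng(cfg.seed, k + 1, 2), depth=age)
        tree = Phylogeny(
            tree.parent,
            tree.blen,
            {n: f"{clade}_sp{lab[1:]}" for n, lab in tree.labels.items()},
        )
        species_trees[clade] = tree

        # log-scale Brownian evolution of mean chromosome size
        rng_tr = _rng(cfg.seed, k + 1, 3)
        s2 = cfg.bm_sigma2_log[regime]
        x = np.zeros(tree.n_nodes)
        x[tree.root] = rng_tr.normal(cfg.logsize_root_mean, cfg.logsize_root_sd)
        for node in tree.preorder():
            p = tree.parent[node]
            if p >= 0:
                x[node] = x[p] + rng_tr.normal(0.0, np.sqrt(s2 * tree.blen[node]))

        rng_k = _rng(cfg.seed, k + 1, 4)
        base_2n = int(rng_k.choice(cfg.base_2n_support))
        karyo_species = tree.tip_labels[:n_karyo]
        for sp in karyo_species:
            node = next(n for n in tree.tip_ids if tree.labels[n] == sp)
            size = float(np.exp(x[node]))
            two_n = base_2n * (2 if rng_k.random() < cfg.polyploidy_rate else 1)
            karyo_rows.append(
                {
                    "species": sp,
                    "clade": clade,
                    "regime": regime,
                    "2C_Mb": size * two_n,
                    "2n": two_n,
                }
            )

        # selection-test tables: gene tree with paralogue subtrees
        rng_s = _rng(cfg.seed, k + 1, 5)
        n_branches = 2 * n_seq - 2
        n_paralog_branches = 2 * int(extra_alloc[k])
        pb = cfg.p_branch[regime]
        for b in range(n_branches):
            ortho = b >= n_paralog_branches
            sig = rng_s.random() < pb
            p_val = (
                rng_s.uniform(0.0, cfg.alpha_branch)
                if sig
                else rng_s.uniform(cfg.alpha_branch, 1.0)
            )
            omega = 1.0 + rng_s.exponential(2.0) if sig else float(
                np.exp(rng_s.normal(-1.0, 0.5))
            )
            branch_rows.append(
                {
                    "clade": clade,
                    "branch_id": f"{clade}_b{b + 1}",
                    "omega": omega,
                    "p_value": p_val,
                    "orthologous": int(ortho),
                }
            )
        for region, n_cod in cfg.n_codons.items():
            pc = cfg.p_codon[regime][region]
            length_rows.append({"clade": clade, "region": region, "n_codons": n_cod})
            for ci in range(1, n_cod + 1):
                sig = rng_s.random() < pc
                p_val = (
                    rng_s.uniform(0.0, cfg.alpha_codon)
                    if sig
                    else rng_s.uniform(cfg.alpha_codon, 1.0)
                )
                codon_rows.append(
                    {
                        "clade": clade,
                        "region": region,
                        "codon_index": ci,
                        "p_value": p_val,
                        "omega": 1.0 + rng_s.exponential(1.0) if sig else float(
                            np.exp(rng_s.normal(-0.7, 0.4))
                        ),
                    }
                )

        clade_rows.append(
            {
                "clade": clade,
                "regime": regime,
                "n_taxa": n_taxa,
                "n_karyotyped": n_karyo,
                "n_sequences": n_seq,
                "age_myr": age,
            }
        )
        truth_clades[clade] = {
            "regime": regime,
            "age_myr": age,
            "bm_sigma2_log": s2,
            "p_branch": pb,
            "p_codon": cfg.p_codon[regime],
            "expected_F": {
                region: pb * cfg.p_codon[regime][region] for region in cfg.n_codons
            },
        }

    truth = {
        "config": asdict(cfg),
        "clade_level": {
            "model": cfg.response_model,
            "theta": cfg.theta,
            "alpha": cfg.alpha,
            "sigma2": cfg.sigma2,
        },
        "clades": truth_clades,
    }
    return SyntheticStudy(
        config=cfg,
        clade_tree=clade_tree,
        regime_map=regime_map,
        clades=pd.DataFrame(clade_rows),
        species_trees=species_trees,
        karyotypes=pd.DataFrame(karyo_rows),
        branch_tests=pd.DataFrame(branch_rows),
        codon_tests=pd.DataFrame(codon_rows),
        alignment_lengths=pd.DataFrame(length_rows),
        truth=truth,
    )


def simulate_clade_response(
    clade_tree: Phylogeny,
    regime_map: RegimeMap,
    config: ScenarioConfig,
    seed,
) -> dict[str, float]:
    """Draw a clade-level response directly under the scenario's generating
    model (the clade tree analogue of one observed column of clade
    statistics)."""
    theta = [config.theta[r] for r in regime_map.alphabet]
    params = {"theta": theta, "alpha": config.alpha, "sigma2": config.sigma2}
    if config.response_model in ("BM1", "BMS"):
        params["alpha"] = 0.0
        params["theta"] = float(np.mean(theta))
    return simulate_tips(clade_tree, regime_map, params, seed)


# ------------------------------------------------------------------ presets
def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named scenarios with fully specified ground truth.

    ``paper_like``
        Regime optima of the clade-level response set to the study-scale
        values (asymmetric 0.118, symmetric 0.058) with stationary SD 0.02,
        and species/selection parameters that land the clade statistics in
        the same range.
    ``null``
        Both regimes share one optimum (0.088, the midpoint) -- the type-I
        error scenario.
    ``strong_effect``
        Optimum gap of 4 stationary SDs -- the power/model-selection scenario.
    """
    paper_like = ScenarioConfig(name="paper_like")
    null = replace(
        paper_like,
        name="null",
        theta={ASYM: 0.088, SYM: 0.088},
        bm_sigma2_log={ASYM: 0.002, SYM: 0.002},
        clade_age_range={ASYM: (80.0, 160.0), SYM: (80.0, 160.0)},
        p_branch={ASYM: 0.32, SYM: 0.32},
        p_codon={
            ASYM: {"full": 0.015, "N": 0.5, "C": 0.004},
            SYM: {"full": 0.015, "N": 0.5, "C": 0.004},
        },
    )
    strong = replace(
        paper_like,
        name="strong_effect",
        theta={ASYM: 1.1, SYM: 0.1},
        alpha_rel=2.0,
        stationary_sd=0.25,
    )
    return {"null": null, "paper_like": paper_like, "strong_effect": strong}
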