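"""Synthetic expression compendia with planted independent-component structure.

The generator emulates a bacterial RNA-seq compendium of ~100 samples x
~3000 genes: a small number of sparse co-regulated gene modules whose
activities vary by growth condition (replicate group), a designated
reference condition used for centering, a transcription-factor (TF) gene
per module whose expression tracks the module activity, and a
RegPrecise-style regulon database that only partially matches the planted
modules. Every downstream stage (QC, ICA, thresholding, enrichment,
activity analysis) can be scored against the planted truth.

Model: the log2 expression of gene g in sample s is

    log2 x_gs = baseline + (M A)_gs + eps_gs,   eps ~ N(0, noise_sd)

with M (genes x modules) sparse — nonzero only on member genes — and A
(modules x samples) constant within a replicate group. Linear-scale
expression is 2**(log2 x), which resembles RPKM magnitudes for the
default baseline of 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium


class SyntheticConfigError(ValueError):
    """Infeasible generator parameterization."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-truth compendium generator.

    Defaults mirror the scale of a typical single-species compendium:
    3000 genes, 100 samples in 50 duplicate groups, 20 sparse modules.
    """

    n_genes: int = 3000
    n_samples: int = 100
    n_modules: int = 20
    module_size_range: tuple[int, int] = (5, 20)
    n_replicate_groups: int = 50
    replicates_per_group: int = 2
    reference_group: str = "grp00"
    weight_magnitude: float = 1.0
    noise_sd: float = 0.1
    activity_sd: float = 1.0
    regulon_jitter: float = 0.2
    seed: int = 0
    log_baseline: float = 8.0
    # "positive" (default): member weights share a sign, as in real
    # iModulons where members are co-transcribed/co-regulated operons;
    # this also keeps the weight vector's heavy tail one-sided, which the
    # skewness arm of the K² statistic detects at any vector length.
    # "random": independent +/- signs per member.
    weight_sign: str = "positive"
    # Optional condition effects: module index -> {group id: activity shift}.
    activity_shifts: dict | None = None

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise SyntheticConfigError(f"bad module_size_range {self.module_size_range}")
        if self.n_modules * hi > self.n_genes:
            raise SyntheticConfigError(
                f"{self.n_modules} modules of up to {hi} genes exceed {self.n_genes} genes"
            )
        if self.n_replicate_groups * self.replicates_per_group != self.n_samples:
            raise SyntheticConfigError(
                "n_samples must equal n_replicate_groups * replicates_per_group"
            )
        if self.replicates_per_group < 2:
            raise SyntheticConfigError("replicates_per_group must be >= 2 for replicate QC")
        if not 0.0 <= self.regulon_jitter <= 1.0:
            raise SyntheticConfigError("regulon_jitter must lie in [0, 1]")
        if self.weight_sign not in ("random", "positive"):
            raise SyntheticConfigError(f"unknown weight_sign {self.weight_sign!r}")
        if self.reference_group not in self.group_ids():
            raise SyntheticConfigError(f"reference group {self.reference_group!r} not among groups")

    def group_ids(self) -> list[str]:
        return [f"grp{i:02d}" for i in range(self.n_replicate_groups)]


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the generated compendium."""

    config: SyntheticConfig
    planted_M: pd.DataFrame  # genes x modules, zero off the member genes
    planted_A: pd.DataFrame  # modules x samples
    modules: dict[str, set[str]]  # module id -> member gene ids (incl. TF)
    tf_genes: dict[str, str]  # module id -> TF gene id
    regulons: dict[str, set[str]]  # regulator name -> gene ids (jittered)
    compendium: ExpressionCompendium  # linear-scale RPKM-like expression

    @property
    def gene_ids(self) -> list[str]:
        return list(self.planted_M.index)

    def module_snr(self) -> dict[str, float]:
        """Per-module signal-to-noise: var of the module's log-space
        contribution over its member-gene rows, divided by noise_sd**2."""
        out = {}
        for mod, members in self.modules.items():
            w = self.planted_M.loc[sorted(members), mod].to_numpy()
            a = self.planted_A.loc[mod].to_numpy()
            out[mod] = float(np.var(np.outer(w, a)) / self.config.noise_sd**2) \
                if self.config.noise_sd > 0 else math.inf
        return out


def _sample_modules(cfg: SyntheticConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint member-gene index sets, one per module."""
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    pool = rng.permutation(cfg.n_genes)
    sets, offset = [], 0
    for s in sizes:
        sets.append(np.sort(pool[offset:offset + s]))
        offset += s
    return sets


def generate_compendium(config: SyntheticConfig) -> SyntheticTruth:
    """Generate a compendium with planted module structure.

    Deterministic given ``config.seed``. The reference group's activities
    are subtracted from every group at generation time, so ``planted_A``
    is already expressed relative to the reference baseline and
    log-transform + reference centering recovers M.A up to noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    groups = config.group_ids()
    sample_ids, sample_groups = [], []
    for g in groups:
        for r in range(config.replicates_per_group):
            sample_ids.append(f"{g}_r{r + 1}")
            sample_groups.append(g)

    module_ids = [f"mod{j + 1:02d}" for j in range(config.n_modules)]
    member_idx = _sample_modules(config, rng)

    # Member weights: +/- weight_magnitude * (1 + U(0, 0.2)); the first
    # member of each module is the module's TF gene and is kept positive
    # so its expression tracks the activity with r = +1 at zero noise.
    M = np.zeros((config.n_genes, config.n_modules))
    modules: dict[str, set[str]] = {}
    tf_genes: dict[str, str] = {}
    for j, idx in enumerate(member_idx):
        mags = config.weight_magnitude * (1.0 + rng.uniform(0.0, 0.2, size=idx.size))
        if config.weight_sign == "random":
            signs = rng.choice([-1.0, 1.0], size=idx.size)
        else:
            signs = np.ones(idx.size)
        w = signs * mags
        tf_pos = int(rng.integers(idx.size))
        w[tf_pos] = abs(w[tf_pos])
        M[idx, j] = w
        modules[module_ids[j]] = {gene_ids[i] for i in idx}
        tf_genes[module_ids[j]] = gene_ids[idx[tf_pos]]

    # Activities: one draw per replicate group, shared by its replicates.
    A_groups = rng.normal(0.0, config.activity_sd, size=(config.n_modules, len(groups)))
    if config.activity_shifts:
        gindex = {g: k for k, g in enumerate(groups)}
        for mod_j, shifts in config.activity_shifts.items():
            for grp, delta in shifts.items():
                A_groups[mod_j, gindex[grp]] += delta
    ref_col = groups.index(config.reference_group)
    A_groups = A_groups - A_groups[:, [ref_col]]
    group_of = np.array([groups.index(g) for g in sample_groups])
    A = A_groups[:, group_of]

    log_signal = config.log_baseline + M @ A
    noise = rng.normal(0.0, config.noise_sd, size=log_signal.shape) \
        if config.noise_sd > 0 else 0.0
    expression = np.exp2(log_signal + noise)

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "project": "synthetic",
            "condition": sample_groups,
            "replicate_group": sample_groups,
            "is_reference": [g == config.reference_group for g in sample_groups],
        }
    )
    compendium = ExpressionCompendium(
        values=pd.DataFrame(expression, index=gene_ids, columns=sample_ids),
        metadata=metadata,
        state="raw",
    )
    truth = SyntheticTruth(
        config=config,
        planted_M=pd.DataFrame(M, index=gene_ids, columns=module_ids),
        planted_A=pd.DataFrame(A, index=module_ids, columns=sample_ids),
        modules=modules,
        tf_genes=tf_genes,
        regulons={},
        compendium=compendium,
    )
    truth.regulons = derive_regulons(truth, config.regulon_jitter, rng=rng)
    return truth


def derive_regulons(
    truth: SyntheticTruth,
    jitter: float,
    rng: np.random.Generator | None = None,
) -> dict[str, set[str]]:
    """Regulons = planted modules with ``ceil(jitter * size)`` members
    swapped for random non-member genes (size-preserving). jitter = 0
    reproduces the modules exactly; jitter = 1 replaces every member.
    """
    if not 0.0 <= jitter <= 1.0:
        raise SyntheticConfigError("jitter must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    all_genes = np.array(truth.gene_ids)
    regulons: dict[str, set[str]] = {}
    for mod, members in truth.modules.items():
        members_sorted = sorted(members)
        n_swap = math.ceil(jitter * len(members_sorted))
        keep = list(rng.choice(members_sorted, size=len(members_sorted) - n_swap, replace=False))
        outside = np.array([g for g in all_genes if g not in members])
        added = list(rng.choice(outside, size=n_swap, replace=False)) if n_swap else []
        regulons[f"TF_{mod}"] = set(keep) | set(added)
    return regulons


# -- on-disk layout ------------------------------------------------------------

def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write the generated compendium and ground truth as plain TSVs."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.compendium.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    truth.compendium.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.planted_M.to_csv(out / "planted_M.tsv", sep="\t", index_label="gene_id")
    truth.planted_A.to_csv(out / "planted_A.tsv", sep="\t", index_label="module")
    write_regulons_tsv(truth.regulons, out / "regulons.tsv")
    pd.DataFrame(
        {"module": list(truth.tf_genes), "tf_gene": list(truth.tf_genes.values())}
    ).to_csv(out / "tf_genes.tsv", sep="\t", index=False)


def write_regulons_tsv(regulons: dict[str, set[str]], path) -> None:
    rows = [(reg, gene) for reg in sorted(regulons) for gene in sorted(regulons[reg])]
    pd.DataFrame(rows, columns=["regulator", "gene"]).to_csv(path, sep="\t", index=False)
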