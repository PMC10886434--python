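"""iModulon member-gene extraction by iterative D'Agostino K² thresholding.

Each robust component assigns a signed weight to every gene. Most weights
are near-zero background; member genes form a heavy tail. The D'Agostino-
Pearson omnibus statistic K² = Z²(skewness) + Z²(kurtosis) measures how
far the current weight vector is from normality, so the member genes are
found by stripping the largest-|weight| gene one at a time until the
remaining weights look normal (K² at or below the cutoff, default 550).
The removed genes are the members; the threshold is the smallest removed
|weight|, making membership a strict-inequality predicate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ica import IcaDecomposition

#: below this length the skewness/kurtosis standardizations are unreliable
MIN_K2_LENGTH = 9

DEFAULT_K2_CUTOFF = 550.0


class K2Undefined(ValueError):
    """K² statistic undefined (too few values or zero variance)."""


def dagostino_k2(values) -> float:
    """D'Agostino-Pearson omnibus normality statistic.

    Raises :class:`K2Undefined` for vectors shorter than
    :data:`MIN_K2_LENGTH` or with zero variance, rather than returning a
    number.
    """
    v = np.asarray(values, dtype=float)
    if v.size < MIN_K2_LENGTH:
        raise K2Undefined(f"need >= {MIN_K2_LENGTH} values, got {v.size}")
    if np.ptp(v) == 0:
        raise K2Undefined("zero-variance vector")
    with warnings.catch_warnings():
        # kurtosistest warns for n < 20; the min-length floor already
        # guards the worst cases and the statistic is still defined
        warnings.simplefilter("ignore")
        stat, _ = stats.normaltest(v)
    return float(stat)


@dataclass
class IModulon:
    """One component's gene weights with its extracted member set."""

    id: str
    weights: pd.Series  # per-gene signed weights (one M column)
    threshold: float  # smallest removed |weight|; +inf when empty
    members: set[str]
    k2_trace: list[tuple[str, float]] = field(default_factory=list)
    regulator_label: str = ""
    status: str = "uncharacterized"  # regulon_enrichment | motif_comparison | uncharacterized
    function_label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)

    def member_weights(self) -> pd.Series:
        return self.weights.loc[sorted(self.members)]


def compute_threshold(
    weights: pd.Series,
    cutoff: float = DEFAULT_K2_CUTOFF,
    min_length: int = MIN_K2_LENGTH,
) -> tuple[float, set[str], list[tuple[str, float]]]:
    """Iterative K² stripping of a gene-weight vector.

    While K² of the surviving weights exceeds ``cutoff`` and more than
    ``min_length`` genes survive, the gene with the largest |weight| is
    removed (ties broken by compendium order, earliest first) and the
    statistic recomputed. Returns ``(threshold, members, trace)`` where
    members are the removed genes, threshold is the smallest removed
    |weight| (+inf when nothing was removed, an empty iModulon), and the
    trace lists (removed gene, K² before its removal).
    """
    if len(weights) < min_length:
        raise K2Undefined(f"need >= {min_length} genes, got {len(weights)}")
    w = weights.to_numpy(dtype=float).copy()
    gene_order = list(weights.index)
    alive = np.ones(w.size, dtype=bool)
    trace: list[tuple[str, float]] = []
    removed_abs: list[float] = []
    while alive.sum() > min_length:
        try:
            stat = dagostino_k2(w[alive])
        except K2Undefined:
            break
        if stat <= cutoff:
            break
        absw = np.where(alive, np.abs(w), -np.inf)
        # argmax returns the first index on ties: earliest compendium order
        top = int(absw.argmax())
        alive[top] = False
        trace.append((gene_order[top], stat))
        removed_abs.append(abs(w[top]))
    threshold = min(removed_abs) if removed_abs else math.inf
    members = {g for g, _ in trace}
    return threshold, members, trace


def extract_imodulons(
    dec: IcaDecomposition,
    cutoff: float = DEFAULT_K2_CUTOFF,
    min_length: int = MIN_K2_LENGTH,
) -> list[IModulon]:
    """Apply K² thresholding to every column of the M matrix."""
    ims = []
    for comp in dec.component_ids():
        col = dec.M[comp]
        threshold, members, trace = compute_threshold(col, cutoff=cutoff, min_length=min_length)
        ims.append(IModulon(id=comp, weights=col, threshold=threshold,
                            members=members, k2_trace=trace))
    return ims


def imodulon_gene_table(ims: list[IModulon]) -> pd.DataFrame:
    """Long-format per-iModulon gene table (gene id, weight, member flag)."""
    rows = []
    for im in ims:
        for gene, wt in im.weights.items():
            rows.append(
                {
                    "imodulon": im.id,
                    "gene_id": gene,
                    "weight": float(wt),
                    "member": gene in im.members,
                    "threshold": im.threshold,
                }
            )
    return pd.DataFrame(rows)


def write_im_genes(ims: list[IModulon], path, members_only: bool = True) -> None:
    table = imodulon_gene_table(ims)
    if members_only:
        table = table[table["member"]]
    table.to_csv(path, index=False)
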