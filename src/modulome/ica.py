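"""Robust independent component analysis of the centered compendium.

A single FastICA run (log-cosh contrast, parallel fixed-point search,
tolerance 1e-7) is not reproducible across random initializations, so the
decomposition is repeated from many random restarts and the pooled source
vectors are clustered by density on the distance d = 1 - |Pearson r|.
Clusters that recur in at least half of the restarts are considered
robust; each contributes one component — its centrotype, the member
source minimizing the summed distance to the rest of its cluster. The
activity matrix A is then the least-squares projection of the data onto
the retained components, which makes M.A a well-defined reconstruction
and the explained variance coherent.

Dimensionality is selected by sweeping candidate dimensions and counting
robust components that are not dominated by a single gene (the OptICA
idea): the smallest dimension maximizing that count wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning


class IcaError(RuntimeError):
    pass


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index.astype(str)), list(X.columns.astype(str))
    X = np.asarray(X, dtype=float)
    return X, [f"g{i}" for i in range(X.shape[0])], [f"s{j}" for j in range(X.shape[1])]


def _canonicalize_columns(S: np.ndarray) -> np.ndarray:
    """Unit L2 norm per column; the largest-|weight| entry made positive."""
    S = S.copy()
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    S /= norms
    top = np.abs(S).argmax(axis=0)
    flip = S[top, np.arange(S.shape[1])] < 0
    S[:, flip] *= -1.0
    return S


@dataclass
class IcaRunRecord:
    seed: int
    n_iter: int
    converged: bool


def run_ica_once(
    X,
    k: int,
    seed: int,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[np.ndarray, IcaRunRecord]:
    """One FastICA decomposition of the genes x samples matrix X.

    Whitening retains exactly ``k`` principal components of the sample
    dimension; sources (columns of the returned genes x k array) are
    unit-norm with a positive dominant weight. Deterministic given seed.
    Non-convergence within ``max_iter`` fixed-point steps is flagged on
    the run record rather than raised.
    """
    Xv, _, _ = _as_matrix(X)
    n_genes, n_samples = Xv.shape
    if not 1 <= k <= min(n_genes, n_samples):
        raise IcaError(f"dimension k={k} outside [1, min(genes, samples)={min(n_genes, n_samples)}]")
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=int(seed),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(Xv)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        warnings.warn(f"FastICA run (seed={seed}, k={k}) did not converge in {max_iter} steps")
    record = IcaRunRecord(seed=int(seed), n_iter=int(getattr(ica, "n_iter_", max_iter)), converged=converged)
    return _canonicalize_columns(S), record


@dataclass
class IcaDecomposition:
    """Robust decomposition X ~ M.A with per-component reproducibility."""

    M: pd.DataFrame  # genes x components, unit-norm columns
    A: pd.DataFrame  # components x samples (least-squares projection)
    dimension: int  # requested k per restart
    restarts: int
    seeds: list[int]
    robustness: pd.Series  # fraction of restarts containing each component
    runs: list[IcaRunRecord] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.M.shape[1]

    def component_ids(self) -> list[str]:
        return list(self.M.columns)


def robust_ica(
    X,
    k: int,
    n_restarts: int = 100,
    base_seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 1000,
    cluster_eps: float = 0.2,
    min_restart_fraction: float = 0.5,
    resample: bool = True,
) -> IcaDecomposition:
    """Multi-restart FastICA with density-based component clustering.

    Sources pooled over ``n_restarts`` runs (seeds base_seed ..
    base_seed + n_restarts - 1) are clustered by DBSCAN on
    d = 1 - |Pearson r| with neighborhood radius ``cluster_eps``; a
    cluster is kept when its members span at least
    ``ceil(min_restart_fraction * n_restarts)`` distinct restarts. Zero
    robust clusters is a valid outcome (pure-noise input) and yields an
    empty decomposition with a warning.

    With ``resample`` (default) each restart bootstraps the sample
    columns before decomposing, so a component must recur under data
    perturbation as well as under re-initialization to count as robust.
    Random re-initialization alone cannot discriminate genuine structure:
    on a fixed matrix the fixed points of the contrast are properties of
    the data, and even pure-noise components recur across restarts.
    """
    if n_restarts < 2:
        raise IcaError("n_restarts must be >= 2")
    Xv, gene_ids, sample_ids = _as_matrix(X)
    seeds = [int(base_seed) + i for i in range(n_restarts)]
    pooled, origin, runs = [], [], []
    for s in seeds:
        if resample:
            rng = np.random.default_rng(s)
            cols = rng.integers(Xv.shape[1], size=Xv.shape[1])
            Xr = Xv[:, cols]
        else:
            Xr = Xv
        S, rec = run_ica_once(Xr, k, s, tol=tol, max_iter=max_iter)
        runs.append(rec)
        pooled.append(S)
        origin.extend([s] * S.shape[1])
    P = np.hstack(pooled)  # genes x (k * restarts)
    origin = np.asarray(origin)

    # d = 1 - |r| between pooled source vectors
    C = np.corrcoef(P.T)
    D = np.clip(1.0 - np.abs(C), 0.0, None)
    np.fill_diagonal(D, 0.0)

    min_members = int(np.ceil(min_restart_fraction * n_restarts))
    labels = DBSCAN(eps=cluster_eps, min_samples=min_members, metric="precomputed").fit_predict(D)

    centro_idx, robustness = [], []
    for lab in sorted(set(labels) - {-1}):
        members = np.flatnonzero(labels == lab)
        coverage = len(set(origin[members]))
        if coverage < min_members:
            continue
        sub = D[np.ix_(members, members)]
        centro_idx.append(members[sub.sum(axis=1).argmin()])
        robustness.append(coverage / n_restarts)

    comp_ids = [f"IM-{i + 1}" for i in range(len(centro_idx))]
    if not centro_idx:
        warnings.warn("no robust components found; returning an empty decomposition")
        M = pd.DataFrame(np.zeros((len(gene_ids), 0)), index=gene_ids)
        A = pd.DataFrame(np.zeros((0, len(sample_ids))), columns=sample_ids)
        return IcaDecomposition(M, A, k, n_restarts, seeds, pd.Series(dtype=float), runs)

    Mv = _canonicalize_columns(P[:, centro_idx])
    Av, *_ = np.linalg.lstsq(Mv, Xv, rcond=None)
    M = pd.DataFrame(Mv, index=gene_ids, columns=comp_ids)
    A = pd.DataFrame(Av, index=comp_ids, columns=sample_ids)
    rob = pd.Series(robustness, index=comp_ids, name="robustness")
    return IcaDecomposition(M, A, k, n_restarts, seeds, rob, runs)


def explained_variance(X, dec: IcaDecomposition) -> float:
    """1 - ||X - M.A||_F^2 / ||X||_F^2; zero for an empty decomposition."""
    Xv, _, _ = _as_matrix(X)
    if dec.n_components == 0:
        return 0.0
    resid = Xv - dec.M.to_numpy() @ dec.A.to_numpy()
    denom = float(np.sum(Xv**2))
    if denom == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / denom)


def is_single_gene(weights: np.ndarray, dominance: float = 0.7) -> bool:
    """A component is single-gene-like when one gene carries more than
    ``dominance`` of the column's squared norm."""
    w2 = np.asarray(weights, dtype=float) ** 2
    total = w2.sum()
    return bool(total > 0 and w2.max() / total > dominance)


@dataclass
class OpticaResult:
    table: pd.DataFrame  # per candidate dimension: robust / single-gene counts
    selected_dimension: int
    decomposition: IcaDecomposition  # the decomposition at the selected dimension
    rationale: str = ""


def optica(
    X,
    candidate_dimensions: list[int],
    n_restarts: int = 100,
    base_seed: int = 0,
    dominance: float = 0.7,
    **robust_kwargs,
) -> OpticaResult:
    """Sweep candidate dimensions; pick the smallest one maximizing the
    number of robust components not dominated by a single gene."""
    if not candidate_dimensions:
        raise IcaError("candidate_dimensions is empty")
    Xv, _, _ = _as_matrix(X)
    kmax = min(Xv.shape)
    rows, decs = [], {}
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no robust components")
        for k in sorted(set(candidate_dimensions)):
            if k > kmax:
                raise IcaError(f"candidate dimension {k} exceeds min(genes, samples)={kmax}")
            dec = robust_ica(Xv, k, n_restarts=n_restarts,
                             base_seed=base_seed + 10_000 * k, **robust_kwargs)
            n_single = sum(
                is_single_gene(dec.M.iloc[:, j].to_numpy(), dominance)
                for j in range(dec.n_components)
            )
            rows.append(
                {
                    "dimension": k,
                    "n_robust": dec.n_components,
                    "n_single_gene": n_single,
                    "n_non_single_gene": dec.n_components - n_single,
                }
            )
            decs[k] = dec
    table = pd.DataFrame(rows)
    if (table["n_robust"] == 0).all():
        raise IcaError(f"no robust components at any candidate dimension:\n{table}")
    best_count = table["n_non_single_gene"].max()
    selected = int(table.loc[table["n_non_single_gene"] == best_count, "dimension"].min())
    rationale = (
        f"selected k={selected}: smallest dimension with the maximal count "
        f"({best_count}) of non-single-gene robust components"
    )
    # Re-index component ids of the winning decomposition for presentation.
    dec = decs[selected]
    return OpticaResult(table=table, selected_dimension=selected, decomposition=dec, rationale=rationale)


def write_decomposition(dec: IcaDecomposition, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dec.M.to_csv(out / "M.tsv", sep="\t", index_label="gene_id")
    dec.A.to_csv(out / "A.tsv", sep="\t", index_label="component")
    meta = pd.DataFrame(
        {
            "component": dec.component_ids(),
            "robustness": [float(dec.robustness[c]) for c in dec.component_ids()],
        }
    )
    meta.to_csv(out / "components.tsv", sep="\t", index=False)
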