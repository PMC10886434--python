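"""Expression-compendium container and tabular I/O.

The compendium is a genes x samples matrix of RPKM-scale values together
with per-sample metadata (project, condition, replicate group, reference
flag). The matrix passes through three states: ``raw`` (linear RPKM),
``log`` (log2(x + pseudocount)) and ``centered`` (log values relative to
the mean of the reference-condition samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

METADATA_COLUMNS = ["sample_id", "project", "condition", "replicate_group", "is_reference"]

VALID_STATES = ("raw", "log", "centered")
# Only forward transitions are allowed.
_STATE_ORDER = {s: i for i, s in enumerate(VALID_STATES)}


class CompendiumError(ValueError):
    """Malformed compendium data or an invalid state transition."""


@dataclass
class ExpressionCompendium:
    """Genes x samples expression matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    metadata
        DataFrame with one row per sample; must contain the columns in
        :data:`METADATA_COLUMNS` and cover exactly the samples in
        ``values`` (same order).
    state
        One of ``raw``, ``log``, ``centered``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    state: str = "raw"
    log_pseudocount: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise CompendiumError(f"unknown state {self.state!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise CompendiumError(f"duplicated gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise CompendiumError("duplicated sample ids in expression matrix")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise CompendiumError(f"metadata missing columns: {missing}")
        if self.metadata["sample_id"].duplicated().any():
            raise CompendiumError("duplicated sample ids in metadata")
        meta_samples = list(self.metadata["sample_id"])
        if meta_samples != list(self.values.columns):
            raise CompendiumError(
                "metadata sample order does not match expression matrix columns"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def reference_samples(self) -> list[str]:
        mask = self.metadata["is_reference"].astype(bool)
        return list(self.metadata.loc[mask, "sample_id"])

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map replicate-group id -> ordered list of sample ids."""
        groups: dict[str, list[str]] = {}
        for sid, grp in zip(self.metadata["sample_id"], self.metadata["replicate_group"]):
            groups.setdefault(str(grp), []).append(sid)
        return groups

    def with_values(self, values: pd.DataFrame, state: str) -> "ExpressionCompendium":
        """Return a copy with new values in a later (or equal) state."""
        if _STATE_ORDER[state] < _STATE_ORDER[self.state]:
            raise CompendiumError(f"illegal state transition {self.state} -> {state}")
        return replace(self, values=values, state=state)


def read_expression_tsv(path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes x samples table (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_metadata_tsv(path, sep: str = "\t") -> pd.DataFrame:
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "replicate_group": str})
    meta["is_reference"] = meta["is_reference"].astype(bool)
    return meta


def load_compendium(expression_path, metadata_path, state: str = "raw") -> ExpressionCompendium:
    values = read_expression_tsv(expression_path)
    metadata = read_metadata_tsv(metadata_path)
    # Align column order to metadata order; genes absent in either side are kept as-is.
    values = values[metadata["sample_id"].tolist()]
    return ExpressionCompendium(values=values, metadata=metadata, state=state)


def merge_sources(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge several genes x samples tables on their shared gene set.

    Genes absent from any source are dropped (ICA needs a complete
    matrix); this is lossy and intentional.
    """
    if not tables:
        raise CompendiumError("no tables to merge")
    shared = tables[0].index
    for t in tables[1:]:
        shared = shared.intersection(t.index)
    return pd.concat([t.loc[shared] for t in tables], axis=1)


def write_expression_tsv(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)
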