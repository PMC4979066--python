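"""Expression-matrix I/O, validation, filtering and conspecific collapsing.

The matrix holds normalized expression values (genes x samples); missing
cells mark genes absent from a sample's transcriptome assembly.  Species with
several sequenced accessions are collapsed to their arithmetic mean before
any species-level analysis, and genes are kept only when observed in enough
species for the comparative methods to be informative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMap",
    "read_expression",
    "read_sample_map",
    "collapse_conspecifics",
    "filter_genes",
    "transform",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized expression.

    ``data`` is a float DataFrame (index = gene ids, columns = sample or
    species ids) with NaN marking missing cells.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            raise ValueError(f"duplicate gene ids: "
                             f"{sorted(df.index[df.index.duplicated()])}")
        if df.columns.duplicated().any():
            raise ValueError(f"duplicate sample ids: "
                             f"{sorted(df.columns[df.columns.duplicated()])}")
        vals = df.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if not np.all(np.isfinite(vals[present])):
            raise ValueError("non-finite expression values")
        if np.any(vals[present] < 0):
            raise ValueError("negative expression values")
        if present.size and not present.any(axis=1).all():
            bad = df.index[~present.any(axis=1)]
            raise ValueError(f"genes entirely missing: {list(bad[:5])}")
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data.to_numpy())

    @property
    def missing_fraction(self) -> float:
        m = self.missing_mask
        return float(m.mean()) if m.size else 0.0

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def species_counts(self) -> pd.Series:
        """Number of non-missing columns per gene."""
        return self.data.notna().sum(axis=1)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


@dataclass
class SampleMap:
    """sample id -> species label, with an optional tissue tag."""

    species: dict = field(default_factory=dict)
    tissue: dict = field(default_factory=dict)

    def species_of(self, sample_id: str) -> str:
        return self.species[sample_id]

    def samples_for(self, species_label: str) -> list[str]:
        return [s for s, sp in self.species.items() if sp == species_label]

    @property
    def species_labels(self) -> list[str]:
        seen = []
        for sp in self.species.values():
            if sp not in seen:
                seen.append(sp)
        return seen

    def validate_against(self, X: ExpressionMatrix) -> None:
        missing = [s for s in X.sample_ids if s not in self.species]
        if missing:
            raise ValueError(f"samples absent from sample map: {missing}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tspecies\ttissue\n")
            for s, sp in self.species.items():
                fh.write(f"{s}\t{sp}\t{self.tissue.get(s, '')}\n")


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id; blanks = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    X = ExpressionMatrix(df)
    log.info("read expression matrix: %d genes x %d samples, %.1f%% missing",
             X.n_genes, X.n_samples, 100 * X.missing_fraction)
    return X


def read_sample_map(path) -> SampleMap:
    """Read a sample map TSV with columns sample_id, species[, tissue]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = list(df.columns)
    if "sample_id" not in cols or "species" not in cols:
        raise ValueError("sample map needs 'sample_id' and 'species' columns")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample map")
    smap = SampleMap()
    for _, row in df.iterrows():
        smap.species[row["sample_id"]] = row["species"]
        if "tissue" in cols and row.get("tissue", ""):
            smap.tissue[row["sample_id"]] = row["tissue"]
    return smap


def collapse_conspecifics(X: ExpressionMatrix, smap: SampleMap) -> ExpressionMatrix:
    """Average expression over conspecific accessions.

    Each species column is the arithmetic mean of that species' non-missing
    samples per gene; a species cell is missing only when every conspecific
    cell is missing.
    """
    smap.validate_against(X)
    groups = {}
    for s in X.sample_ids:
        groups.setdefault(smap.species_of(s), []).append(s)
    out = {}
    for sp, samples in groups.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            out[sp] = X.data[samples].mean(axis=1, skipna=True)
    collapsed = pd.DataFrame(out, index=X.data.index)
    # a gene entirely missing at species level can only arise if it was
    # entirely missing at sample level, which the invariant forbids
    return ExpressionMatrix(collapsed)


def filter_genes(X: ExpressionMatrix, min_species: int = 30) -> ExpressionMatrix:
    """Keep genes observed in at least ``min_species`` columns (inclusive)."""
    if min_species < 2:
        raise ValueError("min_species must be >= 2")
    keep = X.species_counts() >= min_species
    if not keep.any():
        raise ValueError(
            f"no gene present in >= {min_species} species; lower min_species "
            f"(max observed: {int(X.species_counts().max())})")
    kept = ExpressionMatrix(X.data.loc[keep])
    log.info("gene filter: kept %d / %d genes (min_species=%d)",
             kept.n_genes, X.n_genes, min_species)
    return kept


def transform(X: ExpressionMatrix, mode: str = "none") -> ExpressionMatrix:
    """Value transform: ``none`` (identity) or ``log2p1`` (log2(x+1)).

    Spearman-based distances are invariant under any strictly monotone
    transform, so RRBL results do not depend on this choice; OU fits operate
    on the transformed scale and do.
    """
    if mode == "none":
        return ExpressionMatrix(X.data.copy())
    if mode == "log2p1":
        return ExpressionMatrix(np.log2(X.data + 1.0))
    raise ValueError(f"unknown transform mode: {mode!r}")
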