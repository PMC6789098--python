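"""Count-matrix container and plain-text I/O.

The genes x cells integer count matrix is the interchange object for every
stage of the framework: parameter estimation, simulation, normalisation and
DE testing all consume and produce :class:`CountMatrix`.  Spike-in rows
(ERCC-style synthetic transcripts) travel inside the same matrix, flagged
per gene, and are split off before any biological computation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


def _as_id_array(ids: Sequence[str], n: int, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or arr.size != n:
        raise CountMatrixError(f"{what}: expected {n} ids, got shape {arr.shape}")
    if len(set(arr)) != n:
        raise CountMatrixError(f"duplicate {what}")
    return arr.astype(str)


@dataclass
class CountMatrix:
    """Genes x cells count matrix with ids and per-gene spike-in flags.

    Parameters
    ----------
    counts
        Non-negative (genes, cells) array. Integral unless
        ``allow_float=True`` (used for imputed matrices that only feed
        size-factor estimation, never DE testing).
    gene_ids, cell_ids
        Unique string identifiers.
    is_spike
        Boolean flag per gene; default all ``False``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_spike: np.ndarray = field(default=None)  # type: ignore[assignment]
    allow_float: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be 2-D (genes x cells)")
        if self.counts.size and self.counts.min() < 0:
            raise CountMatrixError("negative counts")
        if not self.allow_float:
            if not np.issubdtype(self.counts.dtype, np.integer):
                rounded = np.rint(self.counts)
                if not np.allclose(self.counts, rounded, atol=1e-8):
                    raise CountMatrixError("non-integral counts")
                self.counts = rounded.astype(np.int64)
        n_genes, n_cells = self.counts.shape
        self.gene_ids = _as_id_array(self.gene_ids, n_genes, "gene ids")
        self.cell_ids = _as_id_array(self.cell_ids, n_cells, "cell ids")
        if self.is_spike is None:
            self.is_spike = np.zeros(n_genes, dtype=bool)
        self.is_spike = np.asarray(self.is_spike, dtype=bool)
        if self.is_spike.shape != (n_genes,):
            raise CountMatrixError("is_spike length mismatch")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[idx],
            self.gene_ids[idx],
            self.cell_ids,
            self.is_spike[idx],
            allow_float=self.allow_float,
        )

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.is_spike,
            allow_float=self.allow_float,
        )

    def split_spikes(self) -> "SplitCounts":
        """Separate biological genes from spike-in rows."""
        return SplitCounts(
            genes=self.subset_genes(~self.is_spike),
            spikes=self.subset_genes(self.is_spike),
        )

    # -- I/O -------------------------------------------------------------
    def to_mtx(self, prefix: str) -> None:
        """Write ``<prefix>.mtx`` plus gene/cell id files.

        Spike flags are encoded in ``<prefix>.genes.tsv`` as a second column.
        """
        mmwrite(prefix + ".mtx", coo_matrix(self.counts), field="integer"
                if not self.allow_float else "real")
        pd.DataFrame({"gene_id": self.gene_ids, "is_spike": self.is_spike.astype(int)}
                     ).to_csv(prefix + ".genes.tsv", sep="\t", index=False)
        pd.DataFrame({"cell_id": self.cell_ids}).to_csv(
            prefix + ".cells.tsv", sep="\t", index=False)

    @classmethod
    def from_mtx(cls, prefix: str, spike_prefix: str = "ERCC-") -> "CountMatrix":
        counts = np.asarray(mmread(prefix + ".mtx").todense())
        genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")
        cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")
        gene_ids = genes["gene_id"].astype(str).to_numpy()
        if "is_spike" in genes.columns:
            is_spike = genes["is_spike"].astype(bool).to_numpy()
        else:
            is_spike = np.array([g.startswith(spike_prefix) for g in gene_ids])
        return cls(counts, gene_ids, cells["cell_id"].astype(str).to_numpy(), is_spike)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str, spike_prefix: str = "ERCC-",
                 spike_list: Sequence[str] | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = df.index.astype(str).to_numpy()
        if spike_list is not None:
            is_spike = np.isin(gene_ids, list(spike_list))
        else:
            is_spike = np.array([g.startswith(spike_prefix) for g in gene_ids])
        return cls(df.to_numpy(), gene_ids, df.columns.astype(str).to_numpy(), is_spike)


class SplitCounts(NamedTuple):
    genes: CountMatrix
    spikes: CountMatrix


def simple_count_matrix(counts, prefix: str = "g", cell_prefix: str = "c") -> CountMatrix:
    """Build a CountMatrix with auto-generated ids (convenience for tests/fixtures)."""
    counts = np.asarray(counts)
    g, c = counts.shape
    return CountMatrix(
        counts,
        np.array([f"{prefix}{i}" for i in range(g)]),
        np.array([f"{cell_prefix}{j}" for j in range(c)]),
    )
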