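"""Aligned sparse cells x features matrices of edits, reads and rates.

The container mirrors the layout used throughout single-cell tooling: rows
are cell barcodes (or pseudocell/pseudobulk identifiers), columns are
features (genes or isoforms), and three label-aligned sparse matrices hold
edit counts, read counts and the derived rate (EPR or EditsC).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["CellFeatureMatrix"]


def _to_csr(x) -> sp.csr_matrix:
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


@dataclass
class CellFeatureMatrix:
    """Label-aligned sparse matrices of edits, reads and rate per cell/feature.

    ``edits`` holds integer counts before Stamp normalization and
    non-negative reals after; ``rate`` is zero wherever ``reads`` falls
    below the read-depth mask that produced it.
    """

    barcodes: list[str]
    features: list[str]
    edits: sp.csr_matrix
    reads: sp.csr_matrix
    rate: sp.csr_matrix | None = field(default=None)

    def __post_init__(self) -> None:
        self.edits = _to_csr(self.edits)
        self.reads = _to_csr(self.reads)
        if self.rate is not None:
            self.rate = _to_csr(self.rate)
        shape = (len(self.barcodes), len(self.features))
        for name in ("edits", "reads", "rate"):
            m = getattr(self, name)
            if m is not None and m.shape != shape:
                raise ValueError(
                    f"{name} matrix shape {m.shape} does not match labels {shape}"
                )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.barcodes), len(self.features))

    def edits_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edits.toarray(), index=self.barcodes, columns=self.features
        )

    def reads_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.reads.toarray(), index=self.barcodes, columns=self.features
        )

    def rate_df(self) -> pd.DataFrame:
        if self.rate is None:
            raise ValueError("rate has not been computed")
        return pd.DataFrame(
            self.rate.toarray(), index=self.barcodes, columns=self.features
        )

    # ------------------------------------------------------------------
    def subset_cells(self, keep: list[str]) -> "CellFeatureMatrix":
        idx = [self.barcodes.index(b) for b in keep]
        return CellFeatureMatrix(
            barcodes=list(keep),
            features=list(self.features),
            edits=self.edits[idx],
            reads=self.reads[idx],
            rate=self.rate[idx] if self.rate is not None else None,
        )

    def subset_features(self, keep: list[str]) -> "CellFeatureMatrix":
        idx = [self.features.index(f) for f in keep]
        return CellFeatureMatrix(
            barcodes=list(self.barcodes),
            features=list(keep),
            edits=self.edits[:, idx],
            reads=self.reads[:, idx],
            rate=self.rate[:, idx] if self.rate is not None else None,
        )

    def align_to(self, other: "CellFeatureMatrix") -> "CellFeatureMatrix":
        """Reorder rows/columns to match ``other``'s labels (must be a superset match)."""
        m = self.subset_cells(other.barcodes)
        return m.subset_features(other.features)

    # ------------------------------------------------------------------
    @classmethod
    def from_dense(
        cls,
        barcodes,
        features,
        edits,
        reads,
        rate=None,
    ) -> "CellFeatureMatrix":
        return cls(
            barcodes=list(barcodes),
            features=list(features),
            edits=_to_csr(edits),
            reads=_to_csr(reads),
            rate=_to_csr(rate) if rate is not None else None,
        )

    @classmethod
    def from_frames(cls, edits: pd.DataFrame, reads: pd.DataFrame) -> "CellFeatureMatrix":
        if not edits.index.equals(reads.index) or not edits.columns.equals(reads.columns):
            raise ValueError("edits and reads frames are not label-aligned")
        return cls.from_dense(
            edits.index.tolist(), edits.columns.tolist(), edits.values, reads.values
        )

    # ------------------------------------------------------------------
    def write_mtx(self, out_dir: str | os.PathLike) -> None:
        """Write MTX triplets (edits, reads, optionally rate) plus label TSVs."""
        os.makedirs(out_dir, exist_ok=True)
        mmwrite(os.path.join(out_dir, "edits.mtx"), sp.coo_matrix(self.edits))
        mmwrite(os.path.join(out_dir, "reads.mtx"), sp.coo_matrix(self.reads))
        if self.rate is not None:
            mmwrite(os.path.join(out_dir, "rate.mtx"), sp.coo_matrix(self.rate))
        with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(self.barcodes) + "\n")
        with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
            fh.write("\n".join(self.features) + "\n")

    @classmethod
    def read_mtx(cls, in_dir: str | os.PathLike) -> "CellFeatureMatrix":
        with open(os.path.join(in_dir, "barcodes.tsv")) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        with open(os.path.join(in_dir, "features.tsv")) as fh:
            features = [line.strip() for line in fh if line.strip()]
        edits = _to_csr(mmread(os.path.join(in_dir, "edits.mtx")))
        reads = _to_csr(mmread(os.path.join(in_dir, "reads.mtx")))
        rate_path = os.path.join(in_dir, "rate.mtx")
        rate = _to_csr(mmread(rate_path)) if os.path.exists(rate_path) else None
        return cls(barcodes=barcodes, features=features, edits=edits, reads=reads, rate=rate)
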