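"""Spectral-count enrichment scoring for IP mass-spectrometry tables.

The score for a protein is the mean over bait replicates of
``(count + 1) / sample_total``, divided by the same quantity in the
untagged control IP. The +1 pseudocount keeps absent proteins on a rational
scale; no significance model is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_ROLES = ("bait_rep1", "bait_rep2", "untagged_control")


@dataclass
class SpectralCountTable:
    """Protein-by-sample spectral counts with per-sample totals.

    ``sample_totals`` given at construction are authoritative (so adding a
    row never perturbs other proteins' scores); a mismatch against column
    sums is only warned about. When omitted, column sums are used.
    """

    proteins: list[str]
    counts: np.ndarray                       # shape (n_proteins, 3)
    sample_totals: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(SAMPLE_ROLES):
            raise ValueError(f"counts must be n_proteins x {len(SAMPLE_ROLES)}")
        if len(self.proteins) != self.counts.shape[0]:
            raise ValueError("protein list and count matrix disagree")
        if np.any(self.counts < 0):
            raise ValueError("negative spectral counts")
        col_sums = self.counts.sum(axis=0)
        if self.sample_totals is None:
            self.sample_totals = col_sums
        else:
            self.sample_totals = np.asarray(self.sample_totals, dtype=np.int64)
            if not np.array_equal(self.sample_totals, col_sums):
                logger.warning(
                    "sample_totals %s disagree with column sums %s; "
                    "keeping the provided totals",
                    self.sample_totals.tolist(), col_sums.tolist(),
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectralCountTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("protein", *SAMPLE_ROLES) if c not in df.columns]
        if missing:
            raise ValueError(f"spectral-count table missing columns {missing}")
        return cls(
            proteins=df["protein"].astype(str).tolist(),
            counts=df[list(SAMPLE_ROLES)].to_numpy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, columns=list(SAMPLE_ROLES))
        df.insert(0, "protein", self.proteins)
        df.to_csv(path, sep="\t", index=False)

    def row(self, protein: str) -> np.ndarray:
        try:
            i = self.proteins.index(protein)
        except ValueError:
            raise KeyError(f"protein {protein!r} not in table") from None
        return self.counts[i]


def enrichment(table: SpectralCountTable, protein: str) -> float:
    """Pseudocounted, total-normalized bait/control spectral-count ratio."""
    totals = table.sample_totals
    if np.any(totals <= 0):
        raise ValueError("all sample totals must be positive")
    c = table.row(protein).astype(float)
    rep_norm = (c[:2] + 1.0) / totals[:2]
    ctrl_norm = (c[2] + 1.0) / totals[2]
    return float(rep_norm.mean() / ctrl_norm)


def rank_interactors(table: SpectralCountTable) -> pd.DataFrame:
    """Enrichment of every protein, sorted descending (ties by id)."""
    totals = table.sample_totals
    if np.any(totals <= 0):
        raise ValueError("all sample totals must be positive")
    c = table.counts.astype(float)
    rep_norm = (c[:, :2] + 1.0) / totals[:2]
    ctrl_norm = (c[:, 2] + 1.0) / totals[2]
    scores = rep_norm.mean(axis=1) / ctrl_norm
    df = pd.DataFrame({"protein": table.proteins, "enrichment": scores})
    return (
        df.sort_values(["enrichment", "protein"], ascending=[False, True])
        .reset_index(drop=True)
    )
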