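"""Fixed-length composition features for variable-length protein sequences.

Two encoders are provided:

* **Discrete amino-acid composition** — the percentage of each of the 20
  residues in the sequence:  ``comp(i) = 100 * R_i / N`` where ``R_i`` is
  the count of residue ``i`` and ``N`` the sequence length.  A
  20-dimensional vector that discards all sequence-order information.

* **Coupled amino-acid composition** — the percentage of each *ordered*
  adjacent residue pair (dipeptide).  A sequence of length ``L`` contains
  ``L - 1`` overlapping pairs; the value for pair ``j`` is
  ``100 * M_j / (L - 1)`` with ``M_j`` the pair count.  A 400-dimensional
  vector that captures local sequence order, which is what makes it the
  stronger input for chaperone-family discrimination.

Both vectors sum to 100 per sequence and are fed to the classifier as raw
percentages without further standardization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, DIPEPTIDES, N_DIPEPTIDES, N_RESIDUES, residue_indices
from .errors import EligibilityError, HspClassError
from .sequence_io import ProteinRecord


@dataclass(frozen=True)
class CompositionVector:
    """20 per-residue percentages (canonical order) plus the source length."""

    values: np.ndarray  # shape (20,), sums to 100
    length: int  # N, the total residue count

    def __post_init__(self):
        if self.values.shape != (N_RESIDUES,):
            raise HspClassError("composition vector must have 20 components")


@dataclass(frozen=True)
class CoupledCompositionVector:
    """400 ordered-pair percentages (first residue major) plus the pair count."""

    values: np.ndarray  # shape (400,), sums to 100
    pair_count: int  # L - 1 - gap

    def __post_init__(self):
        if self.values.shape != (N_DIPEPTIDES,):
            raise HspClassError("coupled composition vector must have 400 components")


def discrete_composition(record: ProteinRecord) -> CompositionVector:
    """Percentage of each residue in the sequence (20-dimensional)."""
    idx = residue_indices(record.residues)
    n = idx.size
    if n < 1:
        raise HspClassError(f"record {record.id!r} is empty")
    counts = np.bincount(idx, minlength=N_RESIDUES).astype(float)
    return CompositionVector(values=100.0 * counts / n, length=n)


def coupled_composition(record: ProteinRecord, gap: int = 0) -> CoupledCompositionVector:
    """Percentage of each ordered residue pair (400-dimensional).

    ``gap`` is the number of residues skipped between the two members of a
    pair; the default 0 counts adjacent overlapping dipeptides, giving
    ``L - 1`` pairs for a sequence of length ``L``.
    """
    if gap < 0:
        raise HspClassError("gap must be >= 0")
    idx = residue_indices(record.residues)
    n_pairs = idx.size - 1 - gap
    if n_pairs < 1:
        raise HspClassError(
            f"record {record.id!r} (length {idx.size}) is too short for coupled "
            f"encoding with gap {gap}"
        )
    codes = N_RESIDUES * idx[: idx.size - 1 - gap] + idx[1 + gap :]
    counts = np.bincount(codes, minlength=N_DIPEPTIDES).astype(float)
    return CoupledCompositionVector(values=100.0 * counts / n_pairs, pair_count=n_pairs)


ENCODINGS = ("discrete", "coupled")


def _dim(encoding: str) -> int:
    if encoding == "discrete":
        return N_RESIDUES
    if encoding == "coupled":
        return N_DIPEPTIDES
    raise HspClassError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")


def feature_names(encoding: str) -> tuple[str, ...]:
    """Column labels: residues for discrete, ordered pairs for coupled."""
    _dim(encoding)
    return tuple(AMINO_ACIDS) if encoding == "discrete" else DIPEPTIDES


def encode_dataset(
    records: Sequence[ProteinRecord],
    encoding: str = "coupled",
    labels: Sequence | None = None,
    gap: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Encode a record collection into a (n_records, 20 or 400) matrix.

    Row *i* is the single-record encoding of record *i*; column order is
    canonical.  Ineligible records (too short for the coupled encoder) are
    reported in an aggregated :class:`EligibilityError` rather than dropped.
    If ``labels`` is given it must align 1:1 with ``records`` and is
    returned as an array alongside the matrix.
    """
    dim = _dim(encoding)
    if len(records) == 0:
        raise HspClassError("cannot encode an empty record collection")
    if labels is not None and len(labels) != len(records):
        raise HspClassError(
            f"{len(labels)} labels for {len(records)} records; must align 1:1"
        )
    if encoding == "coupled":
        bad = [r.id for r in records if len(r.residues) < 2 + gap]
        if bad:
            raise EligibilityError(bad, f"too short for coupled encoding (gap {gap})")
    X = np.empty((len(records), dim), dtype=float)
    for i, rec in enumerate(records):
        if encoding == "discrete":
            X[i] = discrete_composition(rec).values
        else:
            X[i] = coupled_composition(rec, gap=gap).values
    y = np.asarray(labels) if labels is not None else None
    return X, y


def features_to_tsv(
    X: np.ndarray,
    record_ids: Iterable[str],
    encoding: str,
    sink: str | Path | IO[str],
) -> None:
    """Export a feature matrix as TSV: header of residue/pair names, one row per id."""
    df = pd.DataFrame(X, index=list(record_ids), columns=list(feature_names(encoding)))
    df.index.name = "id"
    df.to_csv(sink, sep="\t")
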