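"""FASTA input/output with sanitization to the canonical 20-letter alphabet.

Every downstream computation (composition features, enrichment statistics)
assumes sequences contain only the 20 standard amino acids.  This module is
the single gate enforcing that contract: records are uppercased and either
cleaned of non-canonical letters (``skip-invalid``, the default) or rejected
outright (``strict``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS
from .errors import HspClassError, RecordRejectedError

logger = logging.getLogger(__name__)

_CANONICAL = set(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the canonical alphabet.

    Parameters
    ----------
    id
        Non-empty identifier, unique within a collection.
    residues
        Uppercase string over ``ACDEFGHIKLMNPQRSTVWY``, length >= 1.
    description
        Free-text FASTA description (may be empty).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise HspClassError("record id must be non-empty")
        if not self.residues:
            raise HspClassError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _CANONICAL
        if bad:
            raise HspClassError(
                f"record {self.id!r} contains non-canonical residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def eligible_for_coupled(self) -> bool:
        """Sequences shorter than 2 residues have no dipeptides."""
        return len(self.residues) >= 2


@dataclass(frozen=True)
class SanitizePolicy:
    """How to treat letters outside the canonical alphabet.

    ``skip-invalid`` (default) drops ambiguity codes, rare residues, stops,
    gaps, digits and whitespace after uppercasing, so the 20/400 feature
    dimensionalities hold exactly.  ``strict`` rejects any record containing
    such a letter.
    """

    mode: str = "skip-invalid"

    def __post_init__(self):
        if self.mode not in ("strict", "skip-invalid"):
            raise HspClassError(
                f"sanitize mode must be 'strict' or 'skip-invalid', got {self.mode!r}"
            )

    def sanitize(self, record_id: str, raw: str) -> str:
        seq = raw.upper()
        if self.mode == "strict":
            bad = set(seq) - _CANONICAL
            if bad:
                raise RecordRejectedError(
                    record_id, f"non-canonical letters {sorted(bad)!r} under strict policy"
                )
            return seq
        cleaned = "".join(c for c in seq if c in _CANONICAL)
        if not cleaned:
            raise RecordRejectedError(record_id, "sequence empty after sanitization")
        return cleaned


def _open_source(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "rt")
    return source


def read_fasta(
    source: str | Path | IO[str],
    policy: SanitizePolicy | None = None,
) -> list[ProteinRecord]:
    """Read and sanitize a multi-record FASTA file.

    Input order is preserved.  Duplicate ids are disambiguated by appending
    ``_2``, ``_3``, ... (with a logged warning) so batch proteome scans with
    repeated headers still run.

    Raises
    ------
    HspClassError
        If the input contains no records.
    RecordRejectedError
        For a record with forbidden letters (strict) or one emptied entirely
        by sanitization (skip-invalid).
    """
    policy = policy or SanitizePolicy()
    handle = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        records: list[ProteinRecord] = []
        seen: dict[str, int] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            rid = rec.id
            if not rid:
                raise RecordRejectedError("<unnamed>", "empty FASTA id")
            count = seen.get(rid, 0) + 1
            seen[rid] = count
            if count > 1:
                new_id = f"{rid}_{count}"
                logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
                rid = new_id
            residues = policy.sanitize(rid, str(rec.seq))
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(ProteinRecord(id=rid, residues=residues, description=desc))
    finally:
        if close:
            handle.close()
    if not records:
        raise HspClassError("no records found in FASTA input")
    return records


def write_fasta(
    records: Iterable[ProteinRecord],
    sink: str | Path | IO[str],
    line_width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``."""
    records = list(records)
    if not records:
        raise HspClassError("cannot write an empty record collection")
    if line_width < 1:
        raise HspClassError("line width must be positive")
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    if isinstance(sink, (str, Path)):
        with open(sink, "wt") as fh:
            _write(seqrecords, fh, line_width)
    else:
        _write(seqrecords, sink, line_width)


def _write(seqrecords: list[SeqRecord], handle: IO[str], width: int) -> None:
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(seqrecords)


def read_fasta_text(text: str, policy: SanitizePolicy | None = None) -> list[ProteinRecord]:
    """Convenience wrapper: parse FASTA from an in-memory string."""
    return read_fasta(io.StringIO(text), policy)
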