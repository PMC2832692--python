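"""Sequence input and tabular/matrix/tree output.

Reads FASTA into validated :class:`SequenceRecord` lists and writes the
artifacts the pipeline produces: tab-separated feature-vector tables,
PHYLIP square distance matrices, and plain-text accession lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, TextIO]

#: Canonical residue orders. Protein order is the conventional one-letter
#: listing by full amino-acid name grouping (Ala, Arg, Asn, ...).
PROTEIN_SYMBOLS = "ARNDCEQGHILKMFPSTWYV"
DNA_SYMBOLS = "ACGT"
RNA_SYMBOLS = "ACGU"


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet.

    Parameters
    ----------
    kind : str
        One of ``"protein"``, ``"dna"``, ``"rna"``.
    symbols : str
        Ordered, unique residue characters.
    """

    kind: str
    symbols: str

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, ch: str) -> bool:
        return ch in self.symbols

    def index(self, ch: str) -> int:
        return self.symbols.index(ch)


PROTEIN = Alphabet("protein", PROTEIN_SYMBOLS)
DNA = Alphabet("dna", DNA_SYMBOLS)
RNA = Alphabet("rna", RNA_SYMBOLS)

_ALPHABETS = {"protein": PROTEIN, "dna": DNA, "rna": RNA}


def get_alphabet(kind: str) -> Alphabet:
    """Return the built-in alphabet named ``kind`` (protein/dna/rna)."""
    try:
        return _ALPHABETS[kind]
    except KeyError:
        raise ValueError(f"unknown alphabet kind {kind!r}") from None


@dataclass(frozen=True)
class SequenceRecord:
    """An identified residue string validated against an alphabet."""

    id: str
    residues: str

    @property
    def N(self) -> int:
        """Sequence length after cleaning."""
        return len(self.residues)

    def validate(self, alphabet: Alphabet) -> None:
        for i, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: character {ch!r} at position "
                    f"{i + 1} is not in the {alphabet.kind} alphabet"
                )


def _as_handle(source: PathOrStream, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fasta(
    source: PathOrStream,
    alphabet: Alphabet = PROTEIN,
    unknown_policy: str = "drop",
) -> list[SequenceRecord]:
    """Read a (possibly multi-line) FASTA stream into SequenceRecords.

    Lowercase residues are uppercased before validation.  Under
    ``unknown_policy="drop"`` characters outside the alphabet are removed
    (with a logged count); under ``"strict"`` any such character raises
    ``ValueError`` naming the record, 1-based position and character.
    """
    if unknown_policy not in ("strict", "drop"):
        raise ValueError(f"unknown_policy must be 'strict' or 'drop', got {unknown_policy!r}")
    handle, close = _as_handle(source)
    try:
        records: list[SequenceRecord] = []
        dropped_total = 0
        for bio in SeqIO.parse(handle, "fasta"):
            raw = str(bio.seq).upper()
            if unknown_policy == "strict":
                rec = SequenceRecord(bio.id, raw)
                rec.validate(alphabet)
            else:
                kept = "".join(ch for ch in raw if ch in alphabet)
                dropped = len(raw) - len(kept)
                if dropped:
                    dropped_total += dropped
                    logger.warning(
                        "record %s: dropped %d character(s) outside the %s alphabet",
                        bio.id, dropped, alphabet.kind,
                    )
                rec = SequenceRecord(bio.id, kept)
            if rec.N == 0:
                raise ValueError(f"record {rec.id!r} has an empty sequence after cleaning")
            records.append(rec)
        if not records:
            raise ValueError("no FASTA records found in input")
        if dropped_total:
            logger.info("dropped %d out-of-alphabet character(s) in total", dropped_total)
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], destination: PathOrStream, width: int = 60) -> None:
    """Write SequenceRecords as wrapped FASTA."""
    handle, close = _as_handle(destination, "w")
    try:
        bio = [
            BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
        ]
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)
    finally:
        if close:
            handle.close()


def vector_component_labels(alphabet: Alphabet) -> list[str]:
    """Column labels ``<residue>_I``, ``_II``, ``_III`` in vector order."""
    labels = []
    for sym in alphabet.symbols:
        labels += [f"{sym}_I", f"{sym}_II", f"{sym}_III"]
    return labels


def write_vectors(vectors, destination: PathOrStream, alphabet: Alphabet | None = None) -> None:
    """Write feature vectors as a TSV table.

    Header row is ``id`` followed by per-residue component labels; one row
    per sequence.  Values are written with full double precision so a
    round-trip read recovers them exactly.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no vectors to write")
    dim = len(vectors[0].components)
    for v in vectors:
        if len(v.components) != dim:
            raise ValueError(
                f"vector dimension mismatch: {v.sequence_id!r} has "
                f"{len(v.components)} components, expected {dim}"
            )
    if alphabet is None:
        alphabet = getattr(vectors[0], "alphabet", None)
    if alphabet is not None and 3 * len(alphabet) == dim:
        labels = vector_component_labels(alphabet)
    else:  # fall back to positional labels for foreign dimensions
        labels = [f"c{i + 1}" for i in range(dim)]
    handle, close = _as_handle(destination, "w")
    try:
        handle.write("id\t" + "\t".join(labels) + "\n")
        for v in vectors:
            vals = "\t".join(format(float(x), ".17g") for x in v.components)
            handle.write(f"{v.sequence_id}\t{vals}\n")
    finally:
        if close:
            handle.close()


def read_vectors(source: PathOrStream) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a vector TSV table back.

    Returns ``(ids, matrix, component_labels)``.
    """
    handle, close = _as_handle(source)
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError("vector table must start with an 'id' header column")
        labels = header[1:]
        ids, rows = [], []
        for line in handle:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"row for {parts[0]!r} has {len(parts) - 1} values, expected {len(labels)}")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if not ids:
            raise ValueError("vector table has no data rows")
        return ids, np.asarray(rows, dtype=float), labels
    finally:
        if close:
            handle.close()


def write_distance_matrix(matrix, destination: PathOrStream) -> None:
    """Write a distance matrix in PHYLIP square format.

    First line is the taxon count; each following line is a taxon name
    followed by its full row of distances.
    """
    d = np.asarray(matrix.d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(d - d.T)) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    if np.max(np.abs(np.diag(d))) > 1e-9:
        raise ValueError("distance matrix diagonal must be zero")
    handle, close = _as_handle(destination, "w")
    try:
        handle.write(f"{len(matrix.ids)}\n")
        for name, row in zip(matrix.ids, d):
            handle.write(name + "\t" + "\t".join(format(x, ".9f") for x in row) + "\n")
    finally:
        if close:
            handle.close()


def read_distance_matrix(source: PathOrStream) -> tuple[list[str], np.ndarray]:
    """Read a PHYLIP square distance matrix; returns ``(ids, matrix)``."""
    handle, close = _as_handle(source)
    try:
        count = int(handle.readline().strip())
        ids, rows = [], []
        for line in handle:
            if not line.strip():
                continue
            parts = line.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if len(ids) != count:
            raise ValueError(f"expected {count} taxa, found {len(ids)}")
        return ids, np.asarray(rows, dtype=float)
    finally:
        if close:
            handle.close()


def read_accession_list(source: PathOrStream) -> list[str]:
    """Read whitespace/newline-separated accession tokens, in order.

    Duplicates are logged but retained; an empty list is an error.  No
    network access is performed.
    """
    handle, close = _as_handle(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    tokens = text.split()
    if not tokens:
        raise ValueError("accession list is empty")
    seen: set[str] = set()
    for tok in tokens:
        if tok in seen:
            logger.warning("duplicate accession %s retained", tok)
        seen.add(tok)
    return tokens
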