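"""I/O for the standard formats the pipeline touches.

Sequences (FASTA), JASPAR position frequency matrices, and tab-separated
differential-expression tables.  All sequence input is normalised to the
uppercase DNA alphabet at this boundary (RNA ``U`` becomes ``T``), so every
downstream module matches DNA words only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("utr3", "utr5", "cds", "cdna", "promoter")

# IUPAC nucleotide codes accepted on input; ambiguity codes other than N are
# rejected because no downstream semantics are defined for them.
_VALID_CHARS = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message carries file and line provenance."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single per-gene region sequence (uppercase DNA over {A,C,G,T,N})."""

    seq_id: str
    region: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(f"illegal characters in sequence {self.seq_id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CountMatrix:
    """A JASPAR-style position frequency matrix, rows ordered A, C, G, T."""

    motif_id: str
    name: str
    counts: np.ndarray  # shape (4, L), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError(f"negative count in matrix {self.motif_id!r}")
        if (counts.sum(axis=0) == 0).any():
            raise ValueError(f"all-zero column in matrix {self.motif_id!r}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])


def _normalize_sequence(raw: str, path: str, lineno: int) -> str:
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ParseError(
            f"{path}:{lineno}: illegal sequence character(s) {sorted(bad)} "
            "(expected A/C/G/T/U/N)"
        )
    return seq


def read_fasta(path: str | Path, region: str) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Lowercase is uppercased and RNA ``U`` is converted to ``T``.  Characters
    outside {A,C,G,T,U,N} (case-insensitive) raise :class:`ParseError`
    naming the offending line.  Record order is preserved; the first
    whitespace-separated token of each header is the sequence id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            records.append(SequenceRecord(current_id, region, "".join(chunks)))

    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                current_id = header.split()[0]
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before any '>' header")
                chunks.append(_normalize_sequence(line, str(path), lineno))
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta` on
    normalised records."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
            if not rec.sequence:
                handle.write("\n")


def collapse_isoforms(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Keep one record per seq_id: the longest isoform.

    Ties on length are broken by the lexicographically smallest sequence so
    the result is deterministic and order-independent.
    """
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        prev = best.get(rec.seq_id)
        if (
            prev is None
            or len(rec) > len(prev)
            or (len(rec) == len(prev) and rec.sequence < prev.sequence)
        ):
            best[rec.seq_id] = rec
    # preserve first-appearance order of ids
    seen: list[str] = []
    for rec in records:
        if rec.seq_id not in seen:
            seen.append(rec.seq_id)
    return [best[sid] for sid in seen]


_JASPAR_ROW_LETTERS = "ACGT"


def read_jaspar(path: str | Path) -> list[CountMatrix]:
    """Read JASPAR PFM count matrices (bare-number or ``A [ ... ]`` rows).

    Each matrix is a ``>ID NAME`` header followed by exactly four rows.  Rows
    may either be bare whitespace-separated numbers (implicitly ordered
    A, C, G, T) or carry a leading base letter and optional brackets, in
    which case rows are reordered to A, C, G, T.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        lines = [(i, ln.strip()) for i, ln in enumerate(handle, start=1)]
    lines = [(i, ln) for i, ln in lines if ln]

    matrices: list[CountMatrix] = []
    pos = 0
    while pos < len(lines):
        lineno, line = lines[pos]
        if not line.startswith(">"):
            raise ParseError(f"{path}:{lineno}: expected '>' matrix header, got {line!r}")
        header = line[1:].strip().split(None, 1)
        if not header:
            raise ParseError(f"{path}:{lineno}: empty matrix header")
        motif_id = header[0]
        name = header[1] if len(header) > 1 else motif_id
        pos += 1

        rows: dict[str, list[int]] = {}
        bare_rows: list[list[int]] = []
        while pos < len(lines) and not lines[pos][1].startswith(">"):
            rlineno, row = lines[pos]
            letter = None
            body = row
            if row[0].upper() in _JASPAR_ROW_LETTERS and (len(row) == 1 or not row[1].isdigit()):
                letter = row[0].upper()
                body = row[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                values = [int(float(tok)) for tok in body.split()]
            except ValueError as exc:
                raise ParseError(f"{path}:{rlineno}: non-numeric count in matrix row") from exc
            if any(float(tok) < 0 for tok in body.split()):
                raise ParseError(f"{path}:{rlineno}: negative count")
            if letter is not None:
                if letter in rows:
                    raise ParseError(f"{path}:{rlineno}: duplicate row for base {letter}")
                rows[letter] = values
            else:
                bare_rows.append(values)
            pos += 1

        if rows and bare_rows:
            raise ParseError(f"{path}:{lineno}: matrix {motif_id!r} mixes labelled and bare rows")
        if rows:
            if set(rows) != set(_JASPAR_ROW_LETTERS):
                raise ParseError(
                    f"{path}:{lineno}: matrix {motif_id!r} must have rows A, C, G, T "
                    f"(got {sorted(rows)})"
                )
            ordered = [rows[b] for b in _JASPAR_ROW_LETTERS]
        else:
            if len(bare_rows) != 4:
                raise ParseError(
                    f"{path}:{lineno}: matrix {motif_id!r} has {len(bare_rows)} rows; expected 4"
                )
            ordered = bare_rows
        lengths = {len(r) for r in ordered}
        if len(lengths) != 1:
            raise ParseError(f"{path}:{lineno}: ragged columns in matrix {motif_id!r}")
        matrices.append(CountMatrix(motif_id, name, np.array(ordered, dtype=np.int64)))
    return matrices


_DIFF_COLUMNS = ("gene_id", "logFC", "p", "fdr")


def read_diff_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV with columns gene_id, logFC, p, fdr.

    Lines starting with ``#`` are treated as comments.  Duplicate gene ids
    and p/fdr values outside [0, 1] are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = [c for c in _DIFF_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = df[list(_DIFF_COLUMNS)].copy()
    for col in ("logFC", "p", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene id(s): {dups[:5]}")
    for col in ("p", "fdr"):
        vals = df[col].to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ParseError(f"{path}: column {col!r} has values outside [0, 1]")
    return df.reset_index(drop=True)


def write_enrichment_table(
    result: pd.DataFrame, path: str | Path, params: dict | None = None
) -> None:
    """Write a result table as TSV with a commented parameter header line.

    Column order follows the DataFrame; floats round-trip to 6 significant
    digits through :func:`read_enrichment_table`.
    """
    with open(path, "w", encoding="utf-8") as handle:
        if params:
            rendered = " ".join(f"{k}={v}" for k, v in params.items())
            handle.write(f"# {rendered}\n")
        result.to_csv(handle, sep="\t", index=False, float_format="%.6g")


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_enrichment_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
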