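"""Readers and writers for the external representations.

Formats: multi-record FASTA (sequences; DNA transcribed to RNA on
read), BED6 single-base poly(A)-site annotations, the fold-change TSV
(header ``gene_id<TAB>fold_change``), MEME minimal motif files for the
PWM, and generic results TSVs.

Coordinate convention: BED is 0-based half-open; a site line annotates
the single-base interval at the cleavage junction. The stored
``junction`` is chromStart on the + strand and chromEnd-1 on the -
strand — the boundary between the last transcribed nucleotide and the
cleaved-off downstream sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .alphabet import is_rna, normalize_rna

if TYPE_CHECKING:  # pragma: no cover
    from .kmers import MotifPWM

__all__ = [
    "SequenceRecord",
    "PolyASite",
    "FoldChangeRow",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_sites",
    "write_sites",
    "read_fold_changes",
    "write_fold_changes",
    "read_pwm_meme",
    "write_pwm_meme",
    "read_tsv",
    "write_tsv",
]


class ParseError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sense-strand RNA sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not is_rna(self.seq):
            raise ValueError(f"record {self.id}: sequence must be non-empty RNA")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PolyASite:
    """One annotated cleavage junction on a reference sequence."""

    seq_id: str
    junction: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.junction < 0:
            raise ValueError("junction must be non-negative")


@dataclass(frozen=True)
class FoldChangeRow:
    """Knockdown-vs-control fold reduction for one gene."""

    gene_id: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.gene_id}: fold_change must be positive")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA into normalized RNA records, order preserved."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        raw = str(rec.seq)
        if not raw:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, normalize_rna(raw, name=f"record {rec.id!r}")))
        seen.add(rec.id)
    if not records and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _sequence_lengths(
    sequences: Iterable[SequenceRecord] | Mapping[str, SequenceRecord],
) -> dict[str, int]:
    if isinstance(sequences, Mapping):
        return {k: len(v) for k, v in sequences.items()}
    return {r.id: len(r) for r in sequences}


def read_sites(
    path: str | Path,
    sequences: Iterable[SequenceRecord] | Mapping[str, SequenceRecord],
) -> list[PolyASite]:
    """Parse BED6 poly(A)-site annotations against known sequences.

    Each line must be a single-base interval (chromStart+1 == chromEnd)
    whose name column carries the gene id; the strand column is
    required (the unicode minus sign is accepted for '-').
    """
    lengths = _sequence_lengths(sequences)
    sites: list[PolyASite] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            seq_id, start_s, end_s, gene_id = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5].replace("−", "-")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end - start != 1:
                raise ParseError(
                    f"{path}:{lineno}: poly(A) site must be a single-base interval "
                    f"(width {end - start})"
                )
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: missing or invalid strand {fields[5]!r}")
            if seq_id not in lengths:
                raise ParseError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
            junction = start if strand == "+" else end - 1
            if junction > lengths[seq_id]:
                raise ParseError(
                    f"{path}:{lineno}: junction {junction} beyond sequence "
                    f"{seq_id!r} (length {lengths[seq_id]})"
                )
            sites.append(PolyASite(seq_id, junction, strand, gene_id))
    return sites


def write_sites(sites: Iterable[PolyASite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.seq_id}\t{s.junction}\t{s.junction + 1}\t{s.gene_id}\t0\t{s.strand}\n")


def read_fold_changes(path: str | Path) -> list[FoldChangeRow]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "fold_change"]:
        raise ParseError(
            f"{path}: expected header 'gene_id\\tfold_change', got {list(df.columns)}"
        )
    rows = []
    for rec in df.itertuples(index=False):
        fc = float(rec.fold_change)
        if not np.isfinite(fc) or fc <= 0:
            raise ParseError(f"{path}: gene {rec.gene_id}: fold_change must be > 0")
        rows.append(FoldChangeRow(str(rec.gene_id), fc))
    return rows


def write_fold_changes(rows: Iterable[FoldChangeRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfold_change\n")
        for r in rows:
            fh.write(f"{r.gene_id}\t{r.fold_change:.6g}\n")


# -- MEME minimal motif format -------------------------------------------

_MEME_HEADER = """MEME version 4

ALPHABET= ACGU

strands: +

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 U 0.25000

"""


def write_pwm_meme(
    pwm: "MotifPWM", path: str | Path, name: str = "AUA_core"
) -> None:
    """Serialize a PWM as a MEME minimal motif (RNA alphabet).

    Refuses matrices whose columns do not sum to 1 within 1e-9;
    probabilities are printed with 6 decimals and round-trip through
    :func:`read_pwm_meme` at that precision.
    """
    sums = pwm.matrix.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("refusing to write a PWM with non-normalized columns")
    nsites = max(1, int(round(sum(w for _, w in pwm.support))) or 1)
    with open(path, "w") as fh:
        fh.write(_MEME_HEADER)
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {nsites} E= 0\n"
        )
        for j in range(pwm.width):
            fh.write(" " + " ".join(f"{pwm.matrix[b, j]:.6f}" for b in range(4)) + "\n")


def read_pwm_meme(path: str | Path) -> "MotifPWM":
    """Read back a MEME minimal motif file written by this package."""
    from .kmers import MotifPWM

    rows: list[list[float]] = []
    width = None
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("letter-probability matrix:"):
                in_matrix = True
                parts = stripped.split()
                if "w=" in parts:
                    width = int(parts[parts.index("w=") + 1])
                continue
            if in_matrix:
                if not stripped:
                    if rows:
                        break
                    continue
                vals = stripped.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
    if not rows:
        raise ParseError(f"{path}: no letter-probability matrix found")
    if width is not None and len(rows) != width:
        raise ParseError(f"{path}: matrix has {len(rows)} rows, declared w= {width}")
    return MotifPWM(np.array(rows, dtype=float).T)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
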