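"""Readers and writers for on-disk artifacts.

Formats handled here:

* FASTA protein sequences (via biopython);
* MoRF annotation TSVs with columns ``protein_id``, ``start``, ``end``
  (1-based inclusive residue coordinates, header line required);
* PSI-BLAST ASCII PSSM files as written by ``psiblast -out_ascii_pssm``
  (only the first 20-column log-odds block is consumed);
* transformed score-matrix TSVs (lossless round-trip of values and stage);
* per-residue prediction TSVs.

Annotation coordinates are converted to/from the package's internal 0-based
representation only here, at the I/O boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AMINO_ACIDS, MatrixError, ProteinRecord, ScoreMatrix

_VALID_LETTERS = set(AMINO_ACIDS) | {"X"}


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, on_nonstandard: str = "map") -> list[ProteinRecord]:
    """Read a FASTA file into protein records (no intervals attached).

    Sequences are uppercased.  Letters outside the 20 standard amino acids
    are mapped to ``X`` when ``on_nonstandard="map"`` (default) or rejected
    when ``on_nonstandard="error"``.  Duplicate identifiers are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        bad = set(seq) - _VALID_LETTERS
        if bad:
            if on_nonstandard == "error":
                raise FormatError(
                    f"non-standard letters {sorted(bad)} in sequence {entry.id!r}"
                )
            seq = "".join(c if c in _VALID_LETTERS else "X" for c in seq)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# MoRF annotations

def read_annotations(
    path: str | Path,
    proteins: list[ProteinRecord],
    on_unknown: str = "error",
) -> list[ProteinRecord]:
    """Attach MoRF intervals from a TSV to matching protein records.

    The TSV must have a header with columns ``protein_id``, ``start``,
    ``end``; coordinates are 1-based inclusive.  Intervals are canonicalized
    (sorted, merged).  Rows naming unknown proteins raise an error, or are
    skipped with a warning when ``on_unknown="warn"``.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"annotation file {path} must have columns {sorted(required)}"
        )
    by_id = {r.id: r for r in proteins}
    intervals: dict[str, list[tuple[int, int]]] = {r.id: [] for r in proteins}
    for row in table.itertuples(index=False):
        pid, start, end = str(row.protein_id), int(row.start), int(row.end)
        if pid not in by_id:
            if on_unknown == "warn":
                warnings.warn(f"annotation for unknown protein {pid!r} skipped")
                continue
            raise FormatError(f"annotation for unknown protein {pid!r}")
        n = len(by_id[pid])
        if start > end:
            raise FormatError(f"interval start {start} > end {end} for {pid!r}")
        if not (1 <= start and end <= n):
            raise FormatError(
                f"interval ({start}, {end}) out of range for {pid!r} (length {n})"
            )
        intervals[pid].append((start, end))
    return [r.with_intervals(intervals[r.id]) for r in proteins]


def write_annotations(records: list[ProteinRecord], path: str | Path) -> None:
    rows = [
        {"protein_id": r.id, "start": s, "end": e}
        for r in records
        for s, e in r.morf_intervals
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_psiblast_pssm(path: str | Path) -> tuple[str, ScoreMatrix]:
    """Parse the ASCII matrix written by ``psiblast -out_ascii_pssm``.

    Returns the query sequence (column 2 of the data rows) and a raw-stage
    score matrix holding the first 20-column block of integer log-odds
    scores.  The trailing weighted-percentage block and the information
    columns, when present, are ignored.  Column order is taken from the
    header line and reordered to canonical order if it differs.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    seq_letters: list[str] = []
    rows: list[list[int]] = []
    for line in lines:
        tokens = line.split()
        if header_cols is None:
            # header: at least 20 single-letter AA tokens
            if len(tokens) >= 20 and all(
                t in _VALID_LETTERS and len(t) == 1 for t in tokens[:20]
            ):
                header_cols = tokens[:20]
                if sorted(header_cols) != sorted(AMINO_ACIDS):
                    raise FormatError(
                        f"PSSM header in {path} does not list the 20 standard "
                        "amino acids"
                    )
            continue
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # footer (Lambda/K statistics)
        if len(tokens) < 22:
            raise FormatError(
                f"malformed PSSM row in {path}: expected >= 20 score columns, "
                f"got {len(tokens) - 2}"
            )
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise FormatError(f"non-integer score in PSSM row of {path}") from exc
        seq_letters.append(tokens[1])
        rows.append(scores)
    if header_cols is None:
        raise FormatError(f"no PSSM header line found in {path}")
    if not rows:
        raise FormatError(f"no PSSM data rows in {path}")
    values = np.asarray(rows, dtype=float)
    if header_cols != list(AMINO_ACIDS):
        order = [header_cols.index(a) for a in AMINO_ACIDS]
        values = values[:, order]
    matrix = ScoreMatrix(path.stem, values, stage="raw").validate()
    return "".join(seq_letters), matrix


def write_psiblast_pssm(
    protein_id: str, sequence: str, matrix: ScoreMatrix, path: str | Path
) -> None:
    """Write a raw matrix in the PSI-BLAST ASCII PSSM layout.

    The file is readable by :func:`read_psiblast_pssm` and mimics the
    aligner's format closely enough for fixture purposes (the second
    percentage block is filled with zeros).
    """
    if matrix.stage != "raw":
        raise MatrixError("only raw matrices are written in PSSM format")
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    for i, (letter, row) in enumerate(zip(sequence, matrix.values), start=1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        pct = " ".join(f"{0:3d}" for _ in row)
        lines.append(f"{i:5d} {letter}  {scores}  {pct}  0.00 0.00")
    lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Matrix TSV

def write_matrix_tsv(matrix: ScoreMatrix, sequence: str, path: str | Path) -> None:
    """Write a score matrix as TSV with full float precision.

    Layout: a ``# stage=...`` comment line, a header row (position, residue,
    20 amino-acid letters), then one data row per residue.
    """
    with open(path, "w") as fh:
        fh.write(f"# protein_id={matrix.protein_id} stage={matrix.stage}\n")
        fh.write("position\tresidue\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(matrix.values):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{i + 1}\t{sequence[i]}\t{vals}\n")


def read_matrix_tsv(path: str | Path) -> tuple[str, ScoreMatrix]:
    """Read a matrix TSV written by :func:`write_matrix_tsv`.

    Returns the residue string and the matrix; the stage-specific value
    contract is re-validated on read.
    """
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("#"):
            raise FormatError(f"missing metadata line in {path}")
        fields = dict(kv.split("=", 1) for kv in meta.lstrip("# ").split())
        table = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if list(table.columns[2:]) != list(AMINO_ACIDS):
        raise FormatError(f"unexpected matrix columns in {path}")
    values = table[list(AMINO_ACIDS)].to_numpy(dtype=float)
    sequence = "".join(table["residue"].astype(str))
    matrix = ScoreMatrix(
        fields.get("protein_id", path.stem), values, stage=fields["stage"]
    ).validate()
    return sequence, matrix


# ---------------------------------------------------------------------------
# Optional PSI-BLAST wrapper

def run_psiblast(
    query_fasta: str | Path,
    out_pssm: str | Path,
    db: str = "nr",
    iterations: int = 3,
    evalue: float = 0.001,
) -> None:
    """Shell out to ``psiblast`` to produce an ASCII PSSM for one query.

    Convenience only: profiles are normally precomputed, and nothing in the
    package requires a local sequence database.  Defaults mirror the usual
    profile-search settings (three iterations, e-value 0.001).
    """
    import subprocess

    subprocess.run(
        [
            "psiblast",
            "-query", str(query_fasta),
            "-db", db,
            "-num_iterations", str(iterations),
            "-evalue", str(evalue),
            "-out_ascii_pssm", str(out_pssm),
        ],
        check=True,
    )


# ---------------------------------------------------------------------------
# Predictions

def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    """Write per-residue predictions (protein_id, position, residue, score, call)."""
    cols = ["protein_id", "position", "residue", "score", "call"]
    frame[cols].to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "score", "call"}
    if not required.issubset(frame.columns):
        raise FormatError(f"prediction file {path} lacks columns {sorted(required)}")
    return frame
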