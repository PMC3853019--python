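"""Seeded synthetic proteins with planted, locally conserved MoRFs.

The generator emulates the one property the predictor consumes: MoRF
regions are more conserved than their surroundings.  Each residue position
is independently "conserved" with a region-dependent probability (high
inside planted MoRFs, low elsewhere).  A conserved position's score row has
a high value in the column of its own amino acid (log-odds near +7) and low
values elsewhere (near -3), mimicking a strongly constrained alignment
column; a variable position's row is i.i.d. noise near -1.  Scores are
integers clipped to a PSI-BLAST-plausible range so that parsed real PSSMs
and generated fixtures exercise identical code paths.

This is a test harness, not a biological simulator: no evolutionary model,
no alignment statistics, no realistic disorder content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as io_
from .records import AMINO_ACIDS, ProteinRecord, ScoreMatrix

#: Disorder-promoting letters used for the optional flank composition bias.
DISORDER_LETTERS = "AGEST"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    MoRF lengths default to the 5-25 residue band of short MoRFs; the
    conservation contrast (0.7 vs 0.15 probability of a conserved position)
    is the planted, recoverable signal.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (60, 200)
    morf_length_range: tuple[int, int] = (5, 25)
    morfs_per_protein: tuple[int, int] = (1, 2)
    p_conserved_in_morf: float = 0.7
    p_conserved_background: float = 0.15
    conserved_high_mean: float = 7.0
    conserved_low_mean: float = -3.0
    variable_mean: float = -1.0
    score_spread: float = 2.0
    score_range: tuple[int, int] = (-10, 12)
    baseline_sd: float = 3.0
    min_separation: int = 10
    flank_bias: float = 0.0  # extra prob. mass on disorder-promoting letters near MoRFs
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.morf_length_range,
                       self.morfs_per_protein):
            if lo > hi:
                raise ValueError(f"min > max in range ({lo}, {hi})")
        for p in (self.p_conserved_in_morf, self.p_conserved_background,
                  self.flank_bias):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _place_morfs(
    rng: np.random.Generator, length: int, config: SimulationConfig
) -> list[tuple[int, int]]:
    """Non-overlapping 1-based inclusive intervals with minimum separation."""
    k = int(rng.integers(config.morfs_per_protein[0],
                         config.morfs_per_protein[1] + 1))
    intervals: list[tuple[int, int]] = []
    for _ in range(200):  # rejection sampling
        if len(intervals) == k:
            break
        mlen = int(rng.integers(config.morf_length_range[0],
                                config.morf_length_range[1] + 1))
        if mlen > length:
            continue
        start = int(rng.integers(1, length - mlen + 2))
        end = start + mlen - 1
        if all(
            end < s - config.min_separation or start > e + config.min_separation
            for s, e in intervals
        ):
            intervals.append((start, end))
    if len(intervals) < k and not intervals:
        raise ValueError(
            f"could not place any MoRF of length "
            f"{config.morf_length_range} in a protein of length {length}"
        )
    return sorted(intervals)


def _sequence(
    rng: np.random.Generator, length: int, labels: np.ndarray, config: SimulationConfig
) -> str:
    probs = np.full((length, 20), 1.0 / 20)
    if config.flank_bias > 0:
        flank = np.zeros(length, dtype=bool)
        morf = labels.astype(bool)
        for i in np.flatnonzero(morf):
            lo, hi = max(0, i - 5), min(length, i + 6)
            flank[lo:hi] = True
        flank &= ~morf
        extra = config.flank_bias / len(DISORDER_LETTERS)
        for letter in DISORDER_LETTERS:
            probs[flank, AMINO_ACIDS.index(letter)] += extra
        probs[flank] /= probs[flank].sum(axis=1, keepdims=True)
    idx = np.array([rng.choice(20, p=p) for p in probs])
    return "".join(AMINO_ACIDS[i] for i in idx)


def simulate(config: SimulationConfig = SimulationConfig()) -> list[ProteinRecord]:
    """Generate annotated proteins with raw score matrices, reproducibly.

    Every protein carries a stage=raw matrix whose MoRF rows are, in
    expectation, more locally conserved than background rows.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    lo_clip, hi_clip = config.score_range
    for p in range(config.n_proteins):
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        intervals = _place_morfs(rng, length, config)
        labels = np.zeros(length, dtype=bool)
        for s, e in intervals:
            labels[s - 1 : e] = True
        sequence = _sequence(rng, length, labels, config)
        p_cons = np.where(labels, config.p_conserved_in_morf,
                          config.p_conserved_background)
        conserved = rng.random(length) < p_cons
        values = rng.normal(config.variable_mean, config.score_spread,
                            size=(length, 20))
        cons_rows = np.flatnonzero(conserved)
        if cons_rows.size:
            values[cons_rows] = rng.normal(
                config.conserved_low_mean, config.score_spread,
                size=(cons_rows.size, 20),
            )
            own = np.array([AMINO_ACIDS.index(sequence[i]) for i in cons_rows])
            values[cons_rows, own] = rng.normal(
                config.conserved_high_mean, config.score_spread,
                size=cons_rows.size,
            )
        if config.baseline_sd > 0:
            # per-protein, per-column baseline: real profiles score each
            # amino-acid column against the alignment's own composition, so
            # absolute levels carry a protein-specific fingerprint that does
            # not transfer across proteins; column-wise masking subtracts a
            # per-column constant exactly, leaving relative local
            # conservation intact
            values += rng.normal(0.0, config.baseline_sd, size=(1, 20))
        values = np.clip(np.round(values), lo_clip, hi_clip)
        matrix = ScoreMatrix(f"synth{p:04d}", values, stage="raw").validate()
        records.append(
            ProteinRecord(
                id=f"synth{p:04d}",
                sequence=sequence,
                morf_intervals=intervals,
                matrix=matrix,
            )
        )
    return records


def write_fixture_bundle(records: list[ProteinRecord], directory: str | Path) -> None:
    """Write FASTA + annotation TSV + one ASCII PSSM file per protein.

    Everything is re-readable by the package's own readers without
    special-casing.
    """
    if not records:
        raise ValueError("cannot write an empty fixture bundle")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    io_.write_fasta(records, directory / "proteins.fasta")
    io_.write_annotations(records, directory / "annotations.tsv")
    for rec in records:
        if rec.matrix is None:
            raise ValueError(f"record {rec.id!r} lacks a matrix")
        io_.write_psiblast_pssm(
            rec.id, rec.sequence, rec.matrix, directory / f"{rec.id}.pssm"
        )


def read_fixture_bundle(directory: str | Path) -> list[ProteinRecord]:
    """Re-read a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    records = io_.read_fasta(directory / "proteins.fasta")
    records = io_.read_annotations(directory / "annotations.tsv", records)
    out = []
    for rec in records:
        seq, matrix = io_.read_psiblast_pssm(directory / f"{rec.id}.pssm")
        if seq != rec.sequence:
            raise ValueError(f"PSSM sequence mismatch for {rec.id!r}")
        out.append(rec.with_matrix(matrix))
    return out
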