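"""Region composition analysis: MoRFs, their flanks, and the rest.

For a flank length W, every residue of an annotated protein falls in exactly
one of three regions: ``morf`` (inside an annotated interval), ``flank``
(within W residues of a MoRF boundary but not inside any MoRF), or
``nonmorf`` (everything else).  Composition profiles pool residue counts
over a whole dataset; difference curves track how flank composition departs
from the general non-MoRF background as W grows, and their association with
W is summarised by a Pearson correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .records import AMINO_ACIDS, ProteinRecord

MORF, FLANK, NONMORF = "morf", "flank", "nonmorf"

#: Taylor's amino-acid classification; the ten physicochemical groups.
PROPERTY_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFGHIKLMTVWY"),
    "polar": frozenset("CDEHKNQRSTWY"),
    "small": frozenset("ACDGNPSTV"),
    "proline": frozenset("P"),
    "tiny": frozenset("ACGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FHWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("DEHKR"),
}


def partition(protein: ProteinRecord, w: int) -> np.ndarray:
    """Per-residue region tags for flank length ``w``.

    Flank residues lie within ``w`` positions of a MoRF boundary and outside
    every MoRF; when two MoRFs are closer than 2w the intervening residues
    are flank (tagged once).
    """
    if w < 0:
        raise ValueError("flank length must be >= 0")
    n = len(protein)
    tags = np.full(n, NONMORF, dtype=object)
    for start, end in protein.morf_intervals:  # 1-based inclusive
        lo, hi = start - 1, end  # 0-based half-open
        tags[max(0, lo - w) : lo] = np.where(
            tags[max(0, lo - w) : lo] == MORF, MORF, FLANK
        )
        tags[hi : min(n, hi + w)] = np.where(
            tags[hi : min(n, hi + w)] == MORF, MORF, FLANK
        )
    for start, end in protein.morf_intervals:
        tags[start - 1 : end] = MORF
    return tags


def _region_residues(records: list[ProteinRecord], w: int, region: str) -> str:
    letters = []
    for rec in records:
        tags = partition(rec, w)
        letters.extend(c for c, t in zip(rec.sequence, tags) if t == region)
    return "".join(letters)


def composition(records: list[ProteinRecord], w: int, region: str) -> pd.Series:
    """Pooled amino-acid fractions of one region across a dataset.

    Fractions sum to 1 over the 20 standard letters (X residues are counted
    in the denominator of nothing: they are excluded).  An empty region
    yields an all-NaN series.
    """
    residues = _region_residues(records, w, region).replace("X", "")
    counts = pd.Series(
        {aa: residues.count(aa) for aa in AMINO_ACIDS}, dtype=float
    )
    if counts.sum() == 0:
        return counts * np.nan
    return counts / counts.sum()


def property_composition(
    records: list[ProteinRecord],
    w: int,
    region: str,
    groups: dict[str, frozenset[str]] | None = None,
) -> pd.Series:
    """Fraction of region residues belonging to each physicochemical group.

    Groups overlap, so the fractions do not sum to one.
    """
    groups = PROPERTY_GROUPS if groups is None else groups
    residues = _region_residues(records, w, region).replace("X", "")
    if not residues:
        return pd.Series({g: np.nan for g in groups}, dtype=float)
    n = len(residues)
    return pd.Series(
        {g: sum(residues.count(a) for a in members) / n for g, members in groups.items()},
        dtype=float,
    )


def difference_curve(
    records: list[ProteinRecord],
    region_a: str,
    region_b: str,
    w_range: list[int],
    kind: str = "aa",
    groups: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Composition differences fraction(A) - fraction(B), one row per W.

    ``kind="aa"`` compares amino-acid fractions, ``kind="property"``
    physicochemical-group fractions.  Index: W; columns: features.
    """
    if not len(w_range):
        raise ValueError("w_range must be non-empty")
    comp = composition if kind == "aa" else (
        lambda r, w, reg: property_composition(r, w, reg, groups)
    )
    rows = {
        w: comp(records, w, region_a) - comp(records, w, region_b)
        for w in w_range
    }
    frame = pd.DataFrame(rows).T
    frame.index.name = "W"
    return frame


def flank_correlation(series: pd.Series) -> tuple[float, float]:
    """Pearson r (and two-sided p) between flank length W and a difference.

    ``series`` is indexed by W.  A constant series has undefined r,
    reported as (nan, nan).
    """
    w = np.asarray(series.index, dtype=float)
    d = np.asarray(series.values, dtype=float)
    if len(w) < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(w) == 0 or np.ptp(d) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(w, d)
    return float(r), float(p)


def correlation_table(differences: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Pearson correlation of composition difference vs W."""
    rows = []
    for feature in differences.columns:
        r, p = flank_correlation(differences[feature])
        rows.append({"feature": feature, "r": r, "p": p})
    return pd.DataFrame(rows)
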