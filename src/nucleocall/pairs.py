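"""Ligation pair records: reading, classification, deduplication, subsampling, binning.

A pair record is one proximity-ligation read pair with a mapped position and
strand per mate.  Mates follow the upper-triangular convention: the mate with
the lexicographically/numerically smaller (chrom, pos) is stored first.
Coordinates are 0-based throughout; genomic bins are half-open ``[start, end)``.

Pair classes
------------
mononucleosomal
    cis, convergent (+/- under upper-triangular ordering), mates >100 bp and
    <201 bp apart — a pair spanning a single nucleosome, used as an occupancy
    proxy for the captured histone mark.
distal
    cis, mates >5000 bp apart — the proximity-ligation signal proper.
other
    everything else (trans pairs, short non-convergent pairs, the 201 bp –
    5 kb window); retained in files, never analyzed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nucleocall")

DEFAULT_BIN_WIDTH = 250

MONO_MIN_SEP = 100   # strict: separation must exceed this
MONO_MAX_SEP = 201   # strict: separation must stay below this
DISTAL_MIN_SEP = 5000  # strict: separation must exceed this

PAIR_FIELDS = ("chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2")


class PairRecord(NamedTuple):
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str


class GenomicBin(NamedTuple):
    """Fixed-width genomic bin, 0-based half-open, start aligned to the width."""

    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class PairsDialect:
    """Column layout of a tab-separated pairs file (4DN-style).

    ``columns`` names every column in file order; names from ``PAIR_FIELDS``
    are mapped onto :class:`PairRecord` fields, anything else is ignored.
    """

    columns: tuple = ("readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2")

    def __post_init__(self) -> None:
        missing = [f for f in PAIR_FIELDS if f not in self.columns]
        if missing:
            raise ValueError(f"dialect lacks required columns: {missing}")

    @property
    def indices(self) -> dict:
        return {name: i for i, name in enumerate(self.columns) if name in PAIR_FIELDS}


DEFAULT_DIALECT = PairsDialect()


@dataclass
class ReadStats:
    """Counters accumulated while streaming a pairs file."""

    n_read: int = 0
    n_skipped_chrom: int = 0
    skipped_chroms: dict = field(default_factory=dict)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_pairs(
    path,
    dialect: PairsDialect = DEFAULT_DIALECT,
    chromosomes: Sequence[str] | None = None,
    stats: ReadStats | None = None,
) -> Iterator[PairRecord]:
    """Stream :class:`PairRecord` from a pairs file in file order.

    Header lines (``#``-prefixed) are skipped.  If ``chromosomes`` is given,
    records touching any other chromosome are dropped and counted in ``stats``.
    Malformed lines raise ``ValueError`` naming the offending line number.
    """
    allowed = set(chromosomes) if chromosomes is not None else None
    idx = dialect.indices
    ncol = len(dialect.columns)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < ncol:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(parts)}"
                )
            try:
                rec = PairRecord(
                    chrom1=parts[idx["chrom1"]],
                    pos1=int(parts[idx["pos1"]]),
                    strand1=parts[idx["strand1"]],
                    chrom2=parts[idx["chrom2"]],
                    pos2=int(parts[idx["pos2"]]),
                    strand2=parts[idx["strand2"]],
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed pair record ({exc})")
            if allowed is not None and (rec.chrom1 not in allowed or rec.chrom2 not in allowed):
                if stats is not None:
                    stats.n_skipped_chrom += 1
                    for c in {rec.chrom1, rec.chrom2} - allowed:
                        stats.skipped_chroms[c] = stats.skipped_chroms.get(c, 0) + 1
                continue
            if stats is not None:
                stats.n_read += 1
            yield rec


def read_pairs_frame(path, dialect: PairsDialect = DEFAULT_DIALECT,
                     chromosomes: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a whole pairs file into a DataFrame with :data:`PAIR_FIELDS` columns."""
    stats = ReadStats()
    recs = list(read_pairs(path, dialect=dialect, chromosomes=chromosomes, stats=stats))
    if stats.n_skipped_chrom:
        logger.info("read_pairs: skipped %d records on unlisted chromosomes %s",
                    stats.n_skipped_chrom, sorted(stats.skipped_chroms))
    if not recs:
        return pd.DataFrame(columns=list(PAIR_FIELDS))
    return pd.DataFrame(recs, columns=list(PAIR_FIELDS))


def write_pairs(path, pairs, dialect: PairsDialect = DEFAULT_DIALECT,
                header: bool = True) -> int:
    """Write records (iterable of PairRecord or DataFrame) in the given dialect."""
    if isinstance(pairs, pd.DataFrame):
        pairs = (PairRecord(*row) for row in pairs[list(PAIR_FIELDS)].itertuples(index=False))
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        if header:
            fh.write("## pairs format v1.0\n#columns: " + " ".join(dialect.columns) + "\n")
        for i, rec in enumerate(pairs):
            d = dict(zip(PAIR_FIELDS, rec))
            row = [d.get(c, f"r{i}") for c in dialect.columns]
            fh.write("\t".join(str(x) for x in row) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(p: PairRecord) -> str:
    """Classify one pair as 'mononucleosomal', 'distal' or 'other'.

    Separation is measured on the stored (5') positions.  All thresholds are
    strict inequalities.
    """
    if p.chrom1 != p.chrom2:
        return "other"
    sep = abs(p.pos2 - p.pos1)
    if p.strand1 == "+" and p.strand2 == "-" and MONO_MIN_SEP < sep < MONO_MAX_SEP:
        return "mononucleosomal"
    if sep > DISTAL_MIN_SEP:
        return "distal"
    return "other"


def classify_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_pair` over a pairs DataFrame."""
    cis = df["chrom1"].to_numpy() == df["chrom2"].to_numpy()
    sep = np.abs(df["pos2"].to_numpy() - df["pos1"].to_numpy())
    conv = (df["strand1"].to_numpy() == "+") & (df["strand2"].to_numpy() == "-")
    mono = cis & conv & (sep > MONO_MIN_SEP) & (sep < MONO_MAX_SEP)
    distal = cis & ~mono & (sep > DISTAL_MIN_SEP)
    out = np.full(len(df), "other", dtype=object)
    out[mono] = "mononucleosomal"
    out[distal] = "distal"
    return pd.Series(out, index=df.index, name="pair_class")


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _sort_key(rec: PairRecord):
    return (rec.chrom1, rec.pos1, rec.chrom2, rec.pos2)


def deduplicate(pairs: Iterable[PairRecord], tolerance: int = 0) -> Iterator[PairRecord]:
    """Drop duplicate records, keeping the first of each duplicate group.

    Two records are duplicates when both mates lie within ``tolerance`` bp
    (default 0, exact positions) and share chromosomes and strands.  Input
    must be sorted by (chrom1, pos1, chrom2, pos2); unsorted input raises.
    """
    kept: list[PairRecord] = []  # retained records still within tolerance window
    prev_key = None
    for rec in pairs:
        key = _sort_key(rec)
        if prev_key is not None and key < prev_key:
            raise ValueError("deduplicate requires input sorted by (chrom1,pos1,chrom2,pos2)")
        prev_key = key
        kept = [k for k in kept if k.chrom1 == rec.chrom1 and rec.pos1 - k.pos1 <= tolerance]
        dup = any(
            k.chrom2 == rec.chrom2
            and k.strand1 == rec.strand1
            and k.strand2 == rec.strand2
            and abs(rec.pos1 - k.pos1) <= tolerance
            and abs(rec.pos2 - k.pos2) <= tolerance
            for k in kept
        )
        if not dup:
            kept.append(rec)
            yield rec


def deduplicate_frame(df: pd.DataFrame, tolerance: int = 0) -> pd.DataFrame:
    """Frame version of :func:`deduplicate`; sorts, then drops duplicates."""
    df = df.sort_values(["chrom1", "pos1", "chrom2", "pos2"], kind="mergesort")
    if tolerance == 0:
        return df.drop_duplicates(subset=list(PAIR_FIELDS)).reset_index(drop=True)
    recs = (PairRecord(*r) for r in df[list(PAIR_FIELDS)].itertuples(index=False))
    out = list(deduplicate(recs, tolerance=tolerance))
    return pd.DataFrame(out, columns=list(PAIR_FIELDS))


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_pairs(pairs, fraction: float, seed: int):
    """Keep each record independently with probability ``fraction`` (seeded).

    Accepts an iterable of records (returns a list) or a DataFrame (returns a
    DataFrame).  ``fraction`` must lie in (0, 1]; 1.0 reproduces the input.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    if isinstance(pairs, pd.DataFrame):
        keep = rng.random(len(pairs)) < fraction
        return pairs.loc[keep].reset_index(drop=True)
    pairs = list(pairs)
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def assign_bin(pos: int, chrom: str, width: int = DEFAULT_BIN_WIDTH,
               chrom_size: int | None = None) -> GenomicBin:
    """Return the fixed-width bin containing ``pos`` (start = floor(pos/width)*width)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    if pos < 0:
        raise ValueError(f"negative position {pos}")
    start = (pos // width) * width
    end = start + width
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicBin(chrom, start, end)


def class_report(df: pd.DataFrame) -> dict:
    """JSON-ready classification summary for a pairs DataFrame."""
    labels = classify_frame(df)
    cis = df["chrom1"] == df["chrom2"]
    sep = (df["pos2"] - df["pos1"]).abs()
    n = len(df)
    counts = labels.value_counts().to_dict()
    return {
        "n_pairs": int(n),
        "counts": {k: int(counts.get(k, 0)) for k in ("mononucleosomal", "distal", "other")},
        "pct_cis_within_1kb": float(100.0 * (cis & (sep <= 1000)).sum() / n) if n else 0.0,
        "pct_cis_over_5kb": float(100.0 * (cis & (sep > 5000)).sum() / n) if n else 0.0,
    }
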