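"""FASTQ ingestion, variable-region extraction and frequency tables.

An amplicon read is expected to contain a 40-44 nt variable region between
two known constant flanks.  Extraction locates the best Hamming match of
each flank (lowest mismatch count, ties to the left-most position), checks
the enclosed region's length, and tallies accepted regions into per-cycle
count tables.  Frequencies are computed over extraction-passing reads;
library complexity is ``100 x unique / total reads``.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import DEFAULT_FLANK3, DEFAULT_FLANK5

__all__ = [
    "CycleLibrary",
    "FrequencyMatrix",
    "ExtractionConfig",
    "FastqFormatError",
    "parse_fastq",
    "extract_variable_region",
    "build_cycle_library",
    "complexity",
    "frequencies",
    "read_manifest",
]

REJECTION_CATEGORIES = ("no_flank5", "no_flank3", "bad_length", "ambiguous_base")


class FastqFormatError(ValueError):
    """Malformed FASTQ record, annotated with its 1-based record index."""


@dataclass
class CycleLibrary:
    """Per-cycle multiset of extracted variable regions.

    ``total_reads`` counts every read seen in the input; ``extracted_reads``
    those that passed extraction (equals ``sum(counts.values())``).
    """

    cycle_id: str
    counts: dict[str, int]
    total_reads: int
    extracted_reads: int
    rejections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = sum(self.counts.values())
        if s != self.extracted_reads:
            raise ValueError("extracted_reads must equal sum(counts)")
        if self.extracted_reads > self.total_reads:
            raise ValueError("extracted_reads cannot exceed total_reads")

    @property
    def unique_count(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class ExtractionConfig:
    """How to locate the variable region between the constant flanks."""

    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    max_mismatch: int = 1
    len_range: tuple[int, int] = (40, 44)
    search_both_strands: bool = False

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        lo, hi = self.len_range
        if not (0 < lo <= hi):
            raise ValueError("len_range must be a positive interval")


def parse_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, sequence, quality)`` from a FASTQ(.gz) file.

    Sequences are uppercased with U normalized to T (RNA aptamers are
    handled via their cDNA).  Malformed records raise
    :class:`FastqFormatError` naming the failing record.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record #{i + 1}: {exc}") from exc
            i += 1
            yield title, seq.upper().replace("U", "T"), qual


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _best_hamming(read: str, flank: str, start: int = 0) -> tuple[int, int]:
    """(offset, mismatches) of the best Hamming match of ``flank`` in
    ``read[start:]``; lowest mismatch wins, ties to the left-most offset."""
    k = len(flank)
    n = len(read)
    if n - start < k:
        return -1, k + 1
    # fast path: exact occurrence
    pos = read.find(flank, start)
    if pos != -1:
        return pos, 0
    window = np.frombuffer(read.encode(), dtype=np.uint8)
    pat = np.frombuffer(flank.encode(), dtype=np.uint8)
    n_off = n - start - k + 1
    sub = np.lib.stride_tricks.sliding_window_view(window[start:], k)
    mism = (sub != pat).sum(axis=1)
    best = int(mism.argmin())
    return start + best, int(mism[best])


def extract_variable_region(read: str, config: ExtractionConfig):
    """Return the variable region, or ``(None, reason)``.

    Returns ``(region, None)`` on success and ``(None, category)`` with
    ``category`` in :data:`REJECTION_CATEGORIES` otherwise.  With
    ``search_both_strands`` the reverse complement is tried when the
    forward orientation fails.
    """
    region, reason = _extract_oriented(read, config)
    if region is None and config.search_both_strands:
        rc = read.translate(_REVCOMP)[::-1]
        region2, reason2 = _extract_oriented(rc, config)
        if region2 is not None:
            return region2, None
    return region, reason


def _extract_oriented(read: str, config: ExtractionConfig):
    off5, mm5 = _best_hamming(read, config.flank5)
    if off5 < 0 or mm5 > config.max_mismatch:
        return None, "no_flank5"
    inner_start = off5 + len(config.flank5)
    off3, mm3 = _best_hamming(read, config.flank3, start=inner_start)
    if off3 < 0 or mm3 > config.max_mismatch:
        return None, "no_flank3"
    region = read[inner_start:off3]
    lo, hi = config.len_range
    if not lo <= len(region) <= hi:
        return None, "bad_length"
    if "N" in region:
        return None, "ambiguous_base"
    return region, None


def build_cycle_library(reads: Iterable[tuple[str, str, str]], config: ExtractionConfig,
                        cycle_id: str = "") -> CycleLibrary:
    """Tally accepted variable regions over a read stream.

    Identical reads are extracted once and their multiplicities accumulated,
    so cost scales with the number of distinct reads.
    """
    read_counts = Counter(seq for _, seq, _ in reads)
    total = sum(read_counts.values())
    counts: Counter[str] = Counter()
    rejections = dict.fromkeys(REJECTION_CATEGORIES, 0)
    for read, n in read_counts.items():
        region, reason = extract_variable_region(read, config)
        if region is None:
            rejections[reason] += n
        else:
            counts[region] += n
    return CycleLibrary(
        cycle_id=cycle_id,
        counts=dict(sorted(counts.items())),
        total_reads=total,
        extracted_reads=sum(counts.values()),
        rejections=rejections,
    )


def complexity(lib: CycleLibrary, denominator: str = "total_reads") -> float:
    """Library complexity: ``100 x unique sequences / denominator`` (%).

    ``denominator`` is ``"total_reads"`` (the published definition) or
    ``"extracted_reads"``.
    """
    if denominator not in ("total_reads", "extracted_reads"):
        raise ValueError("denominator must be 'total_reads' or 'extracted_reads'")
    denom = getattr(lib, denominator)
    if denom <= 0:
        raise ZeroDivisionError(f"{denominator} is zero; complexity undefined")
    return 100.0 * lib.unique_count / denom


class FrequencyMatrix:
    """Sequences x cycles table of relative frequencies.

    Frequencies are counts over extraction-passing reads; a sequence absent
    from a cycle has frequency 0 and is flagged undetected.  The detection
    floor ``epsilon`` is carried for downstream selection rules but never
    applied to the matrix itself.
    """

    def __init__(self, counts: pd.DataFrame, extracted: pd.Series,
                 epsilon: float = 1e-6):
        self.counts = counts
        self.extracted = extracted
        self.freq = counts.div(extracted, axis=1).fillna(0.0)
        self.epsilon = epsilon

    @property
    def cycles(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> pd.Index:
        return self.counts.index

    def detected(self, cycle: str) -> pd.Series:
        """Boolean detection mask (observed count > 0) for one cycle."""
        return self.counts[cycle] > 0

    def require_cycle(self, cycle: str) -> None:
        if cycle not in self.counts.columns:
            raise KeyError(f"cycle {cycle!r} not in matrix "
                           f"(have {list(self.counts.columns)})")

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out.index.name = "sequence"
        out.to_csv(path, sep="\t", float_format="%.10g")


def frequencies(libs: list[CycleLibrary], epsilon: float = 1e-6) -> FrequencyMatrix:
    """Build a :class:`FrequencyMatrix` over the union of sequences.

    Row order is deterministic: by decreasing final-cycle count, then
    decreasing total count, then lexicographic sequence.
    """
    if not libs:
        raise ValueError("need at least one cycle library")
    ids = [lib.cycle_id for lib in libs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cycle ids")
    counts = pd.DataFrame(
        {lib.cycle_id: pd.Series(lib.counts, dtype=np.int64) for lib in libs}
    ).fillna(0).astype(np.int64)
    order = pd.DataFrame({
        "last": -counts[ids[-1]],
        "total": -counts.sum(axis=1),
        "seq": counts.index,
    }, index=counts.index).sort_values(["last", "total", "seq"], kind="stable")
    counts = counts.loc[order.index]
    extracted = pd.Series({lib.cycle_id: lib.extracted_reads for lib in libs})
    return FrequencyMatrix(counts, extracted, epsilon=epsilon)


def read_manifest(path) -> pd.DataFrame:
    """Read a run manifest TSV with columns
    cycle_id, path, positive_class, negative_class (in cycle order)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cycle_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    df["path"] = [str(p) if Path(p).is_absolute() else str(base / p)
                  for p in df["path"]]
    return df
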