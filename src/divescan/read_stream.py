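"""Streaming FASTQ access and anchor/target window extraction.

A *read* is scanned with a stride-1 sliding window. Every window of length
``k`` is an anchor; the ``k``-mer immediately downstream (after an optional
gap ``g``) is its downstream target, and the ``k``-mer immediately upstream
is its upstream target. Windows containing ambiguous bases (``N``) are
skipped, as are targets that would run off either end of the read.

Reads are processed exactly as written: no reverse-complement
canonicalisation is performed, so the two strands of a locus give rise to
distinct anchors. Quality strings are ignored.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "WindowConfig",
    "stream_reads",
    "count_records",
    "extract_pairs",
    "UP",
    "DOWN",
]

#: direction labels used throughout the package
UP = "up"
DOWN = "down"

_VALID = frozenset("ACGT")

DEFAULT_K = 27
DEFAULT_G = 0
DEFAULT_MAX_RECORDS = 2_500_000


@dataclass(frozen=True)
class Read:
    """One FASTQ record: identifier, sequence, ordinal position in the file."""

    id: str
    sequence: str
    index: int


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry.

    Parameters
    ----------
    k
        Anchor and target k-mer length (default 27).
    g
        Gap in bases between the anchor and each target (default 0).
    max_records
        Cap on the number of FASTQ records consumed per sample
        (default 2,500,000).
    """

    k: int = DEFAULT_K
    g: int = DEFAULT_G
    max_records: int = DEFAULT_MAX_RECORDS

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.max_records < 0:
            raise ValueError("max_records must be >= 0")

    @property
    def span(self) -> int:
        """Bases needed for one anchor plus one flanking target."""
        return 2 * self.k + self.g


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b" or path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def stream_reads(
    fastq_path: str | Path,
    max_records: int = DEFAULT_MAX_RECORDS,
    start_index: int = 0,
) -> Iterator[Read]:
    """Yield :class:`Read` objects from a (possibly gzipped) FASTQ file.

    At most ``max_records`` records are yielded, in file order.
    ``start_index`` offsets the ordinal index, so multiple files (e.g. the
    two mates of a paired-end run, treated as independent inputs to one
    sample) can share a single global read counter.

    Raises
    ------
    ValueError
        On a malformed FASTQ record, reporting the index of the offending
        record.
    """
    if max_records <= 0:
        return
    n = 0
    with _open_text(fastq_path) as handle:
        try:
            for title, seq, _qual in FastqGeneralIterator(handle):
                yield Read(id=title.split(None, 1)[0], sequence=seq.upper(), index=start_index + n)
                n += 1
                if n >= max_records:
                    break
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record at index {start_index + n} in {fastq_path}: {exc}"
            ) from exc


def count_records(paths: Iterable[str | Path], max_records: int = DEFAULT_MAX_RECORDS) -> int:
    """Count FASTQ records across ``paths``, capped at ``max_records``.

    This is a cheap line count (records = lines / 4), used to fix the total
    record number L that the admission and retention probability models
    require before the analysis pass begins.
    """
    total = 0
    for path in paths:
        with _open_text(path) as fh:
            for line in fh:
                if line.strip():
                    total += 1
                    if total >= 4 * max_records:
                        return max_records
    return total // 4


def extract_pairs(
    read: Read | str, cfg: WindowConfig
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Extract (anchor, direction, target) tuples from one read.

    For every window start ``p`` with ``p + k <= len(seq)`` the anchor is
    ``seq[p:p+k]``; the downstream target ``seq[p+k+g : p+2k+g]`` is emitted
    iff it fits within the read, and the upstream target
    ``seq[p-k-g : p-g]`` iff ``p >= k + g``. Any window containing a base
    outside {A,C,G,T} is skipped.

    Returns
    -------
    pairs
        List of ``(anchor, direction, target)`` with direction ``"up"`` or
        ``"down"``.
    multiplicity
        Anchor -> number of (valid) occurrences of that anchor within this
        read, counted over all anchor windows regardless of whether a target
        fit.
    """
    seq = read if isinstance(read, str) else read.sequence
    k, g = cfg.k, cfg.g
    n = len(seq)
    pairs: list[tuple[str, str, str]] = []
    multiplicity: dict[str, int] = {}
    if n < k:
        return pairs, multiplicity

    # Positions of invalid bases; ok[p] tells whether window [p, p+k) is clean.
    clean = _clean_window_starts(seq, k)

    kg = k + g
    for p in range(n - k + 1):
        if not clean[p]:
            continue
        anchor = seq[p : p + k]
        multiplicity[anchor] = multiplicity.get(anchor, 0) + 1
        q = p + kg
        if q + k <= n and clean[q]:
            pairs.append((anchor, DOWN, seq[q : q + k]))
        r = p - kg
        if r >= 0 and clean[r]:
            pairs.append((anchor, UP, seq[r : r + k]))
    return pairs, multiplicity


def _clean_window_starts(seq: str, k: int) -> list[bool]:
    """clean[p] is True iff seq[p:p+k] contains only A/C/G/T."""
    n = len(seq)
    bad = [i for i, b in enumerate(seq) if b not in _VALID]
    clean = [True] * (n - k + 1)
    for i in bad:
        lo = max(0, i - k + 1)
        hi = min(n - k, i)
        for p in range(lo, hi + 1):
            clean[p] = False
    return clean
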