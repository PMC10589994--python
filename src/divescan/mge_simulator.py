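"""Planted mobile-genetic-element read simulator and ROC evaluation.

Two scenarios are generated:

* *ancestral* — a single ancestral genome carries ``copy_number`` copies of
  the element; each descendant genome is an independently mutated copy of
  that ancestor (per-base mutation+indel rate ``mir``).
* *active* — each descendant genome is first mutated from an ancestor
  carrying one element copy, then receives ``activity`` additional exact
  copies at independent random loci, mimicking recent transposition.

Reads are fixed-length single-end, sampled uniformly from both strands
(each with probability 0.5) of every genome at the requested coverage,
with uniform substitution sequencing errors. Reads from all genomes are
shuffled into one pooled sample, so an anchor's reads arrive uniformly
over the file — the arrival model assumed by the admission and retention
rules. The ground truth records every element junction and the set of
*terminus k-mers*: at each junction, the element-side window occupying the
element's terminal k bases (the k-mer touching the junction), in both
orientations, as it appears in the final genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "SimRead",
    "SimTruth",
    "SimResult",
    "simulate_ancestral",
    "simulate_active",
    "write_fastq",
    "write_truth",
    "evaluate_auc",
    "reverse_complement",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-element simulation.

    ``copy_number`` applies to the ancestral scenario, ``activity`` (new
    insertions per genome) to the active scenario. ``mir`` is the combined
    per-base mutation+indel rate applied between the ancestor and each
    genome (9:1 substitutions to indels, indel lengths geometric with mean
    2); ``error_rate`` is the per-base substitution sequencing error.
    """

    genome_len: int = 100_000
    element_len: int = 1_500
    copy_number: int = 5
    activity: int = 20
    n_genomes: int = 10
    mir: float = 0.001
    coverage: float = 30.0
    read_len: int = 150
    error_rate: float = 0.001
    k: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.element_len >= self.genome_len:
            raise ValueError("element must be shorter than the genome")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0 <= self.mir < 1 and 0 <= self.error_rate < 1):
            raise ValueError("rates must lie in [0, 1)")


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str


@dataclass
class SimTruth:
    """Planted junction coordinates and true terminus k-mers.

    ``junctions`` holds (genome id, start, end, copy id) with start/end the
    0-based half-open element interval on that genome; ``terminus_kmers``
    is the set of element-terminal k-mers (both orientations) across all
    genomes.
    """

    k: int
    junctions: list[tuple[int, int, int, int]] = field(default_factory=list)
    terminus_kmers: set[str] = field(default_factory=set)

    def add_copy(self, genome_id: int, start: int, end: int, copy_id: int, genome: str) -> None:
        self.junctions.append((genome_id, start, end, copy_id))
        k = self.k
        for kmer in (genome[start : start + k], genome[end - k : end]):
            if len(kmer) == k:
                self.terminus_kmers.add(kmer)
                self.terminus_kmers.add(reverse_complement(kmer))

    def proximal_kmers(self, genomes: Sequence[str], window: int) -> set[str]:
        """All genome k-mers whose window lies within ``window`` bp of a junction.

        Alternative, looser positive labelling for sensitivity analysis.
        """
        k = self.k
        out: set[str] = set()
        for gid, start, end, _cid in self.junctions:
            g = genomes[gid]
            for j in (start, end):
                lo = max(0, j - window - k)
                hi = min(len(g) - k, j + window)
                for s in range(lo, hi + 1):
                    kmer = g[s : s + k]
                    out.add(kmer)
                    out.add(reverse_complement(kmer))
        return out


@dataclass
class SimResult:
    """Genomes, pooled shuffled reads, and ground truth for one scenario."""

    genomes: list[str]
    reads: list[SimRead]
    truth: SimTruth
    element: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(
    seq: str, mir: float, rng: np.random.Generator, tracked: Sequence[int]
) -> tuple[str, list[int]]:
    """Apply substitutions and indels at combined rate ``mir`` per base.

    Events are drawn per input base: 90% substitutions, 10% indels;
    indels split evenly between insertions and deletions with geometric
    (p=0.5, mean 2) lengths. ``tracked`` positions (sorted) are mapped to
    coordinates in the mutated sequence; a position deleted outright maps
    to the deletion point.
    """
    if mir == 0:
        return seq, list(tracked)
    n = len(seq)
    n_events = rng.binomial(n, mir)
    if n_events == 0:
        return seq, list(tracked)
    positions = np.sort(rng.choice(n, size=n_events, replace=False))
    kinds = rng.random(n_events)  # <0.9 sub; <0.95 ins; else del
    lens = rng.geometric(0.5, size=n_events)
    parts: list[str] = []
    # (orig_start, orig_end, out_start, deleted) spans covering [0, n)
    segs: list[tuple[int, int, int, bool]] = []
    cur = 0
    out_len = 0
    for pos, kind, ln in zip(positions, kinds, lens):
        pos = int(pos)
        if pos < cur:
            continue  # swallowed by a previous deletion
        segs.append((cur, pos, out_len, False))
        parts.append(seq[cur:pos])
        out_len += pos - cur
        cur = pos
        if kind < 0.9:  # substitution (length-preserving)
            old = seq[pos]
            parts.append("ACGT".replace(old, "")[rng.integers(3)])
            segs.append((pos, pos + 1, out_len, False))
            out_len += 1
            cur = pos + 1
        elif kind < 0.95:  # insertion before pos
            ins = _random_seq(rng, int(ln))
            parts.append(ins)
            out_len += len(ins)
        else:  # deletion starting at pos
            end = min(n, pos + int(ln))
            segs.append((pos, end, out_len, True))
            cur = end
    segs.append((cur, n, out_len, False))
    parts.append(seq[cur:])
    out_len += n - cur
    mapped: list[int] = []
    si = 0
    for t in tracked:  # tracked is sorted ascending
        while si < len(segs) and segs[si][1] <= t:
            si += 1
        if si == len(segs):
            mapped.append(out_len)  # t == n boundary
        else:
            a, _b, o, deleted = segs[si]
            mapped.append(o if deleted else o + (t - a))
    return "".join(parts), mapped


def _place_copies(
    backbone_len: int, element_len: int, n_copies: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping insertion points on the backbone, ascending."""
    if n_copies == 0:
        return []
    for _ in range(1000):
        points = np.sort(rng.integers(0, backbone_len + 1, size=n_copies))
        if n_copies == 1 or np.all(np.diff(points) > 0):
            return [int(p) for p in points]
    raise ValueError("could not place element copies without overlap")


def _insert_copies(backbone: str, element: str, points: Sequence[int]) -> tuple[str, list[tuple[int, int]]]:
    """Insert ``element`` at each backbone point; returns genome + intervals."""
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    cur = 0
    out_len = 0
    for p in points:
        parts.append(backbone[cur:p])
        out_len += p - cur
        intervals.append((out_len, out_len + len(element)))
        parts.append(element)
        out_len += len(element)
        cur = p
    parts.append(backbone[cur:])
    return "".join(parts), intervals


def _sequence_reads(
    genomes: Sequence[str], cfg: SimConfig, rng: np.random.Generator
) -> list[SimRead]:
    """Uniform fixed-length reads from both strands, with substitution errors,
    pooled over genomes and shuffled."""
    reads: list[SimRead] = []
    for gid, genome in enumerate(genomes):
        n_reads = int(round(cfg.coverage * len(genome) / cfg.read_len))
        starts = rng.integers(0, len(genome) - cfg.read_len + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for ri, (s, flip) in enumerate(zip(starts, flips)):
            seq = genome[int(s) : int(s) + cfg.read_len]
            if flip:
                seq = reverse_complement(seq)
            n_err = rng.binomial(cfg.read_len, cfg.error_rate)
            if n_err:
                arr = list(seq)
                for pos in rng.choice(cfg.read_len, size=n_err, replace=False):
                    old = arr[pos]
                    choices = [b for b in "ACGT" if b != old]
                    arr[pos] = choices[rng.integers(3)]
                seq = "".join(arr)
            reads.append(SimRead(id=f"g{gid}_r{ri}", sequence=seq))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def simulate_ancestral(cfg: SimConfig) -> SimResult:
    """Multi-copy inactive element: copies planted once in the ancestor,
    descendants diverge by ``mir``."""
    rng = np.random.default_rng(cfg.seed)
    element = _random_seq(rng, cfg.element_len)
    backbone = _random_seq(rng, cfg.genome_len)
    points = _place_copies(cfg.genome_len, cfg.element_len, cfg.copy_number, rng)
    ancestor, intervals = _insert_copies(backbone, element, points)
    truth = SimTruth(k=cfg.k)
    genomes: list[str] = []
    boundaries = [b for iv in intervals for b in iv]
    for gid in range(cfg.n_genomes):
        genome, mapped = _mutate(ancestor, cfg.mir, rng, boundaries)
        genomes.append(genome)
        for cid in range(len(intervals)):
            start, end = mapped[2 * cid], mapped[2 * cid + 1]
            if end - start >= cfg.k:
                truth.add_copy(gid, start, end, cid, genome)
    reads = _sequence_reads(genomes, cfg, rng)
    return SimResult(genomes=genomes, reads=reads, truth=truth, element=element)


def simulate_active(cfg: SimConfig) -> SimResult:
    """Recently active element: one ancestral copy, plus ``activity`` fresh
    exact insertions per genome (applied after divergence, so the new
    junctions flank exact element copies)."""
    rng = np.random.default_rng(cfg.seed)
    element = _random_seq(rng, cfg.element_len)
    backbone = _random_seq(rng, cfg.genome_len)
    ancestor, intervals = _insert_copies(
        backbone, element, _place_copies(cfg.genome_len, cfg.element_len, 1, rng)
    )
    truth = SimTruth(k=cfg.k)
    genomes: list[str] = []
    anc_bounds = [b for iv in intervals for b in iv]
    for gid in range(cfg.n_genomes):
        genome, mapped = _mutate(ancestor, cfg.mir, rng, anc_bounds)
        anc_iv = (mapped[0], mapped[1])
        # fresh insertion points, outside the ancestral copy
        pts: list[int] = []
        while len(pts) < cfg.activity:
            p = int(rng.integers(0, len(genome) + 1))
            if anc_iv[0] < p < anc_iv[1]:
                continue
            pts.append(p)
        pts = sorted(set(pts))
        while len(pts) < cfg.activity:  # resample collisions
            p = int(rng.integers(0, len(genome) + 1))
            if not (anc_iv[0] < p < anc_iv[1]) and p not in pts:
                pts.append(p)
                pts.sort()
        genome2, new_ivs = _insert_copies(genome, element, pts)
        genomes.append(genome2)
        shift = sum(1 for p in pts if p <= anc_iv[0]) * cfg.element_len
        anc_start = anc_iv[0] + shift
        if anc_iv[1] - anc_iv[0] >= cfg.k:
            truth.add_copy(gid, anc_start, anc_start + (anc_iv[1] - anc_iv[0]), 0, genome2)
        for cid, (s, e) in enumerate(new_ivs, start=1):
            truth.add_copy(gid, s, e, cid, genome2)
    reads = _sequence_reads(genomes, cfg, rng)
    return SimResult(genomes=genomes, reads=reads, truth=truth, element=element)


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> int:
    """Write reads as FASTQ (gzipped iff the path ends in .gz)."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
            n += 1
    return n


def write_truth(truth: SimTruth, bed_path: str | Path, kmer_path: str | Path) -> None:
    """Write junctions as BED-like TSV and the terminus k-mer list."""
    with open(bed_path, "w") as fh:
        fh.write("genome\tstart\tend\tcopy\n")
        for gid, start, end, cid in truth.junctions:
            fh.write(f"g{gid}\t{start}\t{end}\t{cid}\n")
    with open(kmer_path, "w") as fh:
        for kmer in sorted(truth.terminus_kmers):
            fh.write(kmer + "\n")


def evaluate_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
) -> float:
    """Rank-based ROC AUC (Mann-Whitney with mid-rank ties).

    Raises if either class is empty.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both positives and negatives")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)
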