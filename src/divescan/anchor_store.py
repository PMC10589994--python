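"""Streaming anchor dictionary with on-the-fly target clustering.

For every anchor k-mer the store keeps two *target dictionaries* (upstream
and downstream). Each newly observed target is compared, by Jaccard
similarity over its 7-mer set, against the keys of the clusters formed so
far: if some key exceeds the similarity threshold the target joins the
first such cluster (and replaces its key with probability 0.5), otherwise
it founds a new cluster. The binary new-cluster indicator sequence
X_1..X_N (the *trajectory*) is retained per dictionary; it is the raw
material for the null model fitted downstream.

Two probability rules keep the dictionary small on large files:

* admission — once the probability of having seen *zero* targets for a
  hypothetical anchor observed at the minimum viable rate,
  ``(1 - Nmin/L)^l``, drops below 0.01, no new anchors are admitted;
* retention — after admission closes, anchors whose predicted probability
  of reaching ``Nmin`` targets by end of file (normal approximation to the
  binomial survival function) falls below 0.5 are evicted.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable

from scipy.stats import norm

from .read_stream import DOWN, UP

__all__ = [
    "AdmissionConfig",
    "TargetCluster",
    "TargetDictionary",
    "AnchorState",
    "AnchorStore",
    "jaccard_similarity",
    "subkmer_set",
    "update_target_dictionary",
    "admission_zero_prob",
    "close_admission",
    "retention_probability",
    "ingest",
]

DEFAULT_NMIN = 25
DEFAULT_NMAX = 75


@dataclass(frozen=True)
class AdmissionConfig:
    """Thresholds governing target clustering and dictionary admission.

    ``js_threshold`` is strict: a target joins a cluster only when the
    Jaccard similarity to its key is strictly larger than the threshold.
    """

    Nmin: int = DEFAULT_NMIN
    Nmax: int = DEFAULT_NMAX
    js_threshold: float = 0.2
    sub_k: int = 7
    replace_prob: float = 0.5
    admission_alpha: float = 0.01
    retention_cutoff: float = 0.5
    sweep_interval: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.js_threshold < 1):
            raise ValueError("js_threshold must be in (0, 1)")
        if self.Nmin < 1 or self.Nmax < self.Nmin:
            raise ValueError("need 1 <= Nmin <= Nmax")


def subkmer_set(t: str, sub_k: int) -> frozenset[str]:
    """Set of all overlapping ``sub_k``-mers of ``t`` (duplicates collapse)."""
    if sub_k > len(t):
        raise ValueError("sub_k larger than sequence length")
    return frozenset(t[i : i + sub_k] for i in range(len(t) - sub_k + 1))


def jaccard_similarity(t1: str, t2: str, sub_k: int = 7) -> float:
    """Jaccard similarity between the ``sub_k``-mer sets of two sequences.

    For the default k=27, sub_k=7 each sequence contributes up to 21
    overlapping 7-mers.
    """
    x1 = subkmer_set(t1, sub_k)
    x2 = subkmer_set(t2, sub_k)
    inter = len(x1 & x2)
    if inter == 0:
        return 0.0
    return inter / len(x1 | x2)


class TargetCluster:
    """A cluster of mutually similar targets: current key plus a count."""

    __slots__ = ("key", "count")

    def __init__(self, key: str, count: int = 1) -> None:
        self.key = key
        self.count = count

    def __repr__(self) -> str:  # pragma: no cover
        return f"TargetCluster({self.key!r}, {self.count})"


class TargetDictionary:
    """Ordered clusters plus the new-cluster trajectory for one direction."""

    __slots__ = ("clusters", "trajectory", "closed")

    def __init__(self) -> None:
        self.clusters: list[TargetCluster] = []
        self.trajectory = bytearray()
        self.closed = False

    @property
    def N(self) -> int:
        """Targets observed so far."""
        return len(self.trajectory)

    @property
    def C_N(self) -> int:
        """Clusters formed so far."""
        return len(self.clusters)


class AnchorState:
    """Per-anchor record: two directional target dictionaries and metadata."""

    __slots__ = ("anchor", "up", "down", "first_seen", "max_within_read")

    def __init__(self, anchor: str, first_seen: int) -> None:
        self.anchor = anchor
        self.up = TargetDictionary()
        self.down = TargetDictionary()
        self.first_seen = first_seen
        self.max_within_read = 1

    def dictionary(self, direction: str) -> TargetDictionary:
        return self.up if direction == UP else self.down


def update_target_dictionary(
    d: TargetDictionary,
    target: str,
    cfg: AdmissionConfig,
    rng: random.Random,
) -> bool:
    """Route one target into ``d``; returns False if ``d`` is closed.

    The first cluster (in insertion order) whose key has Jaccard similarity
    strictly above ``cfg.js_threshold`` recruits the target; its key is
    replaced by the target with probability ``cfg.replace_prob``. If no
    cluster matches, a new cluster is appended. The trajectory records 1
    for a new cluster, 0 otherwise.
    """
    if d.closed:
        return False
    thr = cfg.js_threshold
    sub_k = cfg.sub_k
    target_set: frozenset[str] | None = None
    for cl in d.clusters:
        if target == cl.key:
            js = 1.0
        else:
            if target_set is None:
                target_set = subkmer_set(target, sub_k)
            key_set = subkmer_set(cl.key, sub_k)
            inter = len(target_set & key_set)
            js = inter / len(target_set | key_set) if inter else 0.0
        if js > thr:
            cl.count += 1
            if rng.random() < cfg.replace_prob:
                cl.key = target
            d.trajectory.append(0)
            if len(d.trajectory) >= cfg.Nmax:
                d.closed = True
            return True
    d.clusters.append(TargetCluster(target))
    d.trajectory.append(1)
    if len(d.trajectory) >= cfg.Nmax:
        d.closed = True
    return True


def admission_zero_prob(l: int, p_min: float) -> float:
    """P[zero targets after ``l`` records] for per-read target rate ``p_min``.

    ``p_min = Nmin / L`` is the slowest per-read rate at which an anchor
    could still accrue ``Nmin`` targets over the whole file.
    """
    if not (0.0 <= p_min <= 1.0):
        raise ValueError("p_min must be in [0, 1]")
    if l < 0:
        raise ValueError("l must be >= 0")
    if p_min == 1.0:
        return 1.0 if l == 0 else 0.0
    return math.exp(l * math.log1p(-p_min))


def close_admission(l: int, L: int, Nmin: int, alpha: float = 0.01) -> bool:
    """True once new anchors should no longer be admitted.

    An anchor first seen at record ``l`` has, under the minimum viable rate
    ``Nmin/L``, probability ``(1 - Nmin/L)^l`` of having produced no target
    yet; when that drops below ``alpha`` the anchor arrived too late to
    reach ``Nmin`` by end of file with high probability.
    """
    if L <= 0:
        return False
    p_min = min(1.0, Nmin / L)
    return admission_zero_prob(l, p_min) < alpha


def retention_probability(x: int, l: int, L: int, Nmin: int) -> float:
    """Approximate P[N >= Nmin] for final target count N ~ Binomial(L, x/l).

    ``x`` targets over ``l`` records give the empirical per-read rate
    ``x/l``; a normal approximation with continuity correction to the
    binomial survival function predicts whether the anchor will reach
    ``Nmin`` targets by the end of the file. Clamped to [0, 1].
    """
    if l <= 0:
        raise ValueError("l must be > 0 (rate undefined)")
    if not (0 <= x <= l <= L):
        raise ValueError("need 0 <= x <= l <= L")
    rate = x / l
    if rate == 0.0:
        return 0.0 if Nmin >= 1 else 1.0
    if rate == 1.0:
        return 1.0 if L >= Nmin else 0.0
    mean = L * rate
    sd = math.sqrt(L * rate * (1.0 - rate))
    z = (Nmin - 0.5 - mean) / sd
    p = float(norm.sf(z))
    return min(1.0, max(0.0, p))


class AnchorStore:
    """The anchor dictionary D_A for a single streaming pass.

    Parameters
    ----------
    cfg
        Admission/clustering thresholds.
    L
        Total number of FASTQ records that will be processed (after the
        per-sample cap). Needed by the admission and retention rules.
    rng
        A seeded ``random.Random``; consumed in stream order, so replaying
        the same file with the same seed reproduces the store exactly.
    """

    def __init__(self, cfg: AdmissionConfig, L: int, rng: random.Random) -> None:
        self.cfg = cfg
        self.L = L
        self.rng = rng
        self.anchors: dict[str, AnchorState] = {}
        self.admission_closed = False
        self.admission_close_index: int | None = None
        self.n_evicted = 0
        self._next_sweep = None  # set once admission closes

    # -- admission ---------------------------------------------------------

    def _update_admission(self, l: int) -> None:
        if not self.admission_closed and close_admission(
            l, self.L, self.cfg.Nmin, self.cfg.admission_alpha
        ):
            self.admission_closed = True
            self.admission_close_index = l
            self._next_sweep = l + self.cfg.sweep_interval

    # -- retention ---------------------------------------------------------

    def retention_sweep(self, l: int) -> int:
        """Evict anchors unlikely to reach Nmin in either direction.

        An anchor is kept if the retention probability of its better
        direction is at least the cutoff; anchors that already reached Nmin
        in some direction are always kept. Returns the number evicted.
        """
        cfg = self.cfg
        doomed: list[str] = []
        for anchor, st in self.anchors.items():
            nu, nd = st.up.N, st.down.N
            if nu >= cfg.Nmin or nd >= cfg.Nmin:
                continue
            p = retention_probability(max(nu, nd), l, self.L, cfg.Nmin)
            if p < cfg.retention_cutoff:
                doomed.append(anchor)
        for anchor in doomed:
            del self.anchors[anchor]
        self.n_evicted += len(doomed)
        return len(doomed)

    # -- ingestion ---------------------------------------------------------

    def ingest_read(
        self,
        pairs: Iterable[tuple[str, str, str]],
        multiplicity: dict[str, int],
        read_index: int,
    ) -> None:
        """Ingest one read's (anchor, direction, target) tuples.

        ``read_index`` is the 0-based ordinal of the read; admission state
        is updated from the number of records seen so far (index + 1).
        """
        l = read_index + 1
        self._update_admission(l)
        anchors = self.anchors
        admitting = not self.admission_closed
        rng = self.rng
        cfg = self.cfg
        for anchor, direction, target in pairs:
            st = anchors.get(anchor)
            if st is None:
                if not admitting:
                    continue
                st = AnchorState(anchor, first_seen=read_index)
                anchors[anchor] = st
            d = st.up if direction == UP else st.down
            if not d.closed:
                update_target_dictionary(d, target, cfg, rng)
        for anchor, count in multiplicity.items():
            if count > 1:
                st = anchors.get(anchor)
                if st is not None and count > st.max_within_read:
                    st.max_within_read = count
        if self._next_sweep is not None and l >= self._next_sweep:
            self.retention_sweep(l)
            self._next_sweep += cfg.sweep_interval

    # -- export ------------------------------------------------------------

    def dump_tsv(self, path) -> None:
        """Debug dump of the whole store: every anchor/direction with its
        target cluster keys and counts."""
        with open(path, "w") as fh:
            fh.write("anchor\tdirection\tN\tC_N\tclusters\n")
            for anchor, direction, d, _st in self.iter_dictionaries():
                if d.N == 0:
                    continue
                keys = ";".join(f"{cl.key}:{cl.count}" for cl in d.clusters)
                fh.write(f"{anchor}\t{direction}\t{d.N}\t{d.C_N}\t{keys}\n")

    def iter_dictionaries(self):
        """Yield (anchor, direction, TargetDictionary, AnchorState) sorted."""
        for anchor in sorted(self.anchors):
            st = self.anchors[anchor]
            yield anchor, UP, st.up, st
            yield anchor, DOWN, st.down, st


def ingest(
    pairs_and_multiplicity: Iterable[tuple[list[tuple[str, str, str]], dict[str, int], int]],
    store: AnchorStore,
) -> AnchorStore:
    """Feed a stream of per-read extractions into ``store`` and return it."""
    for pairs, multiplicity, read_index in pairs_and_multiplicity:
        store.ingest_read(pairs, multiplicity, read_index)
    return store
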