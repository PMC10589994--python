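"""Post-hoc processing of significant anchors.

Overlapping significant anchors are largely redundant (a hyper-variable
locus lights up a run of consecutive k-mers), so they are collapsed with
DBSCAN over Levenshtein edit distance (eps=2, min_samples=1 — equivalent
to connected components of the <=2-edit graph). Within each cluster a
representative anchor is picked per direction by maximal effect size.
Clusters that are significant in both directions, show a large mean effect
size and whose representative recurs within single reads are flagged as
CRISPR direct-repeat candidates. Further utilities classify supplied BLAST
hits, regress per-sample cluster proportions on covariates, and cluster
target sequences across samples.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import DBSCAN

from .anchor_store import jaccard_similarity
from .diversity_stats import DiversityResult, Q_CUTOFF
from .read_stream import DOWN, UP

__all__ = [
    "AnchorCluster",
    "AnnotationCall",
    "RegressionFit",
    "levenshtein",
    "cluster_anchors",
    "select_representatives",
    "crispr_filter",
    "classify_annotation",
    "read_blast_table",
    "fit_binomial_regression",
    "greedy_cluster_targets",
    "emit_seed_fasta",
]

CRISPR_ALPHA = 3.5
DBSCAN_EPS = 2

ANNOTATED = "annotated"
QUESTIONABLE = "questionable"
UNANNOTATED = "unannotated"


@dataclass
class AnchorCluster:
    """A group of near-identical significant anchors."""

    members: list[str]
    rep_up: str | None = None
    rep_down: str | None = None
    bidirectional: bool = False
    crispr_candidate: bool = False


@dataclass(frozen=True)
class AnnotationCall:
    """Annotation status of a representative anchor from BLAST e-values."""

    anchor: str
    best_evalue: float | None
    label: str
    source_db: str | None


@dataclass
class RegressionFit:
    """Binomial-GLM fit of cluster proportions on sample covariates."""

    beta: np.ndarray
    covariates: list[str]
    p_values: np.ndarray
    converged: bool


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (via edlib's global alignment)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def cluster_anchors(anchors: Sequence[str], eps: int = DBSCAN_EPS) -> list[AnchorCluster]:
    """Cluster anchor sequences with DBSCAN on Levenshtein distance.

    With min_samples=1 every point is a core point, so the clusters are the
    connected components of the graph joining anchors at edit distance
    <= eps; there are no noise points. Input order does not affect the
    partition; members are returned sorted and clusters ordered by their
    smallest member.
    """
    uniq = sorted(set(anchors))
    if not uniq:
        return []
    n = len(uniq)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(uniq[i], uniq[j])
            dist[i, j] = dist[j, i] = d
    labels = DBSCAN(eps=eps, min_samples=1, metric="precomputed").fit_predict(dist)
    groups: dict[int, list[str]] = {}
    for lab, a in zip(labels, uniq):
        groups.setdefault(int(lab), []).append(a)
    clusters = [AnchorCluster(members=sorted(ms)) for ms in groups.values()]
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def _best_member(
    cluster: AnchorCluster,
    results: Mapping[tuple[str, str], DiversityResult],
    direction: str,
) -> str | None:
    best: tuple[float, str] | None = None
    for a in cluster.members:
        r = results.get((a, direction))
        if r is None:
            continue
        # ties broken lexicographically: larger alpha wins, then smaller anchor
        cand = (-r.alpha, a)
        if best is None or cand < best:
            best = cand
    return best[1] if best else None


def select_representatives(
    cluster: AnchorCluster,
    results: Mapping[tuple[str, str], DiversityResult],
) -> tuple[str | None, str | None]:
    """Per-direction member with maximal effect size (lexicographic ties).

    A direction with no tested member yields ``None``.
    """
    rep_up = _best_member(cluster, results, UP)
    rep_down = _best_member(cluster, results, DOWN)
    cluster.rep_up = rep_up
    cluster.rep_down = rep_down
    return rep_up, rep_down


def crispr_filter(
    clusters: Iterable[AnchorCluster],
    results: Mapping[tuple[str, str], DiversityResult],
    alpha_threshold: float = CRISPR_ALPHA,
    q_cutoff: float = Q_CUTOFF,
) -> list[AnchorCluster]:
    """Flag CRISPR direct-repeat candidate clusters.

    A cluster is flagged when (i) it has significant members in both
    directions (bidirectional significance), (ii) the mean representative
    effect size 0.5*(alpha_up + alpha_down) reaches ``alpha_threshold``,
    and (iii) a representative anchor occurred more than once within at
    least one read (repeats recur within a read; isolated MGE termini do
    not). Returns the flagged clusters; all clusters get their
    ``bidirectional`` and ``crispr_candidate`` fields set.
    """
    flagged = []
    for cluster in clusters:
        if cluster.rep_up is None and cluster.rep_down is None:
            select_representatives(cluster, results)
        sig_up = any(
            (r := results.get((a, UP))) is not None
            and r.q_value is not None
            and r.q_value < q_cutoff
            for a in cluster.members
        )
        sig_down = any(
            (r := results.get((a, DOWN))) is not None
            and r.q_value is not None
            and r.q_value < q_cutoff
            for a in cluster.members
        )
        cluster.bidirectional = sig_up and sig_down
        cluster.crispr_candidate = False
        if cluster.bidirectional and cluster.rep_up and cluster.rep_down:
            alpha_u = results[(cluster.rep_up, UP)].alpha
            alpha_d = results[(cluster.rep_down, DOWN)].alpha
            multi = max(
                results[(cluster.rep_up, UP)].max_within_read,
                results[(cluster.rep_down, DOWN)].max_within_read,
            )
            if 0.5 * (alpha_u + alpha_d) >= alpha_threshold and multi >= 2:
                cluster.crispr_candidate = True
                flagged.append(cluster)
    return flagged


_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_table(path: str | Path, source_db: str | None = None) -> pd.DataFrame:
    """Read 12-column tabular alignment output (BLAST outfmt 6).

    Malformed rows are skipped with a warning.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                warnings.warn(f"skipping malformed BLAST row {i} in {path}")
                continue
            try:
                evalue = float(parts[10])
            except ValueError:
                warnings.warn(f"skipping malformed BLAST row {i} in {path}")
                continue
            rows.append({"qseqid": parts[0], "sseqid": parts[1], "evalue": evalue})
    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])
    df["source_db"] = source_db
    return df


def classify_annotation(blast_rows: pd.DataFrame, anchor: str) -> AnnotationCall:
    """Annotation label for one anchor from its minimum BLAST e-value.

    e <= 0.01 -> annotated; 0.01 < e < 0.25 -> questionable; e >= 0.25 or
    no hits at all -> unannotated.
    """
    hits = blast_rows[blast_rows["qseqid"] == anchor] if len(blast_rows) else blast_rows
    if len(hits) == 0:
        return AnnotationCall(anchor, None, UNANNOTATED, None)
    idx = hits["evalue"].idxmin()
    e = float(hits.loc[idx, "evalue"])
    db = hits.loc[idx].get("source_db")
    if e <= 0.01:
        label = ANNOTATED
    elif e < 0.25:
        label = QUESTIONABLE
    else:
        label = UNANNOTATED
    return AnnotationCall(anchor, e, label, db)


def fit_binomial_regression(
    C: Sequence[int],
    N: Sequence[int],
    X: pd.DataFrame | np.ndarray,
) -> RegressionFit:
    """Binomial GLM of per-sample cluster proportions on covariates.

    Models C_s ~ Binomial(N_s, p(x_s)) with logistic link
    p(x) = 1 / (1 + exp(-beta' x)); ``X`` must already contain an intercept
    column. Perfect separation or other convergence failure is reported via
    ``converged=False`` (coefficients are still returned, with a warning).
    """
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(C > N):
        raise ValueError("cluster count exceeds target count")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        exog = X.to_numpy(dtype=float)
    else:
        exog = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(exog.shape[1])]
    endog = np.column_stack([C, N - C])
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:  # e.g. PerfectSeparationError
            warnings.warn(f"binomial regression failed to converge: {exc}")
            beta = np.full(exog.shape[1], np.nan)
            return RegressionFit(beta, names, np.full_like(beta, np.nan), False)
        if any("separation" in str(w.message).lower() or "converge" in str(w.message).lower()
               for w in caught):
            converged = False
    if not getattr(fit, "converged", True):
        converged = False
    return RegressionFit(
        beta=np.asarray(fit.params, dtype=float),
        covariates=names,
        p_values=np.asarray(fit.pvalues, dtype=float),
        converged=converged,
    )


def greedy_cluster_targets(
    targets_with_counts: Iterable[tuple[str, int]],
    js_threshold: float = 0.2,
    sub_k: int = 7,
) -> dict[str, str]:
    """Greedy across-sample clustering of target sequences.

    Repeatedly seed with the highest-total-count unassigned target (ties by
    lexicographic order for determinism) and recruit every unassigned
    target with Jaccard similarity strictly above ``js_threshold`` to the
    seed. Returns target -> seed assignments; the number of distinct seeds
    is the number of across-sample clusters.
    """
    pool: dict[str, int] = {}
    for t, c in targets_with_counts:
        pool[t] = pool.get(t, 0) + int(c)
    remaining = sorted(pool, key=lambda t: (-pool[t], t))
    assignment: dict[str, str] = {}
    unassigned = set(remaining)
    for seed in remaining:
        if seed not in unassigned:
            continue
        assignment[seed] = seed
        unassigned.discard(seed)
        recruits = [
            t for t in unassigned if jaccard_similarity(seed, t, sub_k) > js_threshold
        ]
        for t in recruits:
            assignment[t] = seed
            unassigned.discard(t)
    return assignment


def emit_seed_fasta(
    clusters: Iterable[AnchorCluster],
    results: Mapping[tuple[str, str], DiversityResult],
    path: str | Path,
    q_cutoff: float = Q_CUTOFF,
) -> int:
    """Write representatives significant in exactly one direction as FASTA.

    One-sided hyper-variability is the signature of an MGE terminus, so
    these anchors are the seeds for downstream (external) seed-based
    assembly. Headers carry anchor, direction, effect size and q-value.
    Returns the number of records written.
    """
    n = 0
    with open(path, "w") as fh:
        for cluster in clusters:
            sides: list[tuple[str, DiversityResult]] = []
            for direction, rep in ((UP, cluster.rep_up), (DOWN, cluster.rep_down)):
                if rep is None:
                    continue
                r = results.get((rep, direction))
                if r is not None and r.q_value is not None and r.q_value < q_cutoff:
                    sides.append((direction, r))
            if len(sides) != 1:
                continue
            direction, r = sides[0]
            fh.write(
                f">{r.anchor}|direction={direction}|alpha={r.alpha:.4f}|q={r.q_value:.3e}\n"
            )
            fh.write(r.anchor + "\n")
            n += 1
    return n
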