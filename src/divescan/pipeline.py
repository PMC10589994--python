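"""End-to-end pipeline: stream reads -> anchor store -> statistics -> output.

A single analysis pass over the FASTQ builds the anchor store (a cheap
record count fixes the total L first); the pooled trajectories then
calibrate the null model, every anchor x direction with at least Nmin
targets is tested, p-values are BH-corrected, effect sizes computed,
significant anchors clustered, representatives picked, CRISPR candidates
flagged and assembly seeds written.
"""

from __future__ import annotations

import logging
import random
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import anchor_store as astore
from . import diversity_stats as dstats
from . import postprocess as post
from . import read_stream as rs


__all__ = ["RunConfig", "RunResult", "run_dive", "build_store", "analyze_store"]

Q_CUTOFF_DEFAULT = dstats.Q_CUTOFF

logger = logging.getLogger("divescan")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (defaults as shipped)."""

    k: int = 27
    g: int = 0
    Nmin: int = 25
    Nmax: int = 75
    max_records: int = 2_500_000
    js_threshold: float = 0.2
    sub_k: int = 7
    replace_prob: float = 0.5
    q_cutoff: float = 0.1
    p_drop: float = 0.1
    dbscan_eps: int = 2
    crispr_alpha: float = 3.5
    bh_monotone: bool = True
    seed: int = 0

    def window(self) -> rs.WindowConfig:
        return rs.WindowConfig(k=self.k, g=self.g, max_records=self.max_records)

    def admission(self) -> astore.AdmissionConfig:
        return astore.AdmissionConfig(
            Nmin=self.Nmin,
            Nmax=self.Nmax,
            js_threshold=self.js_threshold,
            sub_k=self.sub_k,
            replace_prob=self.replace_prob,
        )


@dataclass
class RunResult:
    """Everything the pipeline produced, in memory."""

    results: list[dstats.DiversityResult]
    results_table: pd.DataFrame
    null_model: dstats.NullModel | None
    clusters: list[post.AnchorCluster]
    store: astore.AnchorStore
    L: int
    reads_processed: int
    m: int = 0
    n_retained: int = 0
    n_significant: int = 0

    def by_key(self) -> dict[tuple[str, str], dstats.DiversityResult]:
        return {(r.anchor, r.direction): r for r in self.results}


def build_store(
    fastq_paths: Sequence[str | Path],
    cfg: RunConfig,
    L: int | None = None,
) -> tuple[astore.AnchorStore, int, int]:
    """Single streaming pass over the input files. Returns (store, L, reads)."""
    wcfg = cfg.window()
    if L is None:
        L = rs.count_records(fastq_paths, cfg.max_records)
    rng = random.Random(cfg.seed)
    store = astore.AnchorStore(cfg.admission(), L=L, rng=rng)
    index = 0
    remaining = cfg.max_records
    for path in fastq_paths:
        if remaining <= 0:
            break
        for read in rs.stream_reads(path, max_records=remaining, start_index=index):
            pairs, mult = rs.extract_pairs(read, wcfg)
            store.ingest_read(pairs, mult, read.index)
            index = read.index + 1
            if index % 100_000 == 0:
                logger.info(
                    "processed %d reads; %d anchors held", index, len(store.anchors)
                )
        remaining = cfg.max_records - index
    return store, L, index


def analyze_store(store: astore.AnchorStore, cfg: RunConfig) -> RunResult:
    """Fit the null, test every eligible anchor x direction, correct, cluster."""
    trajectories = []
    for _anchor, _direction, d, _st in store.iter_dictionaries():
        if d.N >= 1:
            trajectories.append(d.trajectory)
    if not trajectories:
        logger.warning("no trajectories observed; emitting empty results")
        return RunResult(
            results=[], results_table=_empty_table(), null_model=None,
            clusters=[], store=store, L=store.L, reads_processed=0,
        )
    null = dstats.estimate_null(trajectories)

    ledger = dstats.TestLedger()
    results: list[dstats.DiversityResult] = []
    tail_cache: dict[int, "list[float]"] = {}
    p_hat = null.p_hat
    for anchor, direction, d, st in store.iter_dictionaries():
        N = d.N
        if N < cfg.Nmin:
            continue
        c = d.C_N
        tails = tail_cache.get(N)
        if tails is None:
            pmf = dstats.poisson_binomial_pmf(p_hat[:N])
            # tails[c] = P[C >= c], c = 0..N
            acc = pmf[::-1].cumsum()[::-1]
            tails = [min(1.0, max(float(acc[i]), 0.0)) for i in range(N + 1)]
            tail_cache[N] = tails
        p = tails[c] if c <= N else 0.0
        p = max(p, 5e-324)
        alpha = dstats.effect_size(c, N, p_hat)
        r = dstats.DiversityResult(
            anchor=anchor, direction=direction, N=N, C_N=c,
            p_value=p, alpha=alpha, max_within_read=st.max_within_read,
        )
        results.append(r)
        ledger.record((anchor, direction), p, p_drop=cfg.p_drop)

    qmap = dstats.bh_correct(ledger, monotone=cfg.bh_monotone, q_cutoff=cfg.q_cutoff)
    for r in results:
        r.q_value = qmap.get((r.anchor, r.direction))
    n_significant = sum(1 for r in results if r.q_value is not None and r.q_value < cfg.q_cutoff)

    significant = sorted(
        {r.anchor for r in results if r.q_value is not None and r.q_value < cfg.q_cutoff}
    )
    by_key = {(r.anchor, r.direction): r for r in results}
    clusters = post.cluster_anchors(significant, eps=cfg.dbscan_eps)
    for cluster in clusters:
        post.select_representatives(cluster, by_key)
    post.crispr_filter(clusters, by_key, alpha_threshold=cfg.crispr_alpha, q_cutoff=cfg.q_cutoff)

    out = RunResult(
        results=results,
        results_table=_results_table(results),
        null_model=null,
        clusters=clusters,
        store=store,
        L=store.L,
        reads_processed=store.L,
        m=ledger.m,
        n_retained=len(ledger.retained),
        n_significant=n_significant,
    )
    logger.info(
        "m=%d tests; %d retained at p<=%.3g; %d significant at q<%.3g",
        out.m, out.n_retained, cfg.p_drop, out.n_significant, cfg.q_cutoff,
    )
    return out


_COLUMNS = ["anchor", "direction", "N", "C_N", "p_value", "q_value", "alpha", "max_within_read"]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_COLUMNS)


def _results_table(results: list[dstats.DiversityResult]) -> pd.DataFrame:
    rows = [
        {
            "anchor": r.anchor,
            "direction": r.direction,
            "N": r.N,
            "C_N": r.C_N,
            "p_value": r.p_value,
            "q_value": r.q_value if r.q_value is not None else "NA",
            "alpha": r.alpha,
            "max_within_read": r.max_within_read,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.sort_values(["anchor", "direction"], kind="mergesort").reset_index(drop=True)


def run_dive(
    fastq_paths: Sequence[str | Path],
    cfg: RunConfig,
    out_prefix: str | Path | None = None,
    L: int | None = None,
) -> RunResult:
    """Run the full pipeline; optionally write the output bundle.

    Outputs (with ``out_prefix``): ``<prefix>.results.tsv``,
    ``<prefix>.clusters.tsv``, ``<prefix>.seeds.fasta``,
    ``<prefix>.targets.tsv`` (per-anchor target cluster dump for
    across-sample merging), ``<prefix>.log`` and ``<prefix>.config``.
    """
    handler = None
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(f"{out_prefix}.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        store, L, n_reads = build_store(fastq_paths, cfg, L=L)
        logger.info(
            "L=%d records; %d reads processed; admission closed at read %s; %d anchors held; %d evicted",
            L, n_reads, store.admission_close_index, len(store.anchors), store.n_evicted,
        )
        result = analyze_store(store, cfg)
        result.reads_processed = n_reads
        if not result.results:
            logger.info("no anchor reached Nmin=%d; results are empty", cfg.Nmin)
        if out_prefix is not None:
            _write_bundle(result, cfg, out_prefix)
        return result
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _write_bundle(result: RunResult, cfg: RunConfig, prefix: Path) -> None:
    result.results_table.to_csv(f"{prefix}.results.tsv", sep="\t", index=False)
    by_key = result.by_key()
    rows = []
    for i, cluster in enumerate(result.clusters):
        rows.append(
            {
                "cluster_id": i,
                "members": ",".join(cluster.members),
                "rep_up": cluster.rep_up or "NA",
                "rep_down": cluster.rep_down or "NA",
                "bidirectional": cluster.bidirectional,
                "crispr_flag": cluster.crispr_candidate,
            }
        )
    pd.DataFrame(
        rows, columns=["cluster_id", "members", "rep_up", "rep_down", "bidirectional", "crispr_flag"]
    ).to_csv(f"{prefix}.clusters.tsv", sep="\t", index=False)
    post.emit_seed_fasta(result.clusters, by_key, f"{prefix}.seeds.fasta", q_cutoff=cfg.q_cutoff)
    _write_targets(result, f"{prefix}.targets.tsv")
    with open(f"{prefix}.config", "w") as fh:
        for key, value in asdict(cfg).items():
            fh.write(f"{key}={value}\n")


def _write_targets(result: RunResult, path: str) -> None:
    """Merge dump: target clusters of the significant anchors.

    Restricted to anchors reported at q < 0.1 in some direction — these are
    the loci whose target repertoires are compared across samples.
    """
    significant = {
        r.anchor for r in result.results
        if r.q_value is not None and r.q_value < Q_CUTOFF_DEFAULT
    }
    with open(path, "w") as fh:
        fh.write("anchor\tdirection\tN\tC_N\tclusters\n")
        for anchor, direction, d, _st in result.store.iter_dictionaries():
            if d.N == 0 or anchor not in significant:
                continue
            keys = ";".join(f"{cl.key}:{cl.count}" for cl in d.clusters)
            fh.write(f"{anchor}\t{direction}\t{d.N}\t{d.C_N}\t{keys}\n")
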