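"""Anchor clustering, representatives, CRISPR filter, annotation, regression."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import divescan as dv
from divescan.diversity_stats import DiversityResult
from divescan.read_stream import DOWN, UP

from conftest import random_seq


def components_oracle(anchors, eps=2):
    """Brute-force connected components of the <=eps edit-distance graph."""
    parent = {a: a for a in anchors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(anchors, 2):
        if dv.levenshtein(a, b) <= eps:
            parent[find(a)] = find(b)
    comps = {}
    for a in anchors:
        comps.setdefault(find(a), set()).add(a)
    return {frozenset(c) for c in comps.values()}


def result(anchor, direction, alpha=1.0, q=0.01, multi=1, N=30, C=20):
    return DiversityResult(
        anchor=anchor, direction=direction, N=N, C_N=C,
        p_value=1e-4, alpha=alpha, q_value=q, max_within_read=multi,
    )


class TestClusterAnchors:
    def test_identical_anchors_one_cluster(self):
        a = random_seq(random.Random(0), 27)
        clusters = dv.cluster_anchors([a, a])
        assert len(clusters) == 1 and clusters[0].members == [a]

    def test_distance_three_separates(self):
        a = random_seq(random.Random(1), 27)
        b = "TTT" + a[3:] if not a.startswith("TTT") else "AAA" + a[3:]
        assert dv.levenshtein(a, b) == 3
        clusters = dv.cluster_anchors([a, b])
        assert len(clusters) == 2

    def test_transitive_chaining(self):
        a = random_seq(random.Random(2), 27)
        b = ("TT" + a[2:]) if a[:2] != "TT" else ("AA" + a[2:])
        c = b[:-2] + ("GG" if b[-2:] != "GG" else "CC")
        assert dv.levenshtein(a, b) == 2 and dv.levenshtein(b, c) == 2
        assert dv.levenshtein(a, c) == 4
        clusters = dv.cluster_anchors([a, b, c])
        assert len(clusters) == 1
        assert {frozenset(cl.members) for cl in clusters} == components_oracle([a, b, c])

    def test_matches_components_oracle_on_random_anchors(self):
        rng = random.Random(3)
        base = [random_seq(rng, 27) for _ in range(20)]
        anchors = set(base)
        for a in base:  # add near-duplicates to create edges
            for _ in range(4):
                pos = rng.randrange(27)
                anchors.add(a[:pos] + rng.choice("ACGT") + a[pos + 1 :])
        anchors = sorted(anchors)[:100]
        clusters = dv.cluster_anchors(anchors)
        assert {frozenset(cl.members) for cl in clusters} == components_oracle(anchors)
        # partition property
        assert sorted(m for cl in clusters for m in cl.members) == sorted(anchors)


class TestRepresentatives:
    def test_singleton_is_its_own_representative(self):
        a = random_seq(random.Random(4), 27)
        res = {(a, UP): result(a, UP), (a, DOWN): result(a, DOWN)}
        cluster = dv.AnchorCluster(members=[a])
        assert dv.select_representatives(cluster, res) == (a, a)

    def test_max_alpha_wins(self):
        a, b = sorted(random_seq(random.Random(i), 27) for i in (5, 6))
        res = {(a, DOWN): result(a, DOWN, alpha=1.0), (b, DOWN): result(b, DOWN, alpha=2.5)}
        cluster = dv.AnchorCluster(members=[a, b])
        assert dv.select_representatives(cluster, res) == (None, b)

    def test_tie_breaks_lexicographically(self):
        anchors = sorted(random_seq(random.Random(i), 27) for i in (7, 8, 9))
        res = {(a, DOWN): result(a, DOWN, alpha=1.5) for a in anchors}
        cluster = dv.AnchorCluster(members=list(reversed(anchors)))
        _, rep_down = dv.select_representatives(cluster, res)
        # oracle: enumerate (alpha, anchor) pairs, max alpha then min anchor
        expected = min(anchors)
        assert rep_down == expected


class TestCrisprFilter:
    def _cluster(self, alpha_u, alpha_d, q_u=0.01, q_d=0.01, multi=2):
        a = random_seq(random.Random(10), 27)
        res = {
            (a, UP): result(a, UP, alpha=alpha_u, q=q_u, multi=multi),
            (a, DOWN): result(a, DOWN, alpha=alpha_d, q=q_d, multi=multi),
        }
        return dv.AnchorCluster(members=[a]), res

    def test_boundary_mean_passes(self):
        cluster, res = self._cluster(4.0, 3.0)
        assert dv.crispr_filter([cluster], res) == [cluster]
        assert cluster.crispr_candidate and cluster.bidirectional

    def test_one_sided_significance_fails(self):
        cluster, res = self._cluster(4.0, 4.0, q_d=0.5)
        assert dv.crispr_filter([cluster], res) == []
        assert not cluster.bidirectional

    def test_small_effect_fails(self):
        cluster, res = self._cluster(3.3, 3.3)
        assert dv.crispr_filter([cluster], res) == []

    def test_single_occurrence_per_read_fails(self):
        cluster, res = self._cluster(4.0, 4.0, multi=1)
        assert dv.crispr_filter([cluster], res) == []


class TestAnnotation:
    def _rows(self, evalues, anchor="A" * 27):
        return pd.DataFrame(
            {"qseqid": [anchor] * len(evalues), "sseqid": "db1", "evalue": evalues,
             "source_db": "db"}
        )

    @pytest.mark.parametrize(
        "evalues,label",
        [
            ([1e-5, 0.3], "annotated"),
            ([0.05], "questionable"),
            ([0.5], "unannotated"),
            ([0.01], "annotated"),   # boundary: e = 0.01
            ([0.25], "unannotated"), # boundary: e = 0.25
        ],
    )
    def test_evalue_bands(self, evalues, label):
        call = dv.classify_annotation(self._rows(evalues), "A" * 27)
        assert call.label == label
        assert call.best_evalue == min(evalues)

    def test_no_hits_unannotated(self):
        call = dv.classify_annotation(self._rows([]), "A" * 27)
        assert call.label == "unannotated" and call.best_evalue is None

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        good = "\t".join(["A" * 27, "s1", "100", "27", "0", "0", "1", "27", "5", "31", "1e-8", "50"])
        path.write_text(f"{good}\nnot\tenough\tcolumns\n")
        with pytest.warns(UserWarning, match="malformed"):
            df = dv.read_blast_table(path)
        assert len(df) == 1


class TestBinomialRegression:
    def test_intercept_only_closed_form(self):
        # intercept-only binomial MLE: beta0 = logit(sum C / sum N)
        rng = np.random.default_rng(0)
        N = np.full(50, 40)
        C = rng.binomial(40, 0.3, size=50)
        X = np.ones((50, 1))
        fit = dv.fit_binomial_regression(C, N, X)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(logit(C.sum() / N.sum()), abs=1e-6)

    def test_balanced_gives_zero_intercept(self):
        N = np.full(20, 50)
        C = N // 2
        fit = dv.fit_binomial_regression(C, N, np.ones((20, 1)))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n_samples, trials = 200, 50
        beta = np.array([-1.0, 0.8])
        x = rng.normal(size=n_samples)
        X = np.column_stack([np.ones(n_samples), x])
        p = 1 / (1 + np.exp(-(X @ beta)))
        C = rng.binomial(trials, p)
        fit = dv.fit_binomial_regression(C, np.full(n_samples, trials), X)
        assert fit.converged
        # within 3 SE of the planted coefficients
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ (X * (trials * p * (1 - p))[:, None]))))
        assert np.all(np.abs(fit.beta - beta) < 3 * se)

    def test_c_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            dv.fit_binomial_regression([5], [3], np.ones((1, 1)))


class TestGreedyTargetClustering:
    def test_all_identical_one_cluster(self):
        t = random_seq(random.Random(11), 27)
        assignment = dv.greedy_cluster_targets([(t, 3), (t, 2)])
        assert assignment == {t: t}

    def test_dissimilar_targets_separate_seeded_by_count(self):
        t1, t2 = "A" * 27, "C" * 27
        assignment = dv.greedy_cluster_targets([(t1, 2), (t2, 5)])
        assert assignment == {t1: t1, t2: t2}

    def test_matches_greedy_oracle(self):
        rng = random.Random(12)
        targets = []
        base = [random_seq(rng, 27) for _ in range(3)]
        for b in base:
            targets.append((b, rng.randrange(1, 50)))
            for _ in range(2):
                pos = rng.randrange(27)
                variant = b[:pos] + rng.choice("ACGT") + b[pos + 1 :]
                targets.append((variant, rng.randrange(1, 50)))
        got = dv.greedy_cluster_targets(targets)

        # independent re-implementation of the greedy rule
        pool = {}
        for t, c in targets:
            pool[t] = pool.get(t, 0) + c
        expected = {}
        remaining = set(pool)
        while remaining:
            seed = min(remaining, key=lambda t: (-pool[t], t))
            members = {t for t in remaining if t == seed or dv.jaccard_similarity(seed, t) > 0.2}
            for t in members:
                expected[t] = seed
            remaining -= members
        assert got == expected


class TestSeedFasta:
    def _setup(self, q_up, q_down):
        a = random_seq(random.Random(13), 27)
        res = {
            (a, UP): result(a, UP, q=q_up),
            (a, DOWN): result(a, DOWN, q=q_down),
        }
        cluster = dv.AnchorCluster(members=[a], rep_up=a, rep_down=a)
        return a, cluster, res

    def test_bidirectional_excluded(self, tmp_path):
        _, cluster, res = self._setup(0.01, 0.01)
        path = tmp_path / "seeds.fasta"
        assert dv.emit_seed_fasta([cluster], res, path) == 0
        assert path.read_text() == ""

    def test_one_sided_included_with_direction(self, tmp_path):
        a, cluster, res = self._setup(0.5, 0.01)
        path = tmp_path / "seeds.fasta"
        assert dv.emit_seed_fasta([cluster], res, path) == 1
        text = path.read_text()
        assert "direction=down" in text and a in text

    def test_empty_results_valid_fasta(self, tmp_path):
        path = tmp_path / "seeds.fasta"
        assert dv.emit_seed_fasta([], {}, path) == 0
        assert path.exists()
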