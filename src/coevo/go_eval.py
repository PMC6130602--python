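"""Functional evaluation of profile clusterings with the Gene Ontology.

Term-to-term similarity follows the Wang (G-SESAME) measure: a term's
semantic value is spread to its ancestors with multiplicative decay per
edge (0.8 for ``is_a``, 0.6 for ``part_of`` by default), and two terms
are compared by the aggregate contribution of their shared ancestors.
Gene-to-gene similarity is the best-match average over the two
annotation sets.  Clusterings are scored by the size-weighted mean of
within-cluster gene similarities, with a tip-relabel permutation null.
Term enrichment across clusters uses Pearson's chi-squared statistic
with a resampling null (random reassignment of annotated genes to the
observed cluster sizes), followed by Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GoDag",
    "parse_obo",
    "read_annotations",
    "propagate_annotations",
    "term_similarity",
    "gene_similarity",
    "clustering_score",
    "relabel_null",
    "enrichment_test",
    "bh_adjust",
    "binomial_overrepresentation",
]

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class GoDag:
    """Directed acyclic ontology graph (edges child -> parent).

    Only ``is_a`` and ``part_of`` edges carry semantic weight; other
    relationship types are ignored.  ``weights`` maps edge type to its
    semantic decay factor.
    """

    graph: nx.MultiDiGraph
    weights: dict = field(default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS))
    _svalues: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, term: str):
        """(parent, weight) pairs for the weighted relations of a term."""
        out = []
        for _, parent, rel in self.graph.out_edges(term, keys=True):
            if rel in self.weights:
                out.append((parent, self.weights[rel]))
        return out

    def ancestors(self, term: str) -> set:
        """Weighted-relation ancestor closure of a term, including itself."""
        if term not in self.graph:
            raise KeyError(f"unknown GO term {term!r}")
        seen = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, _ in self.parents(t):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def s_values(self, term: str) -> dict:
        """Wang semantic contributions of a term's ancestors.

        S(term) = 1; walking upward, S(parent) = max over incoming
        weighted edges of w_e * S(child).
        """
        if term in self._svalues:
            return self._svalues[term]
        if term not in self.graph:
            raise KeyError(f"unknown GO term {term!r}")
        anc = self.ancestors(term)
        sub = self.graph.subgraph(anc)
        s = {term: 1.0}
        # relax in topological order from the query term upward
        for t in nx.topological_sort(sub):
            if t not in s:
                continue
            for parent, w in self.parents(t):
                cand = w * s[t]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        self._svalues[term] = s
        return s

    def semantic_value(self, term: str) -> float:
        return sum(self.s_values(term).values())


def parse_obo(path: str, namespace: str | None = "biological_process",
              weights: dict | None = None) -> GoDag:
    """Read an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are dropped; ``namespace=None`` keeps every namespace
    (the default keeps biological_process only).
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    if namespace is not None:
        keep = [n for n, d in graph.nodes(data=True)
                if d.get("namespace", namespace) == namespace]
        graph = graph.subgraph(keep).copy()
    roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
    if graph.number_of_nodes() and not roots:
        raise ValueError("ontology has no root term")
    return GoDag(graph=nx.MultiDiGraph(graph),
                 weights=dict(weights or DEFAULT_EDGE_WEIGHTS))


def read_annotations(path: str, dag: GoDag | None = None) -> dict:
    """Two-column TSV (gene, GO term) -> {gene: set of terms}.

    Terms absent from ``dag`` are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "term"], dtype=str)
    annot: dict = {}
    dropped = set()
    for gene, term in df.itertuples(index=False):
        if dag is not None and term not in dag:
            dropped.add(term)
            continue
        annot.setdefault(gene, set()).add(term)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} annotation terms absent "
                      f"from the ontology: {sorted(dropped)[:5]}...")
    return annot


def propagate_annotations(dag: GoDag, annot: dict) -> dict:
    """Expand each gene's terms to their full ancestor closure.

    By default genes are compared through their directly assigned terms
    (ancestors contribute only via the Wang S-values); this helper
    supports sensitivity analyses with explicitly propagated
    annotations.
    """
    return {g: set().union(*(dag.ancestors(t) for t in terms)) if terms
            else set() for g, terms in annot.items()}


# ---------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------


def term_similarity(dag: GoDag, a: str, b: str) -> float:
    """Wang similarity: shared-ancestor contributions over total
    semantic values.  Symmetric, in [0, 1], and 1 on identity."""
    sa, sb = dag.s_values(a), dag.s_values(b)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


def gene_similarity(dag: GoDag, annot: dict, g1: str, g2: str) -> float:
    """Best-match-average similarity of two genes' annotation sets."""
    t1, t2 = annot.get(g1), annot.get(g2)
    if not t1 or not t2:
        raise ValueError(f"both genes must be annotated: {g1!r}, {g2!r}")
    t1, t2 = sorted(t1), sorted(t2)
    sim = np.array([[term_similarity(dag, u, v) for v in t2] for u in t1])
    return (sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(t1) + len(t2))


# ---------------------------------------------------------------------
# Clustering-level scores
# ---------------------------------------------------------------------


def _cluster_members(clusters) -> dict:
    if hasattr(clusters, "members"):
        return clusters.members()
    out: dict = {}
    for gene, c in clusters.items():
        out.setdefault(c, []).append(gene)
    return {c: sorted(m) for c, m in out.items()}


def clustering_score(dag: GoDag, annot: dict, clusters):
    """Size-weighted mean within-cluster functional similarity.

    Per cluster: the mean :func:`gene_similarity` over all pairs of
    annotated members.  Overall: the mean of per-cluster scores weighted
    by annotated-member count.  Clusters with fewer than two annotated
    genes cannot be scored and are excluded (returned for reporting).

    Returns ``(overall, per_cluster, excluded)``.
    """
    members = _cluster_members(clusters)
    per_cluster: dict = {}
    excluded: list = []
    for c, genes in members.items():
        ann = [g for g in genes if annot.get(g)]
        if len(ann) < 2:
            excluded.append(c)
            continue
        sims = [gene_similarity(dag, annot, a, b)
                for i, a in enumerate(ann) for b in ann[i + 1:]]
        per_cluster[c] = (float(np.mean(sims)), len(ann))
    if not per_cluster:
        raise ValueError("no cluster with >= 2 annotated genes to score")
    total = sum(n for _, n in per_cluster.values())
    overall = sum(s * n for s, n in per_cluster.values()) / total
    return overall, {c: s for c, (s, _) in per_cluster.items()}, excluded


def relabel_null(dag: GoDag, annot: dict, clusters, n_sets: int = 5,
                 seed: int = 0) -> np.ndarray:
    """Null scores from random reassignment of gene labels to the fixed
    cluster structure (cluster sizes preserved exactly)."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    members = _cluster_members(clusters)
    genes = sorted(g for m in members.values() for g in m)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_sets)
    for k in range(n_sets):
        perm = rng.permutation(genes)
        it = iter(perm)
        shuffled = {c: [next(it) for _ in m] for c, m in members.items()}
        flat = {g: c for c, m in shuffled.items() for g in m}
        scores[k], _, _ = clustering_score(dag, annot, flat)
    return scores


# ---------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _chi2_stat(counts: np.ndarray, expected: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (counts - expected) ** 2 / expected
    term[expected == 0] = 0.0
    return term.sum(axis=-1)


def enrichment_test(clusters, annot: dict, n_resamples: int = 100_000,
                    min_freq: int = 5, seed: int = 0) -> pd.DataFrame:
    """Resampling chi-squared test of term concentration across clusters.

    For each term carried by at least ``min_freq`` annotated genes, the
    observed Pearson chi-squared statistic compares the term's counts per
    cluster with expectations proportional to (annotated) cluster sizes.
    The null distribution comes from ``n_resamples`` random reassignments
    of all annotated genes to clusters of the observed sizes; p-values
    use the add-one estimator (1 + exceedances) / (1 + resamples), so
    they are never zero.  BH-adjusted p-values span all tested terms.
    """
    if n_resamples < 1 or min_freq < 1:
        raise ValueError("n_resamples and min_freq must be >= 1")
    members = _cluster_members(clusters)
    genes = sorted(g for m in members.values() for g in m if annot.get(g))
    if not genes:
        raise ValueError("no annotated genes in the clustering")
    cluster_ids = sorted(members)
    cluster_of = {g: c for c, m in members.items() for g in m}
    labels = np.array([cluster_ids.index(cluster_of[g]) for g in genes])
    sizes = np.bincount(labels, minlength=len(cluster_ids))
    n = len(genes)

    term_freq: dict = {}
    for g in genes:
        for t in annot[g]:
            term_freq[t] = term_freq.get(t, 0) + 1
    terms = sorted(t for t, f in term_freq.items() if f >= min_freq)
    if not terms:
        return pd.DataFrame(columns=["term", "frequency", "chi2", "p", "p_adj"])

    term_row = {t: i for i, t in enumerate(terms)}
    incidence = np.zeros((len(terms), n), dtype=np.float64)
    for j, g in enumerate(genes):
        for t in annot[g]:
            if t in term_row:
                incidence[term_row[t], j] = 1.0
    onehot = np.zeros((n, len(cluster_ids)))
    onehot[np.arange(n), labels] = 1.0
    freqs = incidence.sum(axis=1)
    expected = np.outer(freqs, sizes) / n
    observed = _chi2_stat(incidence @ onehot, expected)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_resamples):
        perm = rng.permutation(n)
        null = _chi2_stat(incidence @ onehot[perm], expected)
        exceed += null >= observed - 1e-12
    p = (1.0 + exceed) / (1.0 + n_resamples)
    return pd.DataFrame({
        "term": terms,
        "frequency": freqs.astype(int),
        "chi2": observed,
        "p": p,
        "p_adj": bh_adjust(p),
    })


def binomial_overrepresentation(clusters, flagged: set,
                                alternative: str = "greater") -> pd.DataFrame:
    """Exact one-sided binomial test for flagged-gene excess per cluster.

    With k flagged among n cluster members and global flagged fraction
    p0, the p-value is P(X >= k | n, p0).  BH adjustment across clusters.
    """
    members = _cluster_members(clusters)
    genes = [g for m in members.values() for g in m]
    if not set(flagged) <= set(genes):
        raise ValueError("flagged set contains genes outside the clustering")
    p0 = len(set(flagged)) / len(genes)
    rows = []
    for c in sorted(members):
        m = members[c]
        k = sum(1 for g in m if g in flagged)
        pval = float(stats.binom.sf(k - 1, len(m), p0)) if p0 > 0 else 1.0
        rows.append({"cluster": c, "size": len(m), "flagged": k, "p": min(pval, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"])
    return df
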