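"""The seven connectivity scores benchmarked by the package.

Given a *query* signature (as up/down gene sets or a full LFC vector) and a
*reference* LFC profile, each score estimates how concordantly the two
signatures deregulate the transcriptome:

* ``cmap1`` -- signed Kolmogorov-Smirnov enrichment of the query gene sets
  in the rank-ordered reference (classic connectivity-map statistic);
* ``cmap2`` -- weighted two-sided connectivity score (WTCS): GSEA-style
  weighted running-sum enrichment of both sets, combined when their
  enrichment signs oppose;
* ``css`` -- connectivity strength score: normalized signed rank product
  over the query's deregulated gene set;
* ``xsum``, ``xcos``, ``xpearson``, ``xspearman`` -- extreme similarity
  scores: the reference is masked to its most extreme up/down genes before
  a sum / cosine / Pearson / Spearman comparison.

Ties in reference ranking are broken by gene id for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signature_model import SignatureVector

__all__ = [
    "SCORE_METHODS",
    "QueryGeneSets",
    "ReferenceProfile",
    "derive_gene_sets",
    "cmap1_score",
    "cmap2_wtcs",
    "css_score",
    "extreme_similarity",
    "score_panel",
    "batch_normalize_cmap1",
]

SCORE_METHODS = ("cmap1", "cmap2", "css", "xsum", "xcos", "xpearson", "xspearman")


@dataclass(frozen=True)
class QueryGeneSets:
    """Disjoint up- and down-regulated query gene sets."""

    up: frozenset
    down: frozenset

    def __post_init__(self):
        up = frozenset(self.up)
        down = frozenset(self.down)
        if not up or not down:
            raise ValueError("both query gene sets must be nonempty")
        if up & down:
            raise ValueError("query up and down sets must be disjoint")
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference LFC profile with a dense 1..G ranking (1 = most up)."""

    gene_ids: np.ndarray
    lfc: np.ndarray
    rank: np.ndarray

    @classmethod
    def from_signature(cls, sig: SignatureVector) -> "ReferenceProfile":
        order = np.lexsort((sig.gene_ids, -sig.lfc))
        rank = np.empty(sig.n_genes, dtype=np.int64)
        rank[order] = np.arange(1, sig.n_genes + 1)
        return cls(gene_ids=np.asarray(sig.gene_ids), lfc=sig.lfc, rank=rank)

    @property
    def n_genes(self) -> int:
        return self.lfc.size

    def ranks_of(self, genes) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids.tolist())}
        try:
            rows = [index[g] for g in genes]
        except KeyError as err:
            raise KeyError(f"query gene {err.args[0]!r} absent from reference") from None
        return self.rank[rows]


def derive_gene_sets(signature: SignatureVector, top_k: int = 100) -> QueryGeneSets:
    """Top-k genes by LFC descending (up) and ascending (down), ties by id."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if 2 * top_k > signature.n_genes:
        raise ValueError("2 * top_k exceeds the gene universe; sets would overlap")
    order_desc = np.lexsort((signature.gene_ids, -signature.lfc))
    up = frozenset(signature.gene_ids[order_desc[:top_k]].tolist())
    down = frozenset(signature.gene_ids[order_desc[-top_k:]].tolist())
    return QueryGeneSets(up=up, down=down)


def _ks_statistic(ranks: np.ndarray, n: int) -> float:
    """Signed one-sided KS enrichment of a rank set in 1..n."""
    v = np.sort(ranks).astype(float)
    t = v.size
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1.0) / t)
    return float(a if a > b else -b)


def cmap1_score(query: QueryGeneSets, ref: ReferenceProfile) -> float:
    """Signed KS connectivity score in [-1, 1] for a single pair.

    ks_up and ks_down are the signed KS statistics of the two sets; the
    score is (ks_up - ks_down)/2 when their signs differ, else 0.  Raising
    batch normalization over a collection is left to the benchmark layer.
    """
    n = ref.n_genes
    ks_up = _ks_statistic(ref.ranks_of(sorted(query.up)), n)
    ks_down = _ks_statistic(ref.ranks_of(sorted(query.down)), n)
    if ks_up * ks_down > 0:
        return 0.0
    return (ks_up - ks_down) / 2.0


def _weighted_es(ranks: np.ndarray, weights: np.ndarray, n: int) -> float:
    """GSEA-style weighted enrichment score of one hit set.

    ``ranks`` are the 1-based positions of the hits in the sorted reference,
    ``weights`` their |LFC| weights.  Increment |lfc|/sum on hits,
    -1/(n - t) on misses; returns the extremum of the running sum.
    """
    order = np.argsort(ranks)
    pos = ranks[order].astype(np.int64)
    w = weights[order]
    t = pos.size
    total = w.sum()
    if total <= 0:
        w = np.ones(t)
        total = float(t)
    miss = 1.0 / (n - t)
    hit_cum = np.cumsum(w) / total
    # running sum just after each hit, and just before each hit
    n_miss_before = pos - np.arange(1, t + 1)  # misses preceding each hit
    after = hit_cum - n_miss_before * miss
    before = np.concatenate([[0.0], hit_cum[:-1]]) - n_miss_before * miss
    lo = min(before.min(), after.min(), 0.0)
    hi = max(after.max(), 0.0)
    return float(hi if hi > -lo else lo)


def cmap2_wtcs(query: QueryGeneSets, ref: ReferenceProfile) -> float:
    """Weighted two-sided connectivity score in [-1, 1]."""
    n = ref.n_genes
    up = sorted(query.up)
    down = sorted(query.down)
    idx = {g: i for i, g in enumerate(ref.gene_ids.tolist())}
    try:
        up_rows = [idx[g] for g in up]
        down_rows = [idx[g] for g in down]
    except KeyError as err:
        raise KeyError(f"query gene {err.args[0]!r} absent from reference") from None
    es_up = _weighted_es(ref.rank[up_rows], np.abs(ref.lfc[up_rows]), n)
    es_down = _weighted_es(ref.rank[down_rows], np.abs(ref.lfc[down_rows]), n)
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def _signed_magnitude_ranks(lfc: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Dense ranks 1..G by increasing |lfc| (ties by id), signed by direction."""
    order = np.lexsort((gene_ids, np.abs(lfc)))
    rank = np.empty(lfc.size, dtype=float)
    rank[order] = np.arange(1, lfc.size + 1)
    return rank * np.sign(lfc)


def css_score(
    query: SignatureVector,
    ref: SignatureVector,
    set_size: int = 100,
    dereg_genes=None,
) -> float:
    """Connectivity strength score in [-1, 1].

    The query's deregulated set (by default its ``set_size`` genes with the
    largest |LFC|) contributes the product of its signed magnitude ranks in
    query and reference, normalized by the maximum attainable for a set of
    that size (the set occupying the most extreme reference ranks, signs
    matched, in order).
    """
    q_ids = query.gene_ids
    if dereg_genes is None:
        order = np.lexsort((q_ids, -np.abs(query.lfc)))
        rows = np.sort(order[:set_size])
    else:
        dereg = set(dereg_genes)
        if not dereg:
            raise ValueError("deregulated gene set must be nonempty")
        rows = np.flatnonzero(np.isin(q_ids, list(dereg)))
        if rows.size != len(dereg):
            raise KeyError("deregulated gene absent from the query signature")
    t = rows.size
    g = ref.n_genes

    ref_index = {gid: i for i, gid in enumerate(ref.gene_ids.tolist())}
    try:
        ref_rows = [ref_index[gid] for gid in q_ids[rows].tolist()]
    except KeyError as err:
        raise KeyError(f"query gene {err.args[0]!r} absent from reference") from None

    q_rank_all = _signed_magnitude_ranks(query.lfc, q_ids)
    # within the set, re-rank by |lfc| so the set's own ordering is 1..t
    sub_order = np.lexsort((q_ids[rows], np.abs(query.lfc[rows])))
    q_set_rank = np.empty(t, dtype=float)
    q_set_rank[sub_order] = np.arange(1, t + 1)
    q_set_rank *= np.sign(query.lfc[rows])
    # genes with exactly zero lfc carry no sign: keep magnitude, sign 0
    r_rank = _signed_magnitude_ranks(ref.lfc, ref.gene_ids)[ref_rows]

    raw = float(q_set_rank @ r_rank)
    ks = np.arange(1, t + 1, dtype=float)
    max_raw = float(ks @ (g - t + ks))
    return raw / max_raw


def extreme_similarity(
    query: SignatureVector,
    ref: SignatureVector,
    n_extreme: int = 500,
    method: str = "pearson",
    query_sets: QueryGeneSets | None = None,
    top_k: int = 100,
) -> float:
    """Similarity after masking the reference to its extreme genes.

    The reference keeps its ``n_extreme`` most up- and most down-regulated
    genes; every other reference value is set to zero.  ``sum`` adds masked
    reference values over the query's up set minus its down set (sets
    derived from the query with ``top_k`` if not given); ``cos``,
    ``pearson`` and ``spearman`` compare the query LFC vector with the
    masked reference over the full gene universe.
    """
    if method not in ("sum", "cos", "pearson", "spearman"):
        raise ValueError(f"unknown extreme-similarity method {method!r}")
    if n_extreme < 1:
        raise ValueError("n_extreme must be >= 1")
    g = ref.n_genes
    if 2 * n_extreme > g:
        raise ValueError("2 * n_extreme exceeds the gene universe")
    order = np.lexsort((ref.gene_ids, -ref.lfc))
    keep = np.zeros(g, dtype=bool)
    keep[order[:n_extreme]] = True
    keep[order[-n_extreme:]] = True
    masked = np.where(keep, ref.lfc, 0.0)

    if method == "sum":
        sets = query_sets or derive_gene_sets(query, top_k=top_k)
        idx = {gid: i for i, gid in enumerate(ref.gene_ids.tolist())}
        try:
            up_rows = [idx[gid] for gid in sorted(sets.up)]
            down_rows = [idx[gid] for gid in sorted(sets.down)]
        except KeyError as err:
            raise KeyError(f"query gene {err.args[0]!r} absent from reference") from None
        return float(masked[up_rows].sum() - masked[down_rows].sum())

    # align the reference to the query's gene order
    if not np.array_equal(query.gene_ids, ref.gene_ids):
        idx = {gid: i for i, gid in enumerate(ref.gene_ids.tolist())}
        try:
            masked = masked[[idx[gid] for gid in query.gene_ids.tolist()]]
        except KeyError as err:
            raise KeyError(f"query gene {err.args[0]!r} absent from reference") from None
    q = query.lfc
    if method == "cos":
        denom = np.linalg.norm(q) * np.linalg.norm(masked)
        return float(q @ masked / denom) if denom > 0 else 0.0
    if method == "pearson":
        if q.std() == 0 or masked.std() == 0:
            return 0.0
        return float(np.corrcoef(q, masked)[0, 1])
    rho = stats.spearmanr(q, masked).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def score_panel(
    query: SignatureVector,
    ref: SignatureVector,
    methods=SCORE_METHODS,
    top_k: int = 100,
    n_extreme: int = 500,
    css_set_size: int | None = None,
) -> dict[str, float]:
    """All requested scores for one (query, reference) pair."""
    panel: dict[str, float] = {}
    sets = None
    profile = None
    if any(m in methods for m in ("cmap1", "cmap2", "xsum")):
        sets = derive_gene_sets(query, top_k=top_k)
    if any(m in methods for m in ("cmap1", "cmap2")):
        profile = ReferenceProfile.from_signature(ref)
    for method in methods:
        if method == "cmap1":
            panel[method] = cmap1_score(sets, profile)
        elif method == "cmap2":
            panel[method] = cmap2_wtcs(sets, profile)
        elif method == "css":
            panel[method] = css_score(query, ref, set_size=css_set_size or top_k)
        elif method in ("xsum", "xcos", "xpearson", "xspearman"):
            panel[method] = extreme_similarity(
                query, ref, n_extreme=n_extreme,
                method=method.removeprefix("x"),
                query_sets=sets, top_k=top_k,
            )
        else:
            raise ValueError(f"unknown score method {method!r}")
    return panel


def batch_normalize_cmap1(scores: np.ndarray) -> np.ndarray:
    """Cross-batch normalization: positives / max, negatives / |min|."""
    s = np.asarray(scores, dtype=float)
    out = s.copy()
    pos = s > 0
    neg = s < 0
    if pos.any():
        out[pos] = s[pos] / s[pos].max()
    if neg.any():
        out[neg] = s[neg] / abs(s[neg].min())
    return out
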