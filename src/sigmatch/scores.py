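"""Context-free pairwise similarity and distance functions.

Every scoring function compares two per-gene value vectors (log2 fold
changes by default, or any other cube representation) and carries a
*polarity*: for the Lp norms and the Kolmogorov-Smirnov statistic a
smaller value means more similar (distance), for everything else a
larger value does (similarity).  Ranking code consumes the polarity so
raw values stay interpretable.

Missing scores (degenerate variance, an empty change set for a
normalised Jaccard) are returned as NaN and rank strictly after every
finite score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

from .cube import EffectCube, FeatureVector, InstanceKey, get_vector
from .mine import mine_stats

__all__ = [
    "ScoreSpec",
    "ScoreResult",
    "METHODS",
    "POLARITY",
    "lp_distance",
    "correlation",
    "ks_statistic",
    "set_overlap",
    "mutual_information",
    "kraskov_mi",
    "score_pair",
    "score_all",
    "align_vectors",
    "ScoreError",
]

log = logging.getLogger("sigmatch")


class ScoreError(ValueError):
    pass


POLARITY = {
    "l1": "distance",
    "l2": "distance",
    "linf": "distance",
    "ks": "distance",
    "pearson": "similarity",
    "spearman": "similarity",
    "cosine": "similarity",
    "bicor": "similarity",
    "gini": "similarity",
    "jaccard": "similarity",
    "same_genes": "similarity",
    "same_dir": "similarity",
    "knn_mi": "similarity",
    "mic": "similarity",
    "gmic": "similarity",
    "mev": "similarity",
}
METHODS = tuple(POLARITY)

#: default log2-change threshold for the set-overlap scores
DEFAULT_CHANGE_THRESHOLD = 0.5
#: default neighbour count for the Kraskov MI estimator
DEFAULT_KNN_K = 6

_SET_METHODS = ("jaccard", "same_genes", "same_dir")
_MINE_METHODS = ("mic", "gmic", "mev")


@dataclass(frozen=True)
class ScoreSpec:
    """Identity of one scoring function: method, input representation, params."""

    method: str
    representation: str = "fc"
    abundance_source: str = "control"
    params: tuple = ()  # sorted (key, value) pairs; dicts accepted at init

    def __post_init__(self):
        if self.method not in METHODS:
            raise ScoreError(
                f"unknown method {self.method!r}; valid: {', '.join(METHODS)}"
            )
        if isinstance(self.params, dict):
            object.__setattr__(self, "params", tuple(sorted(self.params.items())))
        p = dict(self.params)
        direction = p.get("direction")
        if direction is not None and direction not in ("any", "same", "opposite"):
            raise ScoreError(f"invalid direction {direction!r}")
        if "change_threshold" in p and not p["change_threshold"] >= 0:
            raise ScoreError("change_threshold must be >= 0")
        if "k" in p and not (isinstance(p["k"], int) and p["k"] >= 1):
            raise ScoreError("k must be a positive integer")
        unknown = set(p) - {
            "change_threshold",
            "direction",
            "k",
            "center",
            "form",
            "alpha",
            "c",
        }
        if unknown:
            raise ScoreError(f"unknown params for {self.method}: {sorted(unknown)}")

    @property
    def polarity(self) -> str:
        return POLARITY[self.method]

    def param_dict(self) -> dict:
        return dict(self.params)

    def name(self) -> str:
        bits = [self.method, self.representation]
        if self.representation in ("fc_times_abs", "fc_div_abs"):
            bits.append(self.abundance_source)
        bits += [f"{k}={v}" for k, v in self.params]
        return ":".join(str(b) for b in bits)


@dataclass
class ScoreResult:
    query: InstanceKey
    candidate: InstanceKey
    value: float  # NaN = missing
    n_genes_used: int


# -- elementary scores -----------------------------------------------------


def align_vectors(x: FeatureVector, y: FeatureVector, genes=None):
    """Intersect two feature vectors on gene ids (x's order), optionally
    restricted to ``genes``; returns two aligned float arrays."""
    xi = pd.Index(x.gene_ids)
    yi = pd.Index(y.gene_ids)
    common = xi.intersection(yi, sort=False)
    if genes is not None:
        common = common.intersection(pd.Index(np.asarray(genes, dtype=object)), sort=False)
    if len(common) == 0:
        raise ScoreError("empty gene intersection between vectors")
    xv = x.values[xi.get_indexer(common)]
    yv = y.values[yi.get_indexer(common)]
    return xv, yv


def lp_distance(x, y, p) -> float:
    """Minkowski distance between aligned vectors; p in {1, 2, inf}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ScoreError("empty vectors")
    d = x - y
    if p == 1:
        return float(np.abs(d).sum())
    if p == 2:
        return float(np.sqrt((d * d).sum()))
    if p in (np.inf, "inf", float("inf")):
        return float(np.abs(d).max())
    raise ScoreError(f"unsupported norm order {p!r}")


def _bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation (median/MAD-based robust correlation)."""

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a = weighted(x)
    b = weighted(y)
    if a is None or b is None:
        return np.nan
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _gini(x: np.ndarray, y: np.ndarray, form: str = "mean") -> float:
    """Gini correlation: covariance with the partner's rank score,
    normalised by the own-rank form.  ``form`` selects which variable
    plays which role ('xy', 'yx') or their mean (default)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def one(v, rv_other, rv_own):
        num = np.cov(v, rv_other, ddof=1)[0, 1]
        den = np.cov(v, rv_own, ddof=1)[0, 1]
        if den == 0:
            return np.nan
        return num / den

    if form == "xy":
        return float(one(x, ry, rx))
    if form == "yx":
        return float(one(y, rx, ry))
    if form == "mean":
        g1 = one(x, ry, rx)
        g2 = one(y, rx, ry)
        return float((g1 + g2) / 2.0)
    raise ScoreError(f"unknown gini form {form!r}")


def correlation(x, y, method: str = "pearson", center: bool = False, form: str = "mean") -> float:
    """Correlation-type similarity in [-1, 1]; NaN on degenerate variance.

    ``center`` applies only to cosine: mean-centering both vectors first
    makes cosine algebraically identical to Pearson.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ScoreError("correlation needs at least 3 shared genes")
    if method in ("pearson", "spearman", "bicor") and (
        np.all(x == x[0]) or np.all(y == y[0])
    ):
        log.warning("degenerate variance in %s; score is missing", method)
        return np.nan
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return float(np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1])
    if method == "cosine":
        if center:
            x = x - x.mean()
            y = y - y.mean()
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        if denom == 0:
            log.warning("zero-norm vector in cosine; score is missing")
            return np.nan
        return float((x * y).sum() / denom)
    if method == "bicor":
        v = _bicor(x, y)
        if np.isnan(v):
            log.warning("degenerate MAD in bicor; score is missing")
        return v
    if method == "gini":
        return _gini(x, y, form=form)
    raise ScoreError(f"unknown correlation method {method!r}")


def ks_statistic(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov D between the value distributions
    (gene pairing is deliberately ignored)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ScoreError("empty input to ks_statistic")
    return float(sps.ks_2samp(x, y, method="asymp").statistic)


def set_overlap(
    x,
    y,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
    direction: str = "any",
    normalize: bool = True,
) -> float:
    """Jaccard / SameGenes / SameDir style overlap of changed-gene sets.

    A gene is "changed" in a vector when its absolute value exceeds the
    threshold (log2 units).  The matched set is the intersection,
    optionally constrained to same- or opposite-direction changes.
    Normalised form divides by the union size and is NaN when the union
    is empty (no changed gene anywhere — the classic division-by-zero
    failure mode of thresholded signatures).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.abs(x) > change_threshold
    b = np.abs(y) > change_threshold
    matched = a & b
    if direction == "same":
        matched &= np.sign(x) == np.sign(y)
    elif direction == "opposite":
        matched &= np.sign(x) != np.sign(y)
    elif direction != "any":
        raise ScoreError(f"invalid direction {direction!r}")
    m = int(matched.sum())
    if not normalize:
        return float(m)
    union = int((a | b).sum())
    if union == 0:
        log.warning("set_overlap: no gene passes the change threshold; score missing")
        return np.nan
    return m / union


def kraskov_mi(x, y, k: int = DEFAULT_KNN_K) -> float:
    """Kraskov-Stoegbauer-Grassberger (algorithm 1) k-NN mutual
    information estimate, in nats; small negative estimates are clipped
    to 0."""
    from scipy.spatial import cKDTree
    from scipy.special import digamma

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n <= k:
        raise ScoreError(f"knn_mi needs more than k={k} points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, k]
    xs = np.sort(x)
    ys = np.sort(y)
    nx = (
        np.searchsorted(xs, x + eps, side="left")
        - np.searchsorted(xs, x - eps, side="right")
        - 1
    )
    ny = (
        np.searchsorted(ys, y + eps, side="left")
        - np.searchsorted(ys, y - eps, side="right")
        - 1
    )
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(max(mi, 0.0))


def mutual_information(x, y, estimator: str = "knn_mi", k: int = DEFAULT_KNN_K, alpha=0.6, c=15) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if estimator == "knn_mi":
        if len(x) < max(k + 1, 10):
            raise ScoreError(f"knn_mi needs >= {max(k + 1, 10)} shared genes")
        return kraskov_mi(x, y, k=k)
    if estimator in _MINE_METHODS:
        return mine_stats(x, y, alpha=alpha, c=c)[estimator]
    raise ScoreError(f"unknown MI estimator {estimator!r}")


# -- dispatch --------------------------------------------------------------


def score_pair(x, y, spec: ScoreSpec) -> float:
    """Apply one scoring function to a pair of aligned value arrays."""
    p = spec.param_dict()
    m = spec.method
    if m == "l1":
        return lp_distance(x, y, 1)
    if m == "l2":
        return lp_distance(x, y, 2)
    if m == "linf":
        return lp_distance(x, y, np.inf)
    if m in ("pearson", "spearman", "cosine", "bicor", "gini"):
        return correlation(
            x, y, method=m, center=p.get("center", False), form=p.get("form", "mean")
        )
    if m == "ks":
        return ks_statistic(x, y)
    if m in _SET_METHODS:
        direction = p.get("direction", "same" if m == "same_dir" else "any")
        return set_overlap(
            x,
            y,
            change_threshold=p.get("change_threshold", DEFAULT_CHANGE_THRESHOLD),
            direction=direction,
            normalize=(m == "jaccard"),
        )
    if m == "knn_mi":
        return mutual_information(x, y, "knn_mi", k=p.get("k", DEFAULT_KNN_K))
    if m in _MINE_METHODS:
        return mutual_information(
            x, y, m, alpha=p.get("alpha", 0.6), c=p.get("c", 15)
        )
    raise ScoreError(f"unhandled method {m!r}")


def score_all(
    cube: EffectCube,
    query: InstanceKey,
    spec: ScoreSpec,
    gene_filter=None,
    selection: str = "query",
) -> list[ScoreResult]:
    """Score one query instance against every other instance in the cube.

    ``gene_filter`` is any object with a ``select(cube, instance)``
    method returning gene ids (see :mod:`sigmatch.filters`); by default
    it is applied to the query instance only (``selection='query'``),
    mirroring the disease-signature use case.  ``selection='pairwise_union'``
    instead applies it to both instances of each pair and takes the
    union.  The query itself is excluded from the candidates.
    """
    if selection not in ("query", "pairwise_union"):
        raise ScoreError("selection must be 'query' or 'pairwise_union'")
    qvec = get_vector(cube, query, spec.representation, spec.abundance_source)
    q_genes = None
    if gene_filter is not None and selection == "query":
        q_genes = np.asarray(gene_filter.select(cube, query), dtype=object)

    out: list[ScoreResult] = []
    for cand in cube.instances:
        if cand == query:
            continue
        genes = q_genes
        if gene_filter is not None and selection == "pairwise_union":
            g_q = gene_filter.select(cube, query)
            g_c = gene_filter.select(cube, cand)
            genes = pd.Index(np.asarray(g_q, dtype=object)).union(
                pd.Index(np.asarray(g_c, dtype=object)), sort=False
            ).to_numpy(dtype=object)
        cvec = get_vector(cube, cand, spec.representation, spec.abundance_source)
        try:
            xv, yv = align_vectors(qvec, cvec, genes=genes)
            value = score_pair(xv, yv, spec)
            n_used = len(xv)
        except ScoreError as exc:
            log.warning("score %s for %s vs %s missing: %s",
                        spec.name(), query.label(), cand.label(), exc)
            value, n_used = np.nan, 0
        out.append(ScoreResult(query=query, candidate=cand, value=value,
                               n_genes_used=n_used))
    return out
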