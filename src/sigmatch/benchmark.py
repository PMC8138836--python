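"""Same-drug retrieval benchmark.

The evaluation substitutes the hard question "does this drug effect
match this disease signature?" with the self-contained one "can a
scoring function retrieve the *same drug* tested under another
condition (cell line, concentration, platform)?".  For every query
instance whose drug occurs in at least two instances, all other
instances are ranked by the score; the best and worst rank at which
the same drug reappears feed threshold *recovery curves*: how many
queries have at least one match (mode ``any``) or all their matches
(mode ``all``) within the first x ranks.  A band of curves from a
random scorer provides the null reference.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cube import EffectCube, InstanceKey
from .filters import FilterSpec
from .scores import ScoreResult, ScoreSpec, score_all

__all__ = [
    "RankRecord",
    "RecoveryCurve",
    "RandomBand",
    "BenchmarkResult",
    "eligible_queries",
    "rank_candidates",
    "best_worst",
    "recovery_curve",
    "random_baseline",
    "run_benchmark",
    "BenchmarkError",
]

log = logging.getLogger("sigmatch")

DEFAULT_REFERENCE_THRESHOLD = 250
DEFAULT_N_RANDOM_REPS = 100


class BenchmarkError(ValueError):
    pass


@dataclass
class RankRecord:
    query: InstanceKey
    best_rank: int
    worst_rank: int
    n_matches: int
    n_candidates: int

    def __post_init__(self):
        if not (1 <= self.best_rank <= self.worst_rank <= self.n_candidates):
            raise BenchmarkError(
                f"inconsistent ranks: best={self.best_rank} worst={self.worst_rank} "
                f"n_candidates={self.n_candidates}"
            )


@dataclass
class RecoveryCurve:
    thresholds: np.ndarray  # ordered ints
    count_any: np.ndarray  # queries with best_rank <= x
    count_all: np.ndarray  # queries with worst_rank <= x

    def count(self, mode: str) -> np.ndarray:
        if mode == "any":
            return self.count_any
        if mode == "all":
            return self.count_all
        raise BenchmarkError(f"unknown mode {mode!r}")


def eligible_queries(cube: EffectCube) -> list[InstanceKey]:
    """Instances whose drug was tested in >= 2 instances."""
    drugs = cube.drug_ids()
    counts = pd.Series(drugs).value_counts()
    multi = set(counts[counts >= 2].index)
    return [k for k in cube.instances if k.drug_id in multi]


def rank_candidates(
    results: Sequence[ScoreResult], polarity: str, tie_rule: str = "worst"
) -> np.ndarray:
    """Rank per candidate (1 = most similar), aligned with ``results``.

    Missing (NaN) scores rank strictly after every finite score, in
    stable input order.  ``tie_rule='worst'`` gives every member of a
    tied block the block's last position (pessimistic for the scoring
    function under test); ``'average'`` gives the mean position.
    """
    if polarity not in ("similarity", "distance"):
        raise BenchmarkError(f"unknown polarity {polarity!r}")
    if tie_rule not in ("worst", "average"):
        raise BenchmarkError(f"unknown tie_rule {tie_rule!r}")
    values = np.array([r.value for r in results], dtype=float)
    n = len(values)
    if n == 0:
        raise BenchmarkError("no results to rank")
    finite = np.isfinite(values)
    if not finite.any():
        raise BenchmarkError("all scores missing; nothing to rank")
    key = values if polarity == "distance" else -values

    ranks = np.empty(n, dtype=float)
    idx_f = np.flatnonzero(finite)
    order = idx_f[np.argsort(key[finite], kind="mergesort")]
    sk = key[order]
    m = len(order)
    i = 0
    while i < m:
        j = i
        while j + 1 < m and sk[j + 1] == sk[i]:
            j += 1
        block = order[i : j + 1]
        if tie_rule == "worst":
            ranks[block] = j + 1
        else:
            ranks[block] = (i + j + 2) / 2.0  # mean of 1-based positions
        i = j + 1
    # missing: after all finite, stable input order, never tied
    for offset, idx in enumerate(np.flatnonzero(~finite)):
        ranks[idx] = m + offset + 1
    return ranks


def best_worst(
    ranks: np.ndarray, same_drug_mask: np.ndarray, query: InstanceKey
) -> Optional[RankRecord]:
    """Best and worst rank over the same-drug candidates; None when the
    mask marks no candidate (logged, query skipped)."""
    same_drug_mask = np.asarray(same_drug_mask, dtype=bool)
    if not same_drug_mask.any():
        log.warning("query %s has no same-drug candidate; skipped", query.label())
        return None
    match_ranks = ranks[same_drug_mask]
    return RankRecord(
        query=query,
        best_rank=int(np.ceil(match_ranks.min())),
        worst_rank=int(np.ceil(match_ranks.max())),
        n_matches=int(same_drug_mask.sum()),
        n_candidates=len(ranks),
    )


def recovery_curve(
    records: Sequence[RankRecord], thresholds: Optional[np.ndarray] = None
) -> RecoveryCurve:
    """Counts of queries recovered at or below each rank threshold."""
    if len(records) == 0:
        raise BenchmarkError("no rank records")
    if thresholds is None:
        thresholds = np.arange(1, max(r.n_candidates for r in records) + 1)
    thresholds = np.asarray(thresholds, dtype=int)
    best = np.array([r.best_rank for r in records])
    worst = np.array([r.worst_rank for r in records])
    count_any = (best[None, :] <= thresholds[:, None]).sum(axis=1)
    count_all = (worst[None, :] <= thresholds[:, None]).sum(axis=1)
    return RecoveryCurve(thresholds=thresholds, count_any=count_any, count_all=count_all)


@dataclass
class RandomBand:
    """Envelope of recovery curves from a random scorer."""

    thresholds: np.ndarray
    any_counts: np.ndarray  # (n_reps, n_thresholds)
    all_counts: np.ndarray
    n_records: int
    seed: int

    def counts(self, mode: str) -> np.ndarray:
        return self.any_counts if mode == "any" else self.all_counts

    def minimum(self, mode: str = "any") -> np.ndarray:
        return self.counts(mode).min(axis=0)

    def median(self, mode: str = "any") -> np.ndarray:
        return np.median(self.counts(mode), axis=0)

    def maximum(self, mode: str = "any") -> np.ndarray:
        return self.counts(mode).max(axis=0)


def random_baseline(
    cube: EffectCube,
    n_reps: int = DEFAULT_N_RANDOM_REPS,
    seed: int = 0,
    thresholds: Optional[np.ndarray] = None,
    tie_rule: str = "worst",
) -> RandomBand:
    """Run the full pipeline with a scorer that draws i.i.d. uniforms.

    Each repetition draws one independent Uniform(0,1) similarity per
    unordered instance pair from one seeded generator.  The random
    scorer is symmetric — like every real scoring function here — so
    the band reproduces the dependence between the two directions of a
    same-drug pair, which a per-ordered-pair draw would miss.  Rank
    records and recovery curves are then computed exactly as for a
    real scorer.  Fully reproducible for a given (seed, n_reps).
    """
    if n_reps < 1:
        raise BenchmarkError("n_reps must be >= 1")
    rng = np.random.default_rng([seed, 0xBA5E])
    queries = eligible_queries(cube)
    if not queries:
        raise BenchmarkError("no eligible queries (no drug with >= 2 instances)")
    drugs = cube.drug_ids()
    n_inst = cube.n_instances
    qinfo = []
    for q in queries:
        qi = cube.instance_index(q)
        others = np.array([i for i in range(n_inst) if i != qi])
        mask = np.array([drugs[i] == q.drug_id for i in others], dtype=bool)
        qinfo.append((q, qi, others, mask))
    n_cand = n_inst - 1
    iu, ju = np.triu_indices(n_inst, k=1)
    if thresholds is None:
        thresholds = np.arange(1, n_cand + 1)
    thresholds = np.asarray(thresholds, dtype=int)

    any_counts = np.empty((n_reps, len(thresholds)), dtype=int)
    all_counts = np.empty((n_reps, len(thresholds)), dtype=int)
    for rep in range(n_reps):
        pair_scores = np.zeros((n_inst, n_inst))
        draws = rng.random(len(iu))
        pair_scores[iu, ju] = draws
        pair_scores[ju, iu] = draws
        records = []
        for q, qi, others, mask in qinfo:
            scores = pair_scores[qi, others]
            results = [
                ScoreResult(query=q, candidate=None, value=s, n_genes_used=0)
                for s in scores
            ]
            ranks = rank_candidates(results, "similarity", tie_rule=tie_rule)
            rec = best_worst(ranks, mask, q)
            if rec is not None:
                records.append(rec)
        curve = recovery_curve(records, thresholds)
        any_counts[rep] = curve.count_any
        all_counts[rep] = curve.count_all
    return RandomBand(
        thresholds=thresholds,
        any_counts=any_counts,
        all_counts=all_counts,
        n_records=len(records),
        seed=seed,
    )


@dataclass
class BenchmarkResult:
    records: pd.DataFrame  # one row per (score, filter, query)
    curves: pd.DataFrame  # long form: score, filter, threshold, count_any, count_all
    summary: pd.DataFrame  # one row per (score, filter), sorted by reference count
    band: Optional[RandomBand]
    provenance: dict
    failures: list = field(default_factory=list)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_benchmark(
    cube: EffectCube,
    score_specs: Sequence[ScoreSpec],
    filter_specs: Sequence[FilterSpec],
    tie_rule: str = "worst",
    reference_threshold: int = DEFAULT_REFERENCE_THRESHOLD,
    n_random_reps: int = DEFAULT_N_RANDOM_REPS,
    seed: int = 0,
    selection: str = "query",
    with_random_band: bool = True,
) -> BenchmarkResult:
    """Evaluate the cross-product of scoring functions and gene filters.

    Per combination: rank all candidates for every eligible query,
    record best/worst same-drug ranks, and build recovery curves.  The
    summary counts recovered queries at the reference threshold (the
    legend-sorting convention) in both modes and is sorted best-first
    by ``count_any``.  Individual combination failures are recorded and
    the run continues.
    """
    queries = eligible_queries(cube)
    if not queries:
        raise BenchmarkError("no eligible queries in cube")
    drugs = cube.drug_ids()

    rec_rows, curve_rows, summary_rows, failures = [], [], [], []
    n_cand = cube.n_instances - 1
    thresholds = np.arange(1, n_cand + 1)
    ref = min(reference_threshold, n_cand)

    for sspec in score_specs:
        for fspec in filter_specs:
            sname, fname = sspec.name(), fspec.name()
            try:
                records = []
                for q in queries:
                    results = score_all(
                        cube, q, sspec, gene_filter=fspec, selection=selection
                    )
                    mask = np.array(
                        [r.candidate.drug_id == q.drug_id for r in results], dtype=bool
                    )
                    try:
                        ranks = rank_candidates(results, sspec.polarity, tie_rule)
                    except BenchmarkError as exc:
                        log.warning(
                            "query %s under %s/%s: %s; query skipped",
                            q.label(), sname, fname, exc,
                        )
                        continue
                    rec = best_worst(ranks, mask, q)
                    if rec is not None:
                        records.append(rec)
                if records:
                    curve = recovery_curve(records, thresholds)
                else:
                    curve = RecoveryCurve(
                        thresholds,
                        np.zeros(len(thresholds), dtype=int),
                        np.zeros(len(thresholds), dtype=int),
                    )
                for r in records:
                    rec_rows.append(
                        {
                            "score": sname,
                            "filter": fname,
                            "query": r.query.label(),
                            "drug_id": r.query.drug_id,
                            "best_rank": r.best_rank,
                            "worst_rank": r.worst_rank,
                            "n_matches": r.n_matches,
                            "n_candidates": r.n_candidates,
                        }
                    )
                for t, ca, cl in zip(thresholds, curve.count_any, curve.count_all):
                    curve_rows.append(
                        {
                            "score": sname,
                            "filter": fname,
                            "threshold": int(t),
                            "count_any": int(ca),
                            "count_all": int(cl),
                        }
                    )
                at_ref = int(np.searchsorted(thresholds, ref))
                summary_rows.append(
                    {
                        "score": sname,
                        "filter": fname,
                        "n_records": len(records),
                        "reference_threshold": ref,
                        "count_any_at_ref": int(curve.count_any[at_ref]),
                        "count_all_at_ref": int(curve.count_all[at_ref]),
                    }
                )
            except Exception as exc:  # noqa: BLE001 - per-combination isolation
                log.error("combination %s/%s failed: %s", sname, fname, exc)
                failures.append({"score": sname, "filter": fname, "error": str(exc)})

    band = None
    if with_random_band:
        band = random_baseline(
            cube, n_reps=n_random_reps, seed=seed, thresholds=thresholds,
            tie_rule=tie_rule,
        )

    summary = pd.DataFrame(summary_rows)
    if len(summary):
        summary = summary.sort_values(
            ["count_any_at_ref", "score", "filter"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    config = {
        "scores": [s.name() for s in score_specs],
        "filters": [f.name() for f in filter_specs],
        "tie_rule": tie_rule,
        "reference_threshold": reference_threshold,
        "n_random_reps": n_random_reps,
        "seed": seed,
        "selection": selection,
    }
    provenance = {"seed": seed, "config_hash": _config_hash(config)}
    return BenchmarkResult(
        records=pd.DataFrame(rec_rows),
        curves=pd.DataFrame(curve_rows),
        summary=summary,
        band=band,
        provenance=provenance,
        failures=failures,
    )
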