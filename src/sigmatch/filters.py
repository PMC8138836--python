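"""Gene-selection heuristics applied before a similarity computation.

Three families: value-based top-n filters (most abundant, most
changing, highest |z|, lowest p), a static landmark-gene membership
filter (the LINCS idea: a fixed ~1000-gene reduced transcriptome), and
a network-driven reduction ("focus" heuristic) that keeps a gene when
its own change passes a threshold or when it sits on a high-scoring
interaction edge.

All filters are pure functions of their inputs, return genes in a
deterministic order and never return duplicates or genes outside the
cube.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cube import EffectCube, InstanceKey

__all__ = [
    "FilterSpec",
    "GeneNetwork",
    "top_n_filter",
    "landmark_filter",
    "focus_filter",
    "tune_focus_to_n",
    "FilterError",
    "FILTER_METHODS",
]

log = logging.getLogger("sigmatch")

FILTER_METHODS = (
    "none",
    "abundance_top",
    "fc_top",
    "z_top",
    "p_bottom",
    "landmark",
    "focus",
)

_CRITERIA = {"abundance", "abs_fc", "abs_z", "p_value"}


class FilterError(ValueError):
    pass


@dataclass
class GeneNetwork:
    """Undirected weighted gene-interaction network.

    Edges are stored once with endpoints in sorted order; weights are
    in [0, 1] (STRING combined scores divided by 1000).
    """

    edges: pd.DataFrame  # columns gene_a, gene_b, weight

    def __post_init__(self):
        req = ["gene_a", "gene_b", "weight"]
        if list(self.edges.columns[:3]) != req:
            self.edges = self.edges[req]
        e = self.edges
        if (e["gene_a"] == e["gene_b"]).any():
            raise FilterError("self-loop in gene network")
        w = e["weight"].to_numpy(dtype=float)
        if np.any((w < 0) | (w > 1)):
            raise FilterError("network weight outside [0, 1]")
        a = e["gene_a"].astype(str).to_numpy(dtype=object)
        b = e["gene_b"].astype(str).to_numpy(dtype=object)
        swap = a > b
        a2 = np.where(swap, b, a)
        b2 = np.where(swap, a, b)
        canon = pd.DataFrame({"gene_a": a2, "gene_b": b2, "weight": w})
        canon = canon.drop_duplicates(subset=["gene_a", "gene_b"], keep="first")
        canon = canon.sort_values(["gene_a", "gene_b"], kind="mergesort")
        self.edges = canon.reset_index(drop=True)

    @classmethod
    def from_edge_list(cls, triples: Iterable[tuple]) -> "GeneNetwork":
        df = pd.DataFrame(list(triples), columns=["gene_a", "gene_b", "weight"])
        return cls(df)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


def top_n_filter(
    cube: EffectCube,
    instance: InstanceKey,
    criterion: str,
    n: int,
    abundance_source: str = "control",
) -> np.ndarray:
    """Top-n genes of one instance by a cube statistic.

    ``abundance``/``abs_fc``/``abs_z`` sort descending, ``p_value``
    ascending; missing values are excluded; ties break by ascending
    gene id so the output is reproducible.
    """
    if criterion not in _CRITERIA:
        raise FilterError(f"unknown criterion {criterion!r}; valid: {sorted(_CRITERIA)}")
    if n < 1:
        raise FilterError("n must be >= 1")
    j = cube.instance_index(instance)
    if criterion == "abundance":
        vals = cube.layers[f"abund_{abundance_source}"][:, j].copy()
        ascending = False
    elif criterion == "abs_fc":
        vals = np.abs(cube.layers["logfc"][:, j])
        ascending = False
    elif criterion == "abs_z":
        vals = np.abs(cube.layers["z"][:, j])
        ascending = False
    else:
        vals = cube.layers["p"][:, j].copy()
        ascending = True
    df = pd.DataFrame({"value": vals, "gene": cube.gene_ids})
    df = df[np.isfinite(df["value"].to_numpy(dtype=float))]
    df = df.sort_values(["value", "gene"], ascending=[ascending, True], kind="mergesort")
    return df["gene"].to_numpy(dtype=object)[:n]


def landmark_filter(cube: EffectCube, gene_set: Sequence[str]) -> np.ndarray:
    """Static membership filter: cube genes in ``gene_set``, cube order.

    Instance-independent by construction — the landmark selection is
    fixed, not adapted to the individual experiment.
    """
    if len(gene_set) == 0:
        raise FilterError("empty landmark gene set")
    members = set(str(g) for g in gene_set)
    out = np.asarray([g for g in cube.gene_ids if g in members], dtype=object)
    if len(out) == 0:
        raise FilterError("landmark gene set has empty intersection with cube genes")
    return out


def _link_scores(network: GeneNetwork, logfc: pd.Series, form: str) -> np.ndarray:
    fa = logfc.loc[network.edges["gene_a"]].to_numpy(dtype=float)
    fb = logfc.loc[network.edges["gene_b"]].to_numpy(dtype=float)
    if form == "sum":
        return np.abs(fa + fb)
    if form == "product":
        return np.abs(fa * fb)
    raise FilterError(f"unknown link score form {form!r} (use 'sum' or 'product')")


def focus_filter(
    network: GeneNetwork,
    logfc: pd.Series,
    abundance_delta: pd.Series,
    fc_threshold: float,
    expr_threshold: float,
    link_threshold: float,
    link_score: str = "sum",
) -> np.ndarray:
    """Network-driven gene reduction.

    A gene is kept iff its \\|log2 FC\\| >= ``fc_threshold``, or its
    \\|abundance change\\| >= ``expr_threshold``, or it participates in
    at least one edge whose link score passes ``link_threshold``.  The
    default link score of an edge is \\|logfc_a + logfc_b\\| (joint
    displacement); the alternative is the product form.
    """
    genes = pd.Index(logfc.index)
    missing = sorted(set(network.nodes()) - set(genes))
    if missing:
        raise FilterError(f"network genes absent from scores: {missing[:10]}"
                          + ("" if len(missing) <= 10 else f" (+{len(missing) - 10})"))
    keep = (np.abs(logfc.to_numpy(dtype=float)) >= fc_threshold) | (
        np.abs(abundance_delta.reindex(genes).to_numpy(dtype=float)) >= expr_threshold
    )
    keep = pd.Series(keep, index=genes)
    if network.n_edges:
        ls = _link_scores(network, logfc, link_score)
        hit = network.edges[ls >= link_threshold]
        keep.loc[hit["gene_a"]] = True
        keep.loc[hit["gene_b"]] = True
    return genes[keep.to_numpy(dtype=bool)].to_numpy(dtype=object)


def tune_focus_to_n(
    network: GeneNetwork,
    logfc: pd.Series,
    abundance_delta: pd.Series,
    target_n: int,
    tolerance: float = 0.05,
    max_iter: int = 60,
    link_score: str = "sum",
) -> tuple[dict, int]:
    """Bisect one scale factor on all three thresholds to keep ~target_n genes.

    The thresholds are ``scale * max(|statistic|)`` per criterion, so
    scale 0 keeps every gene and scale > 1 keeps none; the kept count is
    non-increasing in the scale.  Returns the threshold dict (including
    the scale used) and the achieved count; warns when ties or plateaus
    make the target unattainable within ``tolerance`` (relative).
    """
    if target_n > len(logfc):
        raise FilterError("target_n exceeds number of scored genes")
    base_fc = float(np.nanmax(np.abs(logfc.to_numpy(dtype=float)))) or 1.0
    base_ex = float(np.nanmax(np.abs(abundance_delta.to_numpy(dtype=float)))) or 1.0
    if network.n_edges:
        base_link = float(np.max(_link_scores(network, logfc, link_score))) or 1.0
    else:
        base_link = 1.0

    def kept(scale: float) -> int:
        return len(
            focus_filter(
                network,
                logfc,
                abundance_delta,
                fc_threshold=scale * base_fc,
                expr_threshold=scale * base_ex,
                link_threshold=scale * base_link,
                link_score=link_score,
            )
        )

    lo, hi = 0.0, 1.0 + 1e-9
    best_scale, best_count = lo, kept(lo)
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        c = kept(mid)
        if abs(c - target_n) < abs(best_count - target_n):
            best_scale, best_count = mid, c
        if c > target_n:
            lo = mid
        elif c < target_n:
            hi = mid
        else:
            break
    if abs(best_count - target_n) > tolerance * target_n:
        warnings.warn(
            f"focus tuner: target {target_n} unattainable, nearest achievable "
            f"count is {best_count}",
            stacklevel=2,
        )
    thresholds = {
        "scale": best_scale,
        "fc_threshold": best_scale * base_fc,
        "expr_threshold": best_scale * base_ex,
        "link_threshold": best_scale * base_link,
    }
    return thresholds, best_count


@dataclass
class FilterSpec:
    """Identity of one gene-selection heuristic.

    ``method`` picks the family; ``n`` the target gene count for the
    value-based and focus methods; ``gene_set`` the landmark list;
    ``network`` the interaction network for focus.  Instances expose
    ``select(cube, instance)`` so scoring code can stay agnostic.
    """

    method: str = "none"
    n: Optional[int] = None
    abundance_source: str = "control"
    gene_set: Optional[Sequence[str]] = None
    network: Optional[GeneNetwork] = None
    link_score: str = "sum"
    focus_thresholds: Optional[dict] = None  # fc/expr/link thresholds; tuned if absent

    def __post_init__(self):
        if self.method not in FILTER_METHODS:
            raise FilterError(
                f"unknown filter method {self.method!r}; valid: {', '.join(FILTER_METHODS)}"
            )
        if self.method in ("abundance_top", "fc_top", "z_top", "p_bottom", "focus"):
            if self.n is None and not (
                self.method == "focus" and self.focus_thresholds is not None
            ):
                raise FilterError(f"filter {self.method!r} requires n")
            if self.n is not None and self.n < 1:
                raise FilterError("n must be >= 1")
        if self.method == "landmark" and not self.gene_set:
            raise FilterError("landmark filter requires gene_set")
        if self.method == "focus" and self.network is None:
            raise FilterError("focus filter requires network")

    def name(self) -> str:
        if self.method == "none":
            return "all"
        bits = [self.method]
        if self.n is not None:
            bits.append(str(self.n))
        if self.method == "abundance_top":
            bits.append(self.abundance_source)
        return ":".join(bits)

    def select(self, cube: EffectCube, instance: InstanceKey) -> np.ndarray:
        if self.method == "none":
            return np.asarray(cube.gene_ids, dtype=object)
        if self.method == "abundance_top":
            return top_n_filter(cube, instance, "abundance", self.n, self.abundance_source)
        if self.method == "fc_top":
            return top_n_filter(cube, instance, "abs_fc", self.n)
        if self.method == "z_top":
            return top_n_filter(cube, instance, "abs_z", self.n)
        if self.method == "p_bottom":
            return top_n_filter(cube, instance, "p_value", self.n)
        if self.method == "landmark":
            return landmark_filter(cube, self.gene_set)
        # focus
        j = cube.instance_index(instance)
        logfc = pd.Series(cube.layers["logfc"][:, j], index=cube.gene_ids)
        ad = pd.Series(
            np.exp2(cube.layers["abund_treated"][:, j])
            - np.exp2(cube.layers["abund_control"][:, j]),
            index=cube.gene_ids,
        )
        logfc = logfc.fillna(0.0)
        ad = ad.fillna(0.0)
        th = self.focus_thresholds
        if th is None:
            th, _ = tune_focus_to_n(
                self.network, logfc, ad, target_n=self.n, link_score=self.link_score
            )
        return focus_filter(
            self.network,
            logfc,
            ad,
            fc_threshold=th["fc_threshold"],
            expr_threshold=th["expr_threshold"],
            link_threshold=th["link_threshold"],
            link_score=self.link_score,
        )
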