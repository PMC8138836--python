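"""Synthetic effect cubes, gene networks and landmark lists.

The generator states a simple world: every drug has a sparse, fixed
log2-scale expression signature; every instance of that drug (another
cell line and concentration) shows the same signature up to a scalar
multiplier, on top of a shared per-gene baseline abundance, with
per-instance context noise and per-replicate technical noise, both
Gaussian on the log2 scale.  Controls are baseline plus replicate
noise.  Ground truth (signatures, per-instance scales, instance-drug
map) is returned so tests can verify recovery.

A heavy-tailed replicate-noise option (Student t, 3 df) exists to
exercise scoring behaviours dominated by extreme values.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .cube import EffectCube, build_cube
from .filters import GeneNetwork

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cube",
    "simulate_effect_cube",
    "simulate_network",
    "make_landmark_list",
]


@dataclass
class SimConfig:
    """Parameters of the stated synthetic world (all log2 scale).

    Defaults: 40 drugs x 2 instances over 1000 genes, 5% signature
    sparsity, mean absolute signature effect 1.0 log2 units (a 2-fold
    change), context and replicate noise SD 0.25, 3 treated + 3 control
    replicates, baseline abundance ~ N(7, 2).
    """

    seed: int
    n_drugs: int = 40
    instances_per_drug: int = 2
    n_genes: int = 1000
    signature_sparsity: float = 0.05
    effect_size: float = 1.0
    context_noise_sd: float = 0.25
    replicate_sd: float = 0.25
    n_replicates: tuple[int, int] = (3, 3)  # (treated, control)
    abundance_mean: float = 7.0
    abundance_sd: float = 2.0
    scale_range: tuple[float, float] = (0.5, 1.5)  # per-instance signature scale
    n_cell_lines: int = 3
    heavy_tails: bool = False  # replicate noise ~ t(3) scaled to replicate_sd

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_drugs",
            "instances_per_drug",
            "n_genes",
            "n_cell_lines",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.signature_sparsity <= 1):
            raise ValueError("signature_sparsity must be in (0, 1]")
        for name in ("effect_size", "context_noise_sd", "replicate_sd", "abundance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_replicates) < 1:
            raise ValueError("need >= 1 replicate on each side")


@dataclass
class SimTruth:
    signatures: pd.DataFrame  # genes x drugs, sparse log2 effects
    scales: pd.Series  # per instance_id
    instance_drug: pd.Series  # instance_id -> drug_id
    baseline: pd.Series  # per-gene baseline log2 abundance


def _replicate_noise(rng, shape, sd, heavy_tails):
    if sd == 0:
        return np.zeros(shape)
    if heavy_tails:
        # t(3) has SD sqrt(3); rescale so the marginal SD stays `sd`
        return rng.standard_t(3, size=shape) * (sd / np.sqrt(3.0))
    return rng.normal(0.0, sd, size=shape)


def simulate_cube(config: SimConfig):
    """Generate replicate matrices + metadata feeding :func:`build_cube`.

    Returns ``(treated, control, metadata, truth)`` where treated and
    control map instance_id -> genes x replicates log2 matrices.
    """
    rng = np.random.default_rng([config.seed, 0x51A1])
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    drugs = [f"drug{d:03d}" for d in range(config.n_drugs)]
    baseline = pd.Series(
        rng.normal(config.abundance_mean, config.abundance_sd, config.n_genes),
        index=genes,
    )

    k = max(1, round(config.signature_sparsity * config.n_genes))
    signatures = pd.DataFrame(0.0, index=genes, columns=drugs)
    for d in drugs:
        support = rng.choice(config.n_genes, size=k, replace=False)
        mags = np.abs(rng.normal(config.effect_size, config.effect_size / 4.0, k))
        signs = rng.choice([-1.0, 1.0], size=k)
        signatures.iloc[support, signatures.columns.get_loc(d)] = signs * mags

    n_t, n_c = config.n_replicates
    treated, control, meta_rows = {}, {}, []
    scales, inst_drug = {}, {}
    idx = 0
    for d in drugs:
        for r in range(config.instances_per_drug):
            iid = f"inst{idx:04d}"
            idx += 1
            scale = rng.uniform(*config.scale_range)
            context = (
                rng.normal(0.0, config.context_noise_sd, config.n_genes)
                if config.context_noise_sd > 0
                else np.zeros(config.n_genes)
            )
            true_mean = baseline.to_numpy() + scale * signatures[d].to_numpy() + context
            tmat = true_mean[:, None] + _replicate_noise(
                rng, (config.n_genes, n_t), config.replicate_sd, config.heavy_tails
            )
            cmat = baseline.to_numpy()[:, None] + _replicate_noise(
                rng, (config.n_genes, n_c), config.replicate_sd, config.heavy_tails
            )
            treated[iid] = pd.DataFrame(
                tmat, index=genes, columns=[f"{iid}_t{j}" for j in range(n_t)]
            )
            control[iid] = pd.DataFrame(
                cmat, index=genes, columns=[f"{iid}_c{j}" for j in range(n_c)]
            )
            meta_rows.append(
                {
                    "instance_id": iid,
                    "drug_id": d,
                    "cell_line": f"CL{r % config.n_cell_lines}",
                    "concentration": f"{10.0 ** -(6 + r):g}",
                    "platform": "SIM1",
                }
            )
            scales[iid] = scale
            inst_drug[iid] = d
    metadata = pd.DataFrame(meta_rows)
    truth = SimTruth(
        signatures=signatures,
        scales=pd.Series(scales),
        instance_drug=pd.Series(inst_drug),
        baseline=baseline,
    )
    return treated, control, metadata, truth


def simulate_effect_cube(config: SimConfig) -> tuple[EffectCube, SimTruth]:
    """Convenience: simulate and build the cube in one step."""
    treated, control, metadata, truth = simulate_cube(config)
    return build_cube(treated, control, metadata), truth


def simulate_network(
    n_genes: int,
    edge_density: float,
    hub_fraction: float = 0.0,
    hub_boost: float = 10.0,
    seed: int = 0,
    gene_ids=None,
) -> GeneNetwork:
    """Random undirected network with an optional hub tail.

    Each gene pair gets an edge with probability ``edge_density``,
    boosted by ``hub_boost`` (capped at 1) when either endpoint is a
    hub; weights ~ Uniform(0.9, 1) so every edge passes a STRING-style
    combined-score cut of 0.9.
    """
    if not (0 < edge_density < 1):
        raise ValueError("edge_density must be in (0, 1)")
    rng = np.random.default_rng([seed, 0x2E7])
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)[:n_genes]
    iu, ju = np.triu_indices(n_genes, k=1)
    hubs = np.zeros(n_genes, dtype=bool)
    n_hubs = int(round(hub_fraction * n_genes))
    if n_hubs:
        hubs[rng.choice(n_genes, size=n_hubs, replace=False)] = True
    p = np.full(len(iu), edge_density)
    boosted = hubs[iu] | hubs[ju]
    p[boosted] = np.minimum(1.0, edge_density * hub_boost)
    keep = rng.random(len(iu)) < p
    weights = rng.uniform(0.9, 1.0, int(keep.sum()))
    garr = np.asarray(gene_ids, dtype=object)
    edges = pd.DataFrame(
        {"gene_a": garr[iu[keep]], "gene_b": garr[ju[keep]], "weight": weights}
    )
    return GeneNetwork(edges)


def make_landmark_list(
    cube: EffectCube, n: int, seed: int = 0, enrich_abundance: bool = False
) -> list[str]:
    """Sample n genes without replacement to act as a landmark set.

    ``enrich_abundance`` biases sampling towards highly expressed genes
    (probability proportional to the mean control-abundance rank),
    mimicking how landmark genes were chosen among well-measured
    transcripts.
    """
    if n > cube.n_genes:
        raise ValueError("n exceeds number of cube genes")
    rng = np.random.default_rng([seed, 0x1A7D])
    if enrich_abundance:
        mean_ab = np.nanmean(cube.layers["abund_control"], axis=1)
        ranks = np.argsort(np.argsort(mean_ab)) + 1.0
        prob = ranks / ranks.sum()
        picks = rng.choice(cube.n_genes, size=n, replace=False, p=prob)
    else:
        picks = rng.choice(cube.n_genes, size=n, replace=False)
    return [str(cube.gene_ids[i]) for i in sorted(picks)]
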