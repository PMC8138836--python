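import numpy as np
import pandas as pd
import pytest

from sigmatch import SimConfig, simulate_effect_cube
from sigmatch.cube import build_cube


@pytest.fixture(scope="session")
def small_cube():
    """Small simulated cube with clear signal (6 drugs x 2 instances)."""
    cfg = SimConfig(seed=7, n_drugs=6, instances_per_drug=2, n_genes=120)
    cube, _ = simulate_effect_cube(cfg)
    return cube


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)


def toy_cube(columns: dict[str, np.ndarray], drug_of: dict[str, str] | None = None):
    """Build a tiny cube directly from desired logfc columns.

    Each entry name -> per-gene logfc vector becomes one instance with
    3+3 noiseless replicates around a flat baseline of 5.0, so logfc is
    exact and the abundance layers are well defined.
    """
    names = list(columns)
    n_genes = len(next(iter(columns.values())))
    genes = [f"g{i}" for i in range(n_genes)]
    treated, control, rows = {}, {}, []
    for i, name in enumerate(names):
        fc = np.asarray(columns[name], dtype=float)
        base = np.full(n_genes, 5.0)
        jitter = np.array([-0.01, 0.0, 0.01])
        tmat = (base + fc)[:, None] + jitter[None, :]
        cmat = base[:, None] + jitter[None, :]
        treated[name] = pd.DataFrame(tmat, index=genes,
                                     columns=[f"{name}_t{j}" for j in range(3)])
        control[name] = pd.DataFrame(cmat, index=genes,
                                     columns=[f"{name}_c{j}" for j in range(3)])
        drug = (drug_of or {}).get(name, f"D{i}")
        rows.append({"instance_id": name, "drug_id": drug, "cell_line": f"CL{i}",
                     "concentration": "1e-06", "platform": "P1"})
    return build_cube(treated, control, pd.DataFrame(rows))
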