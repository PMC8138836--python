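"""The drug-effect cube: a genes x instances array with per-gene statistic layers.

One *instance* is a single drug-treatment experiment, identified by the
4-tuple (drug, cell line, concentration, platform).  For every gene and
instance the cube stores the log2 fold change of treated over control
expression together with the statistics needed to judge its reliability:
mean log2 abundance on either side, the pooled replicate variance, a
standardized change (z), the Welch t statistic with its p-value and
degrees of freedom, and the replicate counts.

Missing statistics (e.g. a t-test that could not be computed because a
side has fewer than two replicates) are stored as NaN, never as zero.
Replicate counts are plain integers and are always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InstanceKey",
    "EffectCube",
    "FeatureVector",
    "build_cube",
    "get_vector",
    "write_cube",
    "read_cube",
    "STAT_LAYERS",
    "COUNT_LAYERS",
    "REPRESENTATIONS",
    "CubeError",
    "GeneIndexMismatch",
    "UnknownInstance",
]

#: float layers, NaN = missing
STAT_LAYERS = (
    "logfc",
    "abund_control",
    "abund_treated",
    "variance",
    "z",
    "p",
    "t",
    "df",
)
#: integer layers, always defined
COUNT_LAYERS = ("n_case", "n_control")

#: feature-vector representations derivable from the cube
REPRESENTATIONS = ("fc", "fc_times_abs", "fc_div_abs", "raw_diff", "z")

#: guard for the fc_div_abs division
DIV_ABS_EPS = 1e-6


class CubeError(ValueError):
    """Base class for effect-cube construction and access errors."""


class GeneIndexMismatch(CubeError):
    def __init__(self, instance_id: str, genes: Sequence[str]):
        self.instance_id = instance_id
        self.genes = list(genes)
        shown = ", ".join(self.genes[:10])
        more = "" if len(self.genes) <= 10 else f" (+{len(self.genes) - 10} more)"
        super().__init__(
            f"instance {instance_id!r}: gene index mismatch for genes: {shown}{more}"
        )


class UnknownInstance(CubeError, KeyError):
    pass


@dataclass(frozen=True, order=True)
class InstanceKey:
    """Identity of one treatment experiment.

    ``concentration`` is kept as a string so that keys survive TSV
    round-trips exactly; floats passed in are normalised with ``repr``.
    """

    drug_id: str
    cell_line: str
    concentration: str
    platform: str

    def __post_init__(self):
        if not self.drug_id:
            raise CubeError("InstanceKey.drug_id must be non-empty")
        if not isinstance(self.concentration, str):
            object.__setattr__(self, "concentration", repr(self.concentration))

    def label(self) -> str:
        return f"{self.drug_id}|{self.cell_line}|{self.concentration}|{self.platform}"


@dataclass
class FeatureVector:
    """Per-instance gene value vector handed to a scoring function."""

    gene_ids: np.ndarray  # object array of gene id strings
    values: np.ndarray  # float64, no NaN
    representation: str
    abundance_source: str
    n_dropped: int = 0  # genes removed because an input layer was missing

    def __post_init__(self):
        if len(self.gene_ids) != len(self.values):
            raise CubeError("FeatureVector gene_ids and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.gene_ids)


@dataclass
class EffectCube:
    """Genes x instances with statistic layers; the central data structure."""

    gene_ids: np.ndarray  # object array of gene id strings, ordered
    instances: list[InstanceKey]  # ordered, unique
    layers: dict[str, np.ndarray]  # name -> (n_genes, n_instances)

    _index: dict[InstanceKey, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_g, n_i = len(self.gene_ids), len(self.instances)
        for name in STAT_LAYERS + COUNT_LAYERS:
            if name not in self.layers:
                raise CubeError(f"missing layer {name!r}")
            if self.layers[name].shape != (n_g, n_i):
                raise CubeError(
                    f"layer {name!r} has shape {self.layers[name].shape}, "
                    f"expected {(n_g, n_i)}"
                )
        if len(set(self.instances)) != n_i:
            raise CubeError("duplicate InstanceKey in cube")
        p = self.layers["p"]
        with np.errstate(invalid="ignore"):
            if np.any((p < 0) | (p > 1)):
                raise CubeError("p layer outside [0, 1]")
        self._index = {key: i for i, key in enumerate(self.instances)}

    # -- access -----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def instance_index(self, key: InstanceKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise UnknownInstance(f"instance not in cube: {key}") from None

    def layer_frame(self, name: str) -> pd.DataFrame:
        cols = [k.label() for k in self.instances]
        return pd.DataFrame(self.layers[name], index=self.gene_ids, columns=cols)

    def column(self, layer: str, key: InstanceKey) -> np.ndarray:
        return self.layers[layer][:, self.instance_index(key)]

    def drug_ids(self) -> np.ndarray:
        return np.array([k.drug_id for k in self.instances], dtype=object)

    def reordered_genes(self, gene_ids: Sequence[str]) -> "EffectCube":
        """Return a cube with rows permuted into the given gene order."""
        pos = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if np.any(pos < 0):
            missing = [g for g, p in zip(gene_ids, pos) if p < 0]
            raise CubeError(f"genes not in cube: {missing[:10]}")
        return EffectCube(
            gene_ids=np.asarray(gene_ids, dtype=object),
            instances=list(self.instances),
            layers={k: v[pos] for k, v in self.layers.items()},
        )

    def equals(self, other: "EffectCube") -> bool:
        if not np.array_equal(self.gene_ids, other.gene_ids):
            return False
        if self.instances != other.instances:
            return False
        for name in STAT_LAYERS + COUNT_LAYERS:
            a, b = self.layers[name], other.layers[name]
            if not np.array_equal(a, b, equal_nan=(a.dtype.kind == "f")):
                return False
        return True


# -- construction ----------------------------------------------------------


def _welch(mean_t, var_t, n_t, mean_c, var_c, n_c):
    """Welch two-sample t, df and two-sided p, elementwise with NaN where undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var_t / n_t + var_c / n_c
        t = (mean_t - mean_c) / np.sqrt(se2)
        df = se2**2 / (
            (var_t / n_t) ** 2 / (n_t - 1) + (var_c / n_c) ** 2 / (n_c - 1)
        )
        # identical replicates on both sides: 0/0 -> no evidence, not infinity
        t = np.where(se2 == 0, np.nan, t)
        df = np.where(se2 == 0, np.nan, df)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def build_cube(
    treated: Mapping[str, pd.DataFrame],
    control: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
) -> EffectCube:
    """Assemble an :class:`EffectCube` from per-instance replicate matrices.

    Parameters
    ----------
    treated, control
        Maps from ``instance_id`` to a genes x replicates matrix of log2
        expression values.  All matrices must share one gene index (any
        row order).
    metadata
        One row per instance with columns ``instance_id, drug_id,
        cell_line, concentration, platform``.

    Statistics per gene and instance: ``logfc`` is the difference of
    replicate means (log2 domain); ``t``/``p``/``df`` come from a Welch
    two-sample t-test, defined only when both sides have >= 2
    replicates; ``z`` is logfc divided by its Welch standard error;
    ``variance`` is the pooled replicate variance.
    """
    required = {"instance_id", "drug_id", "cell_line", "concentration", "platform"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        raise CubeError(f"metadata missing columns: {sorted(missing_cols)}")

    ids = list(metadata["instance_id"].astype(str))
    if len(set(ids)) != len(ids):
        raise CubeError("duplicate instance_id in metadata")
    for iid in ids:
        if iid not in treated:
            raise CubeError(f"instance {iid!r} in metadata has no treated matrix")
        if iid not in control:
            raise CubeError(f"instance {iid!r} in metadata has no control matrix")
        if treated[iid].shape[1] < 1:
            raise CubeError(f"instance {iid!r} has no treated replicate")

    ref_genes = pd.Index(treated[ids[0]].index)
    if ref_genes.has_duplicates:
        raise CubeError("duplicate gene ids in expression matrix")
    for iid in ids:
        for mat in (treated[iid], control[iid]):
            diff = ref_genes.symmetric_difference(mat.index)
            if len(diff):
                raise GeneIndexMismatch(iid, [str(g) for g in diff])

    n_g, n_i = len(ref_genes), len(ids)
    layers = {name: np.full((n_g, n_i), np.nan) for name in STAT_LAYERS}
    layers.update({name: np.zeros((n_g, n_i), dtype=np.int64) for name in COUNT_LAYERS})

    keys = []
    for j, row in enumerate(metadata.itertuples(index=False)):
        iid = str(row.instance_id)
        tm = treated[iid].reindex(ref_genes).to_numpy(dtype=float)
        cm = control[iid].reindex(ref_genes).to_numpy(dtype=float)
        n_t, n_c = tm.shape[1], cm.shape[1]
        mean_t, mean_c = tm.mean(axis=1), cm.mean(axis=1)
        var_t = tm.var(axis=1, ddof=1) if n_t >= 2 else np.full(n_g, np.nan)
        var_c = cm.var(axis=1, ddof=1) if n_c >= 2 else np.full(n_g, np.nan)

        layers["logfc"][:, j] = mean_t - mean_c
        layers["abund_treated"][:, j] = mean_t
        layers["abund_control"][:, j] = mean_c
        layers["n_case"][:, j] = n_t
        layers["n_control"][:, j] = n_c

        if n_t >= 2 and n_c >= 2:
            t, df, p = _welch(mean_t, var_t, n_t, mean_c, var_c, n_c)
            layers["t"][:, j] = t
            layers["df"][:, j] = df
            layers["p"][:, j] = p
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(var_t / n_t + var_c / n_c)
                z = np.where(se > 0, (mean_t - mean_c) / se, np.nan)
            layers["z"][:, j] = z
            layers["variance"][:, j] = (
                (n_t - 1) * var_t + (n_c - 1) * var_c
            ) / (n_t + n_c - 2)
        elif n_t >= 2:
            layers["variance"][:, j] = var_t
        elif n_c >= 2:
            layers["variance"][:, j] = var_c

        keys.append(
            InstanceKey(
                drug_id=str(row.drug_id),
                cell_line=str(row.cell_line),
                concentration=str(row.concentration),
                platform=str(row.platform),
            )
        )

    return EffectCube(
        gene_ids=np.asarray([str(g) for g in ref_genes], dtype=object),
        instances=keys,
        layers=layers,
    )


def get_vector(
    cube: EffectCube,
    instance: InstanceKey,
    representation: str = "fc",
    abundance_source: str = "control",
) -> FeatureVector:
    """Derive the per-gene value vector a scoring function consumes.

    Representations: ``fc`` is the log2 fold change itself;
    ``fc_times_abs`` multiplies it with the log2 abundance (an implicit
    weight towards expressed genes); ``fc_div_abs`` divides by the
    abundance (relative change, genes with \\|abundance\\| < 1e-6 dropped);
    ``raw_diff`` is the difference of de-logged expression levels
    ``2^treated - 2^control``; ``z`` is the standardized change.

    Genes with a missing required layer are dropped and counted in
    ``FeatureVector.n_dropped``.
    """
    if representation not in REPRESENTATIONS:
        raise CubeError(
            f"unknown representation {representation!r}; valid: {REPRESENTATIONS}"
        )
    if abundance_source not in ("control", "treated"):
        raise CubeError("abundance_source must be 'control' or 'treated'")
    j = cube.instance_index(instance)

    logfc = cube.layers["logfc"][:, j]
    abund = cube.layers[f"abund_{abundance_source}"][:, j]

    if representation == "fc":
        values = logfc
    elif representation == "fc_times_abs":
        values = logfc * abund
    elif representation == "fc_div_abs":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(np.abs(abund) < DIV_ABS_EPS, np.nan, logfc / abund)
    elif representation == "raw_diff":
        at = cube.layers["abund_treated"][:, j]
        ac = cube.layers["abund_control"][:, j]
        values = np.exp2(at) - np.exp2(ac)
    else:  # z
        values = cube.layers["z"][:, j]

    keep = np.isfinite(values)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise CubeError(
            f"no usable genes for instance {instance.label()} "
            f"representation {representation!r}"
        )
    return FeatureVector(
        gene_ids=cube.gene_ids[keep],
        values=np.asarray(values[keep], dtype=float),
        representation=representation,
        abundance_source=abundance_source,
        n_dropped=n_dropped,
    )


# -- serialization ---------------------------------------------------------

_FORMAT = "sigmatch-cube"
_VERSION = 1
_KEY_FIELDS = ("drug_id", "cell_line", "concentration", "platform")


def write_cube(cube: EffectCube, path) -> None:
    """Write the cube to one HDF5 file (layout in docs/methods.md)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["version"] = _VERSION
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("genes", data=np.asarray(cube.gene_ids, dtype=str_dt))
        grp = f.create_group("instances")
        for fld in _KEY_FIELDS:
            vals = [getattr(k, fld) for k in cube.instances]
            grp.create_dataset(fld, data=np.asarray(vals, dtype=str_dt))
        lay = f.create_group("layers")
        for name in STAT_LAYERS + COUNT_LAYERS:
            lay.create_dataset(name, data=cube.layers[name])


def read_cube(path) -> EffectCube:
    """Read a cube written by :func:`write_cube`; round-trip is exact."""
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise CubeError(f"cannot open cube file {path}: {exc}") from exc
    with f:
        fmt = f.attrs.get("format")
        ver = f.attrs.get("version")
        if fmt != _FORMAT or ver != _VERSION:
            raise CubeError(
                f"not a {_FORMAT} v{_VERSION} file (format={fmt!r}, version={ver!r})"
            )
        try:
            genes = np.asarray([g.decode() for g in f["genes"][()]], dtype=object)
            cols = {
                fld: [v.decode() for v in f["instances"][fld][()]]
                for fld in _KEY_FIELDS
            }
            layers = {
                name: f["layers"][name][()] for name in STAT_LAYERS + COUNT_LAYERS
            }
        except KeyError as exc:
            raise CubeError(f"truncated or malformed cube file: missing {exc}") from exc
    instances = [
        InstanceKey(*(cols[fld][i] for fld in _KEY_FIELDS))
        for i in range(len(cols["drug_id"]))
    ]
    return EffectCube(gene_ids=genes, instances=instances, layers=layers)
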