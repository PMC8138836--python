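"""Readers and writers for the plain-text dialects shared by all modules.

Expression matrices and metadata are TSV; networks are TSV in either
the STRING dialect (``combined_score`` 0-1000 integers, kept when
score/1000 > 0.9) or a plain dialect (``weight`` floats in [0, 1], all
kept); gene lists are one id per line with ``#`` comments.

Every writer emits comment-header lines carrying the tool version, the
config hash and the seed, so any output can be traced to the run that
produced it; :func:`strip_header` removes them for byte-comparison.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .filters import FilterError, GeneNetwork

__all__ = [
    "read_expression_tsv",
    "read_metadata_tsv",
    "read_network_tsv",
    "read_gene_list",
    "write_expression_tsv",
    "write_metadata_tsv",
    "write_network_tsv",
    "write_gene_list",
    "write_table",
    "read_table",
    "strip_header",
    "config_hash",
    "split_by_instance",
    "DialectError",
]

STRING_SCORE_CUT = 0.9  # strict: combined_score/1000 must exceed this

METADATA_COLUMNS = (
    "instance_id",
    "drug_id",
    "cell_line",
    "concentration",
    "platform",
    "role",
    "sample_ids",
)


class DialectError(ValueError):
    pass


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header_lines(provenance: Optional[dict]) -> list[str]:
    prov = dict(provenance or {})
    prov.setdefault("version", __version__)
    return [f"# sigmatch {k}={v}" for k, v in sorted(prov.items())]


def write_table(df: pd.DataFrame, path, provenance: Optional[dict] = None, index=False):
    """TSV with provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def strip_header(path) -> str:
    """File contents without the provenance comment lines."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                out.append(line)
    return "".join(out)


# -- expression + metadata -------------------------------------------------


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples log2 matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise DialectError(f"{path}: expected gene id column plus >=1 sample column")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:10]
        raise DialectError(f"{path}: duplicate gene ids: {dups}")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise DialectError(f"{path}: non-numeric expression value: {exc}") from exc


def write_expression_tsv(df: pd.DataFrame, path, provenance=None):
    out = df.copy()
    out.index.name = "gene_id"
    write_table(out.reset_index(), path, provenance)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Instance metadata with treated/control roles and sample lists."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise DialectError(f"{path}: metadata missing columns: {sorted(missing)}")
    bad_role = df[~df["role"].isin(["treated", "control"])]
    if len(bad_role):
        lines = (bad_role.index + 2).tolist()[:5]
        raise DialectError(f"{path}: invalid role (line(s) {lines}); use treated|control")
    return df


def write_metadata_tsv(df: pd.DataFrame, path, provenance=None):
    write_table(df, path, provenance)


def split_by_instance(expression: pd.DataFrame, metadata: pd.DataFrame):
    """Split a wide expression matrix into per-instance replicate matrices.

    Returns ``(treated, control, instance_table)`` ready for
    :func:`sigmatch.cube.build_cube`.  ``sample_ids`` are
    semicolon-separated column names of the expression matrix.
    """
    treated, control = {}, {}
    rows = {}
    for _, row in metadata.iterrows():
        iid = row["instance_id"]
        samples = [s for s in str(row["sample_ids"]).split(";") if s]
        missing = [s for s in samples if s not in expression.columns]
        if missing:
            raise DialectError(
                f"instance {iid!r}: sample ids not in expression matrix: {missing}"
            )
        target = treated if row["role"] == "treated" else control
        if iid in target:
            raise DialectError(f"instance {iid!r}: duplicate {row['role']} row")
        target[iid] = expression[samples]
        rows.setdefault(
            iid,
            {
                "instance_id": iid,
                "drug_id": row["drug_id"],
                "cell_line": row["cell_line"],
                "concentration": row["concentration"],
                "platform": row["platform"],
            },
        )
    only_t = sorted(set(treated) - set(control))
    only_c = sorted(set(control) - set(treated))
    if only_t or only_c:
        raise DialectError(
            f"instances missing a role: treated-only={only_t[:5]} control-only={only_c[:5]}"
        )
    table = pd.DataFrame([rows[i] for i in rows])
    return treated, control, table


def metadata_from_instances(metadata: pd.DataFrame, treated, control) -> pd.DataFrame:
    """Build the two-role metadata table from per-instance matrices."""
    rows = []
    for _, row in metadata.iterrows():
        iid = row["instance_id"]
        for role, mats in (("treated", treated), ("control", control)):
            rows.append(
                {
                    "instance_id": iid,
                    "drug_id": row["drug_id"],
                    "cell_line": row["cell_line"],
                    "concentration": row["concentration"],
                    "platform": row["platform"],
                    "role": role,
                    "sample_ids": ";".join(mats[iid].columns),
                }
            )
    return pd.DataFrame(rows)


# -- networks + gene lists -------------------------------------------------


def read_network_tsv(path) -> GeneNetwork:
    """Auto-detects the STRING dialect (combined_score) vs plain (weight)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise DialectError(f"{path}: network needs gene_a and gene_b columns")
    if "combined_score" in df.columns:
        score = df["combined_score"].to_numpy(dtype=float)
        if np.any((score < 0) | (score > 1000)):
            raise DialectError(f"{path}: combined_score outside 0-1000")
        weight = score / 1000.0
        keep = weight > STRING_SCORE_CUT
        df = df.loc[keep, ["gene_a", "gene_b"]].assign(weight=weight[keep])
    elif "weight" in df.columns:
        df = df[["gene_a", "gene_b", "weight"]]
    else:
        raise DialectError(
            f"{path}: network needs a combined_score (STRING) or weight column"
        )
    try:
        return GeneNetwork(df.reset_index(drop=True))
    except FilterError as exc:
        raise DialectError(f"{path}: {exc}") from exc


def write_network_tsv(network: GeneNetwork, path, provenance=None, dialect="plain"):
    if dialect == "plain":
        write_table(network.edges, path, provenance)
    elif dialect == "string":
        out = network.edges.copy()
        out["combined_score"] = (out.pop("weight") * 1000).round().astype(int)
        write_table(out, path, provenance)
    else:
        raise DialectError(f"unknown network dialect {dialect!r}")


def read_gene_list(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    if not out:
        raise DialectError(f"{path}: empty gene list")
    return out


def write_gene_list(genes: Iterable[str], path, provenance=None):
    with open(path, "w") as fh:
        for line in _header_lines(provenance):
            fh.write(line + "\n")
        for g in genes:
            fh.write(f"{g}\n")
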