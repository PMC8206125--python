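"""Readers and writers for the external file formats the pipeline touches.

Formats: TSV expression matrices (genes in rows, samples in columns), GCT
v1.2, GMT gene-set panels, two-column homology tables, DEG tables
(gene / log2FC / pvalue / method), and the module-assignment table.

Gene identifiers are opaque, case-sensitive strings throughout; no symbol or
accession translation is attempted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = 0
UNASSIGNED_NAME = "unassigned"


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(config: Mapping | None = None) -> str:
    from . import __version__

    h = config_hash(config or {})
    return f"# locusnet {__version__} config={h}"


@dataclass
class GeneSetCollection:
    """Named gene sets with optional explicit background universe.

    Members are unique within a set and every set is non-empty; ``provenance``
    carries a free-text source label per set (the GMT description field).
    """

    sets: dict[str, list[str]]
    universe: list[str] | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")
        if self.universe is not None and len(set(self.universe)) != len(self.universe):
            raise ValueError("universe has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class HomologyTable:
    """One-to-one gene homology map between two species' symbol spaces."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("homology table contains duplicate pairs")

    def one_to_one(self) -> dict[str, str]:
        """Drop many-to-many rows; return a deterministic source→target map."""
        src_counts: dict[str, int] = {}
        tgt_counts: dict[str, int] = {}
        for s, t in self.pairs:
            src_counts[s] = src_counts.get(s, 0) + 1
            tgt_counts[t] = tgt_counts.get(t, 0) + 1
        kept = {
            s: t for s, t in self.pairs if src_counts[s] == 1 and tgt_counts[t] == 1
        }
        dropped = len(self.pairs) - len(kept)
        if dropped:
            logger.info("homology filter: dropped %d ambiguous pairs", dropped)
        return kept


def read_expression(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a genes × samples expression matrix (TSV or GCT v1.2).

    Missing entries (empty cells or "NA") become NaN; they are never coerced
    to numeric values. Row and column identifiers keep file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_expression_tsv(path)
    elif format == "gct":
        df = _read_expression_gct(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene ids: {dupes}")
    return df


def _data_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]


def _parse_matrix_lines(
    lines: list[str], header_fields: list[str], first_data_lineno: int
) -> pd.DataFrame:
    n_samples = len(header_fields)
    genes, rows = [], []
    for off, ln in enumerate(lines):
        fields = ln.split("\t")
        if len(fields) != n_samples + 1:
            raise ValueError(
                f"ragged row at line {first_data_lineno + off}: expected "
                f"{n_samples + 1} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        rows.append(
            [np.nan if f in ("", "NA", "NaN", "nan") else float(f) for f in fields[1:]]
        )
    return pd.DataFrame(rows, index=genes, columns=header_fields, dtype=float)


def _read_expression_tsv(path: Path) -> pd.DataFrame:
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")[1:]
    return _parse_matrix_lines(lines[1:], header, first_data_lineno=2)


def _read_expression_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "1.2"):
            raise ValueError(
                f"{path}: unsupported GCT version {version!r}; only v1.2 is "
                "accepted (v1.3 metadata rows would misalign columns)"
            )
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[2:]
        if len(sample_ids) != n_samples:
            raise ValueError(
                f"{path}: GCT declares {n_samples} samples but header has "
                f"{len(sample_ids)}"
            )
        genes, rows = [], []
        for ln in fh:
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != n_samples + 2:
                raise ValueError(f"{path}: ragged GCT data row for {fields[0]!r}")
            genes.append(fields[0])
            rows.append(
                [
                    np.nan if f in ("", "NA", "NaN", "nan") else float(f)
                    for f in fields[2:]
                ]
            )
    if len(genes) != n_genes:
        raise ValueError(
            f"{path}: GCT declares {n_genes} genes but file has {len(genes)} data rows"
        )
    return pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)


def write_expression(expr: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        fh.write("gene\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in zip(expr.index, expr.to_numpy()):
            cells = ["NA" if np.isnan(v) else f"{v:.10g}" for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT panel: one set per line as name, description, members."""
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(Path(path)) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT needs "
                    "name, description and at least one member"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: set {name!r} (line {lineno}) has no members")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s: set %s has %d duplicate members (deduplicated)",
                    path, name, len(members) - len(unique),
                )
            sets[name] = unique
            provenance[name] = desc
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.provenance.get(name, "locusnet")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if cov.index.duplicated().any():
        raise ValueError("duplicate sample ids in covariate table")
    return cov


def write_covariates(cov: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        cov.to_csv(fh, sep="\t", index_label="sample", lineterminator="\n")


def read_homology(path: str | Path) -> HomologyTable:
    pairs: list[tuple[str, str]] = []
    with open(Path(path)) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno} needs exactly 2 columns")
            pairs.append((fields[0], fields[1]))
    return HomologyTable(pairs=pairs)


def write_homology(table: HomologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for s, t in table.pairs:
            fh.write(f"{s}\t{t}\n")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG table with columns gene, log2fc, pvalue, method."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "log2fc", "pvalue", "method"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DEG columns {sorted(missing)}")
    if (df["gene"].astype(str).str.len() == 0).any():
        raise ValueError(f"{path}: empty gene symbols")
    if not df["pvalue"].between(0, 1).all():
        raise ValueError(f"{path}: p-values outside [0,1]")
    if not np.isfinite(df["log2fc"]).all():
        raise ValueError(f"{path}: non-finite log2 fold changes")
    return df


def write_deg_table(df: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_module_table(
    partition: pd.Series,
    kme: pd.DataFrame | None,
    path: str | Path,
    kme_p: pd.DataFrame | None = None,
    config: Mapping | None = None,
) -> None:
    """Write the gene / module / own-module kME / kME p table.

    Rows are sorted by module label then by descending kME (stable);
    unassigned genes carry the reserved label and blank kME fields.
    """
    records = []
    for gene, label in partition.items():
        if label == UNASSIGNED:
            records.append((gene, UNASSIGNED_NAME, -np.inf, "", ""))
            continue
        col = f"M{label}" if kme is not None and f"M{label}" in kme.columns else label
        r = kme.loc[gene, col] if kme is not None else np.nan
        p = kme_p.loc[gene, col] if kme_p is not None else np.nan
        records.append(
            (gene, str(label), r, f"{r:.10g}" if np.isfinite(r) else "",
             f"{p:.10g}" if kme_p is not None and np.isfinite(p) else "")
        )
    records.sort(key=lambda t: (t[1] == UNASSIGNED_NAME, t[1], -t[2]))
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        fh.write("gene\tmodule\tkme\tkme_p\n")
        for gene, label, _, r, p in records:
            fh.write(f"{gene}\t{label}\t{r}\t{p}\n")


def read_module_table(path: str | Path) -> pd.Series:
    """Read back a module-assignment table into a gene → label Series."""
    labels: dict[str, int] = {}
    with open(Path(path)) as fh:
        for ln in fh:
            if ln.startswith("#") or ln.startswith("gene\t"):
                continue
            fields = ln.rstrip("\n").split("\t")
            labels[fields[0]] = (
                UNASSIGNED if fields[1] == UNASSIGNED_NAME else int(fields[1])
            )
    return pd.Series(labels, name="module")


def read_gene_list(path: str | Path) -> list[str]:
    with open(Path(path)) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
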