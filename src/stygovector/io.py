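"""Readers and writers for the pipeline's plain-text formats.

Formats: trajectory CSV (``individual_id, replicate, t_s, x_cm, y_cm``),
classic OTU-table TSV (taxa as rows, samples as columns, first column
``taxon_id``, optional trailing ``taxonomy`` column), metadata TSV
(``sample_id, group``), newick trees, and a YAML run configuration.
Parse errors name the offending line; parse and validation failures raise
distinct exception types so callers (and the CLI) can map them to exit codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .kinematics import Trajectory

__all__ = [
    "ParseError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_trajectories",
    "write_trajectories",
    "read_tree",
    "write_tree",
    "aggregate_taxonomy",
    "RunConfig",
]


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


def read_otu_table(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a classic OTU TSV into a samples x taxa count DataFrame.

    The file stores taxa as rows and samples as columns (first column
    ``taxon_id``); a trailing ``taxonomy`` column, if present, is returned as
    a taxon-indexed Series for later rank aggregation.

    Raises
    ------
    ParseError
        Empty file, ragged rows, duplicate ids or non-integer counts, with
        the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty OTU table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}:1: need a taxon_id column and at least one sample")
    has_taxonomy = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_taxonomy else len(header)]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}:1: duplicate sample ids")
    taxon_ids, counts, taxonomies = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        taxon_ids.append(cells[0])
        row_cells = cells[1 : -1 if has_taxonomy else len(cells)]
        try:
            row = [int(c) for c in row_cells]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer count ({exc})") from None
        if any(v < 0 for v in row):
            raise ParseError(f"{path}:{lineno}: negative count")
        counts.append(row)
        if has_taxonomy:
            taxonomies.append(cells[-1])
    if len(set(taxon_ids)) != len(taxon_ids):
        dupes = sorted({t for t in taxon_ids if taxon_ids.count(t) > 1})
        raise ParseError(f"{path}: duplicate taxon ids: {dupes}")
    table = pd.DataFrame(
        np.asarray(counts, dtype=np.int64).T,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(taxon_ids, name="taxon_id"),
    )
    taxonomy = (
        pd.Series(taxonomies, index=table.columns, name="taxonomy") if has_taxonomy else None
    )
    return table, taxonomy


def write_otu_table(table: pd.DataFrame, path, taxonomy: pd.Series | None = None) -> None:
    """Write a samples x taxa DataFrame as a classic (taxa-rows) OTU TSV."""
    out = table.T.copy()
    out.index.name = "taxon_id"
    if taxonomy is not None:
        out["taxonomy"] = taxonomy.reindex(out.index)
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV with columns ``sample_id`` and ``group``."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    return meta[["sample_id", "group"]]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta[["sample_id", "group"]].to_csv(path, sep="\t", index=False)


def groups_for(table: pd.DataFrame, meta: pd.DataFrame) -> np.ndarray:
    """Group label per table row, validating 1:1 sample coverage."""
    mapping = meta.set_index("sample_id")["group"]
    missing = [s for s in table.index if s not in mapping.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return mapping.reindex(table.index).to_numpy()


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV (one or more individuals/replicates)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["individual_id", "replicate", "t_s", "x_cm", "y_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for (ind, rep), grp in df.groupby(["individual_id", "replicate"], sort=True):
        grp = grp.sort_values("t_s")
        out.append(
            Trajectory(
                individual_id=str(ind),
                replicate=int(rep),
                t_s=grp["t_s"].to_numpy(float),
                x_cm=grp["x_cm"].to_numpy(float),
                y_cm=grp["y_cm"].to_numpy(float),
            )
        )
    if not out:
        raise ParseError(f"{path}: no trajectories")
    return out


def write_trajectories(tracks: list[Trajectory], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "individual_id": tr.individual_id,
                "replicate": tr.replicate,
                "t_s": tr.t_s,
                "x_cm": tr.x_cm,
                "y_cm": tr.y_cm,
            }
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path))


def write_tree(tree, path) -> None:
    from .community import as_tree

    as_tree(tree).write(str(path))


_RANK_PREFIX = {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
                "family": "f", "genus": "g", "species": "s"}


def aggregate_taxonomy(table: pd.DataFrame, taxonomy: pd.Series, rank: str = "order",
                       unassigned: str = "Unassigned") -> pd.DataFrame:
    """Sum taxon columns that share a lineage label at the given rank.

    Taxonomy strings use the semicolon-delimited greengenes dialect
    (``k__Bacteria; p__...; c__...; o__...``); taxa without a non-empty label
    at the rank are pooled under ``unassigned``.  Column sums are preserved.
    """
    rank = rank.lower()
    if rank not in _RANK_PREFIX:
        raise ValueError(f"unknown rank {rank!r}; choose from {sorted(_RANK_PREFIX)}")
    prefix = _RANK_PREFIX[rank] + "__"
    labels = {}
    for taxon in table.columns:
        label = unassigned
        lineage = taxonomy.get(taxon, "")
        if isinstance(lineage, str):
            for part in lineage.split(";"):
                part = part.strip()
                if part.startswith(prefix) and len(part) > len(prefix):
                    label = part[len(prefix):]
                    break
        labels[taxon] = label
    grouped = table.T.groupby(pd.Series(labels), sort=True).sum().T
    grouped.columns.name = rank
    return grouped


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; YAML-loadable.

    All scalar parameters carry units in their key names; bounds must be
    ordered (min <= max) and any referenced file must exist.
    """

    trajectories_csv: str | None = None
    otu_table_tsv: str | None = None
    metadata_tsv: str | None = None
    tree_newick: str | None = None
    output_dir: str = "."
    seed: int = 0
    # kinematics / transport
    tortuosity_min: float = 2.0
    tortuosity_max: float = 4.0
    advection_min_m_yr: float = 1.0
    advection_max_m_yr: float = 1000.0
    # capacity scalars
    body_length_mm: float = 2.7
    body_width_mm: float = 0.5
    body_height_mm: float = 0.5
    surface_area_mm2: float | None = 20.0
    cell_length_um: float = 1.25
    cell_width_um: float = 0.36
    groundwater_cells_per_l: float = 2.4e8
    # CAP
    cap_m: int | None = None
    cap_permutations: int = 9999
    # rarefaction
    rarefaction_max_depth: int = 10_000
    rarefaction_step: int = 500
    rarefaction_iterations: int = 10

    def __post_init__(self) -> None:
        if self.tortuosity_min > self.tortuosity_max:
            raise ValueError("tortuosity_min must be <= tortuosity_max")
        if self.advection_min_m_yr > self.advection_max_m_yr:
            raise ValueError("advection_min must be <= advection_max")
        for attr in ("trajectories_csv", "otu_table_tsv", "metadata_tsv", "tree_newick"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
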