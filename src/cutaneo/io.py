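"""Data model and file I/O for cutaneous-microbiome study objects.

The root object is the OTU count table (taxa x samples, absolute read
counts). Everything downstream -- relative abundances, diversity indices,
UniFrac distances, ordination, typing, marker tests -- derives from it plus
a rooted phylogeny over the OTU tips, a per-OTU taxonomy lineage table and
per-sample clinical metadata.

Formats: count tables as TSV (taxa as rows, samples as columns) or
BIOM-style JSON v1.0 (sparse or dense); trees as Newick with branch
lengths; taxonomy and metadata as TSV with a header row. Writers are
bit-stable given fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("cutaneo")

#: Taxonomic ranks, coarsest to finest, used throughout the package.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Clinical skin types of the triplet design.
SKIN_TYPES = ("control", "unaffected", "lesion")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Absolute abundance table: integer read counts, taxa x samples.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative integer matrix with unique taxon ids as the index and
        unique sample ids as the columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            i, j = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise FormatError(
                f"invalid count {arr[i, j]!r} at taxon {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: counts must be non-negative integers"
            )
        self.data = df.astype(np.int64)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample sequencing depth N_j (column sums)."""
        return self.data.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class RelativeAbundanceTable:
    """Per-sample relative abundances p_ij; every column sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        colsums = self.data.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = colsums[~np.isclose(colsums, 1.0, atol=1e-9)].index.tolist()
            raise FormatError(f"columns do not sum to 1: {bad}")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("negative relative abundance")

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample clinical metadata for a triplet-matched cohort.

    ``data`` is indexed by sample id. Expected columns include
    ``skin_type`` (control/unaffected/lesion), ``triplet_id``,
    ``subject_id``, ``body_site``, ``microenvironment``,
    ``sample_month_year``, demographics and the PASI/BSA/PGA severity
    scores for lesion-bearing subjects; ``week`` for longitudinal samples.
    ``chimera_flags`` is an optional per-OTU boolean vector shared across
    samples (flags are reported, never used to filter by default).
    """

    data: pd.DataFrame
    chimera_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def validate_triplets(self) -> None:
        """Check the triplet invariant.

        Each triplet id maps to exactly one sample per skin type; lesion
        and unaffected share a subject id; the control subject differs.
        """
        for tid, grp in self.data.groupby("triplet_id"):
            types = sorted(grp["skin_type"])
            if types != sorted(SKIN_TYPES):
                raise FormatError(
                    f"triplet {tid!r} has skin types {types}, expected one each of "
                    f"{SKIN_TYPES}"
                )
            by_type = grp.set_index("skin_type")["subject_id"]
            if by_type["lesion"] != by_type["unaffected"]:
                raise FormatError(
                    f"triplet {tid!r}: lesion and unaffected must share subject_id"
                )
            if by_type["control"] == by_type["lesion"]:
                raise FormatError(
                    f"triplet {tid!r}: control subject must differ from patient"
                )

    def complete_triplets(self) -> list:
        """Triplet ids having exactly one sample of each skin type."""
        out = []
        for tid, grp in self.data.groupby("triplet_id"):
            if sorted(grp["skin_type"]) == sorted(SKIN_TYPES):
                out.append(tid)
        return out


@dataclass
class TaxonomyTable:
    """Per-OTU lineage at the five ranks phylum..genus.

    Unassigned ranks carry the label "Other" (kept distinct per parent by
    collapse-time prefixing), mirroring conventional OTU-table exports.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise FormatError(f"taxonomy table missing rank columns: {missing}")

    def lineage(self, rank: str) -> pd.Series:
        """Full lineage string through ``rank``, ';'-joined."""
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
        upto = RANKS[: RANKS.index(rank) + 1]
        return self.data[list(upto)].agg(";".join, axis=1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read an OTU count table from TSV or BIOM-style JSON v1.0."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountTable(df)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        n, m = doc["shape"]
        mat = np.zeros((n, m))
        if doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        elif doc["matrix_type"] == "dense":
            mat = np.asarray(doc["data"], dtype=float)
        else:
            raise FormatError(f"unknown BIOM matrix_type {doc['matrix_type']!r}")
        return CountTable(pd.DataFrame(mat, index=rows, columns=cols))
    raise ValueError(f"unknown format {format!r}")


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    """Write a count table; TSV orientation is taxa-as-rows only."""
    path = Path(path)
    if format == "tsv":
        table.data.to_csv(path, sep="\t", index_label="#OTU_ID")
        return
    if format == "biom-json":
        arr = table.data.to_numpy()
        nz = np.argwhere(arr != 0)
        doc = {
            "id": "cutaneo-count-table",
            "format": "Biological Observation Matrix 1.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(arr.shape),
            "rows": [{"id": str(t), "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": str(s), "metadata": None} for s in table.sample_ids],
            "data": [[int(i), int(j), int(arr[i, j])] for i, j in nz],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
        return
    raise ValueError(f"unknown format {format!r}")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths; tips indexed by label."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(
                "tree has edges without branch lengths; UniFrac requires them"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise FormatError(f"invalid branch length {node.length!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="#OTU_ID")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path) -> None:
    md.data.to_csv(path, sep="\t", index_label="#SampleID")


# ---------------------------------------------------------------------------
# Table operations
# ---------------------------------------------------------------------------

def filter_low_depth(table: CountTable, min_depth: int = 1000) -> CountTable:
    """Drop samples whose depth is not strictly greater than ``min_depth``.

    The retained cohort satisfies N_j > min_depth (strict inequality);
    removed sample ids are logged. The default of 1,000 reads reflects the
    usual adequacy threshold for 16S skin surveys.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depths = table.depths
    keep = depths[depths > min_depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.info("filter_low_depth removed %d samples: %s", len(dropped), dropped)
    if len(keep) == 0:
        raise ValueError("all samples removed by depth filter")
    return CountTable(table.data.loc[:, keep])


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    """Divide absolute abundances by the total sequence count per sample."""
    depths = table.depths
    zero = depths[depths == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-depth samples cannot be normalised: {zero}")
    return RelativeAbundanceTable(table.data / depths)


def collapse_taxonomy(table: CountTable, taxonomy: TaxonomyTable, rank: str) -> CountTable:
    """Sum OTU rows by lineage prefix through ``rank``.

    ``rank='otu'`` is the identity (97%-identity OTUs are the finest
    resolution). The collapsed taxon id is the ';'-joined lineage through
    the rank; per-sample totals are preserved exactly.
    """
    if rank == "otu":
        return CountTable(table.data.copy())
    missing = [t for t in table.taxon_ids if t not in taxonomy.data.index]
    if missing:
        raise KeyError(f"OTUs missing from taxonomy: {missing}")
    lineages = taxonomy.lineage(rank).loc[table.taxon_ids]
    collapsed = table.data.groupby(lineages.to_numpy(), sort=True).sum()
    collapsed.index.name = rank
    return CountTable(collapsed)
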