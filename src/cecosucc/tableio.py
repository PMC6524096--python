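"""Reading, writing and validation of the study's tabular and tree formats.

The in-memory study bundle is a :class:`CountTable` (OTU x sample counts with
sample metadata and taxonomy attached by id) plus an optional rooted
phylogenetic tree (:class:`skbio.TreeNode`) whose tips are OTU ids.

Supported on-disk formats: plain TSV count/metadata/taxonomy tables,
BIOM 1.0 JSON (dense and sparse), and Newick trees with branch lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class FormatError(ValueError):
    """Raised when an input file does not parse in its declared dialect."""


@dataclass
class CountTable:
    """OTU x sample table of non-negative integer counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by OTU id, columns by sample id, integer dtype.
    sample_meta : pandas.DataFrame, optional
        Indexed by sample id with columns ``age_days`` (int),
        ``diet_group`` (str) and ``doe_id`` (str).
    taxonomy : pandas.DataFrame, optional
        Indexed by OTU id with one column per rank in
        ``TAXONOMY_RANKS``; unknown ranks are empty strings.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise FormatError(
                    "non-integer count at row "
                    f"{c.index[bad[0]]!r}, column {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.round().astype(np.int64)
        if (c.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        if self.sample_meta is not None:
            missing = c.columns.difference(self.sample_meta.index)
            if len(missing):
                raise FormatError(
                    f"samples missing from metadata: {sorted(missing)}"
                )
            self.sample_meta = self.sample_meta.loc[c.columns]
        if self.taxonomy is not None:
            missing = c.index.difference(self.taxonomy.index)
            if len(missing):
                raise FormatError(f"OTUs missing from taxonomy: {sorted(missing)}")
            self.taxonomy = self.taxonomy.loc[c.index]

    # -- convenience -------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        return self.counts / totals

    def samples_at_age(self, age: int) -> list[str]:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        m = self.sample_meta
        ids = m.index[m["age_days"] == age].tolist()
        if not ids:
            raise ValueError(f"no samples at age {age}")
        return ids

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        meta = None if self.sample_meta is None else self.sample_meta.loc[sample_ids]
        return CountTable(self.counts[sample_ids], meta, self.taxonomy)

    def subset_otus(self, otu_ids) -> "CountTable":
        otu_ids = list(otu_ids)
        tax = None if self.taxonomy is None else self.taxonomy.loc[otu_ids]
        return CountTable(self.counts.loc[otu_ids], self.sample_meta, tax)

    def ages(self) -> list[int]:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        return sorted(self.sample_meta["age_days"].unique().tolist())


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(path, format: str = "tsv", transposed: bool = False) -> CountTable:
    """Read a counts-only table from TSV or BIOM 1.0 JSON.

    TSV dialect: tab-separated, no quoting, first header cell ignored,
    rows = OTUs, columns = samples (set ``transposed=True`` for the
    samples-as-rows orientation).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    elif format == "biom-json":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if transposed:
        df = df.T
    df.index = pd.Index([str(i) for i in df.index])
    df.columns = pd.Index([str(c) for c in df.columns])
    return CountTable(df)


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")
    elif format == "biom-json":
        _write_biom_json(table.counts, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_url") and "biom-format" not in doc["format_url"]:
        raise FormatError(f"{path}: not a BIOM document")
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    n_r, n_c = doc["shape"]
    if (n_r, n_c) != (len(rows), len(cols)):
        raise FormatError(f"{path}: shape {doc['shape']} inconsistent with ids")
    mat = np.zeros((n_r, n_c))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return pd.DataFrame(mat, index=rows, columns=cols)


def _write_biom_json(counts: pd.DataFrame, path: Path, sparse: bool = True) -> None:
    mat = counts.to_numpy()
    if sparse:
        nz = np.argwhere(mat != 0)
        data = [[int(i), int(j), int(mat[i, j])] for i, j in nz]
        mtype = "sparse"
    else:
        data = mat.astype(int).tolist()
        mtype = "dense"
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "cecosucc",
        "date": "",
        "rows": [{"id": str(i), "metadata": None} for i in counts.index],
        "columns": [{"id": str(c), "metadata": None} for c in counts.columns],
        "matrix_type": mtype,
        "matrix_element_type": "int",
        "shape": [mat.shape[0], mat.shape[1]],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Metadata and taxonomy


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "age_days", "diet_group", "doe_id"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    meta = meta.set_index("sample_id")
    meta["age_days"] = meta["age_days"].astype(int)
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a rank-prefixed, semicolon-delimited lineage string.

    ``"k__Bacteria;p__Firmicutes;...;g__Blautia"`` -> dict by rank name.
    Unknown or multi-affiliated ranks may be empty (``"g__"`` or absent).
    """
    out = dict.fromkeys(TAXONOMY_RANKS, "")
    for part in str(lineage).split(";"):
        part = part.strip()
        for rank, pref in zip(TAXONOMY_RANKS, _RANK_PREFIXES):
            if part.startswith(pref):
                out[rank] = part[len(pref):]
                break
    return out


def format_lineage(row: pd.Series) -> str:
    return ";".join(
        pref + str(row.get(rank, "") or "")
        for rank, pref in zip(TAXONOMY_RANKS, _RANK_PREFIXES)
    )


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "otu_id" not in tax.columns or "lineage" not in tax.columns:
        raise FormatError(f"{path}: taxonomy needs otu_id and lineage columns")
    parsed = pd.DataFrame(
        [parse_lineage(v) for v in tax["lineage"]], index=tax["otu_id"]
    )
    parsed.index.name = "otu_id"
    return parsed


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {"otu_id": taxonomy.index, "lineage": [format_lineage(r) for _, r in taxonomy.iterrows()]}
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees


def read_newick(path_or_str, missing_branch_length: str = "error") -> TreeNode:
    """Read a rooted Newick tree, validating branch lengths.

    ``missing_branch_length`` is ``"error"`` (default) or ``"zero"``
    (treat missing lengths as 0; the root's missing length is always
    tolerated).
    """
    tree = TreeNode.read(str(path_or_str))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_branch_length == "zero":
                node.length = 0.0
            else:
                raise FormatError(
                    f"node {node.name!r} has no branch length "
                    "(pass missing_branch_length='zero' to accept)"
                )
        elif node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# Study bundle


def load_study(counts_path, meta_path, tax_path=None, tree_path=None,
               counts_format: str = "tsv"):
    """Load and cross-validate the full study bundle.

    Returns ``(CountTable, tree-or-None)``. Every OTU must be a tip of the
    tree when one is given; extra tips are pruned away.
    """
    table = read_count_table(counts_path, format=counts_format)
    meta = read_sample_metadata(meta_path)
    tax = read_taxonomy(tax_path) if tax_path is not None else None
    table = CountTable(table.counts, meta, tax)
    tree = None
    if tree_path is not None:
        tree = read_newick(tree_path)
        tips = {t.name for t in tree.tips()}
        missing = set(table.otu_ids) - tips
        if missing:
            raise FormatError(
                f"OTUs absent from tree tips: {sorted(missing)[:10]}"
            )
        if tips - set(table.otu_ids):
            tree = tree.shear(table.otu_ids)
    return table, tree
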