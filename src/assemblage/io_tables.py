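"""Community tables, trees and metadata: reading, writing and normalization.

The central observable is an OTU-by-sample table of integer sequence counts
(:class:`CommunityMatrix`).  Everything downstream — rare/abundant taxon
classes, the neutral community model, the phylogenetic and abundance null
models — consumes either this table, its relative-abundance transform
(:class:`RelAbundanceMatrix`), or a rooted phylogeny whose tips match the
OTU identifiers.

Counts are normalized between data sets by rarefaction: random subsampling
without replacement down to a common depth per sample, the standard
procedure for amplicon surveys.  Typical depths for the kind of survey this
package targets are listed in :data:`RAREFACTION_PRESETS`.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Rarefaction depths (reads per sample) used by the cave-swab survey this
#: package was designed around, per marker gene.  Documented presets only;
#: `rarefy` takes any positive depth.
RAREFACTION_PRESETS: Mapping[str, int] = {
    "bacteria_16S": 12_105,
    "archaea_16S": 6_209,
    "microeukaryota_18S": 31_981,
    "fungi_ITS": 25_821,
}


class FormatError(ValueError):
    """A file or table violates the expected format."""


@dataclass(frozen=True)
class CommunityMatrix:
    """OTU x sample table of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by OTU identifier, columns by sample identifier.
        Values must be whole non-negative numbers.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if arr.size:
            if np.any(arr < 0):
                raise FormatError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise FormatError(
                    f"non-integer count {arr[i, j]!r} at OTU "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                )
        if not np.issubdtype(arr.dtype, np.integer):
            object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def otu_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_otus, n_samples) integer array."""
        return self.data.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def drop_empty_otus(self) -> "CommunityMatrix":
        """Remove OTUs with zero total count."""
        keep = self.data.sum(axis=1) > 0
        return CommunityMatrix(self.data.loc[keep])

    def select_samples(self, sample_ids: Iterable) -> "CommunityMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return CommunityMatrix(self.data[ids])


@dataclass(frozen=True)
class RelAbundanceMatrix:
    """OTU x sample table of per-sample proportions (each column sums to 1)."""

    data: pd.DataFrame

    def __post_init__(self):
        arr = self.data.to_numpy(dtype=float)
        if arr.size:
            if np.any(arr < 0):
                raise FormatError("relative abundances must be non-negative")
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.columns[~np.isclose(sums, 1.0, atol=1e-9)]
                raise FormatError(f"columns do not sum to 1: {list(bad)}")

    @property
    def otu_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample condition group and sampling-campaign (date) labels."""

    data: pd.DataFrame  # index: sample_id; columns: group, date

    def __post_init__(self):
        for col in ("group",):
            if col not in self.data.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in metadata")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def group_of(self) -> pd.Series:
        return self.data["group"]

    def samples_in_group(self, group) -> list:
        return list(self.data.index[self.data["group"] == group])

    @property
    def groups(self) -> list:
        return list(pd.unique(self.data["group"]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> CommunityMatrix:
    """Read an OTU count table from TSV or BIOM-1.0 JSON.

    TSV dialect: first column OTU ids, header row sample ids, tab-separated,
    UTF-8, lines starting with '#' ignored (except a leading '#OTU ID'-style
    header, which is common in practice and treated as the header row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format in ("biom-json", "biom"):
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> CommunityMatrix:
    text = path.read_text(encoding="utf-8")
    lines = []
    for ln in text.splitlines():
        if ln.startswith("#") and not lines:
            # allow the QIIME-style '#OTU ID<tab>...' header line
            if "\t" in ln and len(ln.split("\t")) > 1 and not ln.startswith("##"):
                lines.append(ln.lstrip("#"))
            continue
        if ln.startswith("#") or not ln.strip():
            continue
        lines.append(ln)
    if not lines:
        raise FormatError(f"{path}: empty OTU table")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric count {bad.iloc[0]!r} at OTU "
                f"{bad.index[0]!r}, sample {col!r}"
            )
    return CommunityMatrix(df)


def _read_biom_json(path: Path) -> CommunityMatrix:
    """Minimal BIOM 1.0 (JSON) reader for dense and sparse OTU tables."""
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid BIOM JSON: {e}") from e
    try:
        otu_ids = [str(r["id"]) for r in obj["rows"]]
        sample_ids = [str(c["id"]) for c in obj["columns"]]
        mtype = obj.get("matrix_type", "sparse")
        data = obj["data"]
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: missing BIOM field: {e}") from e
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if mtype == "dense":
        mat[:] = np.asarray(data)
    else:
        for i, j, v in data:
            mat[int(i), int(j)] = v
    df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    return CommunityMatrix(df)


def write_otu_table(cm: CommunityMatrix, path) -> None:
    """Write a CommunityMatrix as TSV (first column 'otu_id')."""
    df = cm.data.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV with columns sample_id, group[, date]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path) -> None:
    df = md.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_tree(path, default_length: float | None = None) -> TreeNode:
    """Read a rooted Newick tree and validate it for downstream null models.

    Every tip must be labeled and every non-root branch must carry a
    non-negative length.  Missing lengths are rejected unless
    ``default_length`` is given, in which case they are filled in.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as e:  # skbio raises several parse error types
        raise FormatError(f"{path}: cannot parse Newick: {e}") from e
    for tip in tree.tips():
        if tip.name is None or tip.name == "":
            raise FormatError(f"{path}: tree contains an unlabeled tip")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError(f"{path}: duplicate tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_length is None:
                raise FormatError(
                    f"{path}: branch above {node.name or '<internal>'} has no "
                    "length (pass default_length to fill in)"
                )
            node.length = default_length
        elif node.length < 0:
            raise FormatError(f"{path}: negative branch length {node.length}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV (no index column unless it is named)."""
    table.to_csv(path, sep="\t", index=table.index.name is not None)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def rarefy(cm: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total count is below ``depth`` are dropped with a warning.
    The subsample within each sample is multivariate hypergeometric, the
    distribution of drawing ``depth`` reads from the observed read pool.
    Deterministic for identical ``(cm, depth, seed)``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    sums = cm.sample_sums()
    keep = sums[sums >= depth].index
    dropped = [s for s in cm.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
        logger.warning("rarefy: dropped %s (below depth %d)", dropped, depth)
    if len(keep) == 0:
        raise ValueError(f"all samples are below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = cm.data[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=cm.data.index)
    return CommunityMatrix(df)


def to_relative(cm: CommunityMatrix) -> RelAbundanceMatrix:
    """Convert counts to per-sample proportions."""
    sums = cm.sample_sums()
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    return RelAbundanceMatrix(cm.data / sums)
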