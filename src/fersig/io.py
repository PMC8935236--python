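"""Readers, writers and domain containers for the pipeline's file formats.

Every reader validates its output against the container invariants so the
rest of the pipeline can assume well-formed data: non-negative log-scale
expression, unique identifiers, binary event indicators, integer single-cell
counts.  All tabular interchange is tab-separated UTF-8 with '.' decimals and
no quoting, which makes write -> read round trips bit-stable at the printed
precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "MutationTable",
    "SingleCellMatrix",
    "FormatError",
    "read_expression_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_clinical_table",
    "read_mutation_table",
    "read_sparse_counts",
    "write_results",
    "DEFAULT_VARIANT_VOCABULARY",
    "NONSILENT_CLASSES",
]

FLOAT_FORMAT = "%.10g"

#: Variant classifications accepted verbatim; anything else is kept but
#: re-tagged "other" with a warning.
DEFAULT_VARIANT_VOCABULARY = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
        "Nonstop_Mutation",
        "Silent",
        "3'UTR",
        "5'UTR",
        "Intron",
        "RNA",
        "other",
    }
)

#: Classes counted as non-silent for tumor mutation burden.
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)


class FormatError(ValueError):
    """A file violated the declared format or a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression on a log2(x+1)-like scale."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = df.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("expression contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative expression at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise FormatError("expression matrix needs >= 2 genes and >= 2 samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep])


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional role tag per set."""

    sets: dict[str, list[str]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            dedup = list(dict.fromkeys(members))
            if not dedup:
                warnings.warn(f"gene set {name!r} empty after de-duplication; dropped")
                continue
            cleaned[name] = dedup
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g)
        return list(seen)


@dataclass
class ClinicalTable:
    """Per-sample survival and categorical annotations.

    Rows with missing time/event are flagged (``missing_survival``) and kept
    for counting but excluded by survival routines.
    """

    table: pd.DataFrame  # columns: sample_id, time, event, ...

    def __post_init__(self) -> None:
        df = self.table
        for col in ("sample_id", "time", "event"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in clinical table")
        time = pd.to_numeric(df["time"], errors="coerce")
        event = pd.to_numeric(df["event"], errors="coerce")
        missing = time.isna() | event.isna()
        bad_event = ~missing & ~event.isin([0, 1])
        if bad_event.any():
            raise FormatError(
                f"event values outside {{0,1}}: {sorted(event[bad_event].unique())}"
            )
        if ((~missing) & (time < 0)).any():
            raise FormatError("negative survival time")
        df = df.copy()
        df["time"] = time
        df["event"] = event
        df["missing_survival"] = missing.to_numpy()
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def survival(self) -> pd.DataFrame:
        """Rows usable for survival analysis (complete time and event)."""
        ok = ~self.table["missing_survival"]
        out = self.table.loc[ok, :].copy()
        out["event"] = out["event"].astype(int)
        return out.set_index("sample_id")


@dataclass
class MutationTable:
    """MAF-lite records: (sample_id, gene_symbol, variant_classification)."""

    table: pd.DataFrame
    vocabulary: frozenset[str] = DEFAULT_VARIANT_VOCABULARY

    def __post_init__(self) -> None:
        df = self.table
        required = ["sample_id", "gene_symbol", "variant_classification"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"mutation table missing column {col!r}")
        df = df.copy()
        unknown = ~df["variant_classification"].isin(self.vocabulary)
        if unknown.any():
            bad = sorted(df.loc[unknown, "variant_classification"].unique())
            warnings.warn(
                f"unknown variant classifications {bad[:5]} re-tagged as 'other'"
            )
            df.loc[unknown, "variant_classification"] = "other"
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SingleCellMatrix:
    """Sparse non-negative integer counts (genes x cells) plus cell metadata."""

    counts: scipy.sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"count matrix {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell identifiers")
        data = self.counts.data
        if data.size and (data < 0).any():
            raise FormatError("negative counts")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("fractional counts are not valid")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        elif len(self.cell_meta) != len(self.cell_ids):
            raise FormatError("cell metadata rows do not align with cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def log_normalized(self, scale: float = 1e4) -> pd.DataFrame:
        """log1p of counts scaled to ``scale`` per cell (dense, genes x cells)."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel().astype(float)
        totals[totals == 0] = 1.0
        dense = self.counts.toarray().astype(float)
        return pd.DataFrame(
            np.log1p(dense / totals * scale),
            index=pd.Index(self.gene_ids, name="gene"),
            columns=self.cell_ids,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path, transpose: bool = False, log2p1: bool = False
) -> ExpressionMatrix:
    """Load a genes x samples TSV (first column = gene symbols).

    Duplicate gene rows are collapsed to the one with the larger mean (the
    usual probe-collapse heuristic); duplicate sample columns are an error.
    ``log2p1`` applies log2(x+1) for matrices still on the raw count scale.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header) and not transpose:
        raise FormatError(f"duplicate sample identifiers in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    if df.columns.duplicated().any():
        raise FormatError(f"duplicate sample identifiers in {path}")
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        dropped = int(df.index.duplicated(keep="first").sum())
        df = df[~df.index.duplicated(keep="first")]
        logger.info("collapsed %d duplicate gene rows by larger mean", dropped)
        df = df.sort_index()
    if log2p1:
        if (df.to_numpy() < 0).any():
            raise FormatError("negative values cannot be log2(x+1)-transformed")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df)


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; the description field may carry a role tag."""
    sets: dict[str, list[str]] = {}
    roles: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, description = parts[0], parts[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = [g for g in parts[2:] if g]
            sets[name] = members
            if description in {"driver", "suppressor", "marker", "other"}:
                roles[name] = description
    return GeneSetCollection(sets=sets, roles=roles)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.roles.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def read_mutation_table(
    path: str | Path, vocabulary: frozenset[str] = DEFAULT_VARIANT_VOCABULARY
) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and set(df.columns) >= {"sample_id", "gene_symbol", "variant_classification"}:
        df = df.reindex(columns=["sample_id", "gene_symbol", "variant_classification"])
    return MutationTable(df, vocabulary=vocabulary)


def read_sparse_counts(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path | None = None,
) -> SingleCellMatrix:
    """Load a MatrixMarket triplet with one-column feature/barcode files."""
    mat = scipy.io.mmread(matrix_path)
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix {mat.shape} does not match {len(genes)} features "
            f"and {len(cells)} barcodes"
        )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t")
    return SingleCellMatrix(
        counts=scipy.sparse.csr_matrix(mat), gene_ids=genes, cell_ids=cells, cell_meta=meta
    )


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def _write_frame(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_results(bundle: Mapping[str, object], out_dir: str | Path) -> pd.DataFrame:
    """Write a dict of result objects under ``out_dir``.

    DataFrames and ExpressionMatrix values become TSV, dict/scalar values
    become JSON, GeneSetCollection values become GMT.  Returns the manifest
    (also written as ``manifest.tsv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, obj in bundle.items():
        if isinstance(obj, ExpressionMatrix):
            fname = f"{name}.tsv"
            _write_frame(obj.values, out / fname)
            entries.append((fname, "ExpressionMatrix", obj.shape[0]))
        elif isinstance(obj, ClinicalTable):
            fname = f"{name}.tsv"
            _write_frame(obj.table, out / fname, index=False)
            entries.append((fname, "ClinicalTable", len(obj.table)))
        elif isinstance(obj, MutationTable):
            fname = f"{name}.tsv"
            _write_frame(obj.table, out / fname, index=False)
            entries.append((fname, "MutationTable", len(obj.table)))
        elif isinstance(obj, GeneSetCollection):
            fname = f"{name}.gmt"
            write_gene_sets_gmt(obj, out / fname)
            entries.append((fname, "GeneSetCollection", len(obj.sets)))
        elif isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            _write_frame(obj, out / fname)
            entries.append((fname, "DataFrame", len(obj)))
        elif isinstance(obj, pd.Series):
            fname = f"{name}.tsv"
            _write_frame(obj.to_frame(), out / fname)
            entries.append((fname, "Series", len(obj)))
        else:
            fname = f"{name}.json"
            with open(out / fname, "w", encoding="utf-8") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
                fh.write("\n")
            entries.append((fname, type(obj).__name__, 1))
    manifest = pd.DataFrame(entries, columns=["file", "type", "rows"])
    _write_frame(manifest, out / "manifest.tsv", index=False)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
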