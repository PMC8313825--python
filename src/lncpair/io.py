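"""Core data containers and readers/writers for the tabular formats the pipeline touches.

Expression matrices are genes x samples TSVs (first column = gene id); sample
tumor/normal labels come from a two-column sidecar TSV. Clinical tables carry
overall-survival time/event plus arbitrary covariates. Gene annotation maps
gene ids to biotypes (two-column TSV or GTF); immune gene sets are one id per
line with ``#`` comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CleaningReport",
    "GeneAnnotation",
    "ImmuneGeneSet",
    "LNCRNA_BIOTYPES",
    "load_expression",
    "load_clinical",
    "load_annotation",
    "load_gene_set",
    "subset_lncrnas",
    "strip_ensembl_version",
]

#: Ensembl biotypes counted as long non-coding; configurable in every consumer.
LNCRNA_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)

_ENSEMBL_VERSION_RE = re.compile(r"\.\d+$")


def strip_ensembl_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix (``ENSG000001.5`` -> ``ENSG000001``)."""
    return _ENSEMBL_VERSION_RE.sub("", gene_id)


class SchemaError(ValueError):
    """A required column or structural element is missing from an input file."""


class ValidationError(ValueError):
    """An input value violates a domain invariant (negativity, duplicates, ...)."""


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples expression values with tumor/normal labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Units are
        whatever the source provides (FPKM-like); only non-negativity is
        enforced.
    sample_group
        Series mapping sample id -> ``"tumor"`` or ``"normal"``. May be empty
        when group information is irrelevant (e.g. pair matrices built on
        patients only).
    """

    values: pd.DataFrame
    sample_group: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dup}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("expression values contain NaN")
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        if len(self.sample_group):
            self.sample_group = self.sample_group.reindex(self.values.columns)
            bad = set(self.sample_group.dropna().unique()) - {"tumor", "normal"}
            if bad:
                raise ValidationError(f"unknown sample group labels: {sorted(bad)}")

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        s = self.sample_group
        return list(s.index[s == group])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.sample_group.copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids if s in self.values.columns]
        grp = self.sample_group.reindex(ids) if len(self.sample_group) else self.sample_group
        return ExpressionMatrix(self.values[ids], grp)

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform used by the correlation and DE screens."""
        return np.log2(self.values + 1.0)

    def to_tsv(self, path: str | Path, group_path: str | Path | None = None) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
        if group_path is not None:
            g = self.sample_group.rename("group").to_frame()
            g.index.name = "sample_id"
            g.to_csv(group_path, sep="\t")


@dataclass
class CleaningReport:
    """Counts of clinical rows removed per cleaning rule."""

    n_input: int = 0
    n_zero_followup: int = 0
    n_duplicate: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class ClinicalTable:
    """Per-patient survival outcome and clinical covariates.

    ``data`` is indexed by sample id and always carries ``os_time`` (days,
    strictly positive) and ``os_event`` (0 censored / 1 death); any further
    columns are clinical covariates stored as-is.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise SchemaError(f"clinical table missing mandatory column {col!r}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicated sample ids in clinical table")
        ev = self.data["os_event"]
        if not ev.isin([0, 1]).all():
            bad = sorted(ev[~ev.isin([0, 1])].unique().tolist())
            raise ValidationError(f"os_event values outside {{0,1}}: {bad}")
        if (self.data["os_time"] <= 0).any():
            raise ValidationError("os_time must be strictly positive after cleaning")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.data["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.data["os_event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("os_time", "os_event")]

    def aligned_to(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        ids = [s for s in sample_ids if s in self.data.index]
        return ClinicalTable(self.data.loc[ids])

    def to_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class GeneAnnotation:
    """gene id -> (biotype, symbol) map with one record per gene."""

    table: pd.DataFrame  # index gene_id, columns biotype, symbol

    def __post_init__(self) -> None:
        if "biotype" not in self.table.columns:
            raise SchemaError("annotation requires a 'biotype' column")
        if "symbol" not in self.table.columns:
            self.table = self.table.assign(symbol=self.table.index)
        if self.table.index.duplicated().any():
            self.table = self.table[~self.table.index.duplicated(keep="first")]

    def biotype_of(self, gene_id: str) -> str | None:
        if gene_id in self.table.index:
            return self.table.loc[gene_id, "biotype"]
        return None

    def genes_with_biotypes(self, biotypes: Iterable[str]) -> set[str]:
        wanted = set(biotypes)
        mask = self.table["biotype"].isin(wanted)
        return set(self.table.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class ImmuneGeneSet:
    """Set of gene identifiers designated immune-related (ImmPort style)."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(strip_ensembl_version(g) for g in self.genes)
        if not self.genes:
            raise ValidationError("immune gene set is empty")

    def __contains__(self, gene_id: str) -> bool:
        return strip_ensembl_version(gene_id) in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.genes)) + "\n")


# ---------------------------------------------------------------------------
# loaders


def load_expression(
    path: str | Path,
    group_path: str | Path | None = None,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV into an :class:`ExpressionMatrix`.

    Ensembl version suffixes are stripped from gene ids; duplicated gene ids
    are collapsed by keeping the row with the highest mean expression.
    Tumor/normal labels come from ``groups`` or from a two-column sidecar TSV
    (``sample_id<TAB>group``).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicated sample columns: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna().argmax()]
                raise SchemaError(
                    f"non-numeric expression cell at gene {row!r}, sample {col!r}"
                ) from exc
        raise
    df.index = df.index.astype(str).map(strip_ensembl_version)
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        best = df.iloc[order]
        best = best[~best.index.duplicated(keep="first")]
        df = best.reindex(pd.unique(df.index))
    if group_path is not None:
        sidecar = pd.read_csv(group_path, sep="\t", index_col=0)
        groups = sidecar.iloc[:, 0]
    if groups is None:
        grp = pd.Series(dtype=object)
    else:
        grp = pd.Series(groups).reindex(df.columns)
    return ExpressionMatrix(df, grp)


_CLINICAL_DEFAULT_COLMAP = {
    "sample_id": "sample_id",
    "os_time": "os_time",
    "os_event": "os_event",
}


def load_clinical(
    path: str | Path, colmap: Mapping[str, str] | None = None
) -> tuple[ClinicalTable, CleaningReport]:
    """Read and clean a clinical TSV.

    Cleaning rules: rows with follow-up time <= 0 days are removed; duplicated
    sample ids keep the first occurrence. Counts per rule are returned in the
    :class:`CleaningReport`. Applying the loader to its own output is a no-op.
    """
    cm = dict(_CLINICAL_DEFAULT_COLMAP)
    if colmap:
        cm.update(colmap)
    df = pd.read_csv(path, sep="\t")
    for key in ("sample_id", "os_time", "os_event"):
        if cm[key] not in df.columns:
            raise SchemaError(f"clinical table missing column {cm[key]!r} (for {key})")
    df = df.rename(columns={cm["sample_id"]: "sample_id", cm["os_time"]: "os_time", cm["os_event"]: "os_event"})
    report = CleaningReport(n_input=len(df))
    ev = pd.to_numeric(df["os_event"], errors="coerce")
    if not ev.isin([0, 1]).all():
        bad = sorted(df["os_event"][~ev.isin([0, 1])].unique().tolist())
        raise ValidationError(f"os_event values outside {{0,1}}: {bad}")
    df["os_event"] = ev.astype(int)
    df["os_time"] = pd.to_numeric(df["os_time"])
    keep = df["os_time"] > 0
    report.n_zero_followup = int((~keep).sum())
    df = df[keep]
    dup = df["sample_id"].duplicated(keep="first")
    report.n_duplicate = int(dup.sum())
    df = df[~dup]
    report.n_retained = len(df)
    df = df.set_index("sample_id")
    return ClinicalTable(df), report


def load_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene annotation from a two-column TSV or a GTF file.

    TSV: columns ``gene_id`` and ``biotype`` (optional ``symbol``). GTF: gene
    feature lines with ``gene_id`` and ``gene_biotype``/``gene_type``
    attributes (read through pyranges).
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        import pyranges

        gr = pyranges.read_gtf(str(path)).df
        gr = gr[gr["Feature"] == "gene"]
        biotype_col = "gene_biotype" if "gene_biotype" in gr.columns else "gene_type"
        symbol_col = "gene_name" if "gene_name" in gr.columns else None
        tab = pd.DataFrame(
            {
                "biotype": gr[biotype_col].to_numpy(),
                "symbol": gr[symbol_col].to_numpy() if symbol_col else gr["gene_id"].to_numpy(),
            },
            index=gr["gene_id"].astype(str).map(strip_ensembl_version),
        )
    else:
        tab = pd.read_csv(path, sep="\t", index_col=0)
        if "biotype" not in tab.columns:
            # headerless two-column file
            tab = pd.read_csv(path, sep="\t", index_col=0, header=None, names=["gene_id", "biotype"])
        tab.index = tab.index.astype(str).map(strip_ensembl_version)
    return GeneAnnotation(tab)


def load_gene_set(path: str | Path) -> ImmuneGeneSet:
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return ImmuneGeneSet(frozenset(genes))


def subset_lncrnas(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    biotypes: Iterable[str] = LNCRNA_BIOTYPES,
) -> ExpressionMatrix:
    """Restrict an expression matrix to genes annotated with a lncRNA biotype.

    Raises ``ValidationError`` when no annotated lncRNA is present.
    """
    lnc = annotation.genes_with_biotypes(biotypes)
    ids = [g for g in expr.gene_ids if g in lnc]
    if not ids:
        raise ValidationError("no lncRNAs found: annotation does not overlap the matrix")
    return expr.subset_genes(ids)
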