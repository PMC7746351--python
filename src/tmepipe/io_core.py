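"""Readers, writers and validated domain containers for every external format
the pipeline touches.

All tabular formats are plain TSV.  Coordinates in mutation and segment tables
are 1-based inclusive on disk (MAF/SEG convention); interval arithmetic inside
the package converts to 0-based half-open and back on write.  Gene identifiers
are matched by exact string comparison after upper-casing and stripping
whitespace — no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tmepipe")

EXPRESSION_UNITS = ("counts", "logcpm", "normalized")

#: The nine somatic variant classifications recognised downstream.
VARIANT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Splice_Site",
    "Translation_Start_Site",
    "Nonstop_Mutation",
)

#: Classes counted as nonsilent for tumor mutation burden.
NONSILENT_CLASSES = frozenset(VARIANT_CLASSES)


class ValidationError(ValueError):
    """An input file or in-memory table violates a format invariant."""


def normalize_gene_id(g: str) -> str:
    return str(g).strip().upper()


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a unit tag.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.unit == "counts" and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)


@dataclass
class ClinicalTable:
    """Per-sample overall-survival time (days), event indicator and covariates."""

    table: pd.DataFrame  # index sample_id; columns os_time, os_event, covariates

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        for col in ("os_time", "os_event"):
            if col not in t.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if (t["os_time"] < 0).any():
            raise ValidationError("negative os_time")
        if not t["os_event"].isin([0, 1]).all():
            raise ValidationError("os_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.table["os_time"].to_numpy(float)

    @property
    def os_event(self) -> np.ndarray:
        return self.table["os_event"].to_numpy(int)


MAF_REQUIRED = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)


@dataclass
class MutationTable:
    """MAF-like somatic mutation records (1-based positions, reference strand).

    Optional columns: ``CONTEXT`` (3-mer centred on the mutated base) and
    ``CONTEXT41`` (±20 bp flanks) used by the trinucleotide catalogue and
    APOBEC enrichment respectively.
    """

    records: pd.DataFrame
    contigs: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        r = self.records
        for col in MAF_REQUIRED:
            if col not in r.columns:
                raise ValidationError(f"mutation table missing column {col!r}")
        snv = self.is_snv()
        same = snv & (r["Reference_Allele"] == r["Tumor_Seq_Allele2"])
        if same.any():
            raise ValidationError(
                f"SNV with ref == alt at record {int(np.flatnonzero(same)[0])}"
            )
        if "CONTEXT" in r.columns:
            ctx = r.loc[snv, "CONTEXT"].astype(str)
            mid = ctx.str[1]
            bad = mid.notna() & (mid != r.loc[snv, "Reference_Allele"])
            if bad.any():
                raise ValidationError(
                    "CONTEXT middle base does not match Reference_Allele at record "
                    f"{int(bad[bad].index[0])}"
                )
        if self.contigs is not None:
            unknown = ~r["Chromosome"].astype(str).isin(self.contigs)
            if unknown.any():
                raise ValidationError(
                    f"unknown contig {r['Chromosome'][unknown].iloc[0]!r}"
                )

    def is_snv(self) -> pd.Series:
        r = self.records
        bases = {"A", "C", "G", "T"}
        return (
            r["Reference_Allele"].astype(str).isin(bases)
            & r["Tumor_Seq_Allele2"].astype(str).isin(bases)
        )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["Tumor_Sample_Barcode"].unique())


SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Segment_Mean")


@dataclass
class SegmentTable:
    """SEG-like copy-number segments, 1-based inclusive, caller-relative values."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        for col in SEG_COLUMNS:
            if col not in r.columns:
                raise ValidationError(f"segment table missing column {col!r}")
        bad = r["Start"] > r["End"]
        if bad.any():
            raise ValidationError(
                f"segment start > end at record {int(np.flatnonzero(bad)[0])}"
            )
        # non-overlap within one sample/chromosome
        for (s, c), grp in r.groupby(["Sample", "Chromosome"], sort=False):
            g = grp.sort_values("Start")
            if (g["Start"].to_numpy()[1:] <= g["End"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"overlapping segments for sample {s!r} chromosome {c!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["Sample"].unique())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> member gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SignatureMatrixRef:
    """Cell-type reference expression profiles (genes x cell types, linear scale)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValidationError("reference needs >= 2 cell types")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate genes in reference matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite values in reference matrix")

    @property
    def cell_type_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str})


def read_expression(path, unit: str = "counts") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene ids, header sample ids).

    Duplicate gene rows are collapsed by keeping the row with the highest mean
    expression; the collapse is reported at INFO level.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for s in header:
        if s in seen:
            raise ValidationError(f"duplicate sample id {s!r} in {path}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_gene_id(g) for g in df.index]
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric value {bad.iloc[0]!r} at gene {bad.index[0]!r}, "
                f"sample {col!r} in {path}"
            )
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        kept = df.iloc[order]
        kept = kept[~kept.index.duplicated(keep="first")]
        df2 = kept.loc[[g for g in dict.fromkeys(df.index)]]
        n = len(df) - len(df2)
        logger.info("collapsed %d duplicate gene rows by max mean expression", n)
        df = df2
    return ExpressionMatrix(df, unit=unit)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError("clinical table missing column 'sample_id'")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.table.to_csv(path, sep="\t", index_label="sample_id")


def read_maf(path, contigs: tuple[str, ...] | None = None) -> MutationTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise ValidationError(f"MAF {path} missing mandatory column {col!r}")
    known = df["Variant_Classification"].isin(VARIANT_CLASSES + ("Silent", "other"))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("mapped %d records with unknown variant class to 'other'", n_unknown)
        df = df.copy()
        df.loc[~known, "Variant_Classification"] = "other"
    return MutationTable(df, contigs=contigs)


def write_maf(muts: MutationTable, path) -> None:
    muts.records.to_csv(path, sep="\t", index=False)


def read_seg(path) -> SegmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    return SegmentTable(df)


def write_seg(segs: SegmentTable, path) -> None:
    segs.records.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {i + 1} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            sets[name] = [normalize_gene_id(g) for g in parts[2:] if g]
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            d = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, d, *genes]) + "\n")


def read_signature_matrix(path) -> SignatureMatrixRef:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_gene_id(g) for g in df.index]
    return SignatureMatrixRef(df)


def write_signature_matrix(ref: SignatureMatrixRef, path) -> None:
    ref.values.to_csv(path, sep="\t", index_label="gene_id")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg
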