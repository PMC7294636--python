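"""Typed readers and writers for the tabular artifacts the pipeline touches.

All matrices follow a single internal convention: rows are genes (or CpG
probes), columns are samples.  Files whose layout is samples-in-rows must be
transposed at load time via ``transpose=True`` — there is no orientation
guessing.  Identifiers are opaque strings; no symbol/ID mapping is performed.

Missing values are encoded as ``NA`` on disk.  Expression matrices must be
complete (NA is rejected); methylation beta matrices may contain NA, which
downstream statistics exclude pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIAGNOSES = ("normal", "LGG", "GBM")
GRADES = ("II", "III", "IV")
IDH_STATUSES = ("mut", "WT")
CODEL_STATUSES = ("codel", "non-codel")
ANATOMIC_REGIONS = ("LE", "IT", "CT", "PAN", "MVP")
RECURRENCE = ("primary", "recurrent")
CNV_STATUSES = ("loss", "neutral", "gain")


class OmicsIOError(ValueError):
    """Raised on any validation failure while loading or constructing a table."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = sorted(seen[seen.duplicated()].unique().tolist())
        raise OmicsIOError(f"duplicate {what} identifier(s): {dupes}")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values (TPM or
    normalized intensity; the unit is recorded, never converted)."""

    values: pd.DataFrame  # genes in rows, samples in columns
    unit: str = "TPM"
    sample_annotation: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise OmicsIOError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise OmicsIOError(
                f"expression value missing at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if not np.isfinite(arr).all():
            raise OmicsIOError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise OmicsIOError(
                f"negative expression at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationMatrix:
    """CpG probe x sample beta values in [0, 1] with probe→(gene, promoter)
    annotation.  NA beta values are permitted and excluded pairwise downstream."""

    beta: pd.DataFrame  # probes in rows, samples in columns
    probe_annotation: pd.DataFrame  # index probe_id; columns gene_id, is_promoter

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe")
        _check_unique(self.beta.columns, "sample")
        arr = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            p, s = np.argwhere(bad)[0]
            raise OmicsIOError(
                f"beta value outside [0,1] at probe {self.beta.index[p]!r}, "
                f"sample {self.beta.columns[s]!r}: {arr[p, s]}"
            )
        missing = self.beta.index.difference(self.probe_annotation.index)
        if len(missing):
            raise OmicsIOError(f"probes lack annotation: {sorted(missing.tolist())}")
        dup = self.probe_annotation.index.has_duplicates
        if dup:
            raise OmicsIOError("a probe maps to more than one gene record")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def probes_for_gene(self, gene_id: str, promoter_only: bool = False) -> list[str]:
        ann = self.probe_annotation
        mask = ann["gene_id"] == gene_id
        if promoter_only:
            mask &= ann["is_promoter"].astype(bool)
        return list(ann.index[mask])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: diagnosis, grade, molecular status,
    anatomic region, overall survival and treatment."""

    table: pd.DataFrame  # index sample_id

    _ENUMS = {
        "diagnosis": DIAGNOSES,
        "grade": GRADES,
        "idh_status": IDH_STATUSES,
        "codel_1p19q": CODEL_STATUSES,
        "anatomic_region": ANATOMIC_REGIONS,
        "recurrence": RECURRENCE,
    }

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample")
        if "diagnosis" not in t.columns:
            raise OmicsIOError("clinical table requires a 'diagnosis' column")
        for col, allowed in self._ENUMS.items():
            if col not in t.columns:
                continue
            vals = t[col].dropna()
            bad = set(vals) - set(allowed)
            if bad:
                raise OmicsIOError(f"unknown {col} label(s): {sorted(bad)}")
        if "os_months" in t.columns:
            has_time = t["os_months"].notna()
            if has_time.any():
                if "os_event" not in t.columns:
                    raise OmicsIOError("os_months present without os_event column")
                missing_ev = has_time & t["os_event"].isna()
                if missing_ev.any():
                    raise OmicsIOError(
                        f"os_event missing for samples with os_months: "
                        f"{sorted(t.index[missing_ev].tolist())}"
                    )
                if (t.loc[has_time, "os_months"] < 0).any():
                    raise OmicsIOError("negative os_months")
                ev = t.loc[has_time, "os_event"]
                if not ev.isin([0, 1]).all():
                    raise OmicsIOError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with(self, **filters) -> list[str]:
        """Sample ids matching exact values, e.g. ``diagnosis='GBM'``."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in filters.items():
            if isinstance(val, (list, tuple, set)):
                mask &= self.table[col].isin(list(val))
            else:
                mask &= self.table[col] == val
        return list(self.table.index[mask])


@dataclass
class FluidProteomeTable:
    """Gene ids detectable in a body fluid with a positive fluorescence
    intensity per gene (arbitrary units).  Multiple input rows per gene are
    collapsed to the maximum intensity: detectability is an existence claim."""

    table: pd.DataFrame  # index gene_id; column fluorescence

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        f = self.table["fluorescence"].to_numpy(dtype=float)
        if not np.isfinite(f).all() or (f <= 0).any():
            raise OmicsIOError("fluorescence must be finite and > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class CnvTable:
    """Long-format copy-number records: one row per (sample, gene) with a
    categorical status in {loss, neutral, gain} and an optional numeric
    segment-mean value."""

    table: pd.DataFrame  # columns sample_id, gene_id, status, value

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "gene_id", "status"):
            if col not in t.columns:
                raise OmicsIOError(f"CNV table requires column {col!r}")
        if t.duplicated(subset=["sample_id", "gene_id"]).any():
            raise OmicsIOError("duplicate (sample, gene) CNV record")
        bad = set(t["status"]) - set(CNV_STATUSES)
        if bad:
            raise OmicsIOError(f"unknown CNV status label(s): {sorted(bad)}")

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        sub = self.table[self.table["gene_id"] == gene_id]
        return sub.set_index("sample_id")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise OmicsIOError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise OmicsIOError(f"gene set {name!r} has duplicate members")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_frame(path, transpose: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if transpose:
        df = df.T
    _check_unique(df.index, "row")
    _check_unique(df.columns, "column")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise OmicsIOError(
                    f"non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = coerced
    return df.astype(float)


def read_expression_matrix(path, dialect: str = "tsv_genes_by_samples",
                           unit: str = "TPM") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column = gene id,
    header = sample ids).

    ``dialect`` is one of ``tsv_genes_by_samples`` (the internal convention),
    ``tsv_samples_by_genes`` (transposed on load) or ``gct_like`` (two header
    lines ``#1.2`` / dims, then a Description column, which is dropped).
    """
    path = Path(path)
    if dialect == "gct_like":
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0,
                         na_values=["NA"], keep_default_na=False)
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
        df = df.astype(float)
        _check_unique(df.index, "gene")
    elif dialect in ("tsv_genes_by_samples", "tsv_samples_by_genes"):
        df = _read_matrix_frame(path, transpose=dialect == "tsv_samples_by_genes")
    else:
        raise OmicsIOError(f"unknown dialect {dialect!r}")
    m = ExpressionMatrix(values=df, unit=unit)
    logger.info("read expression matrix %s: %d genes x %d samples",
                path.name, len(m.gene_ids), len(m.sample_ids))
    return m


def read_methylation_matrix(path, annotation_path) -> MethylationMatrix:
    """Read a beta-value matrix plus a probe annotation table
    (columns ``probe_id``, ``gene_id``, ``is_promoter``).

    Probes absent from the annotation are dropped (count logged); beta values
    outside [0, 1] are a hard error.
    """
    beta = _read_matrix_frame(path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    ann = ann.set_index("probe_id")
    ann["is_promoter"] = ann["is_promoter"].astype(bool)
    unannotated = beta.index.difference(ann.index)
    if len(unannotated):
        logger.info("dropping %d probe(s) lacking annotation", len(unannotated))
        beta = beta.drop(index=unannotated)
    ann = ann.loc[ann.index.intersection(beta.index)]
    return MethylationMatrix(beta=beta, probe_annotation=ann.loc[beta.index])


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical CSV/TSV table; delimiter sniffed from the extension."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False,
                     dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise OmicsIOError("clinical table requires a 'sample_id' column")
    df = df.set_index("sample_id")
    for col in ("os_months", "os_event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return ClinicalTable(table=df)


def read_fluid_proteome(path) -> FluidProteomeTable:
    """Read a two-column (gene_id, fluorescence) table; duplicate genes are
    collapsed to their maximum intensity."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df["gene_id"].duplicated().any():
        n = int(df["gene_id"].duplicated().sum())
        logger.info("collapsing %d duplicate fluid-proteome row(s) to max intensity", n)
        df = df.groupby("gene_id", sort=False, as_index=False)["fluorescence"].max()
    return FluidProteomeTable(table=df.set_index("gene_id"))


def read_cnv_table(path) -> CnvTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"sample_id": str, "gene_id": str, "status": str})
    if "value" in df.columns:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    return CnvTable(table=df)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``.

    Blank lines are skipped; duplicate members within a set are deduplicated
    with a warning; an empty member list is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise OmicsIOError(f"GMT line {lineno}: empty member list")
            name = parts[0]
            members, seen = [], set()
            for m in parts[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in seen:
                    logger.warning("GMT set %r: duplicate member %r dropped", name, m)
                    continue
                seen.add(m)
                members.append(m)
            sets[name] = members
    coll = GeneSetCollection(sets=sets)
    for name, members in sets.items():
        logger.info("gene set %r: %d members", name, len(members))
    return coll


# float format fixed for byte-identical reruns
_FLOAT_FMT = "%.12g"


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """Write a genes(probes) x samples matrix as UTF-8 TSV with Unix newlines
    and fixed float precision (NaN rendered as NA)."""
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT,
              na_rep="NA", lineterminator="\n", encoding="utf-8")


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    write_matrix(m.values, path, index_label="gene_id")


def write_methylation_matrix(m: MethylationMatrix, path, annotation_path) -> None:
    write_matrix(m.beta, path, index_label="probe_id")
    m.probe_annotation.to_csv(annotation_path, sep="\t", index_label="probe_id",
                              lineterminator="\n", encoding="utf-8")


def write_clinical_table(c: ClinicalTable, path) -> None:
    c.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
                   float_format=_FLOAT_FMT, lineterminator="\n", encoding="utf-8")


def write_fluid_proteome(f: FluidProteomeTable, path) -> None:
    f.table.to_csv(path, sep="\t", index_label="gene_id",
                   float_format=_FLOAT_FMT, lineterminator="\n", encoding="utf-8")


def write_cnv_table(c: CnvTable, path) -> None:
    c.table.to_csv(path, sep="\t", index=False, na_rep="NA",
                   float_format=_FLOAT_FMT, lineterminator="\n", encoding="utf-8")
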