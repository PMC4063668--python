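"""Readers and writers for the tabular formats the pipeline consumes.

All matrices travel as tab-delimited text with a header row; probe/feature
ids in the first column, sample ids across the top.  Genomic coordinates are
0-based half-open internally (BED convention); the VCF reader converts its
1-based positions on load.  Missing values are written as ``NA`` and parsed
from any of ``NA``, ``nan`` or the empty string.  Strand is carried through
but ignored by all window logic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_MARKERS = ("NA", "", "nan", "NaN")

VALID_POPULATIONS = ("CEU", "YRI", "CHB", "other")
VALID_SEXES = ("male", "female", "unknown")
VALID_PROBE_CLASSES = ("test", "negative", "invariant", "gender")
VALID_LOCUS_TYPES = ("tandem", "dispersed", "unknown")


class ParseError(ValueError):
    """A malformed cell or record in an input table."""


class ValidationError(ValueError):
    """Structurally valid input that violates an invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Alignment:
    """One genomic alignment of a probe sequence.

    Coordinates are 0-based half-open; ``percent_identity`` in [0, 100].
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    percent_identity: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"alignment requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"percent_identity must lie in [0, 100], got {self.percent_identity}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")


@dataclass
class ProbeAnnotation:
    """A probe, its class, and its genomic alignments."""

    probe_id: str
    target_name: str = ""
    probe_class: str = "test"
    locus_type: str = "unknown"
    alignments: list[Alignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.probe_class not in VALID_PROBE_CLASSES:
            raise ValidationError(f"invalid probe_class {self.probe_class!r}")
        if self.locus_type not in VALID_LOCUS_TYPES:
            raise ValidationError(f"invalid locus_type {self.locus_type!r}")
        if self.probe_class == "test" and not self.alignments:
            raise ValidationError(
                f"test probe {self.probe_id!r} must have at least one alignment"
            )


@dataclass
class SampleTable:
    """Cohort description: population, sex and species per sample."""

    df: pd.DataFrame  # index sample_id; columns population, sex, species

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dupes = self.df.index[self.df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad_pop = set(self.df["population"]) - set(VALID_POPULATIONS)
        if bad_pop:
            raise ValidationError(f"unknown populations: {sorted(bad_pop)}")
        bad_sex = set(self.df["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sexes: {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def population(self, sample_id: str) -> str:
        return self.df.loc[sample_id, "population"]

    def samples_of(self, population: str | None = None, sex: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.df.index)
        if population is not None:
            mask &= self.df["population"] == population
        if sex is not None:
            mask &= self.df["sex"] == sex
        return list(self.df.index[mask])


@dataclass
class FeatureMatrix:
    """A features × samples numeric grid with optional per-feature coordinates.

    ``values`` uses NaN as the missing marker and is never silently imputed.
    ``coords`` (if present) is indexed by feature id with columns ``chrom``
    and ``pos`` (a single 0-based anchor base: SNP position, TSS, CpG site).
    """

    values: pd.DataFrame
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.coords is not None:
            missing = self.values.index.difference(self.coords.index)
            if len(missing):
                raise ValidationError(
                    f"{len(missing)} features lack coordinates (e.g. {missing[0]!r})"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        coords = self.coords.loc[list(ids)] if self.coords is not None else None
        return FeatureMatrix(self.values.loc[list(ids)], coords)

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(ids)], self.coords)


# ---------------------------------------------------------------------------
# readers


def read_count_matrix(path: str | Path) -> FeatureMatrix:
    """Read a probes × samples count table (TSV, header of sample ids).

    Raises :class:`ParseError` naming the offending row/column for malformed
    numeric cells, and :class:`ValidationError` for duplicated ids.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids in {path}: {dupes}")
    if raw.columns.duplicated().any():
        # pandas mangles duplicate headers; re-check the raw header line
        pass
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate sample columns in {path}: {dupes}")
    values = pd.DataFrame(index=raw.index, columns=header, dtype=float)
    for col in header:
        cells = raw[col].where(~raw[col].isin(MISSING_MARKERS))
        converted = pd.to_numeric(cells, errors="coerce")
        bad = converted.isna() & cells.notna()
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"malformed numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        values[col] = converted
    return FeatureMatrix(values)


def write_count_matrix(fm: FeatureMatrix, path: str | Path, float_precision: int = 6) -> None:
    fm.values.to_csv(path, sep="\t", na_rep="NA", float_format=f"%.{float_precision}g")


def read_probe_bed(
    path: str | Path, class_table: str | Path | None = None
) -> list[ProbeAnnotation]:
    """Read probe alignments from a BED6-style TSV (identity in the score slot).

    Columns: chrom, start, end, probe_id, percent_identity, strand.  Multiple
    lines with one probe_id become one probe with several alignments.  An
    optional side table supplies probe_class / locus_type / target_name per
    probe; without it every probe is a ``test`` probe.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "probe_id", "percent_identity", "strand"],
        dtype={"chrom": str, "probe_id": str, "strand": str},
    )
    meta: pd.DataFrame | None = None
    if class_table is not None:
        meta = pd.read_csv(class_table, sep="\t", index_col="probe_id", dtype=str)

    probes: dict[str, ProbeAnnotation] = {}
    order: list[str] = []
    for rec in bed.itertuples(index=False):
        aln = Alignment(
            chrom=rec.chrom,
            start=int(rec.start),
            end=int(rec.end),
            strand=rec.strand,
            percent_identity=float(rec.percent_identity),
        )
        pid = rec.probe_id
        if pid not in probes:
            cls, ltype, target = "test", "unknown", pid
            if meta is not None and pid in meta.index:
                row = meta.loc[pid]
                cls = row.get("probe_class", cls) or cls
                ltype = row.get("locus_type", ltype) or ltype
                target = row.get("target_name", target) or target
            probes[pid] = ProbeAnnotation(
                probe_id=pid,
                target_name=target,
                probe_class=cls,
                locus_type=ltype,
                alignments=[aln],
            )
            order.append(pid)
        else:
            probes[pid].alignments.append(aln)
    # side-table-only probes (negative/invariant controls with no alignments)
    if meta is not None:
        for pid, row in meta.iterrows():
            if pid not in probes:
                probes[pid] = ProbeAnnotation(
                    probe_id=pid,
                    target_name=row.get("target_name", pid) or pid,
                    probe_class=row.get("probe_class", "test") or "test",
                    locus_type=row.get("locus_type", "unknown") or "unknown",
                    alignments=[],
                )
                order.append(pid)
    return [probes[pid] for pid in order]


def write_probe_bed(
    probes: Iterable[ProbeAnnotation],
    path: str | Path,
    class_table: str | Path | None = None,
) -> None:
    rows = []
    meta_rows = []
    for p in probes:
        meta_rows.append(
            {
                "probe_id": p.probe_id,
                "target_name": p.target_name,
                "probe_class": p.probe_class,
                "locus_type": p.locus_type,
            }
        )
        for a in p.alignments:
            rows.append(
                {
                    "chrom": a.chrom,
                    "start": a.start,
                    "end": a.end,
                    "probe_id": p.probe_id,
                    "percent_identity": a.percent_identity,
                    "strand": a.strand,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    if class_table is not None:
        pd.DataFrame(meta_rows).to_csv(class_table, sep="\t", index=False)


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    if "species" not in df.columns:
        df["species"] = "human"
    df["species"] = df["species"].fillna("human")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, fmt: str | None = None):
    """Read a SNP panel from a genotype TSV or an uncompressed VCF subset.

    TSV dialect: columns ``snp_id  chrom  pos`` (pos 0-based) then one column
    per sample holding allele-pair calls like ``AA``/``AG``; missing as NA.
    VCF dialect: v4.x text, GT field only; positions converted 1-based→0-based
    and calls reconstructed from REF/ALT.  Returns an
    :class:`~tandemcnv.association.SnpPanel`.
    """
    from .association import SnpPanel  # local import avoids a cycle

    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        meta, calls = _read_vcf_calls(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
        if df["snp_id"].duplicated().any():
            dupes = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValidationError(f"duplicate SNP ids: {dupes}")
        df = df.set_index("snp_id")
        meta = df[["chrom", "pos"]].copy()
        meta["pos"] = meta["pos"].astype(int)
        calls = df.drop(columns=["chrom", "pos"]).astype("string")
        calls = calls.replace(dict.fromkeys(MISSING_MARKERS, pd.NA))
    _check_position_conflicts(meta)
    return SnpPanel.from_calls(calls, meta)


def _check_position_conflicts(meta: pd.DataFrame) -> None:
    if meta.index.duplicated().any():
        conflicted = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValidationError(f"conflicting records for SNP ids: {conflicted}")


def _read_vcf_calls(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    call_rows: list[list] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            if not sample_ids:
                raise ParseError(f"{path}: VCF data before #CHROM header")
            chrom, pos, snp_id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            fmt_keys = fields[8].split(":")
            if "GT" not in fmt_keys:
                raise ParseError(f"{path}: record {snp_id} lacks a GT field")
            gt_idx = fmt_keys.index("GT")
            alleles = [ref] + ([] if alt == "." else alt.split(","))
            row = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx]
                sep = "|" if "|" in gt else "/"
                parts = gt.split(sep)
                if any(p == "." for p in parts):
                    row.append(pd.NA)
                else:
                    row.append("".join(sorted(alleles[int(p)] for p in parts)))
            meta_rows.append({"snp_id": snp_id, "chrom": chrom, "pos": int(pos) - 1})
            call_rows.append(row)
    meta = pd.DataFrame(meta_rows).set_index("snp_id")
    calls = pd.DataFrame(call_rows, index=meta.index, columns=sample_ids, dtype="string")
    return meta, calls


# ---------------------------------------------------------------------------
# generic record tables


def write_records(
    records: Sequence, path: str | Path, float_precision: int = 6, record_type=None
) -> None:
    """Write a list of dataclass records as a TSV with a stable column order.

    Missing floats serialise as ``NA``; an empty list yields a header-only
    file when ``record_type`` supplies the fields, else an empty file.
    """
    if len(records) == 0:
        if record_type is not None:
            header = "\t".join(f.name for f in dataclasses.fields(record_type))
            Path(path).write_text(header + "\n")
        else:
            Path(path).write_text("")
        return
    fields = [f.name for f in dataclasses.fields(records[0])]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=fields)
    df.to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format=f"%.{float_precision}g"
    )


def read_records(record_type, path: str | Path) -> list:
    """Inverse of :func:`write_records` for a known dataclass type."""
    df = pd.read_csv(path, sep="\t", na_values=list(MISSING_MARKERS), keep_default_na=False)
    hints = {f.name: f.type for f in dataclasses.fields(record_type)}
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in hints:
            v = row[name]
            kwargs[name] = None if pd.isna(v) else v
        out.append(record_type(**kwargs))
    return out
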