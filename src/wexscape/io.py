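"""Tab-separated readers and writers for the cohort tables.

All dialects are plain TSV with a header line; lines starting with ``#``
are ignored.  Column names can be remapped via a ``columns`` mapping so
that externally produced mutation lists with different headers are
directly consumable.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import (
    CohortDataset,
    Group,
    MutationRecord,
    RowParseError,
    SampleMeta,
    SchemaError,
    SegmentRecord,
    Subtype,
    ValidationError,
    VariantType,
    classify_variant_type,
    parse_variant_class,
    _check_segment_overlaps,
)

MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene",
    "variant_class", "alt_count", "ref_count",
]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_total", "cn_minor"]
SAMPLE_COLUMNS = ["sample_id", "group", "subtype", "age", "purity", "ploidy", "panel_size_mb"]


def _read_tsv(path, required: Sequence[str], columns: Optional[Mapping[str, str]], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required column(s): {missing}")
    return df


def _int(value, name: str, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise RowParseError(f"non-integer {name}: {value!r}", line) from None


def _float(value, name: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowParseError(f"non-numeric {name}: {value!r}", line) from None


def read_mutation_table(path, columns: Optional[Mapping[str, str]] = None) -> list[MutationRecord]:
    """Parse a MAF-like mutation TSV into :class:`MutationRecord` rows.

    ``variant_type`` is derived from allele lengths when the column is
    absent.  ``columns`` maps canonical names to the file's header names,
    e.g. ``{"gene": "Hugo_Symbol"}``.  Row order is preserved.
    """
    df = _read_tsv(path, MUTATION_COLUMNS, columns, "mutation")
    records = []
    has_vtype = "variant_type" in df.columns
    has_ctx = "context3" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        line = i
        ref, alt = str(row["ref"]), str(row["alt"])
        if has_vtype and isinstance(row["variant_type"], str) and row["variant_type"]:
            vtype = VariantType(row["variant_type"])
        else:
            vtype = classify_variant_type(ref, alt)
        ctx = None
        if has_ctx:
            raw = row["context3"]
            if isinstance(raw, str) and raw and raw != ".":
                ctx = raw.upper()
        try:
            rec = MutationRecord(
                sample_id=str(row["sample_id"]),
                chrom=str(row["chrom"]),
                pos=_int(row["pos"], "pos", line),
                ref=ref,
                alt=alt,
                gene=str(row["gene"]),
                variant_class=parse_variant_class(str(row["variant_class"])),
                variant_type=vtype,
                alt_count=_int(row["alt_count"], "alt_count", line),
                ref_count=_int(row["ref_count"], "ref_count", line),
                context3=ctx,
            )
        except ValidationError as e:
            raise RowParseError(str(e), line) from None
        records.append(rec)
    return records


def read_segment_table(path, columns: Optional[Mapping[str, str]] = None) -> list[SegmentRecord]:
    """Parse a SEG-like allele-specific copy-number TSV.

    Segments are returned sorted by (sample, chromosome, start); overlapping
    segments within a sample/chromosome raise :class:`ValidationError`.
    """
    df = _read_tsv(path, SEGMENT_COLUMNS, columns, "segment")
    has_log2r = "log2r" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        log2r = None
        if has_log2r:
            raw = row["log2r"]
            if isinstance(raw, str) and raw not in ("", "."):
                log2r = _float(raw, "log2r", i)
                if math.isnan(log2r):
                    log2r = None
        try:
            rec = SegmentRecord(
                sample_id=str(row["sample_id"]),
                chrom=str(row["chrom"]),
                start=_int(row["start"], "start", i),
                end=_int(row["end"], "end", i),
                cn_total=_int(row["cn_total"], "cn_total", i),
                cn_minor=_int(row["cn_minor"], "cn_minor", i),
                log2r=log2r,
            )
        except ValidationError as e:
            raise RowParseError(str(e), i) from None
        records.append(rec)
    records.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    _check_segment_overlaps(records)
    return records


def read_sample_sheet(path, columns: Optional[Mapping[str, str]] = None) -> list[SampleMeta]:
    """Parse the sample sheet; duplicate sample ids and unknown controlled-
    vocabulary labels are rejected."""
    df = _read_tsv(path, SAMPLE_COLUMNS, columns, "sample sheet")
    records, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r} in sample sheet")
        seen.add(sid)
        try:
            group = Group(str(row["group"]))
        except ValueError:
            raise ValidationError(
                f"unknown group {row['group']!r}; allowed: {[g.value for g in Group]}"
            ) from None
        try:
            subtype = Subtype(str(row["subtype"]))
        except ValueError:
            raise ValidationError(
                f"unknown subtype {row['subtype']!r}; allowed: {[s.value for s in Subtype]}"
            ) from None
        records.append(
            SampleMeta(
                sample_id=sid,
                group=group,
                subtype=subtype,
                age=_float(row["age"], "age", i),
                purity=_float(row["purity"], "purity", i),
                ploidy=_float(row["ploidy"], "ploidy", i),
                panel_size_mb=_float(row["panel_size_mb"], "panel_size_mb", i),
            )
        )
    return records


def read_cohort(mutation_path, segment_path, sample_path, columns=None) -> CohortDataset:
    return CohortDataset(
        mutations=read_mutation_table(mutation_path, columns=(columns or {}).get("mutations")),
        segments=read_segment_table(segment_path, columns=(columns or {}).get("segments")),
        samples=read_sample_sheet(sample_path, columns=(columns or {}).get("samples")),
    )


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in records],
            "chrom": [m.chrom for m in records],
            "pos": [m.pos for m in records],
            "ref": [m.ref for m in records],
            "alt": [m.alt for m in records],
            "gene": [m.gene for m in records],
            "variant_class": [m.variant_class.value for m in records],
            "variant_type": [m.variant_type.value for m in records],
            "alt_count": [m.alt_count for m in records],
            "ref_count": [m.ref_count for m in records],
            "context3": [m.context3 if m.context3 is not None else "." for m in records],
        }
    )


def segments_to_frame(records: Sequence[SegmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in records],
            "chrom": [s.chrom for s in records],
            "start": [s.start for s in records],
            "end": [s.end for s in records],
            "cn_total": [s.cn_total for s in records],
            "cn_minor": [s.cn_minor for s in records],
            "log2r": [s.log2r if s.log2r is not None else "." for s in records],
        }
    )


def samples_to_frame(records: Sequence[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in records],
            "group": [s.group.value for s in records],
            "subtype": [s.subtype.value for s in records],
            "age": [s.age for s in records],
            "purity": [s.purity for s in records],
            "ploidy": [s.ploidy for s in records],
            "panel_size_mb": [s.panel_size_mb for s in records],
        }
    )


def write_cohort(dataset: CohortDataset, mutation_path, segment_path, sample_path) -> None:
    """Write the three cohort tables; a write/read round trip reproduces
    identical records."""
    mutations_to_frame(dataset.mutations).to_csv(mutation_path, sep="\t", index=False)
    segments_to_frame(dataset.segments).to_csv(segment_path, sep="\t", index=False)
    samples_to_frame(dataset.samples).to_csv(sample_path, sep="\t", index=False)


def read_gene_model(path, columns: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Gene model TSV: gene, chrom, start, end (1-based closed)."""
    df = _read_tsv(path, ["gene", "chrom", "start", "end"], columns, "gene model")
    df = df.assign(start=df["start"].astype(int), end=df["end"].astype(int))
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene"].tolist()
        raise ValidationError(f"gene model start > end for: {bad}")
    return df
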