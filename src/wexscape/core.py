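"""Core domain types, genome model, and validation.

The package operates downstream of variant calling and allele-specific
copy-number estimation: its inputs are per-sample somatic mutation tables
(MAF-like TSV), allele-specific copy-number segment tables (SEG-like TSV
with integer total/minor copy numbers), and a sample sheet carrying group,
immunohistochemistry subtype, age, tumor purity, ploidy, and the size of
the sequenced coding territory.

Coordinate convention
---------------------
All on-disk formats and all in-memory records use 1-based, closed
intervals, matching MAF/SEG practice.  A segment ``[start, end]`` has
length ``end - start + 1``; abutting segments satisfy
``next.start == prev.end + 1``.  Every interval computation in the
package goes through :func:`interval_length` / :func:`interval_overlap`
so the convention lives in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger("wexscape")


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class RowParseError(ValueError):
    """A row of a table could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ValidationError(ValueError):
    """A parsed record or record set violates a domain invariant."""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SILENT = "silent"
    SPLICE = "splice"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


class VariantType(str, Enum):
    SNV = "SNV"
    INDEL = "indel"


class Group(str, Enum):
    IBC = "IBC"
    NONIBC = "nonIBC"


class Subtype(str, Enum):
    HR_POS_HER2_NEG = "HRpos_HER2neg"
    HER2_POS = "HER2pos"
    TN = "TN"


#: Synonyms for MAF-style variant classifications.  Unmapped terms fall back
#: to ``other`` with a logged warning; the table is deliberately extensible.
VARIANT_CLASS_SYNONYMS: dict[str, VariantClass] = {
    "missense": VariantClass.MISSENSE,
    "missense_mutation": VariantClass.MISSENSE,
    "nonsense": VariantClass.NONSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonstop_mutation": VariantClass.NONSENSE,
    "silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
    "splice": VariantClass.SPLICE,
    "splice_site": VariantClass.SPLICE,
    "splice_region": VariantClass.SPLICE,
    "frameshift_indel": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_del": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INDEL,
    "frameshift": VariantClass.FRAMESHIFT_INDEL,
    "inframe_indel": VariantClass.INFRAME_INDEL,
    "in_frame_del": VariantClass.INFRAME_INDEL,
    "in_frame_ins": VariantClass.INFRAME_INDEL,
    "other": VariantClass.OTHER,
}

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_variant_class(label: str) -> VariantClass:
    key = label.strip().lower()
    vc = VARIANT_CLASS_SYNONYMS.get(key)
    if vc is None:
        logger.warning("unmapped variant classification %r mapped to 'other'", label)
        return VariantClass.OTHER
    return vc


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant with read support and classification."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: VariantClass
    variant_type: VariantType
    alt_count: int
    ref_count: int
    context3: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValidationError("read counts must be nonnegative")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if (self.variant_type is VariantType.SNV) != is_snv:
            raise ValidationError(
                f"variant_type {self.variant_type.value} inconsistent with "
                f"alleles {self.ref}>{self.alt}"
            )
        if self.context3 is not None:
            ctx = self.context3
            if len(ctx) != 3 or any(b not in _DNA for b in ctx):
                raise ValidationError(f"context3 must be a 3-mer over ACGT, got {ctx!r}")
            if is_snv and ctx[1] != self.ref:
                raise ValidationError(
                    f"context3 middle base {ctx[1]} does not match ref {self.ref}"
                )

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def vaf(self) -> float:
        """Variant allele fraction, alt / (alt + ref); NaN at zero depth."""
        d = self.depth
        return self.alt_count / d if d > 0 else float("nan")


def classify_variant_type(ref: str, alt: str) -> VariantType:
    return VariantType.SNV if len(ref) == 1 and len(alt) == 1 else VariantType.INDEL


@dataclass(frozen=True)
class SegmentRecord:
    """Allele-specific copy-number segment (1-based, closed coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int
    log2r: Optional[float] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.cn_minor < 0 or self.cn_total < 0:
            raise ValidationError("copy numbers must be nonnegative")
        if self.cn_minor > self.cn_total:
            raise ValidationError(
                f"cn_minor {self.cn_minor} exceeds cn_total {self.cn_total}"
            )

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    @property
    def cn_major(self) -> int:
        return self.cn_total - self.cn_minor


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: Group
    subtype: Subtype
    age: float
    purity: float
    ploidy: float
    panel_size_mb: float

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")
        if self.panel_size_mb <= 0:
            raise ValidationError("panel_size_mb must be positive")


def interval_length(start: int, end: int) -> int:
    """Length of the 1-based closed interval [start, end]."""
    return end - start + 1


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length of two 1-based closed intervals (0 when disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


@dataclass(frozen=True)
class ChromosomeModel:
    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self):
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValidationError(
                f"chromosome {self.name}: centromere interval "
                f"({self.centromere_start}, {self.centromere_end}) must sit "
                f"strictly inside (0, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (1, self.centromere_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end + 1, self.length)


class GenomeModel:
    """Chromosome lengths and centromere intervals; arm boundaries derive
    from the centromere.  Telomere-touch tests use a configurable tolerance
    because exome-derived segments rarely reach the literal chromosome end.
    """

    def __init__(self, chromosomes: Iterable[ChromosomeModel], telomere_tol: int = 1000):
        self.chromosomes: dict[str, ChromosomeModel] = {c.name: c for c in chromosomes}
        self.telomere_tol = telomere_tol
        if not self.chromosomes:
            raise ValidationError("genome model must contain at least one chromosome")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> ChromosomeModel:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} absent from genome model") from None

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def touches_p_telomere(self, chrom: str, start: int) -> bool:
        return start <= 1 + self.telomere_tol

    def touches_q_telomere(self, chrom: str, end: int) -> bool:
        return end >= self[chrom].length - self.telomere_tol

    def spans_whole_chromosome(self, chrom: str, start: int, end: int) -> bool:
        return self.touches_p_telomere(chrom, start) and self.touches_q_telomere(chrom, end)

    def crosses_centromere(self, chrom: str, start: int, end: int) -> bool:
        c = self[chrom]
        return start <= c.centromere_start and end >= c.centromere_end


def load_genome_model(path=None, telomere_tol: int = 1000) -> GenomeModel:
    """Load a genome model TSV (chrom, length, centromere_start, centromere_end).

    Without *path*, the bundled hg19 autosome + X table is used.
    """
    import pandas as pd

    if path is None:
        src = resources.files("wexscape.data").joinpath("hg19_genome.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "length", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"genome model missing columns: {sorted(missing)}")
    chroms = [
        ChromosomeModel(
            name=str(r.chrom),
            length=int(r.length),
            centromere_start=int(r.centromere_start),
            centromere_end=int(r.centromere_end),
        )
        for r in df.itertuples()
    ]
    return GenomeModel(chroms, telomere_tol=telomere_tol)


@dataclass
class CohortDataset:
    """A validated cohort: mutations + segments + sample sheet."""

    mutations: list[MutationRecord]
    segments: list[SegmentRecord]
    samples: list[SampleMeta]
    _by_sample: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        known = {s.sample_id for s in self.samples}
        if len(known) != len(self.samples):
            raise ValidationError("duplicate sample_id in sample sheet")
        for m in self.mutations:
            if m.sample_id not in known:
                raise ValidationError(
                    f"mutation sample {m.sample_id!r} absent from sample sheet"
                )
        for s in self.segments:
            if s.sample_id not in known:
                raise ValidationError(
                    f"segment sample {s.sample_id!r} absent from sample sheet"
                )
        _check_segment_overlaps(self.segments)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        if not self._by_sample:
            self._by_sample = {s.sample_id: s for s in self.samples}
        return self._by_sample[sample_id]

    def mutations_of(self, sample_id: str) -> list[MutationRecord]:
        return [m for m in self.mutations if m.sample_id == sample_id]

    def segments_of(self, sample_id: str) -> list[SegmentRecord]:
        return sorted(
            (s for s in self.segments if s.sample_id == sample_id),
            key=lambda s: (s.chrom, s.start),
        )

    def groups(self) -> dict[Group, list[str]]:
        out: dict[Group, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out


def _check_segment_overlaps(segments: Sequence[SegmentRecord]) -> None:
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    offenders = []
    for (sample_id, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                offenders.append((sample_id, chrom, (prev.start, prev.end), (cur.start, cur.end)))
    if offenders:
        desc = "; ".join(
            f"{sid}:{chrom} {a} overlaps {b}" for sid, chrom, a, b in offenders[:10]
        )
        raise ValidationError(f"overlapping segments: {desc}")


class ContextUnavailable(Exception):
    """Trinucleotide context cannot be derived (chromosome edge / no source)."""


def trinucleotide_context(chrom: str, pos: int, reference_source) -> str:
    """Forward-strand upper-case 3-mer centered on ``pos`` (1-based).

    ``reference_source`` is any mapping-like object whose ``__getitem__``
    returns an indexable sequence per chromosome — a ``pyfaidx.Fasta``, a
    ``dict`` of strings, or a Biopython ``SeqRecord`` dict all work.
    Positions at a chromosome edge raise :class:`ContextUnavailable`.
    """
    try:
        seq = reference_source[chrom]
    except (KeyError, IndexError):
        raise ContextUnavailable(f"chromosome {chrom!r} not in reference")
    if pos < 2:
        raise ContextUnavailable(f"{chrom}:{pos} at chromosome edge")
    try:
        ctx = str(seq[pos - 2 : pos + 1]).upper()
    except IndexError:
        raise ContextUnavailable(f"{chrom}:{pos} beyond chromosome end")
    if len(ctx) != 3:
        raise ContextUnavailable(f"{chrom}:{pos} at chromosome edge")
    if any(b not in _DNA for b in ctx):
        raise ContextUnavailable(f"{chrom}:{pos} non-ACGT context {ctx!r}")
    return ctx
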