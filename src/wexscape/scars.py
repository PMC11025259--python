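"""Genomic-scar HRD scoring and gene-level copy-number calls.

Three genomic-instability measures are counted from smoothed
allele-specific copy-number segments:

* **LOH** — segments with minor copy number 0 (and total copy number at
  least 1) longer than 15 Mb that do not span the whole chromosome;
* **TAI** — allelically imbalanced segments (major != minor copy number)
  that reach a telomere without crossing the centromere, at least 11 Mb
  long by default;
* **LST** — per chromosome arm, breakpoints between adjacent segments of
  different copy-number state where both flanks are at least 10 Mb and
  the gap between them is under 3 Mb, counted after 3 Mb smoothing.

The HRD score is the plain sum LOH + TAI + LST; a profile is HRD-high
when the score reaches 42.  All size thresholds are keyword parameters
with these literature defaults.

Gene-level calls assign each gene the log2 ratio of its maximally
overlapping segment and threshold it at ±0.2 (gain/loss) and ±0.9
(amplification/deletion); comparisons are strict, so a log2 ratio of
exactly 0.2 is neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomeModel,
    SegmentRecord,
    ValidationError,
    interval_length,
    interval_overlap,
)

MB = 1_000_000

LOH_MIN_BP = 15 * MB          # LOH segments must exceed this length
TAI_MIN_BP = 11 * MB          # minimum telomeric-imbalance segment size
LST_MIN_FLANK_BP = 10 * MB    # both flanks of an LST breakpoint
LST_MAX_GAP_BP = 3 * MB       # maximum gap between LST flanks
SMOOTH_MIN_BP = 3 * MB        # segments below this are dropped pre-scoring
HRD_HIGH_CUTOFF = 42          # inclusive


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    n_loh: int
    n_tai: int
    n_lst: int

    def __post_init__(self):
        if min(self.n_loh, self.n_tai, self.n_lst) < 0:
            raise ValidationError("scar counts must be nonnegative")

    @property
    def hrd_score(self) -> int:
        return self.n_loh + self.n_tai + self.n_lst

    @property
    def hrd_high(self) -> bool:
        return self.hrd_score >= HRD_HIGH_CUTOFF


def _merge_equal_adjacent(
    segments: list[SegmentRecord], max_gap_bp: int = SMOOTH_MIN_BP
) -> list[SegmentRecord]:
    """Merge near-adjacent segments with identical (cn_total, cn_minor).

    Gaps up to ``max_gap_bp`` are bridged: this re-joins flanks around a
    removed sub-3 Mb segment and re-joins arm pieces across the 3 Mb
    centromere gap of the bundled genome model, while leaving genuinely
    separate events (separated by larger segment-free gaps) distinct.
    """
    out: list[SegmentRecord] = []
    for seg in segments:
        if (
            out
            and out[-1].chrom == seg.chrom
            and (out[-1].cn_total, out[-1].cn_minor) == (seg.cn_total, seg.cn_minor)
            and seg.start - out[-1].end - 1 <= max_gap_bp
        ):
            prev = out.pop()
            seg = SegmentRecord(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                start=prev.start,
                end=seg.end,
                cn_total=prev.cn_total,
                cn_minor=prev.cn_minor,
                log2r=prev.log2r,
            )
        out.append(seg)
    return out


def preprocess_segments(
    segments: Sequence[SegmentRecord],
    genome: GenomeModel,
    min_size_bp: int = SMOOTH_MIN_BP,
) -> list[SegmentRecord]:
    """Smooth one sample's segments for scar scoring.

    Segments shorter than ``min_size_bp`` are discarded, flanking segments
    with identical copy-number state are merged, and segments spanning the
    centromere are split into arm-local pieces.  Input must be sorted and
    non-overlapping; a segment extending beyond its chromosome raises.
    """
    segs = sorted(segments, key=lambda s: (s.chrom, s.start))
    for s in segs:
        if s.end > genome[s.chrom].length:
            raise ValidationError(
                f"segment {s.chrom}:{s.start}-{s.end} crosses chromosome boundary "
                f"(length {genome[s.chrom].length})"
            )
    segs = [s for s in segs if s.length >= min_size_bp]
    segs = _merge_equal_adjacent(segs)
    out: list[SegmentRecord] = []
    for s in segs:
        c = genome[s.chrom]
        if s.start <= c.centromere_start and s.end >= c.centromere_end:
            for a, b in ((s.start, c.centromere_start), (c.centromere_end + 1, s.end)):
                out.append(
                    SegmentRecord(
                        sample_id=s.sample_id, chrom=s.chrom, start=a, end=b,
                        cn_total=s.cn_total, cn_minor=s.cn_minor, log2r=s.log2r,
                    )
                )
        else:
            out.append(s)
    return out


def count_hrd_loh(
    segments: Sequence[SegmentRecord],
    genome: GenomeModel,
    min_size_bp: int = LOH_MIN_BP,
) -> int:
    """LOH events: minor copy 0, total >= 1, length > ``min_size_bp``,
    excluding whole-chromosome LOH.

    The centromere split applied by :func:`preprocess_segments` is undone
    here (arm pieces with identical state are re-joined) so that both the
    length rule and the whole-chromosome exclusion see the true event.
    """
    merged = _merge_equal_adjacent(sorted(segments, key=lambda s: (s.chrom, s.start)))
    n = 0
    for s in merged:
        if s.cn_minor != 0 or s.cn_total < 1:
            continue
        if s.length <= min_size_bp:
            continue
        if genome.spans_whole_chromosome(s.chrom, s.start, s.end):
            continue
        n += 1
    return n


def count_tai(
    segments: Sequence[SegmentRecord],
    genome: GenomeModel,
    min_size_bp: int = TAI_MIN_BP,
) -> int:
    """Telomeric allelic-imbalance events: major != minor copy number,
    touching a telomere, not crossing the centromere, length >=
    ``min_size_bp``.  Arm pieces split at the centromere are re-joined
    first so a cross-centromere event is correctly disqualified."""
    merged = _merge_equal_adjacent(sorted(segments, key=lambda s: (s.chrom, s.start)))
    n = 0
    for s in merged:
        if s.cn_major == s.cn_minor:
            continue
        if s.length < min_size_bp:
            continue
        if genome.crosses_centromere(s.chrom, s.start, s.end):
            continue
        if genome.touches_p_telomere(s.chrom, s.start) or genome.touches_q_telomere(s.chrom, s.end):
            n += 1
    return n


def count_lst(
    segments: Sequence[SegmentRecord],
    genome: GenomeModel,
    min_flank_bp: int = LST_MIN_FLANK_BP,
    max_gap_bp: int = LST_MAX_GAP_BP,
) -> int:
    """Large-scale state transitions, counted per chromosome arm."""
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        by_chrom.setdefault(s.chrom, []).append(s)
    n = 0
    for chrom, segs in by_chrom.items():
        c = genome[chrom]
        for arm_start, arm_end in (c.p_arm, c.q_arm):
            arm = [s for s in segs if interval_overlap(s.start, s.end, arm_start, arm_end) > 0]
            for prev, cur in zip(arm, arm[1:]):
                if (prev.cn_total, prev.cn_minor) == (cur.cn_total, cur.cn_minor):
                    continue
                if prev.length < min_flank_bp or cur.length < min_flank_bp:
                    continue
                gap = cur.start - prev.end - 1
                if gap >= max_gap_bp:
                    continue
                n += 1
    return n


def hrd_score(n_loh: int, n_tai: int, n_lst: int, sample_id: str = "") -> ScarScores:
    return ScarScores(sample_id=sample_id, n_loh=n_loh, n_tai=n_tai, n_lst=n_lst)


def score_sample(
    segments: Sequence[SegmentRecord],
    genome: GenomeModel,
    sample_id: Optional[str] = None,
    loh_min_bp: int = LOH_MIN_BP,
    tai_min_bp: int = TAI_MIN_BP,
    lst_min_flank_bp: int = LST_MIN_FLANK_BP,
) -> ScarScores:
    """Preprocess one sample's segments and count all three scar types."""
    sid = sample_id or (segments[0].sample_id if segments else "")
    pre = preprocess_segments(segments, genome)
    return ScarScores(
        sample_id=sid,
        n_loh=count_hrd_loh(pre, genome, min_size_bp=loh_min_bp),
        n_tai=count_tai(pre, genome, min_size_bp=tai_min_bp),
        n_lst=count_lst(pre, genome, min_flank_bp=lst_min_flank_bp),
    )


def scar_table(dataset, genome: GenomeModel) -> pd.DataFrame:
    """Scar scores for every sample of a cohort, as a DataFrame."""
    rows = []
    for s in dataset.samples:
        sc = score_sample(dataset.segments_of(s.sample_id), genome, sample_id=s.sample_id)
        rows.append(
            {
                "sample_id": sc.sample_id,
                "group": s.group.value,
                "subtype": s.subtype.value,
                "n_loh": sc.n_loh,
                "n_tai": sc.n_tai,
                "n_lst": sc.n_lst,
                "hrd_score": sc.hrd_score,
                "hrd_high": sc.hrd_high,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Gene-level copy-number calls


class CnaCall(str, Enum):
    AMPLIFICATION = "amplification"
    GAIN = "gain"
    NEUTRAL = "neutral"
    LOSS = "loss"
    DELETION = "deletion"


@dataclass(frozen=True)
class GeneCnaCall:
    sample_id: str
    gene: str
    value: float  # log2 ratio
    call: CnaCall
    missing: bool = False  # no overlapping segment; neutral by convention


def classify_log2r(
    log2r: float, gain_cut: float = 0.2, amp_cut: float = 0.9
) -> CnaCall:
    """Threshold a log2 ratio; all comparisons strict."""
    if log2r > amp_cut:
        return CnaCall.AMPLIFICATION
    if log2r > gain_cut:
        return CnaCall.GAIN
    if log2r < -amp_cut:
        return CnaCall.DELETION
    if log2r < -gain_cut:
        return CnaCall.LOSS
    return CnaCall.NEUTRAL


def _segment_log2r(seg: SegmentRecord) -> float:
    if seg.log2r is not None:
        return seg.log2r
    # Derive from total copy number vs diploid; floor at CN 0.5 to keep
    # homozygous deletions finite (log2(0.25) = -2, safely past -0.9).
    return math.log2(max(seg.cn_total, 0.5) / 2.0)


def gene_cna_call(
    segments: Sequence[SegmentRecord],
    gene_model: pd.DataFrame,
    sample_id: Optional[str] = None,
    gain_cut: float = 0.2,
    amp_cut: float = 0.9,
) -> list[GeneCnaCall]:
    """One call per gene: log2 ratio of the maximally overlapping segment
    (ties broken toward larger \\|log2r\\|), thresholded at ±gain/amp cuts.
    Genes with no overlapping segment are neutral with ``missing=True``."""
    sid = sample_id or (segments[0].sample_id if segments else "")
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    calls = []
    for row in gene_model.itertuples():
        best: Optional[tuple[int, float]] = None  # (overlap, |log2r|)
        best_val = 0.0
        for seg in by_chrom.get(str(row.chrom), []):
            ov = interval_overlap(seg.start, seg.end, int(row.start), int(row.end))
            if ov <= 0:
                continue
            val = _segment_log2r(seg)
            key = (ov, abs(val))
            if best is None or key > best:
                best = key
                best_val = val
        if best is None:
            calls.append(GeneCnaCall(sid, str(row.gene), 0.0, CnaCall.NEUTRAL, missing=True))
        else:
            calls.append(
                GeneCnaCall(sid, str(row.gene), best_val, classify_log2r(best_val, gain_cut, amp_cut))
            )
    return calls


def load_gene_model() -> pd.DataFrame:
    """Bundled compact hg19 gene model for CNA calls."""
    from .io import read_gene_model

    src = resources.files("wexscape.data").joinpath("gene_model_hg19.tsv")
    with resources.as_file(src) as p:
        return read_gene_model(p)


def cna_call_table(dataset, gene_model: pd.DataFrame, **kwargs) -> pd.DataFrame:
    rows = []
    for s in dataset.samples:
        for call in gene_cna_call(
            dataset.segments_of(s.sample_id), gene_model, sample_id=s.sample_id, **kwargs
        ):
            rows.append(
                {
                    "sample_id": call.sample_id,
                    "group": s.group.value,
                    "gene": call.gene,
                    "log2r": call.value,
                    "call": call.call.value,
                    "missing": call.missing,
                }
            )
    return pd.DataFrame(rows)


def cna_frequency_profile(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-group alteration frequencies (percent, in [0, 100]).

    ``calls`` is the output of :func:`cna_call_table`.  For each gene and
    group the fraction of samples with gain-or-amplification and with
    loss-or-deletion is reported, plus the underlying counts, ready for a
    per-gene Fisher test family.
    """
    gained = {CnaCall.GAIN.value, CnaCall.AMPLIFICATION.value}
    lost = {CnaCall.LOSS.value, CnaCall.DELETION.value}
    rows = []
    for gene, sub in calls.groupby("gene", sort=True):
        row: dict = {"gene": gene}
        for grp, gsub in sub.groupby("group", sort=True):
            n = gsub["sample_id"].nunique()
            n_gain = gsub.loc[gsub["call"].isin(gained), "sample_id"].nunique()
            n_loss = gsub.loc[gsub["call"].isin(lost), "sample_id"].nunique()
            row[f"n_total_{grp}"] = n
            row[f"n_gain_{grp}"] = n_gain
            row[f"n_loss_{grp}"] = n_loss
            row[f"pct_gain_{grp}"] = 100.0 * n_gain / n if n else np.nan
            row[f"pct_loss_{grp}"] = 100.0 * n_loss / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
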