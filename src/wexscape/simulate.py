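"""Synthetic cohort generator with known ground truth.

Every statistical structure the analysis stages assume is emulated so
that each stage is testable by parameter recovery:

* per-sample mutation counts follow a negative binomial (long right
  tail, as real exomes show);
* trinucleotide contexts and substitutions are sampled directly from a
  mixture of reference signature profiles (contexts are emitted in the
  mutation table, so no genome FASTA is needed);
* each mutation belongs to a clonal cluster with a known cancer cell
  fraction; read counts are binomial at the expected VAF given purity,
  local copy number and sequencing depth;
* segment profiles are constructed to contain exactly a requested number
  of qualifying LOH / TAI / LST events (built from the written scar
  definitions, independently of the scoring code), plus diploid filler;
* focal amplifications/deletions (e.g. an ERBB2 amplicon in HER2+
  samples) are carved into the filler below the scar-smoothing size so
  they drive gene-level CNA calls without perturbing scar counts;
* group and subtype effects (signature-mixture shifts, a triple-negative
  scar-burden shift, clonal-architecture differences) are configurable
  effect sizes.

All randomness flows from a single mandatory seed; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CohortDataset,
    GenomeModel,
    Group,
    MutationRecord,
    SampleMeta,
    SegmentRecord,
    Subtype,
    ValidationError,
    VariantClass,
    VariantType,
    load_genome_model,
    revcomp,
)
from .spectra import SBS96_LABELS, SignatureMatrix, load_reference_signatures

MB = 1_000_000

# Variant-classification mix: ~94 % SNVs / 6 % indels, ~25 % silent.
CLASS_MIX = [
    (VariantClass.MISSENSE, 0.625),
    (VariantClass.SILENT, 0.250),
    (VariantClass.NONSENSE, 0.035),
    (VariantClass.SPLICE, 0.030),
    (VariantClass.FRAMESHIFT_INDEL, 0.045),
    (VariantClass.INFRAME_INDEL, 0.015),
]
INDEL_CLASSES = {VariantClass.FRAMESHIFT_INDEL, VariantClass.INFRAME_INDEL}

#: Recurrent-gene draw weights; a ``GENE:p.X`` entry carries its hotspot
#: protein change into the table for actionability matching.
RECURRENT_GENES = {
    "TP53": 0.0125,
    "PIK3CA:p.H1047R": 0.0020,
    "PIK3CA:p.E545K": 0.0012,
    "PIK3CA": 0.0010,
    "KMT2C": 0.0060,
    "GATA3": 0.0040,
    "MAP2K4": 0.0030,
    "AKT1:p.E17K": 0.0004,
    "BRCA1": 0.0012,
    "BRCA2": 0.0012,
    "ESR1:p.D538G": 0.0004,
    "ARID1A": 0.0030,
    "CDH1": 0.0030,
}
N_BACKGROUND_GENES = 400

#: Clonal-architecture archetypes: (cluster CCFs with proportions).
ARCHETYPES: dict[str, list[tuple[float, float]]] = {
    "monoclonal": [(1.0, 1.0)],
    "biclonal": [(1.0, 0.6), (0.4, 0.4)],
    "triclonal": [(1.0, 1 / 3), (0.6, 1 / 3), (0.3, 1 / 3)],
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a two-cohort breast-cancer exome study: 24 samples
    per group split evenly over three molecular subtypes, a long-tailed
    mutation count (median near 60), ~100x depth, purity 0.5–0.9, a
    50 Mb coding territory, signature mixtures dominated by age-related
    and APOBEC-like processes (the age-related share higher in the
    comparator group), a higher scar burden in triple-negative samples,
    and a larger share of polyclonal architectures in the comparator
    group.
    """

    seed: int
    n_per_cell: dict = dc_field(default_factory=lambda: {
        (Group.IBC, Subtype.HR_POS_HER2_NEG): 8,
        (Group.IBC, Subtype.HER2_POS): 8,
        (Group.IBC, Subtype.TN): 8,
        (Group.NONIBC, Subtype.HR_POS_HER2_NEG): 8,
        (Group.NONIBC, Subtype.HER2_POS): 8,
        (Group.NONIBC, Subtype.TN): 8,
    })
    mutation_mean: float = 90.0
    mutation_dispersion: float = 1.3
    depth_mean: float = 100.0
    purity_range: tuple[float, float] = (0.5, 0.9)
    panel_size_mb: float = 50.0
    age_mean: dict = dc_field(default_factory=lambda: {Group.IBC: 52.0, Group.NONIBC: 58.0})
    age_sd: float = 9.0
    signature_mixture: dict = dc_field(default_factory=lambda: {
        Group.IBC: {"Signature_1": 0.30, "Signature_2": 0.16, "Signature_13": 0.15,
                    "Signature_3": 0.24, "Signature_6": 0.10, "Signature_10": 0.05},
        Group.NONIBC: {"Signature_1": 0.40, "Signature_2": 0.12, "Signature_13": 0.12,
                       "Signature_3": 0.22, "Signature_6": 0.09, "Signature_10": 0.05},
    })
    #: optional extra profile mixed in at the given weight (novel-signature tests)
    novel_profile: Optional[np.ndarray] = None
    novel_weight: float = 0.0
    archetype_weights: dict = dc_field(default_factory=lambda: {
        Group.IBC: {"monoclonal": 0.50, "biclonal": 0.30, "triclonal": 0.20},
        Group.NONIBC: {"monoclonal": 0.35, "biclonal": 0.32, "triclonal": 0.33},
    })
    #: Poisson means of (LOH, TAI, LST) event counts per subtype
    scar_means: dict = dc_field(default_factory=lambda: {
        Subtype.HR_POS_HER2_NEG: (7.0, 7.0, 7.0),
        Subtype.HER2_POS: (8.0, 8.0, 8.0),
        Subtype.TN: (13.0, 13.0, 13.0),
    })
    #: additive shift of each TN scar mean in the case (IBC) group
    tn_ibc_scar_shift: float = 2.0
    #: per-sample probabilities of focal CNA events
    focal_probs: dict = dc_field(default_factory=lambda: {
        "ERBB2_amp_her2pos": 0.85,
        "ERBB2_amp_other": 0.03,
        "PTEN_del": 0.06,
        "BRCA1_del": 0.03,
    })

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("SimConfig.seed is mandatory")
        for grp, mix in self.signature_mixture.items():
            total = sum(mix.values()) + (self.novel_weight if self.novel_profile is not None else 0)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValidationError(f"signature mixture for {grp} sums to {total}, expected 1")
        for grp, w in self.archetype_weights.items():
            if not np.isclose(sum(w.values()), 1.0, atol=1e-6):
                raise ValidationError(f"archetype weights for {grp} must sum to 1")


@dataclass
class GroundTruth:
    signature_weights: dict = dc_field(default_factory=dict)   # sid -> pd.Series
    clusters: dict = dc_field(default_factory=dict)            # sid -> [(ccf, prop)]
    heterogeneous: dict = dc_field(default_factory=dict)       # sid -> bool
    clonality: dict = dc_field(default_factory=dict)           # (sid, chrom, pos) -> label
    scar_counts: dict = dc_field(default_factory=dict)         # sid -> (loh, tai, lst)


def novel_signature_profile(seed: int = 7, sparsity: float = 0.05) -> np.ndarray:
    """A random sparse simplex profile, distinct from the bundled catalog;
    used to plant signatures that should stay unassigned when matched."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(96, sparsity))


# ---------------------------------------------------------------------------
# Segment construction

_EVENT_GAP = 4 * MB      # isolation gap so no accidental LST pairs (>= 3 Mb)
_TELO_MARGIN = 2 * MB    # interior events keep clear of telomere tolerance
#: chromosomes kept free of scar events so focal CNAs can be carved there
_FOCAL_CHROMS = {"chr10", "chr17"}

FOCAL_EVENTS = {
    # name: (chrom, start, end, cn_total, cn_minor); all < 3 Mb
    "ERBB2_amp": ("chr17", 37_000_000, 39_400_000, 12, 1),
    "PTEN_del": ("chr10", 88_900_000, 90_700_000, 0, 0),
    "BRCA1_del": ("chr17", 40_500_000, 42_300_000, 0, 0),
}


def _arm_list(genome: GenomeModel, exclude: set[str]) -> list[dict]:
    arms = []
    for name in genome.names():
        if name in exclude:
            continue
        c = genome[name]
        arms.append({"chrom": name, "lo": 1, "hi": c.centromere_start, "telo": "lo"})
        arms.append({"chrom": name, "lo": c.centromere_end + 1, "hi": c.length, "telo": "hi"})
    arms.sort(key=lambda a: a["hi"] - a["lo"], reverse=True)
    return arms


def simulate_segments(
    scar_targets: tuple[int, int, int],
    genome: GenomeModel,
    rng: np.random.Generator,
    sample_id: str,
    focal: Sequence[str] = (),
) -> list[SegmentRecord]:
    """Build a segment profile containing exactly the requested number of
    qualifying LOH, TAI and LST events plus (2,1) diploid filler.

    Events are constructed from the written scar definitions: LOH as an
    interstitial (1,0) segment of 20 Mb; TAI as a telomeric (3,1)
    segment of 12 Mb not crossing the centromere; LST as an abutting
    (2,1)|(3,1) pair of 12 Mb flanks.  Every event is isolated by >= 4 Mb
    segment-free gaps so no unintended breakpoint or telomeric contact
    arises.  Raises when more events are requested than the genome can
    host.
    """
    k_loh, k_tai, k_lst = scar_targets
    if min(scar_targets) < 0:
        raise ValidationError("scar targets must be nonnegative")
    arms = _arm_list(genome, _FOCAL_CHROMS)
    # Each arm: free interval [cur, hi_free]; telomeric end reserved unless
    # a TAI event claims it.
    placements: dict[int, list[tuple[int, int, int, int]]] = {i: [] for i in range(len(arms))}
    free: list[list[int]] = []
    for a in arms:
        lo, hi = a["lo"], a["hi"]
        if a["telo"] == "lo":
            free.append([lo + _TELO_MARGIN, hi])
        else:
            free.append([lo, hi - _TELO_MARGIN])

    tai_size = 12 * MB
    order = rng.permutation(len(arms))
    # TAI events claim the telomeric end of a fresh arm each.
    tai_arms = []
    for i in order:
        if len(tai_arms) == k_tai:
            break
        a = arms[i]
        if (a["hi"] - a["lo"] + 1) >= tai_size + _EVENT_GAP + 5 * MB:
            tai_arms.append(i)
    if len(tai_arms) < k_tai:
        raise ValidationError(f"cannot place {k_tai} TAI events on this genome")
    for i in tai_arms:
        a = arms[i]
        if a["telo"] == "lo":
            seg = (a["lo"], a["lo"] + tai_size - 1, 3, 1)
            free[i][0] = seg[1] + 1 + _EVENT_GAP
        else:
            seg = (a["hi"] - tai_size + 1, a["hi"], 3, 1)
            free[i][1] = seg[0] - 1 - _EVENT_GAP
        placements[i].append(seg)

    def place_interior(size: int, states: list[tuple[int, int]]) -> None:
        """Place abutting segments totalling `size` in the first arm with room."""
        for i in range(len(arms)):
            lo, hi = free[i]
            if hi - lo + 1 >= size + _EVENT_GAP:
                start = lo
                cursor = start
                for length, (cnt, cnm) in states:
                    placements[i].append((cursor, cursor + length - 1, cnt, cnm))
                    cursor += length
                free[i][0] = cursor + _EVENT_GAP
                return
        raise ValidationError("more scar events requested than placeable on this genome")

    loh_size = 20 * MB
    lst_flank = 12 * MB
    for _ in range(k_loh):
        place_interior(loh_size, [(loh_size, (1, 0))])
    for _ in range(k_lst):
        place_interior(2 * lst_flank, [(lst_flank, (2, 1)), (lst_flank, (3, 1))])

    # Diploid filler over the remaining space of every arm (including the
    # focal chromosomes), keeping the isolation gaps segment-free.
    segments: list[SegmentRecord] = []
    for i, a in enumerate(arms):
        intervals = sorted(placements[i])
        for s, e, cnt, cnm in intervals:
            segments.append(SegmentRecord(sample_id, a["chrom"], s, e, cnt, cnm))
        # fill gaps between [arm lo, arm hi] around events with margin
        occupied = [(s - _EVENT_GAP, e + _EVENT_GAP) for s, e, _, _ in intervals]
        cursor = a["lo"]
        for s, e in sorted(occupied) + [(a["hi"] + 1, a["hi"] + 1)]:
            if s - cursor >= 5 * MB:
                segments.append(SegmentRecord(sample_id, a["chrom"], cursor, s - 1, 2, 1))
            cursor = max(cursor, e + 1)
    for name in sorted(_FOCAL_CHROMS):
        c = genome[name]
        segments.append(SegmentRecord(sample_id, name, 1, c.centromere_start, 2, 1))
        segments.append(SegmentRecord(sample_id, name, c.centromere_end + 1, c.length, 2, 1))

    # Carve focal events into their host filler segment.
    for fname in focal:
        chrom, fs, fe, cnt, cnm = FOCAL_EVENTS[fname]
        host_idx = next(
            (j for j, s in enumerate(segments)
             if s.chrom == chrom and s.start <= fs and s.end >= fe and (s.cn_total, s.cn_minor) == (2, 1)),
            None,
        )
        if host_idx is None:
            raise ValidationError(f"no diploid host segment for focal event {fname}")
        host = segments.pop(host_idx)
        pieces = [
            (host.start, fs - 1, 2, 1),
            (fs, fe, cnt, cnm),
            (fe + 1, host.end, 2, 1),
        ]
        for s, e, ct, cm in pieces:
            if e >= s:
                segments.append(SegmentRecord(sample_id, chrom, s, e, ct, cm))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


# ---------------------------------------------------------------------------
# Mutation construction


def _decode_channel(idx: int) -> tuple[str, str, str]:
    """Channel index -> (ref, alt, pyrimidine-strand context)."""
    label = SBS96_LABELS[idx]
    five, sub, three = label[0], label[2:5], label[6]
    ref, alt = sub[0], sub[2]
    return ref, alt, f"{five}{ref}{three}"


def simulate_sample_mutations(
    signature_weights: pd.Series,
    n_mutations: int,
    clusters: list[tuple[float, float]],
    purity: float,
    depth_mean: float,
    rng: np.random.Generator,
    sample_id: str,
    reference: SignatureMatrix,
    diploid_regions: list[tuple[str, int, int]],
    novel_profile: Optional[np.ndarray] = None,
    novel_weight: float = 0.0,
) -> tuple[list[MutationRecord], list[str]]:
    """Emit one sample's mutations with true clonality labels.

    Substitution channels are drawn from the mixed signature profile;
    each mutation is assigned a cluster CCF, placed uniformly in a
    copy-number-neutral region, and its alt count drawn as
    Binomial(depth, CCF * purity * m / (purity*2 + 2*(1-purity))) with
    m = 1.  The truth label is Clonal for CCF >= 0.95.
    """
    name_to_idx = {n: i for i, n in enumerate(reference.names)}
    profile = np.zeros(96)
    for name, w in signature_weights.items():
        profile += w * reference.profiles[name_to_idx[name]]
    if novel_profile is not None and novel_weight > 0:
        profile += novel_weight * np.asarray(novel_profile)
    profile = profile / profile.sum()

    ccfs = np.array([c for c, _ in clusters])
    props = np.array([p for _, p in clusters])
    if not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ValidationError("cluster proportions must sum to 1")
    denom = purity * 2 + 2 * (1 - purity)  # = 2: diploid loci
    evafs = ccfs * purity * 1 / denom
    if (evafs > 1).any():
        raise ValidationError("expected VAF above 1; infeasible configuration")

    region_lens = np.array([e - s + 1 for _, s, e in diploid_regions], dtype=float)
    region_p = region_lens / region_lens.sum()
    class_labels = [c for c, _ in CLASS_MIX]
    class_p = np.array([w for _, w in CLASS_MIX])
    class_p = class_p / class_p.sum()
    gene_names = list(RECURRENT_GENES) + [f"GENE{i:03d}" for i in range(N_BACKGROUND_GENES)]
    rec_w = np.array(list(RECURRENT_GENES.values()))
    gene_p = np.concatenate([rec_w, np.full(N_BACKGROUND_GENES, (1 - rec_w.sum()) / N_BACKGROUND_GENES)])

    records: list[MutationRecord] = []
    labels: list[str] = []
    used_pos: set[tuple[str, int]] = set()
    for _ in range(n_mutations):
        ci = rng.choice(len(ccfs), p=props)
        ccf = float(ccfs[ci])
        depth = max(1, int(rng.poisson(depth_mean)))
        alt = int(rng.binomial(depth, evafs[ci]))
        ref_reads = depth - alt
        ri = rng.choice(len(diploid_regions), p=region_p)
        chrom, rs, re_ = diploid_regions[ri]
        for _try in range(100):
            pos = int(rng.integers(rs, re_ + 1))
            if (chrom, pos) not in used_pos:
                break
        used_pos.add((chrom, pos))
        vclass = class_labels[rng.choice(len(class_labels), p=class_p)]
        gene = gene_names[rng.choice(len(gene_names), p=gene_p)]
        if vclass in INDEL_CLASSES:
            base = "ACGT"[rng.integers(0, 4)]
            ins = rng.random() < 0.5
            if ins:
                ref_allele, alt_allele = base, base + "ACGT"[rng.integers(0, 4)]
            else:
                ref_allele, alt_allele = base + "ACGT"[rng.integers(0, 4)], base
            ctx = None
            vtype = VariantType.INDEL
        else:
            channel = int(rng.choice(96, p=profile))
            pref, palt, pctx = _decode_channel(channel)
            if rng.random() < 0.5:  # emit on the purine strand
                ref_allele, alt_allele, ctx = revcomp(pref), revcomp(palt), revcomp(pctx)
            else:
                ref_allele, alt_allele, ctx = pref, palt, pctx
            vtype = VariantType.SNV
        records.append(
            MutationRecord(
                sample_id=sample_id, chrom=chrom, pos=pos,
                ref=ref_allele, alt=alt_allele, gene=gene,
                variant_class=vclass, variant_type=vtype,
                alt_count=alt, ref_count=ref_reads, context3=ctx,
            )
        )
        labels.append("Clonal" if ccf >= 0.95 else "Subclonal")
    return records, labels


# ---------------------------------------------------------------------------
# Cohort assembly


def simulate_cohort(
    config: SimConfig,
    genome: Optional[GenomeModel] = None,
    reference: Optional[SignatureMatrix] = None,
) -> tuple[CohortDataset, GroundTruth]:
    """Deterministically generate a full cohort from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome = genome or load_genome_model()
    reference = reference or load_reference_signatures()
    truth = GroundTruth()
    mutations: list[MutationRecord] = []
    segments: list[SegmentRecord] = []
    samples: list[SampleMeta] = []

    arch_names = list(ARCHETYPES)
    for (group, subtype) in sorted(config.n_per_cell, key=lambda k: (k[0].value, k[1].value)):
        n = config.n_per_cell[(group, subtype)]
        for i in range(n):
            sid = f"{group.value}_{subtype.value}_{i + 1:03d}"
            purity = float(rng.uniform(*config.purity_range))
            age = float(np.clip(rng.normal(config.age_mean[group], config.age_sd), 25, 90))
            meta = SampleMeta(
                sample_id=sid, group=group, subtype=subtype, age=age,
                purity=purity, ploidy=2.0, panel_size_mb=config.panel_size_mb,
            )
            samples.append(meta)

            # --- segments / scars
            means = np.array(config.scar_means[subtype], dtype=float)
            if subtype is Subtype.TN and group is Group.IBC:
                means = means + config.tn_ibc_scar_shift
            targets = tuple(int(rng.poisson(m)) for m in means)
            focal = []
            p_amp = (
                config.focal_probs["ERBB2_amp_her2pos"]
                if subtype is Subtype.HER2_POS
                else config.focal_probs["ERBB2_amp_other"]
            )
            if rng.random() < p_amp:
                focal.append("ERBB2_amp")
            if rng.random() < config.focal_probs["PTEN_del"]:
                focal.append("PTEN_del")
            if "ERBB2_amp" not in focal and rng.random() < config.focal_probs["BRCA1_del"]:
                focal.append("BRCA1_del")
            segs = simulate_segments(targets, genome, rng, sid, focal=focal)
            segments.extend(segs)
            truth.scar_counts[sid] = targets

            # --- clonal architecture
            weights = config.archetype_weights[group]
            arch = arch_names[rng.choice(len(arch_names), p=[weights[a] for a in arch_names])]
            clusters = ARCHETYPES[arch]
            props = np.array([p for _, p in clusters])
            from .clonality import shannon_index

            truth.clusters[sid] = clusters
            truth.heterogeneous[sid] = shannon_index(props) > 1.0

            # --- mutations
            sig_mix = pd.Series(config.signature_mixture[group], dtype=float)
            truth.signature_weights[sid] = sig_mix
            r = config.mutation_dispersion
            p_nb = r / (r + config.mutation_mean)
            n_mut = max(3, int(rng.negative_binomial(r, p_nb)))
            diploid = [
                (s.chrom, s.start, s.end)
                for s in segs
                if (s.cn_total, s.cn_minor) == (2, 1) and s.length >= 5 * MB
            ]
            recs, labels = simulate_sample_mutations(
                sig_mix, n_mut, clusters, purity, config.depth_mean, rng, sid,
                reference, diploid,
                novel_profile=config.novel_profile, novel_weight=config.novel_weight,
            )
            mutations.extend(recs)
            for rec, lab in zip(recs, labels):
                truth.clonality[(sid, rec.chrom, rec.pos)] = lab

    dataset = CohortDataset(mutations=mutations, segments=segments, samples=samples)
    return dataset, truth
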