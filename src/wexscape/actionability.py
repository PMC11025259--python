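"""Actionable genomic alteration (AGA) annotation and tier summaries.

Per-sample mutations and gene-level copy-number calls are matched against
a tiered knowledge base carrying, per entry, an OncoKB-style level of
evidence (1–4: 1–2 standard-of-care, 3–4 investigational) and/or an
ESCAT tier (I–II).  A bundled frozen mini-KB covers the canonical
breast-cancer actionable classes (ERBB2 amplification, PIK3CA hotspot
mutations, BRCA1/2 mutation or deletion, PTEN deletion, AKT1 E17K, ESR1
hotspots, ERBB2 hotspot mutations); user KBs in the same TSV layout are
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .core import CohortDataset, MutationRecord, ValidationError, VariantClass
from .scars import CnaCall, GeneCnaCall
from .stats import fisher_exact

ALTERATION_TYPES = {"mutation", "amplification", "deletion"}
ONCOKB_LEVELS = {"1", "2", "3", "4", "none"}
ESCAT_TIERS = {"I", "II", "none"}


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    gene: str
    alteration_type: str
    variant_filter: Optional[frozenset]  # protein changes; None = any
    oncokb_loe: str
    escat: str

    def __post_init__(self):
        if self.alteration_type not in ALTERATION_TYPES:
            raise ValidationError(
                f"unknown alteration_type {self.alteration_type!r}; "
                f"allowed: {sorted(ALTERATION_TYPES)}"
            )
        if self.oncokb_loe not in ONCOKB_LEVELS or self.escat not in ESCAT_TIERS:
            raise ValidationError("invalid oncokb_loe/escat label")
        if self.oncokb_loe == "none" and self.escat == "none":
            raise ValidationError("KB entry must carry at least one tier")


def load_knowledge_base(path=None) -> list[KnowledgeBaseEntry]:
    if path is None:
        src = resources.files("wexscape.data").joinpath("actionability_kb.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "alteration_type", "variant_filter", "oncokb_loe", "escat"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"knowledge base missing columns: {sorted(missing)}")
    entries, seen = [], set()
    for row in df.itertuples(index=False):
        vf = None if row.variant_filter in (".", "", None) else frozenset(
            str(row.variant_filter).split("|")
        )
        key = (row.gene, row.alteration_type, vf)
        if key in seen:
            raise ValidationError(f"duplicate KB entry {key}")
        seen.add(key)
        entries.append(
            KnowledgeBaseEntry(
                gene=str(row.gene),
                alteration_type=str(row.alteration_type),
                variant_filter=vf,
                oncokb_loe=str(row.oncokb_loe),
                escat=str(row.escat),
            )
        )
    return entries


@dataclass(frozen=True)
class AgaMatch:
    sample_id: str
    gene: str
    alteration_type: str
    detail: str           # protein change or CNA call
    oncokb_loe: str
    escat: str


def _protein_change(mut: MutationRecord) -> Optional[str]:
    """Protein change is carried in the gene field as GENE:p.X when the
    table provides it; plain gene symbols yield None."""
    if ":" in mut.gene:
        _, change = mut.gene.split(":", 1)
        return change.removeprefix("p.")
    return None


def annotate_aga(
    mutations: Sequence[MutationRecord],
    cna_calls: Sequence[GeneCnaCall],
    kb: Sequence[KnowledgeBaseEntry],
    sample_id: Optional[str] = None,
    protein_changes: Optional[dict] = None,
) -> list[AgaMatch]:
    """Match one sample's alterations against the knowledge base.

    Mutation entries match non-silent mutations of the gene, further
    restricted to a hotspot list when the entry carries one (hotspot
    protein changes come from ``protein_changes``, a mapping
    (chrom, pos) -> change, or from a ``GENE:p.X`` gene field).
    Amplification/deletion entries match the corresponding gene-level
    CNA calls.  Matching is deterministic and order-independent.
    """
    sid = sample_id
    if sid is None:
        sid = mutations[0].sample_id if mutations else (
            cna_calls[0].sample_id if cna_calls else ""
        )
    matches = set()
    for entry in kb:
        if entry.alteration_type == "mutation":
            for mut in mutations:
                gene = mut.gene.split(":", 1)[0]
                if gene != entry.gene or mut.variant_class is VariantClass.SILENT:
                    continue
                change = None
                if protein_changes:
                    change = protein_changes.get((mut.chrom, mut.pos))
                if change is None:
                    change = _protein_change(mut)
                if entry.variant_filter is not None:
                    if change is None or change not in entry.variant_filter:
                        continue
                matches.add(
                    AgaMatch(sid, entry.gene, "mutation", change or mut.variant_class.value,
                             entry.oncokb_loe, entry.escat)
                )
        else:
            wanted = (
                CnaCall.AMPLIFICATION if entry.alteration_type == "amplification" else CnaCall.DELETION
            )
            for call in cna_calls:
                if call.gene == entry.gene and call.call is wanted:
                    matches.add(
                        AgaMatch(sid, entry.gene, entry.alteration_type, call.call.value,
                                 entry.oncokb_loe, entry.escat)
                    )
    return sorted(matches, key=lambda m: (m.gene, m.alteration_type, m.detail))


def summarize_actionability(
    annotations: dict[str, list[AgaMatch]], samples
) -> pd.DataFrame:
    """Per-sample AGA flags and counts.

    Columns: ``n_agas``, ``has_any_aga``, ``has_loe12``, ``has_loe34``,
    ``has_escat_I_II``, joined with group/subtype.  Group percentages are
    means of the per-sample flags.
    """
    rows = []
    for s in samples:
        agas = annotations.get(s.sample_id, [])
        loe = {a.oncokb_loe for a in agas}
        escat = {a.escat for a in agas}
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group.value,
                "subtype": s.subtype.value,
                "n_agas": len(agas),
                "has_any_aga": len(agas) > 0,
                "has_loe12": bool(loe & {"1", "2"}),
                "has_loe34": bool(loe & {"3", "4"}),
                "has_escat_I_II": bool(escat & {"I", "II"}),
                "has_multiple_agas": len(agas) >= 2,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def group_percentages(summary: pd.DataFrame) -> pd.DataFrame:
    flags = ["has_any_aga", "has_loe12", "has_loe34", "has_escat_I_II", "has_multiple_agas"]
    return summary.groupby("group")[flags].mean() * 100.0


def pairwise_exclusivity(
    summary_alterations: dict[str, list[AgaMatch]],
    sample_ids: Sequence[str],
    gene_a: str,
    gene_b: str,
) -> tuple[pd.DataFrame, float, float]:
    """Cross-tabulate per-sample alteration of two genes and Fisher-test
    the association.  Returns (2x2 table, conditional-MLE OR, two-sided p)."""
    if not sample_ids:
        raise ValidationError("no samples to cross-tabulate")
    a_altered = {sid for sid, agas in summary_alterations.items() if any(m.gene == gene_a for m in agas)}
    b_altered = {sid for sid, agas in summary_alterations.items() if any(m.gene == gene_b for m in agas)}
    counts = [[0, 0], [0, 0]]
    for sid in sample_ids:
        counts[0 if sid in a_altered else 1][0 if sid in b_altered else 1] += 1
    table = pd.DataFrame(
        counts,
        index=[f"{gene_a}+", f"{gene_a}-"],
        columns=[f"{gene_b}+", f"{gene_b}-"],
    )
    a, b = counts[0]
    c, d = counts[1]
    # A zero margin (e.g. no sample altered in one gene) makes the test
    # undefined; report OR/p as NaN rather than failing the whole report.
    try:
        or_, p = fisher_exact(a, b, c, d)
    except ValidationError:
        or_, p = float("nan"), float("nan")
    return table, or_, p
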