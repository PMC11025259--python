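"""End-to-end cohort analysis: burden -> spectra/signatures -> scars/CNA
-> clonality -> actionability -> group comparisons.

``run_pipeline`` consumes a validated :class:`CohortDataset`, writes one
TSV per stage plus a JSON summary of group medians, percentages, odds
ratios and p/q-values into the output directory, and returns the summary
dict.  Each multiple-testing family (per-gene mutation frequencies,
per-gene CNA frequencies, per-signature comparisons) is corrected
separately.  Given the same inputs, config and seed the outputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .actionability import (
    annotate_aga,
    group_percentages,
    load_knowledge_base,
    pairwise_exclusivity,
    summarize_actionability,
)
from .clonality import clonal_fraction_summary, heterogeneity_table
from .core import CohortDataset, Group, ValidationError, load_genome_model
from .scars import cna_call_table, cna_frequency_profile, load_gene_model, scar_table
from .spectra import (
    build_spectrum96,
    burden_summary,
    gene_mutation_frequencies,
    load_reference_signatures,
    refit_signatures,
    signature_positivity,
    spectra_matrix,
)
from .stats import apply_fdr, compare_feature, results_to_frame

logger = logging.getLogger("wexscape")


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    panel_size_mb: Optional[float] = None   # None: use per-sample sheet values
    tmb_high: float = 10.0
    hrd_high: int = 42
    cna_gain_cut: float = 0.2
    cna_amp_cut: float = 0.9
    signature_positivity_threshold: float = 0.10
    h_index_cutoff: float = 1.0
    hdi_level: float = 0.95
    min_depth: int = 8
    adjust_covariates: tuple[str, ...] = ("subtype",)

    def __post_init__(self):
        for name in ("tmb_high", "hrd_high", "cna_gain_cut", "cna_amp_cut",
                     "signature_positivity_threshold", "h_index_cutoff", "hdi_level"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        self.outdir = Path(self.outdir)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(dataset: CohortDataset, config: PipelineConfig, genome=None,
                 reference=None, gene_model=None, kb=None) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = genome or load_genome_model()
    reference = reference or load_reference_signatures()
    gene_model = gene_model if gene_model is not None else load_gene_model()
    kb = kb or load_knowledge_base()
    groups = dataset.groups()
    two_groups = len(groups) == 2
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "tmb_high": config.tmb_high, "hrd_high": config.hrd_high,
            "cna_gain": config.cna_gain_cut, "cna_amp": config.cna_amp_cut,
            "signature_positivity": config.signature_positivity_threshold,
            "h_index": config.h_index_cutoff, "hdi_level": config.hdi_level,
        },
        "n_samples": {g.value: len(ids) for g, ids in groups.items()},
    }
    stage = "burden"
    try:
        burden = burden_summary(dataset)
        _write(burden, out / "burden.tsv")
        summary["burden"] = {
            grp.value: {
                "median_mutations": float(burden.loc[ids, "n_mutations"].median()),
                "median_tmb": float(burden.loc[ids, "tmb_per_mb"].median()),
                "pct_tmb_high": 100.0 * float(burden.loc[ids, "tmb_high"].mean()),
            }
            for grp, ids in groups.items()
        }

        stage = "spectra_signatures"
        from .core import VariantType

        spectra = []
        exposures = []
        for s in dataset.samples:
            snvs = [m for m in dataset.mutations_of(s.sample_id)
                    if m.variant_type is VariantType.SNV]
            if not snvs:
                continue
            sp = build_spectrum96(snvs, sample_id=s.sample_id)
            spectra.append(sp)
            if sp.total > 0:
                exposures.append(refit_signatures(sp, reference))
        spec_df = spectra_matrix(spectra)
        _write(spec_df, out / "spectra96.tsv")
        exp_df = pd.DataFrame(
            {e.sample_id: e.weights for e in exposures}
        ).T.rename_axis("sample_id")
        exp_df["reconstruction_cosine"] = [e.reconstruction_cosine for e in exposures]
        _write(exp_df, out / "signature_exposures.tsv")

        stage = "scars_cna"
        scars = scar_table(dataset, genome)
        _write(scars, out / "scar_scores.tsv")
        summary["hrd"] = {
            grp.value: {
                "median_hrd": float(scars.loc[ids, "hrd_score"].median()),
                "pct_hrd_high": 100.0 * float(scars.loc[ids, "hrd_high"].mean()),
            }
            for grp, ids in groups.items()
        }
        cna_calls = cna_call_table(
            dataset, gene_model, gain_cut=config.cna_gain_cut, amp_cut=config.cna_amp_cut
        )
        _write(cna_calls, out / "gene_cna_calls.tsv", index=False)
        cna_freq = cna_frequency_profile(cna_calls)
        _write(cna_freq, out / "cna_frequencies.tsv")

        stage = "clonality"
        het, calls = heterogeneity_table(
            dataset, seed=config.seed, level=config.hdi_level, min_depth=config.min_depth
        )
        _write(het, out / "heterogeneity.tsv")
        clonal = clonal_fraction_summary(calls, dataset.samples)
        _write(clonal, out / "clonal_fractions.tsv")
        summary["clonality"] = {
            grp.value: {
                "median_h_index": float(het.loc[ids, "h_index"].median()),
                "pct_heterogeneous": 100.0 * float(
                    het.loc[ids, "heterogeneous"].astype(float).mean()
                ),
                "median_frac_clonal": float(clonal.loc[ids, "frac_clonal"].median()),
            }
            for grp, ids in groups.items()
        }

        stage = "actionability"
        annotations = {}
        calls_by_sample = {
            sid: [c for c in cna_calls.itertuples() if c.sample_id == sid]
            for sid in dataset.sample_ids
        }
        from .scars import CnaCall, GeneCnaCall

        for s in dataset.samples:
            gene_calls = [
                GeneCnaCall(t.sample_id, t.gene, t.log2r, CnaCall(t.call), t.missing)
                for t in calls_by_sample[s.sample_id]
            ]
            annotations[s.sample_id] = annotate_aga(
                dataset.mutations_of(s.sample_id), gene_calls, kb, sample_id=s.sample_id
            )
        aga = summarize_actionability(annotations, dataset.samples)
        _write(aga, out / "actionability.tsv")
        summary["actionability"] = {
            grp: row.to_dict() for grp, row in group_percentages(aga).iterrows()
        }
        if len(dataset.sample_ids) > 0:
            _, or_excl, p_excl = pairwise_exclusivity(
                annotations, dataset.sample_ids, "PIK3CA", "ERBB2"
            )
            summary["pik3ca_erbb2_exclusivity"] = {"odds_ratio": or_excl, "p": p_excl}

        stage = "comparisons"
        if two_groups:
            results = []
            results.append(compare_feature(
                dataset, lambda sid: burden.loc[sid, "tmb_per_mb"], "tmb_per_mb",
                kind="continuous", adjust=config.adjust_covariates))
            results.append(compare_feature(
                dataset, lambda sid: float(burden.loc[sid, "tmb_high"]), "tmb_high",
                kind="binary"))
            results.append(compare_feature(
                dataset, lambda sid: scars.loc[sid, "hrd_score"], "hrd_score",
                kind="continuous", adjust=config.adjust_covariates))
            results.append(compare_feature(
                dataset, lambda sid: float(scars.loc[sid, "hrd_high"]), "hrd_high",
                kind="binary"))
            het_flag = het["heterogeneous"].astype("boolean")
            results.append(compare_feature(
                dataset,
                lambda sid: float(het_flag[sid]) if het_flag[sid] is not pd.NA else np.nan,
                "heterogeneous", kind="binary"))
            results.append(compare_feature(
                dataset, lambda sid: clonal.loc[sid, "frac_clonal"], "frac_clonal",
                kind="continuous", adjust=config.adjust_covariates))
            for flag in ("has_any_aga", "has_loe12", "has_loe34", "has_escat_I_II"):
                results.append(compare_feature(
                    dataset, lambda sid, f=flag: float(aga.loc[sid, f]), flag, kind="binary"))
            apply_fdr(results)
            _write(results_to_frame(results), out / "comparisons.tsv", index=False)
            summary["comparisons"] = {
                r.feature: {"test": r.test, "p": r.p_value, "q": r.q_value,
                            "odds_ratio": r.odds_ratio}
                for r in results
            }

            # per-signature family
            sig_results = []
            for name in reference.names:
                if name not in exp_df.columns:
                    continue
                col = exp_df[name]
                if col.max() <= 0:
                    continue
                sig_results.append(compare_feature(
                    dataset,
                    lambda sid, c=col: float(c[sid]) if sid in c.index else np.nan,
                    name, kind="continuous"))
            apply_fdr(sig_results)
            _write(results_to_frame(sig_results), out / "signature_comparisons.tsv", index=False)

            # per-gene mutation-frequency family
            gene_freq = gene_mutation_frequencies(dataset)
            _write(gene_freq, out / "gene_mutation_frequencies.tsv")
            mutated_sets: dict[str, set] = {}
            for m in dataset.mutations:
                mutated_sets.setdefault(m.gene.split(":", 1)[0], set()).add(m.sample_id)
            gene_results = []
            min_n = max(2, len(dataset.samples) // 20)
            for gene, sids in sorted(mutated_sets.items()):
                if len(sids) < min_n:
                    continue
                gene_results.append(compare_feature(
                    dataset, lambda sid, s=sids: float(sid in s), f"mut_{gene}",
                    kind="binary"))
            if gene_results:
                apply_fdr(gene_results)
                _write(results_to_frame(gene_results), out / "gene_mutation_comparisons.tsv",
                       index=False)
                summary["n_genes_mut_q_significant"] = int(
                    sum(r.q_value < 0.25 for r in gene_results))
        else:
            logger.warning("single-group cohort: comparison stage skipped")
            summary["comparisons"] = "skipped: single group"
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("pipeline complete: %s", out)
    return summary
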