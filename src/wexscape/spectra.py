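"""Mutation burden, 96-context spectra, and mutational signatures.

The single-base-substitution (SBS) catalog uses the standard
pyrimidine-centric 96-channel convention: every SNV is expressed with a
pyrimidine (C or T) reference base — purine-reference variants are
reverse-complemented — and binned by substitution class
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 5' and 3' flanking bases.
Channel order is fixed and documented in :data:`SBS96_LABELS`:
substitution classes in the order above, and within each class the 16
(5', 3') flank pairs in lexicographic ACGT order, e.g.
``A[C>A]A, A[C>A]C, ..., T[T>G]T``.

Signature refitting solves a nonnegative least-squares problem of the raw
96-count vector against a reference signature matrix and normalises the
exposures to fractions; de-novo extraction uses nonnegative matrix
factorisation with restarts.  The bundled reference matrix is a
*synthetic* 30-signature stand-in that mimics the qualitative structure
of the familiar catalog (an age-related CpG C>T signature, two
APOBEC-like TpC signatures, a flat HRD-like signature, ...) — see
``data/signatures_v2like_synthetic.tsv``; user-supplied matrices in the
same layout are accepted everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import (
    CohortDataset,
    ContextUnavailable,
    MutationRecord,
    ValidationError,
    VariantClass,
    VariantType,
    revcomp,
    trinucleotide_context,
)

logger = logging.getLogger("wexscape")

SBS96_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: The 96 channel labels in canonical order.
SBS96_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS96_SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}

#: Tumor mutational burden above this many mutations per Mb is "high".
TMB_HIGH_THRESHOLD = 10.0

CODING_CLASSES = {VariantClass.MISSENSE, VariantClass.NONSENSE, VariantClass.SILENT}


def sbs96_channel(ref: str, alt: str, context3: str) -> int:
    """Channel index of an SNV given its forward-strand 3-mer context.

    Purine-reference substitutions are mapped to the pyrimidine strand by
    reverse complementing both the context and the alleles.
    """
    if context3[1] != ref:
        raise ValidationError(f"context {context3} middle base != ref {ref}")
    if ref in "GA":
        context3 = revcomp(context3)
        ref = revcomp(ref)
        alt = revcomp(alt)
    label = f"{context3[0]}[{ref}>{alt}]{context3[2]}"
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise ValidationError(f"not an SBS96 channel: {label}") from None


@dataclass
class Spectrum96:
    """Per-sample 96-channel SNV count vector."""

    sample_id: str
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValidationError("Spectrum96 needs exactly 96 channels")
        if (self.counts < 0).any():
            raise ValidationError("negative spectrum counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def six_class(self) -> pd.Series:
        """Collapse to the six substitution classes by summing contexts."""
        sums = self.counts.reshape(6, 16).sum(axis=1)
        return pd.Series(sums, index=list(SBS96_SUBSTITUTIONS))


def build_spectrum96(
    snvs: Sequence[MutationRecord],
    context_source=None,
    sample_id: Optional[str] = None,
) -> Spectrum96:
    """Bin a sample's SNVs into the 96 channels.

    Context comes from each record's ``context3`` field when present,
    otherwise from ``context_source`` (an indexed reference, see
    :func:`wexscape.core.trinucleotide_context`).  Records whose context
    is unavailable or inconsistent with the reference allele are excluded
    and counted in ``n_excluded``.
    """
    counts = np.zeros(96)
    excluded = 0
    sid = sample_id
    for m in snvs:
        if m.variant_type is not VariantType.SNV:
            raise ValidationError("build_spectrum96 accepts SNVs only")
        if sid is None:
            sid = m.sample_id
        ctx = m.context3
        if ctx is None and context_source is not None:
            try:
                ctx = trinucleotide_context(m.chrom, m.pos, context_source)
            except ContextUnavailable:
                ctx = None
        if ctx is None or ctx[1] != m.ref:
            excluded += 1
            continue
        counts[sbs96_channel(m.ref, m.alt, ctx)] += 1
    if excluded:
        logger.warning("spectrum %s: %d SNV(s) excluded (no usable context)", sid, excluded)
    return Spectrum96(sample_id=sid or "", counts=counts, n_excluded=excluded)


def spectra_matrix(spectra: Sequence[Spectrum96]) -> pd.DataFrame:
    """Stack per-sample spectra into a samples x 96 DataFrame."""
    return pd.DataFrame(
        [s.counts for s in spectra],
        index=[s.sample_id for s in spectra],
        columns=list(SBS96_LABELS),
    )


@dataclass
class SignatureMatrix:
    """Named nonnegative 96-channel profiles, each summing to 1."""

    names: list[str]
    profiles: np.ndarray  # (n_signatures, 96)

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] != 96:
            raise ValidationError("profiles must be (n_signatures, 96)")
        if len(self.names) != self.profiles.shape[0]:
            raise ValidationError("names/profiles length mismatch")
        if (self.profiles < 0).any():
            raise ValidationError("negative signature weights")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("each signature profile must sum to 1 (±1e-6)")

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles.T, index=list(SBS96_LABELS), columns=self.names)


def load_reference_signatures(path=None) -> SignatureMatrix:
    """Load a signature matrix TSV (rows = 96 channels in canonical order,
    columns = signatures).  Default: the bundled synthetic 30-signature set."""
    if path is None:
        src = resources.files("wexscape.data").joinpath("signatures_v2like_synthetic.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(SBS96_LABELS):
        raise ValidationError("signature file rows must follow the canonical SBS96 order")
    return SignatureMatrix(names=list(df.columns), profiles=df.to_numpy().T)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SignatureExposure:
    """Per-sample nonnegative signature fractions from a refit."""

    sample_id: str
    weights: pd.Series  # index: signature names; sums to 1
    reconstruction_cosine: float

    def __post_init__(self):
        if (self.weights < -1e-12).any():
            raise ValidationError("negative exposure weight")
        total = float(self.weights.sum())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValidationError(f"exposure weights sum to {total}, expected 1")
        if not (0.0 <= self.reconstruction_cosine <= 1.0 + 1e-12):
            raise ValidationError("reconstruction cosine outside [0, 1]")


def refit_signatures(spectrum: Spectrum96, reference: SignatureMatrix) -> SignatureExposure:
    """Decompose a spectrum over reference signatures by nonnegative least
    squares on the raw counts, then normalise exposures to fractions.

    The refit is scale invariant: multiplying the counts by a constant
    leaves the fractional exposures unchanged.
    """
    if spectrum.total <= 0:
        raise ValidationError("cannot refit an all-zero spectrum")
    A = reference.profiles.T  # (96, S)
    x, _ = nnls(A, spectrum.counts)
    recon = A @ x
    cos = cosine_similarity(spectrum.counts, recon)
    total = x.sum()
    if total <= 0:
        # NNLS found nothing representable; fall back to uniform.
        fractions = np.full(len(reference), 1.0 / len(reference))
        cos = 0.0
    else:
        fractions = x / total
    return SignatureExposure(
        sample_id=spectrum.sample_id,
        weights=pd.Series(fractions, index=reference.names),
        reconstruction_cosine=min(cos, 1.0),
    )


def signature_positivity(exposure: SignatureExposure, threshold: float = 0.10) -> pd.Series:
    """Boolean positivity per signature: strictly greater than *threshold*."""
    return exposure.weights > threshold


def extract_denovo_signatures(
    spectra: pd.DataFrame,
    rank: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 2000,
) -> tuple[SignatureMatrix, pd.DataFrame]:
    """De-novo signature extraction by NMF (Frobenius loss, multiplicative
    updates), best of ``n_restarts`` random initialisations by objective.

    Returns the extracted :class:`SignatureMatrix` (columns normalised to
    sum 1, magnitudes absorbed into the exposures) and a samples x rank
    exposure DataFrame in mutation counts.
    """
    import warnings

    from sklearn.decomposition import NMF
    from sklearn.exceptions import ConvergenceWarning

    X = spectra.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("spectra matrix must be nonnegative")
    n_samples = X.shape[0]
    if not (1 <= rank <= min(96, n_samples)):
        raise ValidationError(f"rank {rank} outside [1, min(96, n_samples={n_samples})]")
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        state = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=1e-8,
            random_state=state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    _, W, H = best
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    profiles = H / scale[:, None]
    exposures = W * scale[None, :]
    names = [f"SBS96{chr(ord('A') + i)}" for i in range(rank)]
    sig = SignatureMatrix(names=names, profiles=profiles)
    exp_df = pd.DataFrame(exposures, index=spectra.index, columns=names)
    return sig, exp_df


def nmf_rank_survey(
    spectra: pd.DataFrame, ranks: Sequence[int] = range(2, 9), seed: int = 0, n_restarts: int = 3
) -> pd.DataFrame:
    """Reconstruction error and profile stability (mean best-pair cosine
    between two half-splits of the cohort) per candidate rank."""
    rows = []
    rng = np.random.default_rng(seed)
    for rank in ranks:
        sig, exp = extract_denovo_signatures(spectra, rank, seed=seed, n_restarts=n_restarts)
        recon = exp.to_numpy() @ sig.profiles
        err = float(np.linalg.norm(spectra.to_numpy() - recon))
        perm = rng.permutation(len(spectra))
        half = len(spectra) // 2
        stab = np.nan
        if half >= rank:
            s1, _ = extract_denovo_signatures(spectra.iloc[perm[:half]], rank, seed=seed + 1, n_restarts=n_restarts)
            s2, _ = extract_denovo_signatures(spectra.iloc[perm[half:]], rank, seed=seed + 2, n_restarts=n_restarts)
            matches = match_signatures(s1, s2, min_cosine=0.0)
            stab = float(np.mean([m.cosine for m in matches]))
        rows.append({"rank": rank, "frobenius_error": err, "split_stability_cosine": stab})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SignatureMatch:
    candidate: str
    reference: Optional[str]  # None => unassigned
    cosine: float


def match_signatures(
    candidate: SignatureMatrix, reference: SignatureMatrix, min_cosine: float = 0.8
) -> list[SignatureMatch]:
    """Best reference signature per candidate by cosine similarity;
    candidates below ``min_cosine`` stay unassigned (novel signatures)."""
    out = []
    for i, name in enumerate(candidate.names):
        sims = [cosine_similarity(candidate.profiles[i], p) for p in reference.profiles]
        j = int(np.argmax(sims))
        best = sims[j]
        out.append(
            SignatureMatch(
                candidate=name,
                reference=reference.names[j] if best >= min_cosine else None,
                cosine=best,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Burden accounting


def is_coding(m: MutationRecord) -> bool:
    """Coding mutation for burden purposes: missense, nonsense or silent
    SNV, or any indel."""
    return m.variant_class in CODING_CLASSES or m.variant_type is VariantType.INDEL


def compute_tmb(mutations: Sequence[MutationRecord], panel_size_mb: float) -> float:
    """Tumor mutational burden: coding mutations per megabase of panel."""
    if panel_size_mb <= 0:
        raise ValidationError("panel_size_mb must be positive")
    return sum(1 for m in mutations if is_coding(m)) / panel_size_mb


def tmb_high(tmb: float, threshold: float = TMB_HIGH_THRESHOLD) -> bool:
    return tmb > threshold


def burden_summary(dataset: CohortDataset) -> pd.DataFrame:
    """Per-sample mutation-class accounting.

    Columns: raw counts per class, TMB, and fractions — ``frac_snv`` of
    all mutations, ``frac_nonsilent`` of all mutations, and missense /
    nonsense fractions among non-silent SNVs (NaN when the denominator is
    empty).
    """
    rows = []
    for s in dataset.samples:
        muts = dataset.mutations_of(s.sample_id)
        n = len(muts)
        n_snv = sum(1 for m in muts if m.variant_type is VariantType.SNV)
        n_indel = n - n_snv
        n_silent = sum(1 for m in muts if m.variant_class is VariantClass.SILENT)
        n_nonsilent = n - n_silent
        nonsilent_snv = [
            m for m in muts
            if m.variant_type is VariantType.SNV and m.variant_class is not VariantClass.SILENT
        ]
        n_mis = sum(1 for m in nonsilent_snv if m.variant_class is VariantClass.MISSENSE)
        n_non = sum(1 for m in nonsilent_snv if m.variant_class is VariantClass.NONSENSE)
        tmb = compute_tmb(muts, s.panel_size_mb)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group.value,
                "subtype": s.subtype.value,
                "n_mutations": n,
                "n_snv": n_snv,
                "n_indel": n_indel,
                "n_silent": n_silent,
                "n_nonsilent": n_nonsilent,
                "n_missense": n_mis,
                "n_nonsense": n_non,
                "tmb_per_mb": tmb,
                "tmb_high": tmb_high(tmb),
                "frac_snv": n_snv / n if n else np.nan,
                "frac_nonsilent": n_nonsilent / n if n else np.nan,
                "frac_missense_of_nonsilent_snv": n_mis / len(nonsilent_snv) if nonsilent_snv else np.nan,
                "frac_nonsense_of_nonsilent_snv": n_non / len(nonsilent_snv) if nonsilent_snv else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def gene_mutation_frequencies(
    dataset: CohortDataset, gene_list: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Fraction of mutated samples per gene and group (a sample counts once
    per gene, however many hits it carries).

    Columns per group g: ``n_mutated_<g>``, ``n_total_<g>``, ``freq_<g>``.
    """
    genes = list(gene_list) if gene_list else sorted({m.gene for m in dataset.mutations})
    mutated: dict[str, set[str]] = {g: set() for g in genes}
    for m in dataset.mutations:
        if m.gene in mutated:
            mutated[m.gene].add(m.sample_id)
    groups = dataset.groups()
    out = {"gene": genes}
    for grp, sample_ids in groups.items():
        ids = set(sample_ids)
        n_total = len(ids)
        n_mut = [len(mutated[g] & ids) for g in genes]
        out[f"n_mutated_{grp.value}"] = n_mut
        out[f"n_total_{grp.value}"] = n_total
        out[f"freq_{grp.value}"] = [m / n_total if n_total else np.nan for m in n_mut]
    return pd.DataFrame(out).set_index("gene")


def load_driver_genes() -> set[str]:
    """Bundled breast-cancer driver-gene tag list."""
    src = resources.files("wexscape.data").joinpath("driver_genes_breast.tsv")
    with resources.as_file(src) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return set(df["gene"])
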