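"""Cancer-cell-fraction estimation, clonal/subclonal calls, CCF
clustering and intratumor heterogeneity.

Model
-----
For a mutation with variant allele fraction ``f`` in a tumor of purity
``p`` at a locus of total copy number ``n_t``, carried on ``m`` of the
tumor copies, the expected VAF is::

    E[f] = CCF * p * m / (p * n_t + 2 * (1 - p))

so the cancer cell fraction is ``CCF = f * (p*n_t + 2*(1-p)) / (p*m)``.
Multiplicity ``m`` is estimated by rounding ``f/p * (p*n_t + 2*(1-p))``
and clamping to ``[1, n_t]``.

Uncertainty comes from read sampling: with a uniform Beta(1, 1) prior the
VAF posterior is Beta(alt+1, ref+1), and the highest-density interval
(HDI) of that posterior maps through the linear VAF->CCF transform.  A
mutation is Clonal when CCF = 1 lies inside its credible interval;
intervals entirely above 1 (a rounding artifact of integer multiplicity)
are also called Clonal unless ``strict_rule`` is set.

Intratumor heterogeneity clusters the CCFs of copy-number-neutral
mutations with a 1-D Gaussian mixture fit by EM (BIC-selected k) whose
component variances are pinned to the known read-sampling variance of
each CCF, drops clusters below 2 % occupancy, and summarises the cluster
proportions with the Shannon index H = -sum p_i ln p_i; a sample is
heterogeneous when H > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .core import CohortDataset, MutationRecord, SampleMeta, ValidationError, VariantType

logger = logging.getLogger("wexscape")

MIN_DEPTH_DEFAULT = 8
CCF_CAP = 2.0
HDI_LEVEL_DEFAULT = 0.95
MIN_MUTATIONS_FOR_CLUSTERING = 10
MIN_CLUSTER_PROPORTION = 0.02
H_INDEX_CUTOFF = 1.0


def expected_vaf(ccf: float, purity: float, cn_total: int, m: int) -> float:
    """Expected allele fraction under the CCF model."""
    return ccf * purity * m / (purity * cn_total + 2.0 * (1.0 - purity))


def estimate_multiplicity(vaf: float, purity: float, cn_total: int) -> int:
    """Integer mutation multiplicity, rounded and clamped to [1, cn_total]."""
    if not (0 < purity <= 1):
        raise ValidationError(f"purity must be in (0, 1], got {purity}")
    if cn_total < 1:
        raise ValidationError("cn_total must be >= 1 for multiplicity estimation")
    if not (0 <= vaf <= 1):
        raise ValidationError(f"vaf must be in [0, 1], got {vaf}")
    raw = vaf / purity * (purity * cn_total + 2.0 * (1.0 - purity))
    return int(min(max(round(raw), 1), cn_total))


def compute_ccf(
    vaf: float, purity: float, cn_total: int, m: int, cap_max: float = CCF_CAP
) -> float:
    """Point-estimate CCF, capped at ``cap_max`` for reporting."""
    if m < 1:
        raise ValidationError("multiplicity must be >= 1")
    ccf = vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / (purity * m)
    return min(ccf, cap_max)


def beta_hdi(a: float, b: float, level: float = HDI_LEVEL_DEFAULT) -> tuple[float, float]:
    """Highest-density interval of a Beta(a, b) posterior.

    The HDI is the narrowest interval carrying ``level`` posterior mass;
    it is found by minimising the interval width over the lower tail mass.
    """
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    dist = stats.beta(a, b)

    def width(lo_mass: float) -> float:
        return dist.ppf(lo_mass + level) - dist.ppf(lo_mass)

    res = minimize_scalar(width, bounds=(0.0, 1.0 - level), method="bounded",
                          options={"xatol": 1e-10})
    lo_mass = float(res.x)
    return float(dist.ppf(lo_mass)), float(dist.ppf(lo_mass + level))


def ccf_credible_interval(
    alt_count: int,
    ref_count: int,
    purity: float,
    cn_total: int,
    m: int,
    level: float = HDI_LEVEL_DEFAULT,
    min_depth: int = MIN_DEPTH_DEFAULT,
) -> tuple[float, float]:
    """HDI on the CCF scale: Beta(alt+1, ref+1) VAF posterior mapped
    through the linear VAF->CCF transform at fixed (purity, cn_total, m)."""
    depth = alt_count + ref_count
    if depth < min_depth:
        raise ValidationError(f"depth {depth} below minimum {min_depth}")
    lo, hi = beta_hdi(alt_count + 1, ref_count + 1, level=level)
    scale = (purity * cn_total + 2.0 * (1.0 - purity)) / (purity * m)
    return lo * scale, hi * scale


def classify_clonality(interval: tuple[float, float], strict_rule: bool = False) -> str:
    """"Clonal" when 1 falls inside the credible interval; intervals lying
    entirely above 1 are Clonal too unless ``strict_rule``."""
    lo, hi = interval
    if lo > hi:
        raise ValidationError("invalid interval: low > high")
    if lo <= 1.0 <= hi:
        return "Clonal"
    if lo > 1.0 and not strict_rule:
        return "Clonal"
    return "Subclonal"


@dataclass(frozen=True)
class ClonalityCall:
    sample_id: str
    chrom: str
    pos: int
    gene: str
    vaf: float
    multiplicity: int
    cn_total: int
    ccf: float
    ccf_sd: float        # posterior sd of the CCF from read sampling
    hdi_low: float
    hdi_high: float
    label: str


def _locus_cn(segments, chrom: str, pos: int, default: int = 2) -> int:
    for s in segments:
        if s.chrom == chrom and s.start <= pos <= s.end:
            return s.cn_total
    return default


def call_sample_clonality(
    mutations: Sequence[MutationRecord],
    meta: SampleMeta,
    segments=(),
    level: float = HDI_LEVEL_DEFAULT,
    min_depth: int = MIN_DEPTH_DEFAULT,
    strict_rule: bool = False,
) -> list[ClonalityCall]:
    """Clonality calls for one sample's mutations.

    Mutations at homozygous-deletion loci (cn_total = 0) or below the
    depth floor are excluded with a logged count.
    """
    calls = []
    n_excluded = 0
    for mut in mutations:
        cn = _locus_cn(segments, mut.chrom, mut.pos)
        depth = mut.depth
        if cn < 1 or depth < min_depth:
            n_excluded += 1
            continue
        vaf = mut.vaf
        m = estimate_multiplicity(vaf, meta.purity, cn)
        ccf = compute_ccf(vaf, meta.purity, cn, m)
        lo, hi = ccf_credible_interval(
            mut.alt_count, mut.ref_count, meta.purity, cn, m,
            level=level, min_depth=min_depth,
        )
        a, b = mut.alt_count + 1, mut.ref_count + 1
        scale = (meta.purity * cn + 2.0 * (1.0 - meta.purity)) / (meta.purity * m)
        vaf_sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        calls.append(
            ClonalityCall(
                sample_id=mut.sample_id, chrom=mut.chrom, pos=mut.pos, gene=mut.gene,
                vaf=vaf, multiplicity=m, cn_total=cn, ccf=ccf,
                ccf_sd=float(vaf_sd * scale),
                hdi_low=lo, hdi_high=hi,
                label=classify_clonality((lo, hi), strict_rule=strict_rule),
            )
        )
    if n_excluded:
        logger.warning(
            "clonality %s: %d mutation(s) excluded (low depth or CN 0)",
            meta.sample_id, n_excluded,
        )
    return calls


# ---------------------------------------------------------------------------
# CCF clustering and the heterogeneity index


@dataclass
class ClusterSolution:
    sample_id: str
    assignments: np.ndarray       # cluster index per mutation (post-merge)
    means: np.ndarray             # cluster mean CCFs
    proportions: np.ndarray       # sums to 1
    h_index: float
    assessable: bool = True

    @property
    def heterogeneous(self) -> bool:
        return self.h_index > H_INDEX_CUTOFF

    @property
    def n_clusters(self) -> int:
        return len(self.means)


def shannon_index(proportions: Sequence[float]) -> float:
    """H = -sum p ln p over cluster proportions (natural log)."""
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValidationError("empty proportions")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValidationError(f"proportions sum to {p.sum()}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _em_known_noise(
    x: np.ndarray, s2: np.ndarray, k: int, init_means: np.ndarray,
    max_iter: int = 300, tol: float = 1e-9,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """EM for a 1-D mixture whose component variance is the known
    per-observation measurement variance ``s2`` (free parameters: the k
    component means and k-1 mixing weights).

    Returns (log-likelihood, weights, means, responsibilities).
    """
    n = len(x)
    mu = init_means.astype(float).copy()
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    inv_s2 = 1.0 / s2
    for _ in range(max_iter):
        logp = (
            np.log(np.maximum(w, 1e-300))[:, None]
            - 0.5 * np.log(2 * np.pi * s2)[None, :]
            - 0.5 * (x[None, :] - mu[:, None]) ** 2 * inv_s2[None, :]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        R = np.exp(logp - lse)
        w = R.mean(axis=1)
        denom = R @ inv_s2
        numer = R @ (x * inv_s2)
        nz = denom > 0
        mu[nz] = numer[nz] / denom[nz]
        if ll - prev_ll < tol:
            break
        prev_ll = ll
    return ll, w, mu, R


def cluster_ccfs(
    calls: Sequence[ClonalityCall],
    max_k: int = 6,
    seed: int = 0,
    min_mutations: int = MIN_MUTATIONS_FOR_CLUSTERING,
    cn_neutral_only: bool = True,
    min_proportion: float = MIN_CLUSTER_PROPORTION,
) -> ClusterSolution:
    """1-D mixture clustering of a sample's CCFs.

    Only copy-number-neutral (cn_total = 2) mutations enter by default.
    Component variances are pinned to each mutation's read-sampling
    variance (``ccf_sd``) rather than fitted, so a spread of genuinely
    distinct clusters cannot be absorbed by one wide component; only the
    component means and mixing weights are estimated, by EM, with
    k = 1..max_k selected by BIC (2k-1 free parameters).  Clusters holding
    under ``min_proportion`` of mutations are dropped and proportions
    renormalised.  Values are sorted internally, so input order does not
    affect the solution.
    """
    sid = calls[0].sample_id if calls else ""
    eligible = [c for c in calls if (not cn_neutral_only or c.cn_total == 2)]
    ccfs = np.array([c.ccf for c in eligible], dtype=float)
    if len(ccfs) < min_mutations:
        return ClusterSolution(
            sample_id=sid, assignments=np.array([], dtype=int),
            means=np.array([]), proportions=np.array([]),
            h_index=float("nan"), assessable=False,
        )
    sds = np.array([c.ccf_sd for c in eligible], dtype=float)
    order = np.argsort(ccfs, kind="stable")
    x = ccfs[order]
    s2 = np.maximum(sds[order], 0.02) ** 2
    n = len(x)
    rng = np.random.default_rng(seed)
    best = None  # (bic, w, mu, R)
    for k in range(1, min(max_k, n) + 1):
        inits = [np.quantile(x, (np.arange(k) + 0.5) / k)]
        for _ in range(2):
            inits.append(np.sort(rng.choice(x, size=k, replace=False)))
        fits = [_em_known_noise(x, s2, k, init) for init in inits]
        ll, w, mu, R = max(fits, key=lambda f: f[0])
        bic = -2.0 * ll + (2 * k - 1) * np.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, w, mu, R)
    _, w, mu, R = best
    labels_sorted = R.argmax(axis=0)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    k = len(mu)
    counts = np.bincount(labels, minlength=k).astype(float)
    props = counts / counts.sum()
    keep = np.where(props >= min_proportion)[0]
    if len(keep) == 0:
        keep = np.array([int(np.argmax(props))])
    # Reassign dropped-cluster mutations to the nearest kept cluster mean.
    remap = {}
    for old in range(k):
        if old in keep:
            remap[old] = int(np.where(keep == old)[0][0])
        else:
            remap[old] = int(np.argmin(np.abs(mu[keep] - mu[old])))
    new_labels = np.array([remap[l] for l in labels], dtype=int)
    new_counts = np.bincount(new_labels, minlength=len(keep)).astype(float)
    new_props = new_counts / new_counts.sum()
    # Order clusters by decreasing mean CCF for stable reporting.
    order_by_mean = np.argsort(-mu[keep], kind="stable")
    rank = np.empty(len(keep), dtype=int)
    rank[order_by_mean] = np.arange(len(keep))
    final_labels = rank[new_labels]
    return ClusterSolution(
        sample_id=sid,
        assignments=final_labels,
        means=mu[keep][order_by_mean],
        proportions=new_props[order_by_mean],
        h_index=shannon_index(new_props),
    )


def clonal_fraction_summary(calls: Sequence[ClonalityCall], samples: Sequence[SampleMeta]) -> pd.DataFrame:
    """Per-sample clonal/subclonal mutation fractions, joined with group."""
    meta = {s.sample_id: s for s in samples}
    rows = []
    by_sample: dict[str, list[ClonalityCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    for s in samples:
        sample_calls = by_sample.get(s.sample_id, [])
        n = len(sample_calls)
        n_clonal = sum(1 for c in sample_calls if c.label == "Clonal")
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group.value,
                "subtype": s.subtype.value,
                "n_calls": n,
                "frac_clonal": n_clonal / n if n else np.nan,
                "frac_subclonal": (n - n_clonal) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def heterogeneity_table(
    dataset: CohortDataset,
    max_k: int = 6,
    seed: int = 0,
    level: float = HDI_LEVEL_DEFAULT,
    min_depth: int = MIN_DEPTH_DEFAULT,
) -> tuple[pd.DataFrame, list[ClonalityCall]]:
    """Clonality calls + per-sample heterogeneity summary for a cohort."""
    all_calls: list[ClonalityCall] = []
    rows = []
    for s in dataset.samples:
        calls = call_sample_clonality(
            dataset.mutations_of(s.sample_id), s,
            segments=dataset.segments_of(s.sample_id),
            level=level, min_depth=min_depth,
        )
        all_calls.extend(calls)
        sol = cluster_ccfs(calls, max_k=max_k, seed=seed)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group.value,
                "subtype": s.subtype.value,
                "n_clusters": sol.n_clusters if sol.assessable else 0,
                "h_index": sol.h_index,
                "heterogeneous": sol.heterogeneous if sol.assessable else None,
                "assessable": sol.assessable,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id"), all_calls
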