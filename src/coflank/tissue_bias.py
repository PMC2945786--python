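"""Tissue-specificity of genes whose exons carry a co-occurring motif pair.

A gene is tissue-specific in tissue t when its expression there exceeds its
own median across tissues by more than two standard deviations.  For a motif
pair, the fraction F_E of its genes that are specific to each tissue is
compared against a permutation null built from randomly drawn exons without
the pair, matched on the genes' exon counts; empirical enrichment/depletion
p-values per tissue use the add-one rule.  A one-sided binomial test measures
concordance between the pair's significant tissues and the cross-tissue
expression profile of a candidate RNA-binding protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exon_model import ExonRecord, RegionPairConfig, extract_region


def tissue_specific_sets(expr: pd.DataFrame) -> pd.DataFrame:
    """Boolean genes x tissues matrix: expr[g, t] > median_t' + 2*sd (strict).

    Per-gene median and standard deviation are computed across tissues
    (sample sd, ddof=1).  Rows with missing values are dropped and logged via
    a warning rather than imputed.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    clean = expr.dropna(axis=0)
    if len(clean) < len(expr):
        import warnings

        dropped = sorted(set(expr.index) - set(clean.index))
        warnings.warn(
            f"dropped {len(dropped)} gene(s) with missing expression values "
            f"(no imputation): {dropped[:5]}...",
            stacklevel=2,
        )
    med = clean.median(axis=1)
    sd = clean.std(axis=1, ddof=1)
    return clean.gt(med + 2 * sd, axis=0)


@dataclass
class TissueBiasResult:
    motif_u: str
    motif_d: str
    n_pair_genes: int
    f_e: pd.Series  # per-tissue fraction of pair genes that are specific
    p_enrich: pd.Series
    p_deplete: pd.Series
    iterations: int
    cutoff: float = 0.001
    enriched_tissues: list = field(init=False)
    depleted_tissues: list = field(init=False)

    def __post_init__(self) -> None:
        self.enriched_tissues = list(self.p_enrich.index[self.p_enrich < self.cutoff])
        self.depleted_tissues = list(self.p_deplete.index[self.p_deplete < self.cutoff])


def pair_tissue_bias(
    pair: tuple[str, str],
    corpus: Sequence[ExonRecord],
    pair_config: RegionPairConfig,
    gene_map: pd.DataFrame,
    expr: pd.DataFrame,
    *,
    iterations: int = 10_000,
    seed: int = 0,
    cutoff: float = 0.001,
) -> TissueBiasResult:
    """Permutation test of the pair's tissue bias.

    Exons carrying the pair define the gene set E and the observed per-tissue
    fractions F_E.  Each iteration draws, for every gene in E, a control gene
    of identical exon count whose exons lack the pair, and recomputes the
    fractions F_C.  Enrichment p = fraction of iterations with F_C >= F_E
    (depletion mirrored), with add-one smoothing so no p is 0.
    """
    u, d = pair
    exon_count = dict(zip(gene_map["exon_id"], gene_map["exon_count"]))
    gene_of = dict(zip(gene_map["exon_id"], gene_map["gene_id"]))

    carries = {}
    for e in corpus:
        up = extract_region(e, pair_config.upstream)
        down = extract_region(e, pair_config.downstream)
        carries[e.exon_id] = u in up and d in down

    pair_genes = sorted(
        {gene_of[eid] for eid, c in carries.items() if c and eid in gene_of}
    )
    if not pair_genes:
        raise ValueError("no exon carries the pair")
    # control pool: genes all of whose surveyed exons lack the pair
    gene_has_pair = {}
    for eid, c in carries.items():
        g = gene_of.get(eid)
        if g is not None:
            gene_has_pair[g] = gene_has_pair.get(g, False) or c
    control_genes = sorted(g for g, has in gene_has_pair.items() if not has)
    if not control_genes:
        raise ValueError("no eligible control genes")

    spec = tissue_specific_sets(expr)
    tissues = spec.columns
    known = set(spec.index)
    pair_known = [g for g in pair_genes if g in known]
    if not pair_known:
        raise ValueError("pair genes absent from the expression matrix")
    spec_np = spec.to_numpy()
    row_of = {g: i for i, g in enumerate(spec.index)}
    f_e = spec_np[[row_of[g] for g in pair_known]].mean(axis=0)

    gene_exons = gene_map.drop_duplicates("gene_id").set_index("gene_id")["exon_count"]
    buckets: dict[int, np.ndarray] = {}
    for g in control_genes:
        if g in known and g in gene_exons.index:
            buckets.setdefault(int(gene_exons[g]), []).append(row_of[g])
    buckets = {c: np.asarray(v) for c, v in buckets.items()}
    counts_sorted = sorted(buckets)

    rng = np.random.default_rng(seed)
    n_e = len(pair_known)
    f_c_sum_ge = np.zeros(len(tissues), dtype=np.int64)
    f_c_sum_le = np.zeros(len(tissues), dtype=np.int64)

    # group the pair genes by exon count; per iteration sample the same
    # number of control genes from the matching bucket, without replacement
    # inside an iteration.  When a bucket cannot supply the demand the pool
    # is widened to the nearest exon counts until it can.
    demand: dict[int, int] = {}
    for g in pair_known:
        c = int(gene_exons.get(g, 1))
        if c not in buckets:
            c = min(counts_sorted, key=lambda b: abs(b - c))
        demand[c] = demand.get(c, 0) + 1
    need: dict[tuple[int, ...], int] = {}
    total_pool = sum(len(v) for v in buckets.values())
    for c, m in demand.items():
        widths = sorted(counts_sorted, key=lambda b: (abs(b - c), b))
        chosen: list[int] = []
        size = 0
        for b in widths:
            chosen.append(b)
            size += len(buckets[b])
            if size >= m:
                break
        if size < m:
            raise ValueError(
                f"control pool too small: need {m} genes near exon count {c}, "
                f"have {total_pool} in total"
            )
        need[tuple(chosen)] = need.get(tuple(chosen), 0) + m

    chunk = max(1, min(iterations, int(2e7 // max(1, n_e * len(tissues)))))
    done = 0
    while done < iterations:
        it = min(chunk, iterations - done)
        spec_sum = np.zeros((it, len(tissues)), dtype=np.int32)
        for key, m in need.items():
            pool = np.concatenate([buckets[b] for b in key])
            keys = rng.random((it, len(pool)))
            take = np.argpartition(keys, m - 1, axis=1)[:, :m]
            sel = pool[take]  # (it, m) row indices
            spec_sum += spec_np[sel].sum(axis=1)
        f_c = spec_sum / n_e
        f_c_sum_ge += (f_c >= f_e - 1e-12).sum(axis=0)
        f_c_sum_le += (f_c <= f_e + 1e-12).sum(axis=0)
        done += it

    p_enrich = pd.Series((f_c_sum_ge + 1) / (iterations + 1), index=tissues)
    p_deplete = pd.Series((f_c_sum_le + 1) / (iterations + 1), index=tissues)
    return TissueBiasResult(
        u, d, len(pair_known), pd.Series(f_e, index=tissues),
        p_enrich, p_deplete, iterations, cutoff,
    )


def concordance_binomial(bias_result: TissueBiasResult, rbp_profile: pd.Series) -> dict:
    """One-sided binomial concordance of the pair's significant tissues with
    an RNA-binding protein's expression profile.

    A significant tissue is concordant when the protein's expression there
    deviates from its own cross-tissue median in the matching direction
    (above for enriched tissues, below for depleted).  Returns the concordant
    count, total and the binomial tail p at success probability 0.5; with no
    significant tissue the result is flagged undefined.
    """
    med = rbp_profile.median()
    n = conc = 0
    for t in bias_result.enriched_tissues:
        if t in rbp_profile.index:
            n += 1
            conc += rbp_profile[t] > med
    for t in bias_result.depleted_tissues:
        if t in rbp_profile.index:
            n += 1
            conc += rbp_profile[t] < med
    if n == 0:
        return dict(n_significant=0, n_concordant=0, p_value=float("nan"), flagged=True)
    p = float(stats.binom.sf(conc - 1, n, 0.5))
    return dict(n_significant=n, n_concordant=int(conc), p_value=p, flagged=False)
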