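"""Evolutionary conservation of motif pairing and SNP density of paired motifs.

Pairing conservation is an alignment-free conditional proportion: among human
exons carrying a co-occurring pair whose downstream motif is found anywhere in
the corresponding window of the ortholog flank, how often is the upstream
partner also found (and vice versa)?  Controls replace one motif with a
same-G+C k-mer that does not significantly co-occur with the partner
(p_upper > 0.05).

SNP density compares, for the same motif set, the proportion of motif
occurrences containing >=1 SNP when the occurrence is part of a co-occurring
pair versus when the motif is alone — purifying selection on functional pairs
predicts the paired proportion to be lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .exon_model import ExonRecord, RegionPairConfig, extract_region, gc_count
from .pair_stats import ScanResult, index_motif


@dataclass
class ConservationResult:
    region_pair: str
    direction: str  # "upstream_given_downstream" | "downstream_given_upstream"
    proportion: float
    n_conditioned: int
    n_conserved: int
    flagged: bool = False  # conditioning event empty -> proportion undefined


def _ortholog_lookup(orthologs) -> Mapping[str, tuple[str, str]]:
    if isinstance(orthologs, pd.DataFrame):
        return {
            r.exon_id: (r.up_flank, r.down_flank) for r in orthologs.itertuples()
        }
    return orthologs


def _region_window(flank: str, spec) -> str:
    if spec.side == "upstream":
        lo = len(flank) + spec.start_offset
        hi = len(flank) + spec.end_offset + 1
    else:
        lo = spec.start_offset - 1
        hi = spec.end_offset
    if lo < 0:
        raise ValueError("ortholog flank too short for region window")
    return flank[lo:hi]


def pairing_conservation(
    corpus: Sequence[ExonRecord],
    orthologs,
    pairs: Sequence[tuple[str, str]],
    region_pair: RegionPairConfig,
    direction: str = "upstream_given_downstream",
) -> ConservationResult:
    """Conditional conservation proportion over all (exon, pair) events.

    A motif is conserved iff it occurs anywhere in the ortholog's
    corresponding region window (no alignment).  The conditioning event is
    conservation of the downstream motif (direction upstream_given_downstream)
    or of the upstream motif (the reverse); the success event is conservation
    of the partner."""
    if direction not in ("upstream_given_downstream", "downstream_given_upstream"):
        raise ValueError(f"unknown direction {direction!r}")
    lut = _ortholog_lookup(orthologs)
    n_cond = n_cons = 0
    for e in corpus:
        if e.exon_id not in lut:
            continue
        up = extract_region(e, region_pair.upstream)
        down = extract_region(e, region_pair.downstream)
        o_up, o_down = lut[e.exon_id]
        w_up = _region_window(o_up, region_pair.upstream)
        w_down = _region_window(o_down, region_pair.downstream)
        for u, d in pairs:
            if u not in up or d not in down:
                continue  # this exon does not carry the pair
            if direction == "upstream_given_downstream":
                cond, succ = d in w_down, u in w_up
            else:
                cond, succ = u in w_up, d in w_down
            if cond:
                n_cond += 1
                n_cons += succ
    if n_cond == 0:
        return ConservationResult(region_pair.label, direction, float("nan"), 0, 0, True)
    return ConservationResult(region_pair.label, direction, n_cons / n_cond, n_cond, n_cons)


def conservation_vs_control(
    corpus,
    orthologs,
    pairs,
    control_pairs,
    region_pair,
    direction="upstream_given_downstream",
) -> dict:
    """Co-occurring versus control conservation with a two-proportion z-test."""
    obs = pairing_conservation(corpus, orthologs, pairs, region_pair, direction)
    ctl = pairing_conservation(corpus, orthologs, control_pairs, region_pair, direction)
    if obs.flagged or ctl.flagged:
        return dict(observed=obs, control=ctl, p_value=float("nan"))
    stat, p = proportions_ztest(
        [obs.n_conserved, ctl.n_conserved], [obs.n_conditioned, ctl.n_conditioned]
    )
    return dict(observed=obs, control=ctl, p_value=float(p))


def select_control_motifs(
    pairs: Sequence[tuple[str, str]],
    pvalue_of: "Callable[[str, str], float] | ScanResult",
    *,
    side: str = "upstream",
    seed: int = 0,
    p_threshold: float = 0.05,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Replace one motif of each pair by a same-G+C-count k-mer that does NOT
    co-occur with the partner (p_upper > 0.05), chosen uniformly at random
    among qualifiers.

    ``pvalue_of`` maps (motif_u, motif_d) to the pair's p_upper; a ScanResult
    run with emit_all serves directly.  Returns (control pairs, dropped pairs
    for which no k-mer qualified).
    """
    if isinstance(pvalue_of, ScanResult):
        scan = pvalue_of
        pvalue_of = scan.pvalue
    rng = np.random.default_rng(seed)
    controls, dropped = [], []
    for u, d in pairs:
        replaced = u if side == "upstream" else d
        k = len(replaced)
        target_gc = gc_count(replaced)
        qualifiers = []
        for idx in range(4**k):
            cand = index_motif(idx, k)
            if cand == replaced or gc_count(cand) != target_gc:
                continue
            p = pvalue_of(cand, d) if side == "upstream" else pvalue_of(u, cand)
            if p > p_threshold:
                qualifiers.append(cand)
        if not qualifiers:
            dropped.append((u, d))
            continue
        chosen = qualifiers[rng.integers(len(qualifiers))]
        controls.append((chosen, d) if side == "upstream" else (u, chosen))
    return controls, dropped


# ---------------------------------------------------------------------------
# SNP density
# ---------------------------------------------------------------------------


@dataclass
class SnpDensityResult:
    n_paired: int
    n_alone: int
    prop_paired: float  # proportion of occurrences containing >=1 SNP
    prop_alone: float
    se_paired: float
    se_alone: float
    p_value: float
    flagged: bool = False  # an occurrence class was empty -> no test


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n)) if n else float("nan")


def snp_motif_density(
    corpus: Sequence[ExonRecord],
    snp_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    region_pair: RegionPairConfig,
) -> SnpDensityResult:
    """SNP density of motif occurrences when paired versus alone.

    An occurrence of a pair's motif is "paired" when the partner motif is
    present in the partner region of the same exon, else "alone"; it contains
    a SNP when any of its k positions carries one.  SNP offsets are
    splice-site-relative flank coordinates (negative upstream / positive
    downstream) with ``side`` in {up, down}.
    """
    snp_by_exon: dict[tuple[str, str], set[int]] = {}
    for r in snp_table.itertuples():
        snp_by_exon.setdefault((r.exon_id, r.side), set()).add(int(r.offset))

    counts = {True: [0, 0], False: [0, 0]}  # paired -> [occurrences, with snp]

    def occurrence_offsets(region_seq: str, spec, motif: str):
        k = len(motif)
        start = region_seq.find(motif)
        while start != -1:
            if spec.side == "upstream":
                first = spec.start_offset + start
            else:
                first = spec.start_offset + start
            yield range(first, first + k)
            start = region_seq.find(motif, start + 1)

    for e in corpus:
        up = extract_region(e, region_pair.upstream)
        down = extract_region(e, region_pair.downstream)
        snps_up = snp_by_exon.get((e.exon_id, "up"), set())
        snps_down = snp_by_exon.get((e.exon_id, "down"), set())
        for u, d in pairs:
            u_present, d_present = u in up, d in down
            for offsets in occurrence_offsets(up, region_pair.upstream, u):
                paired = d_present
                counts[paired][0] += 1
                counts[paired][1] += any(o in snps_up for o in offsets)
            for offsets in occurrence_offsets(down, region_pair.downstream, d):
                paired = u_present
                counts[paired][0] += 1
                counts[paired][1] += any(o in snps_down for o in offsets)

    n_paired, hit_paired = counts[True]
    n_alone, hit_alone = counts[False]
    if n_paired == 0 or n_alone == 0:
        return SnpDensityResult(
            n_paired, n_alone,
            hit_paired / n_paired if n_paired else float("nan"),
            hit_alone / n_alone if n_alone else float("nan"),
            float("nan"), float("nan"), float("nan"), True,
        )
    pp, pa = hit_paired / n_paired, hit_alone / n_alone
    if hit_paired + hit_alone == 0:
        p = 1.0
    else:
        _, p = proportions_ztest([hit_paired, hit_alone], [n_paired, n_alone])
    return SnpDensityResult(
        n_paired, n_alone, pp, pa, _binom_se(pp, n_paired), _binom_se(pa, n_alone), float(p)
    )
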