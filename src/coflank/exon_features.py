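"""Exon-strength covariates and the with/without-pairs comparison.

Exons carrying co-occurring motif pairs are compared to a GC-matched set of
exons without any, on splicing-strength features: coverage of the exon by
enhancer (ESE) and silencer (ESS) hexamers, and splice-site consensus values.
GC matching is exact on the integer G+C counts of both relevant intronic
regions, so base composition cannot confound the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exon_model import (
    ExonRecord,
    RegionPairConfig,
    SpliceSitePWM,
    extract_region,
    gc_count,
    score_splice_site,
)
from .pair_stats import ScanResult


@dataclass(frozen=True)
class HexamerSet:
    label: str
    hexamers: frozenset

    def __post_init__(self) -> None:
        for h in self.hexamers:
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ValueError(f"{self.label}: invalid hexamer {h!r}")

    @classmethod
    def from_iterable(cls, label: str, items) -> "HexamerSet":
        return cls(label, frozenset(str(s).strip().upper() for s in items))


def motif_coverage(exon_seq: str, hexamers: HexamerSet) -> float:
    """Fraction of exonic nucleotides inside >=1 occurrence of any set member
    (union of occupied intervals)."""
    n = len(exon_seq)
    if n < 6:
        warnings.warn(f"exon of length {n} < 6: coverage 0", stacklevel=2)
        return 0.0
    covered = np.zeros(n, dtype=bool)
    for i in range(n - 5):
        if exon_seq[i : i + 6] in hexamers.hexamers:
            covered[i : i + 6] = True
    return covered.sum() / n


def exons_with_pairs(
    corpus: Sequence[ExonRecord],
    scan_result: ScanResult,
    pair_config: RegionPairConfig,
) -> np.ndarray:
    """Boolean mask: exon carries >=1 significant pair (both motifs jointly
    present in its two regions)."""
    pairs = scan_result.significant_pairs()
    mask = np.zeros(len(corpus), dtype=bool)
    for i, e in enumerate(corpus):
        up = extract_region(e, pair_config.upstream)
        down = extract_region(e, pair_config.downstream)
        mask[i] = any(u in up and d in down for u, d in pairs)
    return mask


def gc_matched_partition(
    corpus: Sequence[ExonRecord],
    scan_result: ScanResult,
    pair_config: RegionPairConfig,
    *,
    seed: int = 0,
) -> tuple[list[ExonRecord], list[ExonRecord], list[str]]:
    """Split the corpus into exons with significant pairs and a matched set
    without any, exactly matched on the integer G+C counts of both regions.

    Matching is greedy without replacement within each (gc_up, gc_down)
    class, seeded for determinism; unmatched exons are dropped and returned
    in the log.
    """
    rng = np.random.default_rng(seed)
    mask = exons_with_pairs(corpus, scan_result, pair_config)
    key = [
        (
            gc_count(extract_region(e, pair_config.upstream)),
            gc_count(extract_region(e, pair_config.downstream)),
        )
        for e in corpus
    ]
    pool: dict[tuple[int, int], list[int]] = {}
    for i in np.flatnonzero(~mask):
        pool.setdefault(key[i], []).append(i)
    for members in pool.values():
        rng.shuffle(members)
    with_pairs, without_pairs, dropped = [], [], []
    for i in np.flatnonzero(mask):
        bucket = pool.get(key[i])
        if bucket:
            j = bucket.pop()
            with_pairs.append(corpus[i])
            without_pairs.append(corpus[j])
        else:
            dropped.append(corpus[i].exon_id)
    return with_pairs, without_pairs, dropped


def _features(
    exons: Sequence[ExonRecord],
    hexamer_sets: Sequence[HexamerSet],
    pwms: dict[str, SpliceSitePWM],
) -> pd.DataFrame:
    rows = []
    for e in exons:
        row = {f"{hs.label}_coverage": motif_coverage(e.exon_seq, hs) for hs in hexamer_sets}
        if "acceptor" in pwms and e.acceptor_window:
            row["acceptor_cv"] = score_splice_site(e.acceptor_window, pwms["acceptor"])
        if "donor" in pwms and e.donor_window:
            row["donor_cv"] = score_splice_site(e.donor_window, pwms["donor"])
        rows.append(row)
    return pd.DataFrame(rows)


def compare_exon_strength(
    set_a: Sequence[ExonRecord],
    set_b: Sequence[ExonRecord],
    hexamer_sets: Sequence[HexamerSet],
    pwms: dict[str, SpliceSitePWM],
    *,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-feature group means, standard errors and two-sided p-values.

    ``test`` is "welch" (unequal-variance t-test, default) or "mannwhitney".
    """
    if not len(set_a) or not len(set_b):
        raise ValueError("both exon sets must be non-empty")
    fa = _features(set_a, hexamer_sets, pwms)
    fb = _features(set_b, hexamer_sets, pwms)
    rows = []
    for col in fa.columns:
        a, b = fa[col].to_numpy(), fb[col].to_numpy()
        if test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif test == "mannwhitney":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ValueError("test must be 'welch' or 'mannwhitney'")
        if np.allclose(a.mean(), b.mean()) and np.isnan(p):
            p = 1.0  # zero-variance identical groups
        rows.append(
            dict(
                feature=col,
                mean_a=a.mean(), sem_a=stats.sem(a) if len(a) > 1 else np.nan,
                mean_b=b.mean(), sem_b=stats.sem(b) if len(b) > 1 else np.nan,
                p_value=p, n_a=len(a), n_b=len(b),
            )
        )
    return pd.DataFrame(rows)


def normalize_for_display(value_a: float, value_b: float) -> tuple[float, float]:
    """Scale a two-group comparison for display: subtract the midpoint of the
    two values and divide by the maximum absolute deviation from it, mapping
    the pair onto [-1, +1] (both 0 when the values coincide)."""
    mid = (value_a + value_b) / 2.0
    dev = max(abs(value_a - mid), abs(value_b - mid))
    if dev == 0:
        return 0.0, 0.0
    return (value_a - mid) / dev, (value_b - mid) / dev


# ---------------------------------------------------------------------------
# Pair-list summaries (sequence characteristics of a discovered-pair table)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pair_list_summary(pairs: pd.DataFrame) -> dict:
    """Sequence characteristics of a discovered-pair list.

    ``pairs`` needs columns motif_u, motif_d and optionally region_pair /
    splice_class.  Reports: total pair count, number of perfectly
    reverse-complementary pairs (a secondary-structure signature), fraction
    of individual motifs containing a CpG dinucleotide, and per-region
    counts.
    """
    n = len(pairs)
    rc = sum(
        1 for u, d in zip(pairs["motif_u"], pairs["motif_d"]) if d == reverse_complement(u)
    )
    motifs = pd.concat([pairs["motif_u"], pairs["motif_d"]])
    cpg_fraction = float(np.mean([("CG" in m) for m in motifs])) if n else float("nan")
    by_region = (
        pairs.groupby("region_pair").size().to_dict() if "region_pair" in pairs else {}
    )
    return dict(
        n_pairs=n,
        n_reverse_complementary=rc,
        cpg_motif_fraction=cpg_fraction,
        pairs_per_region=by_region,
    )
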