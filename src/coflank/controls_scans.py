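"""Negative controls and window-placement scans.

The GC-balanced shuffle exchanges the 50-nt region sequence of an exon with
that of another exon having the same integer G+C count, on each side
independently.  This destroys any specific upstream/downstream pairing while
preserving every single-region statistic (GC histogram, per-motif marginal
counts) exactly, so a rescan of a shuffled corpus measures the method's
false-positive background.

The distance scan moves symmetric 50-nt windows away from the exon borders to
map how far from the splice sites co-occurring pairs extend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exon_model import (
    DP,
    ExonRecord,
    RegionPairConfig,
    RegionSpec,
    UP,
    extract_region,
    gc_count,
)
from .pair_stats import ScanResult, default_alpha, scan_pairs


def _replace_region(exon: ExonRecord, spec: RegionSpec, new_seq: str) -> ExonRecord:
    if spec.side == "upstream":
        flank = exon.up_flank
        lo = len(flank) + spec.start_offset
        hi = len(flank) + spec.end_offset + 1
        return replace(exon, up_flank=flank[:lo] + new_seq + flank[hi:])
    flank = exon.down_flank
    lo = spec.start_offset - 1
    hi = spec.end_offset
    return replace(exon, down_flank=flank[:lo] + new_seq + flank[hi:])


def gc_balanced_shuffle(
    corpus: Sequence[ExonRecord],
    region_specs: Sequence[RegionSpec] | RegionSpec,
    seed: int,
) -> list[ExonRecord]:
    """Permute region sequences uniformly at random within classes of equal
    integer G+C count.  Pass both windows of a pairing to randomize both
    sides; all other exon fields are untouched.  Regions containing N keep
    their own sequence (they are excluded from scans anyway)."""
    if isinstance(region_specs, RegionSpec):
        region_specs = [region_specs]
    rng = np.random.default_rng(seed)
    current = list(corpus)
    for spec in region_specs:
        regions = [extract_region(e, spec) for e in current]
        classes: dict[int, list[int]] = {}
        for i, seq in enumerate(regions):
            if "N" in seq:
                continue
            classes.setdefault(gc_count(seq), []).append(i)
        assignment = list(range(len(current)))
        for members in classes.values():
            perm = rng.permutation(len(members))
            for a, b in zip(members, perm):
                assignment[a] = members[b]
        current = [
            _replace_region(e, spec, regions[assignment[i]])
            for i, e in enumerate(current)
        ]
    return current


def shuffle_control_counts(
    corpus: Sequence[ExonRecord],
    pair_config: RegionPairConfig,
    seeds: Sequence[int],
    k: int = 5,
    *,
    n_bins: int = 20,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Run the full scan on repeated GC-balanced shuffles of both regions and
    report the significant-pair count per shuffle; the mean approximates the
    method's false-positive background (about one pair at alpha=1/4^(2k))."""
    rows = []
    for seed in seeds:
        shuffled = gc_balanced_shuffle(
            corpus, [pair_config.upstream, pair_config.downstream], seed
        )
        res = scan_pairs(shuffled, pair_config, k, n_bins=n_bins, alpha=alpha)
        rows.append(dict(seed=seed, n_significant=res.n_significant))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance scan
# ---------------------------------------------------------------------------


def symmetric_pair_config(distance: int, window: int = 50) -> RegionPairConfig:
    """Symmetric 50-nt windows at ``distance`` nt from the exon borders.

    distance 0 denotes the border windows, which respect the consensus
    exclusion zones (upstream ends at -15, downstream starts at +7, matching
    Up/Dp); farther windows are pure 50-nt blocks [-(d+49), -d] / [+d, +d+49].
    """
    if distance == 0:
        return RegionPairConfig(UP, DP, label="d0")
    up = RegionSpec(f"U@{distance}", "upstream", -(distance + window - 1), -distance)
    down = RegionSpec(f"D@{distance}", "downstream", distance, distance + window - 1)
    return RegionPairConfig(up, down, label=f"d{distance}")


@dataclass
class DistanceScanResult:
    k: int
    alpha: float
    table: pd.DataFrame  # columns: distance, n_significant, ok


def distance_scan(
    corpus: Sequence[ExonRecord],
    distances: Sequence[int],
    k: int = 5,
    alpha: float | None = None,
    *,
    n_bins: int = 20,
) -> DistanceScanResult:
    """Significant-pair counts for symmetric window pairs at each distance.

    A distance whose windows exceed the stored flanks is reported with
    ok=False rather than silently skipped.
    """
    if alpha is None:
        alpha = default_alpha(k)
    rows = []
    for d in distances:
        cfg = symmetric_pair_config(d)
        depth = max(cfg.upstream.max_depth, cfg.downstream.max_depth)
        flanks_ok = all(
            len(e.up_flank) >= depth and len(e.down_flank) >= depth for e in corpus
        )
        if not flanks_ok:
            rows.append(dict(distance=d, n_significant=-1, ok=False))
            continue
        res = scan_pairs(corpus, cfg, k, n_bins=n_bins, alpha=alpha)
        rows.append(dict(distance=d, n_significant=res.n_significant, ok=True))
    return DistanceScanResult(k, alpha, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Positional distributions
# ---------------------------------------------------------------------------


def positional_distribution(
    motifs: Sequence[str] | ScanResult,
    corpus: Sequence[ExonRecord],
    region_spec: RegionSpec,
) -> pd.DataFrame:
    """Per-position occurrence counts of each motif within its region,
    positions numbered 1.. from the exon-proximal end.

    The position of an occurrence is that of its most exon-proximal base:
    for an upstream region, proximal is the 3' end of the window; for a
    downstream region, the 5' end.  Column sums equal total occurrence
    counts over the corpus.
    """
    if isinstance(motifs, ScanResult):
        side_attr = "motif_u" if region_spec.side == "upstream" else "motif_d"
        motif_list = sorted(set(motifs.table[side_attr]))
    else:
        motif_list = list(motifs)
    if not motif_list:
        return pd.DataFrame()
    k = len(motif_list[0])
    L = region_spec.length
    counts = {m: np.zeros(L - k + 1, dtype=np.int64) for m in motif_list}
    for e in corpus:
        region = extract_region(e, region_spec)
        for m in motif_list:
            start = region.find(m)
            while start != -1:
                if region_spec.side == "upstream":
                    pos = L - (start + k - 1)  # proximal = right end
                else:
                    pos = start + 1  # proximal = left end
                counts[m][pos - 1] += 1
                start = region.find(m, start + 1)
    return pd.DataFrame(counts, index=pd.RangeIndex(1, L - k + 2, name="position"))
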