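"""Domain types and sequence-level operations for exons and their intronic flanks.

Coordinates are splice-site-relative and 1-based in magnitude, both endpoints
inclusive.  Upstream intron positions are negative, counted toward -1 which is
the intron base immediately adjacent to the exon (the G of the acceptor AG);
downstream positions are positive, +1 being the first intron base after the
exon (the G of the donor GT).  All sequences are stored 5'->3' in transcript
orientation; minus-strand genome features must be reverse-complemented before
an :class:`ExonRecord` is built (see :mod:`coflank.cli_io`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SPLICE_CLASSES = ("constitutive", "alt_cassette", "alt_3ss", "alt_5ss", "pseudo")
VALID_BASES = frozenset("ACGTN")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class InsufficientFlankError(ValueError):
    """Raised when a flank is too short to cover a requested region window."""


@dataclass(frozen=True)
class ExonRecord:
    """One exon with its splice classification and intronic context.

    ``up_flank`` ends at intron position -1 (immediately before the 3' splice
    site); ``down_flank`` starts at intron position +1 (immediately after the
    5' splice site).  ``acceptor_window`` / ``donor_window`` span the splice
    sites themselves and are used only for consensus-value scoring.
    """

    exon_id: str
    gene_id: str
    splice_class: str
    exon_seq: str
    up_flank: str
    down_flank: str
    acceptor_window: str = ""
    donor_window: str = ""

    def __post_init__(self) -> None:
        if self.splice_class not in SPLICE_CLASSES:
            raise ValueError(
                f"exon {self.exon_id}: unknown splice_class {self.splice_class!r}"
            )
        for name in ("exon_seq", "up_flank", "down_flank"):
            seq = getattr(self, name)
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(
                    f"exon {self.exon_id}: {name} contains invalid characters {bad}"
                )


@dataclass(frozen=True)
class RegionSpec:
    """A named window in splice-site-relative coordinates, both ends inclusive.

    Upstream windows use negative offsets with ``start_offset < end_offset <= -1``
    (e.g. Up = [-64, -15]); downstream windows use positive offsets with
    ``1 <= start_offset < end_offset`` (e.g. Dp = [+7, +56]).
    """

    name: str
    side: str  # "upstream" | "downstream"
    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"region {self.name}: side must be upstream/downstream")
        if self.end_offset < self.start_offset:
            raise ValueError(f"region {self.name}: end_offset < start_offset")
        if self.side == "upstream" and self.end_offset > -1:
            raise ValueError(f"region {self.name}: upstream offsets must be <= -1")
        if self.side == "downstream" and self.start_offset < 1:
            raise ValueError(f"region {self.name}: downstream offsets must be >= +1")

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset + 1

    @property
    def max_depth(self) -> int:
        """Minimum flank length needed to cover this window."""
        if self.side == "upstream":
            return -self.start_offset
        return self.end_offset


# Default windows: the upstream search space excludes the polypyrimidine
# tract (-14..-1) and the downstream space excludes the donor consensus
# (+1..+6), so proximal windows start at -15 / +7.
UD = RegionSpec("Ud", "upstream", -100, -51)
UP = RegionSpec("Up", "upstream", -64, -15)
DP = RegionSpec("Dp", "downstream", 7, 56)
DD = RegionSpec("Dd", "downstream", 51, 100)


@dataclass(frozen=True)
class RegionPairConfig:
    """An (upstream window, downstream window) pairing such as UpDp."""

    upstream: RegionSpec
    downstream: RegionSpec
    label: str = ""

    def __post_init__(self) -> None:
        if self.upstream.side != "upstream" or self.downstream.side != "downstream":
            raise ValueError("RegionPairConfig needs one upstream and one downstream window")
        if not self.label:
            object.__setattr__(self, "label", self.upstream.name + self.downstream.name)


UPDP = RegionPairConfig(UP, DP)
UPDD = RegionPairConfig(UP, DD)
UDDP = RegionPairConfig(UD, DP)
UDDD = RegionPairConfig(UD, DD)
DEFAULT_PAIRINGS = (UPDP, UPDD, UDDP, UDDD)

REGIONS_BY_NAME = {r.name: r for r in (UD, UP, DP, DD)}
PAIRINGS_BY_LABEL = {p.label: p for p in DEFAULT_PAIRINGS}


def extract_region(exon: ExonRecord, spec: RegionSpec) -> str:
    """Return the flank substring covered by ``spec``, in transcript orientation."""
    flank = exon.up_flank if spec.side == "upstream" else exon.down_flank
    if len(flank) < spec.max_depth:
        raise InsufficientFlankError(
            f"exon {exon.exon_id}: {spec.side} flank of length {len(flank)} "
            f"cannot cover region {spec.name} [{spec.start_offset},{spec.end_offset}]"
        )
    if spec.side == "upstream":
        # position -1 is the last flank character
        lo = len(flank) + spec.start_offset
        hi = len(flank) + spec.end_offset + 1
    else:
        lo = spec.start_offset - 1
        hi = spec.end_offset
    return flank[lo:hi]


def gc_content(seq: str) -> float:
    """(#G + #C) / counted length; N bases are excluded from the denominator."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    n_count = seq.count("N")
    counted = len(seq) - n_count
    if counted == 0:
        raise ValueError("gc_content: sequence is all N")
    return (seq.count("G") + seq.count("C")) / counted


def gc_count(seq: str) -> int:
    """Integer G+C count, the unit used for shuffle classes and GC matching."""
    return seq.count("G") + seq.count("C")


# ---------------------------------------------------------------------------
# Splice-site scoring (position-specific weight matrix, consensus value 0-100)
# ---------------------------------------------------------------------------

# Window extents: acceptor = intron -14..-1 plus the first exon base
# (15 positions); donor = last 3 exon bases plus intron +1..+6 (9 positions).
ACCEPTOR_POSITIONS = tuple(range(-14, 0)) + (1,)
DONOR_POSITIONS = (-3, -2, -1, 1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SpliceSitePWM:
    """Per-position base frequencies behind a 0-100 consensus value (CV).

    ``s_min``/``s_max`` are the minimal and maximal attainable frequency sums
    used for 0-100 scaling; the minimum at each position is taken over the
    observed (nonzero-frequency) bases, so an unobserved base scores below
    s_min and the CV is clamped at 0.
    """

    site_kind: str  # "acceptor" | "donor"
    window_positions: tuple
    freq: np.ndarray  # (n_positions, 4) rows sum to 1, columns ordered ACGT
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("freq must have shape (n_positions, 4)")
        if not np.allclose(freq.sum(axis=1), 1.0):
            raise ValueError("per-position frequencies must sum to 1")
        object.__setattr__(self, "freq", freq)
        masked = np.where(freq > 0, freq, np.inf)
        object.__setattr__(self, "s_min", float(masked.min(axis=1).sum()))
        object.__setattr__(self, "s_max", float(freq.max(axis=1).sum()))
        # s_min == s_max only for the fully degenerate corpus (every window
        # identical); scoring then returns 100 for the consensus window

    @property
    def length(self) -> int:
        return self.freq.shape[0]


def estimate_pwm(
    windows: Iterable[str],
    site_kind: str,
    *,
    on_n: str = "error",
) -> SpliceSitePWM:
    """Estimate a splice-site PWM from aligned windows of a corpus.

    ``windows`` may be raw strings or :class:`ExonRecord` objects (in which
    case ``acceptor_window``/``donor_window`` is used).  ``on_n`` controls
    windows containing N: ``"error"`` raises, ``"drop"`` excludes them.
    """
    attr = "acceptor_window" if site_kind == "acceptor" else "donor_window"
    seqs = []
    for w in windows:
        seq = getattr(w, attr, w)
        if "N" in seq:
            if on_n == "drop":
                continue
            raise ValueError(f"window {seq!r} contains N")
        seqs.append(seq)
    if not seqs:
        raise ValueError("estimate_pwm: empty corpus")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("estimate_pwm: windows have unequal lengths")
    counts = np.zeros((length, 4), dtype=float)
    for seq in seqs:
        for pos, base in enumerate(seq):
            counts[pos, _BASE_INDEX[base]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    positions = (
        ACCEPTOR_POSITIONS if site_kind == "acceptor" else DONOR_POSITIONS
    )
    if length != len(positions):
        positions = tuple(range(length))
    return SpliceSitePWM(site_kind, positions, freq)


def score_splice_site(window: str, pwm: SpliceSitePWM) -> float:
    """Consensus value cv = 100 * (s - s_min) / (s_max - s_min), s = sum of freqs."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} does not match PWM length {pwm.length}"
        )
    s = 0.0
    for pos, base in enumerate(window):
        if base == "N":
            raise ValueError("cannot score a window containing N")
        s += pwm.freq[pos, _BASE_INDEX[base]]
    if pwm.s_max == pwm.s_min:
        return 100.0 if s >= pwm.s_max else 0.0
    return float(np.clip(100.0 * (s - pwm.s_min) / (pwm.s_max - pwm.s_min), 0.0, 100.0))


def classify_pseudo_exon(
    candidate,
    acceptor_cv: float,
    donor_cv: float,
    distance_to_nearest_real_exon: int,
    *,
    min_len: int = 50,
    max_len: int = 250,
    min_acceptor_cv: float = 75.0,
    min_donor_cv: float = 78.0,
    min_distance: int = 100,
) -> bool:
    """Exon-like intronic decoy test: length 50-250, CV >= 75 (3'ss) and
    >= 78 (5'ss), >= 100 nt from the nearest real exon, canonical AG/GT
    bounding dinucleotides.  All thresholds boundary-inclusive."""
    length = len(candidate.exon_seq)
    canonical = candidate.up_flank.endswith("AG") and candidate.down_flank.startswith(
        "GT"
    )
    return (
        min_len <= length <= max_len
        and acceptor_cv >= min_acceptor_cv
        and donor_cv >= min_donor_cv
        and distance_to_nearest_real_exon >= min_distance
        and canonical
    )


def find_pseudo_splice_sites(
    exon: ExonRecord,
    side: str,
    pwms: dict,
    *,
    min_distance: int = 100,
) -> list[tuple[int, float]]:
    """Scan a flank for decoy splice sites at least as strong as the authentic one.

    For ``side == "upstream"`` the up_flank is scanned for AG-anchored acceptor
    candidates; the returned offset is the splice-site-relative position of the
    candidate's last intron base (the G of AG), e.g. -150.  For
    ``side == "downstream"`` the down_flank is scanned for GT-anchored donor
    candidates and the offset is that of the candidate's first intron base
    (the G of GT).  Candidates closer than ``min_distance`` to the authentic
    site, or whose CV is below the authentic CV, are excluded.
    """
    results: list[tuple[int, float]] = []
    if side == "upstream":
        pwm = pwms["acceptor"]
        authentic_cv = score_splice_site(exon.acceptor_window, pwm)
        flank = exon.up_flank
        L = len(flank)
        # candidate -1 at flank index i; window = flank[i-13 : i+1] + flank[i+1]
        for i in range(13, L - 1):
            if flank[i - 1 : i + 1] != "AG":
                continue
            offset = i - L  # splice-site-relative position of the G
            if -offset < min_distance:
                continue
            window = flank[i - 13 : i + 2]
            if "N" in window or len(window) != pwm.length:
                continue
            cv = score_splice_site(window, pwm)
            if cv >= authentic_cv:
                results.append((offset, cv))
    elif side == "downstream":
        pwm = pwms["donor"]
        authentic_cv = score_splice_site(exon.donor_window, pwm)
        flank = exon.down_flank
        L = len(flank)
        # candidate +1 at flank index j; window = flank[j-3 : j+6]
        for j in range(3, L - 6):
            if flank[j : j + 2] != "GT":
                continue
            offset = j + 1
            if offset < min_distance:
                continue
            window = flank[j - 3 : j + 6]
            if "N" in window or len(window) != pwm.length:
                continue
            cv = score_splice_site(window, pwm)
            if cv >= authentic_cv:
                results.append((offset, cv))
    else:
        raise ValueError("side must be 'upstream' or 'downstream'")
    return results


# ---------------------------------------------------------------------------
# Corpus filtering
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k])


def _shift_within(a: str, b: str, max_shift: int, anchor: str) -> bool:
    """True when b equals a shifted by <= max_shift nt.

    ``anchor == "suffix"`` compares flanks whose distal ends differ (alt
    acceptor sites: one up_flank is the other slid toward the exon);
    ``anchor == "prefix"`` is the mirrored case for alt donor sites.
    """
    for s in range(1, max_shift + 1):
        if anchor == "suffix":
            if a[s:] == b[: len(b) - s] or b[s:] == a[: len(a) - s]:
                return True
        else:
            if a[: len(a) - s] == b[s:] or b[: len(b) - s] == a[s:]:
                return True
    return False


def _dedup_alt_sites(
    exons: list[ExonRecord], rng: np.random.Generator, log: list
) -> list[ExonRecord]:
    """Among alternative 3' (resp. 5') splice sites of the same exon within
    50 nt, keep one record chosen at random.

    Records carry no genomic coordinates, so co-membership is inferred from
    the sequences: alt-3'ss records of one gene share the downstream flank
    and have upstream flanks that are shifted copies of each other (shift =
    the distance between the two acceptor sites); symmetrically for alt-5'ss.
    """
    keep: dict[str, ExonRecord] = {e.exon_id: e for e in exons}
    for splice_class, shared_attr, moving_attr, anchor in (
        ("alt_3ss", "down_flank", "up_flank", "suffix"),
        ("alt_5ss", "up_flank", "down_flank", "prefix"),
    ):
        groups: dict[tuple, list[ExonRecord]] = {}
        for e in exons:
            if e.splice_class == splice_class:
                groups.setdefault((e.gene_id, getattr(e, shared_attr)), []).append(e)
        for members in groups.values():
            if len(members) < 2:
                continue
            members = sorted(members, key=lambda e: e.exon_id)
            # union-find over pairs whose moving flank shifts match within 50 nt
            parent = list(range(len(members)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i, j in itertools.combinations(range(len(members)), 2):
                a = getattr(members[i], moving_attr)
                b = getattr(members[j], moving_attr)
                if a == b or _shift_within(a, b, 50, anchor):
                    parent[find(i)] = find(j)
            clusters: dict[int, list[ExonRecord]] = {}
            for i, e in enumerate(members):
                clusters.setdefault(find(i), []).append(e)
            for cluster in clusters.values():
                if len(cluster) < 2:
                    continue
                chosen = cluster[rng.integers(len(cluster))]
                for e in cluster:
                    if e.exon_id != chosen.exon_id and e.exon_id in keep:
                        del keep[e.exon_id]
                        log.append((e.exon_id, "alt_site_dedup"))
    return [e for e in exons if e.exon_id in keep]


def _purge_similar(
    exons: list[ExonRecord],
    pair_config: RegionPairConfig,
    k: int,
    threshold: float,
    log: list,
) -> list[ExonRecord]:
    """Remove BOTH exons of any pair whose upstream regions and downstream
    regions are each similar (k-mer Jaccard >= threshold, default k=11)."""
    up_sets, down_sets, ids = [], [], []
    for e in exons:
        up_sets.append(_kmer_set(extract_region(e, pair_config.upstream), k))
        down_sets.append(_kmer_set(extract_region(e, pair_config.downstream), k))
        ids.append(e.exon_id)
    # candidate pairs: share at least one upstream k-mer (random regions
    # essentially never do, keeping this near-linear)
    index: dict[str, list[int]] = {}
    for i, s in enumerate(up_sets):
        for km in s:
            index.setdefault(km, []).append(i)
    candidates = set()
    for hits in index.values():
        if len(hits) > 1:
            candidates.update(itertools.combinations(hits, 2))

    def jaccard(a: frozenset, b: frozenset) -> float:
        if not a or not b:
            return 0.0
        inter = len(a & b)
        return inter / (len(a) + len(b) - inter)

    purged: set[int] = set()
    for i, j in candidates:
        if jaccard(up_sets[i], up_sets[j]) >= threshold and jaccard(
            down_sets[i], down_sets[j]
        ) >= threshold:
            purged.update((i, j))
    for i in sorted(purged):
        log.append((ids[i], "similarity_purge"))
    return [e for i, e in enumerate(exons) if i not in purged]


def filter_corpus(
    exons: Sequence[ExonRecord],
    pair_config: RegionPairConfig = UPDP,
    *,
    seed: int = 0,
    similarity_k: int = 11,
    similarity_threshold: float = 0.8,
    gc_min: float = 0.2,
    gc_max: float = 0.8,
) -> tuple[list[ExonRecord], list[tuple[str, str]]]:
    """Apply the three corpus filters in order and return (kept, rejection log).

    1. alternative-splice-site dedup (one record kept per site cluster,
       chosen by the seeded RNG);
    2. similarity purge: both exons of any pair similar in both regions of
       ``pair_config`` are removed;
    3. regions with N, or with GC < ``gc_min`` or > ``gc_max``, drop the exon
       from this regional analysis.
    """
    rng = np.random.default_rng(seed)
    log: list[tuple[str, str]] = []
    kept = _dedup_alt_sites(list(exons), rng, log)
    kept = _purge_similar(kept, pair_config, similarity_k, similarity_threshold, log)
    final = []
    for e in kept:
        up = extract_region(e, pair_config.upstream)
        down = extract_region(e, pair_config.downstream)
        if "N" in up or "N" in down:
            log.append((e.exon_id, "n_in_region"))
            continue
        if not (gc_min <= gc_content(up) <= gc_max) or not (
            gc_min <= gc_content(down) <= gc_max
        ):
            log.append((e.exon_id, "extreme_gc"))
            continue
        final.append(e)
    return final, log
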