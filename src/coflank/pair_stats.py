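"""GC-stratified co-occurrence testing of k-mer pairs across exon flanks.

The statistic: for each ordered (upstream motif Ui, downstream motif Dj) pair,
presence is counted binarily per exon-region.  Exons are stratified into an
equal-occupancy n_bins x n_bins grid by the GC content of the two regions; the
null expectation of the joint count is

    k' = sum_{x,y} K_{x,y} * q_Ui(y) * q_Dj(x)

with q the per-stratum presence frequencies, which absorbs the genome-wide
correlation of flank GC content (GC isochores).  The downstream margin is then
adjusted to n'_Dj = N*k'/n_Ui so that a hypergeometric distribution with
margins (N, n_Ui, n'_Dj) has mean k', and exact tail p-values are computed for
the observed joint count k^a.  Enrichment is judged on the upper tail at a
Bonferroni-like cutoff alpha = 1/4^(2k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exon_model import (
    ExonRecord,
    RegionPairConfig,
    UPDP,
    extract_region,
    gc_content,
)

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def num_hypotheses(k: int) -> int:
    """Number of ordered (upstream, downstream) k-mer pair hypotheses: 4^(2k)."""
    return 4 ** (2 * k)


def default_alpha(k: int) -> float:
    """Per-test cutoff 1/4^(2k): about one false pair expected over the scan."""
    return 1.0 / num_hypotheses(k)


def expected_position_pair_hits(n_exons: int, positions_per_window: int, k: int) -> float:
    """Back-of-envelope power arithmetic: expected number of exons at which a
    specific k-mer pair co-hits, given uniform random sequence —
    n_exons * positions^2 / 4^(2k).  For 80,000 exons and 46 positions this is
    ~161 for pentamers but only ~10 for hexamers, which is why pentamers are
    the largest k with adequate power at genome scale."""
    return n_exons * positions_per_window**2 / num_hypotheses(k)


def motif_index(motif: str) -> int:
    idx = 0
    for b in motif:
        idx = idx * 4 + _BASE_INDEX_CHECK(b)
    return idx


def _BASE_INDEX_CHECK(b: str) -> int:
    c = _CODE[ord(b)]
    if c < 0:
        raise ValueError(f"invalid base {b!r} in motif")
    return int(c)


def index_motif(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def kmer_presence(regions: Sequence[str], k: int) -> np.ndarray:
    """Binary presence matrix (n_regions, 4^k): does region i contain motif j
    at least once?  Windows containing N contribute no motif."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n_mot = 4**k
    out = np.zeros((len(regions), n_mot), dtype=bool)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(regions):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in by_len.items():
        if L < k:
            continue
        arr = np.frombuffer(
            "".join(regions[i] for i in idxs).encode("ascii"), dtype=np.uint8
        ).reshape(len(idxs), L)
        codes = _CODE[arr]
        valid = codes >= 0
        c = codes.astype(np.int64)
        n_win = L - k + 1
        win = np.zeros((len(idxs), n_win), dtype=np.int64)
        ok = np.ones((len(idxs), n_win), dtype=bool)
        for j in range(k):
            win = win * 4 + np.maximum(c[:, j : n_win + j], 0)
            ok &= valid[:, j : n_win + j]
        rows = np.repeat(np.asarray(idxs), n_win)
        flat_ok = ok.ravel()
        out[rows[flat_ok], win.ravel()[flat_ok]] = True
    return out


# ---------------------------------------------------------------------------
# GC grid
# ---------------------------------------------------------------------------


@dataclass
class GCGrid:
    """Equal-occupancy 2-way GC stratification of a corpus.

    ``row_of[i]`` is the stratum of exon i by upstream-region GC, ``col_of[i]``
    by downstream-region GC; ``K[y, x]`` is the number of exons in box
    (row y, column x).  Every row and column holds N/n_bins exons (+-1 when N
    is not divisible); ties in GC are broken by exon_id for determinism.
    """

    n_bins: int
    row_of: np.ndarray
    col_of: np.ndarray
    K: np.ndarray  # (n_bins rows, n_bins cols)
    row_counts: np.ndarray
    col_counts: np.ndarray
    row_edges: np.ndarray
    col_edges: np.ndarray
    N: int


def _equal_occupancy_bins(
    gc: np.ndarray, ids: Sequence[str], n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N = len(gc)
    order = np.lexsort((np.asarray(ids, dtype=object), gc))
    ranks = np.empty(N, dtype=np.int64)
    ranks[order] = np.arange(N)
    bins = (ranks * n_bins) // N
    counts = np.bincount(bins, minlength=n_bins)
    edges = np.empty(n_bins + 1)
    sorted_gc = gc[order]
    boundaries = np.floor(np.arange(1, n_bins) * N / n_bins).astype(int)
    edges[0], edges[-1] = sorted_gc[0], sorted_gc[-1]
    edges[1:-1] = sorted_gc[boundaries]
    return bins, counts, edges


def build_gc_grid(
    corpus: Sequence[ExonRecord],
    pair_config: RegionPairConfig = UPDP,
    n_bins: int = 20,
) -> GCGrid:
    """Stratify exons into n_bins rows by upstream-region GC and n_bins
    columns by downstream-region GC, each with equal occupancy."""
    N = len(corpus)
    if N < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} exons, got {N}")
    gc_up = np.array(
        [gc_content(extract_region(e, pair_config.upstream)) for e in corpus]
    )
    gc_down = np.array(
        [gc_content(extract_region(e, pair_config.downstream)) for e in corpus]
    )
    ids = [e.exon_id for e in corpus]
    rows, row_counts, row_edges = _equal_occupancy_bins(gc_up, ids, n_bins)
    cols, col_counts, col_edges = _equal_occupancy_bins(gc_down, ids, n_bins)
    K = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(K, (rows, cols), 1)
    return GCGrid(n_bins, rows, cols, K, row_counts, col_counts, row_edges, col_edges, N)


# ---------------------------------------------------------------------------
# Presence tables
# ---------------------------------------------------------------------------


@dataclass
class PresenceTable:
    """Per-stratum binary presence counts for every motif of one side."""

    k: int
    side: str
    M: np.ndarray  # (n_bins, 4^k) per-stratum exon counts with the motif
    n: np.ndarray  # (4^k,) per-motif totals
    stratum_counts: np.ndarray  # (n_bins,) exons per stratum
    q: np.ndarray = field(init=False)  # per-stratum presence frequencies

    def __post_init__(self) -> None:
        self.q = self.M / self.stratum_counts[:, None]


def presence_table_from_matrix(
    presence: np.ndarray, strata: np.ndarray, stratum_counts: np.ndarray, k: int, side: str
) -> PresenceTable:
    n_bins = len(stratum_counts)
    onehot = np.zeros((n_bins, presence.shape[0]), dtype=np.float32)
    onehot[strata, np.arange(presence.shape[0])] = 1.0
    M = np.rint(onehot @ presence.astype(np.float32)).astype(np.int64)
    return PresenceTable(k, side, M, M.sum(axis=0), stratum_counts)


def presence_table(
    corpus: Sequence[ExonRecord],
    grid: GCGrid,
    region_spec,
    k: int,
) -> PresenceTable:
    """Binary per-exon presence of every k-mer in ``region_spec``, aggregated
    by the matching stratum axis of the grid."""
    if k < 1:
        raise ValueError("k must be >= 1")
    regions = [extract_region(e, region_spec) for e in corpus]
    presence = kmer_presence(regions, k)
    if region_spec.side == "upstream":
        return presence_table_from_matrix(presence, grid.row_of, grid.row_counts, k, "upstream")
    return presence_table_from_matrix(presence, grid.col_of, grid.col_counts, k, "downstream")


def expected_pair_count(grid: GCGrid, qU: np.ndarray, qD: np.ndarray) -> float:
    """k' = sum_{x,y} K_{y,x} * qU[y] * qD[x] for a single motif pair."""
    qU = np.asarray(qU, dtype=float)
    qD = np.asarray(qD, dtype=float)
    if qU.shape != (grid.n_bins,) or qD.shape != (grid.n_bins,):
        raise ValueError("q vectors must have length n_bins")
    return float(qU @ grid.K @ qD)


def _round_margin(x):
    # snap to 9 decimals first: q values are small rationals, so exact .5
    # ties are common and must not depend on float summation order
    return np.round(np.round(x, 9))


def adjust_margin(N: int, n_Ui: int, k_prime: float):
    """n'_Dj = round(N * k' / n_Ui), round half to even, clamped to [0, N].

    Returns None when n_Ui == 0 (no test possible; record p = 1)."""
    if n_Ui == 0:
        return None
    return int(np.clip(_round_margin(N * k_prime / n_Ui), 0, N))


# ---------------------------------------------------------------------------
# Exact vectorized hypergeometric tails
# ---------------------------------------------------------------------------


def _log_pmf(k, N, nU, nD):
    # log C(nD, k) + log C(N-nD, nU-k) - log C(N, nU)
    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logc(nD, k) + logc(N - nD, nU - k) - logc(N, nU)


def _sum_away(k0, N, nU, nD, edge, step, rel_tol=1e-18):
    """Sum pmf(k) from k0 toward the support ``edge`` in direction ``step``.

    Intended for sums that start at or beyond the mode and move away from it,
    so successive terms decay geometrically; each lane stops once it reaches
    the edge or its next term is negligible relative to its accumulated sum.
    Converged lanes are compacted away every iteration.
    """
    k0 = np.asarray(k0, dtype=np.float64)
    total = np.exp(_log_pmf(k0, N, nU, nD))
    idx = np.arange(len(total))
    kk = k0.copy()
    NN = np.broadcast_to(np.asarray(N, dtype=np.float64), kk.shape).copy()
    nUU = np.broadcast_to(np.asarray(nU, dtype=np.float64), kk.shape).copy()
    nDD = np.broadcast_to(np.asarray(nD, dtype=np.float64), kk.shape).copy()
    ee = np.broadcast_to(np.asarray(edge, dtype=np.float64), kk.shape).copy()
    tt = total.copy()
    ss = total.copy()
    live = (kk != ee) & (tt > 0)
    idx, kk, NN, nUU, nDD, ee, tt, ss = (
        a[live] for a in (idx, kk, NN, nUU, nDD, ee, tt, ss)
    )
    while len(idx):
        if step > 0:
            ratio = (nDD - kk) * (nUU - kk) / ((kk + 1) * (NN - nDD - nUU + kk + 1))
        else:
            ratio = kk * (NN - nDD - nUU + kk) / ((nDD - kk + 1) * (nUU - kk + 1))
        tt = tt * ratio
        ss = ss + tt
        kk = kk + step
        total[idx] = ss
        live = (kk != ee) & (tt > rel_tol * ss)
        if not live.all():
            idx, kk, NN, nUU, nDD, ee, tt, ss = (
                a[live] for a in (idx, kk, NN, nUU, nDD, ee, tt, ss)
            )
    return np.minimum(total, 1.0)


def hypergeom_tails(ka, N, nU, nD):
    """Exact (p_upper, p_lower) = (P(K >= ka), P(K <= ka)) for vectors of
    hypergeometric parameters.  Tails are accumulated moving away from the
    mode so every partial sum converges geometrically; the complementary tail
    is used on the near side of the mode."""
    ka = np.asarray(ka, dtype=np.int64)
    nU = np.broadcast_to(np.asarray(nU, dtype=np.int64), ka.shape).copy()
    nD = np.broadcast_to(np.asarray(nD, dtype=np.int64), ka.shape).copy()
    Nb = np.broadcast_to(np.asarray(N, dtype=np.int64), ka.shape).copy()
    kmin = np.maximum(0, nU + nD - Nb)
    kmax = np.minimum(nU, nD)
    if np.any(ka < kmin) or np.any(ka > kmax):
        raise ValueError("k_a outside hypergeometric support")
    mode = ((nU + 1) * (nD + 1)) // (Nb + 2)

    p_upper = np.ones(ka.shape, dtype=np.float64)
    p_lower = np.ones(ka.shape, dtype=np.float64)

    # p_upper: direct ascending sum where ka is above the mode, else 1 - lower tail
    hi = ka > mode
    if hi.any():
        p_upper[hi] = _sum_away(ka[hi], Nb[hi], nU[hi], nD[hi], kmax[hi], +1)
    lo = ~hi & (ka > kmin)
    if lo.any():
        below = _sum_away(ka[lo] - 1, Nb[lo], nU[lo], nD[lo], kmin[lo], -1)
        p_upper[lo] = np.maximum(1.0 - below, 0.0)

    # p_lower: direct descending sum where ka is below the mode, else 1 - upper tail
    lo2 = ka < mode
    if lo2.any():
        p_lower[lo2] = _sum_away(ka[lo2], Nb[lo2], nU[lo2], nD[lo2], kmin[lo2], -1)
    hi2 = ~lo2 & (ka < kmax)
    if hi2.any():
        above = _sum_away(ka[hi2] + 1, Nb[hi2], nU[hi2], nD[hi2], kmax[hi2], +1)
        p_lower[hi2] = np.maximum(1.0 - above, 0.0)
    return p_upper, p_lower


def pair_pvalue(N: int, n_Ui: int, n_Dj_adj: int, k_a: int) -> tuple[float, float]:
    """Exact (p_upper, p_lower) for one pair under margins (N, n_Ui, n'_Dj)."""
    for name, v in (("N", N), ("n_Ui", n_Ui), ("n_Dj_adj", n_Dj_adj), ("k_a", k_a)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_Ui > N or n_Dj_adj > N:
        raise ValueError("margins exceed N")
    pu, pl = hypergeom_tails(
        np.array([k_a]), np.array([N]), np.array([n_Ui]), np.array([n_Dj_adj])
    )
    return float(pu[0]), float(pl[0])


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------


@dataclass
class PairStatistic:
    motif_u: str
    motif_d: str
    N: int
    n_Ui: int
    n_Dj: int
    k_prime: float
    n_Dj_adj: int
    k_a: int
    p_upper: float
    p_lower: float
    direction: str
    flagged: bool = False


@dataclass
class ScanResult:
    """Outcome of a full 4^(2k)-hypothesis scan over one region pairing."""

    pair_config_label: str
    k: int
    alpha: float
    N: int
    n_bins: int
    n_hypotheses: int
    table: pd.DataFrame  # significant pairs (p_upper <= alpha)
    n_significant: int
    provenance: dict = field(default_factory=dict)
    full: dict | None = None  # emit_all: arrays over the whole pair space

    def significant_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["motif_u"], self.table["motif_d"]))

    def pvalue(self, motif_u: str, motif_d: str) -> float:
        if self.full is None:
            raise ValueError("scan was run without emit_all")
        return float(self.full["p_upper"][motif_index(motif_u), motif_index(motif_d)])


def _adjusted_margins(N, n_U, n_D, k_prime, adjust):
    """Margins making the hypergeometric mean equal k'.  Shapes: n_U rows,
    n_D columns, k_prime (rows, cols)."""
    nU_mat = np.broadcast_to(n_U[:, None], k_prime.shape).astype(np.int64)
    nD_mat = np.broadcast_to(n_D[None, :], k_prime.shape).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        if adjust == "down":
            nD_adj = np.where(
                nU_mat > 0, np.clip(_round_margin(N * k_prime / nU_mat), 0, N), 0
            ).astype(np.int64)
            nU_adj = nU_mat
        elif adjust == "up":
            nU_adj = np.where(
                nD_mat > 0, np.clip(_round_margin(N * k_prime / nD_mat), 0, N), 0
            ).astype(np.int64)
            nD_adj = nD_mat
        elif adjust == "both":
            denom = nU_mat.astype(float) * nD_mat
            scale = np.where(denom > 0, np.sqrt(N * k_prime / np.maximum(denom, 1)), 0.0)
            nU_adj = np.clip(_round_margin(nU_mat * scale), 0, N).astype(np.int64)
            nD_adj = np.clip(_round_margin(nD_mat * scale), 0, N).astype(np.int64)
        else:
            raise ValueError("adjust must be 'down', 'up' or 'both'")
    return nU_adj, nD_adj


def scan_pairs(
    corpus: Sequence[ExonRecord],
    pair_config: RegionPairConfig = UPDP,
    k: int = 5,
    *,
    n_bins: int = 20,
    alpha: float | None = None,
    adjust: str = "down",
    emit_all: bool = False,
    provenance: dict | None = None,
) -> ScanResult:
    """Run the GC-stratified co-occurrence test over all 4^(2k) ordered
    (upstream, downstream) k-mer pairs of one region pairing.

    Exons whose regions contain N are dropped from this regional analysis.
    Deterministic given the corpus.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if alpha is None:
        alpha = default_alpha(k)
    regions_u = [extract_region(e, pair_config.upstream) for e in corpus]
    regions_d = [extract_region(e, pair_config.downstream) for e in corpus]
    keep = [
        i
        for i in range(len(corpus))
        if "N" not in regions_u[i] and "N" not in regions_d[i]
    ]
    kept_corpus = [corpus[i] for i in keep]
    regions_u = [regions_u[i] for i in keep]
    regions_d = [regions_d[i] for i in keep]
    N = len(kept_corpus)
    if N < n_bins:
        raise ValueError(f"only {N} usable exons for n_bins={n_bins}")

    grid = build_gc_grid(kept_corpus, pair_config, n_bins)
    U = kmer_presence(regions_u, k)
    D = kmer_presence(regions_d, k)
    tab_u = presence_table_from_matrix(U, grid.row_of, grid.row_counts, k, "upstream")
    tab_d = presence_table_from_matrix(D, grid.col_of, grid.col_counts, k, "downstream")
    n_U, n_D = tab_u.n, tab_d.n

    # k'[i, j] = sum_{y,x} q_U[y, i] K[y, x] q_D[x, j]
    k_prime = tab_u.q.T @ grid.K @ tab_d.q
    k_a = np.rint(U.T.astype(np.float32) @ D.astype(np.float32)).astype(np.int64)

    nU_adj, nD_adj = _adjusted_margins(N, n_U, n_D, k_prime, adjust)

    # clamp the adjusted margin so k_a stays inside the hypergeometric support;
    # at a clamped bound the tail p collapses to the boundary pmf
    lo_clamp = k_a  # need min(nU', nD') >= k_a
    hi_clamp = N - nU_adj + k_a  # need nU' + nD' - N <= k_a
    flagged = (nD_adj < lo_clamp) | (nD_adj > hi_clamp)
    nD_adj = np.clip(nD_adj, lo_clamp, hi_clamp)
    if adjust != "down":
        bad = nU_adj < k_a
        flagged |= bad
        nU_adj = np.maximum(nU_adj, k_a)

    testable = (n_U > 0)[:, None] & (n_D > 0)[None, :]
    p_upper = np.ones_like(k_prime)
    p_lower = np.ones_like(k_prime)
    t = testable.ravel()
    pu, pl = hypergeom_tails(
        k_a.ravel()[t], N, nU_adj.ravel()[t], nD_adj.ravel()[t]
    )
    p_upper.ravel()[t] = pu
    p_lower.ravel()[t] = pl

    mean = nU_adj * nD_adj / N
    significant = testable & (p_upper <= alpha)
    sig_idx = np.argwhere(significant)
    rows = []
    for i, j in sig_idx:
        rows.append(
            dict(
                motif_u=index_motif(i, k),
                motif_d=index_motif(j, k),
                N=N,
                n_Ui=int(n_U[i]),
                n_Dj=int(n_D[j]),
                k_prime=float(k_prime[i, j]),
                n_Dj_adj=int(nD_adj[i, j]),
                k_a=int(k_a[i, j]),
                p_upper=float(p_upper[i, j]),
                p_lower=float(p_lower[i, j]),
                direction="enriched" if k_a[i, j] > mean[i, j] else "depleted",
                flagged=bool(flagged[i, j]),
            )
        )
    columns = [
        "motif_u", "motif_d", "N", "n_Ui", "n_Dj", "k_prime", "n_Dj_adj",
        "k_a", "p_upper", "p_lower", "direction", "flagged",
    ]
    table = pd.DataFrame(rows, columns=columns).sort_values(
        "p_upper", kind="stable", ignore_index=True
    )
    full = None
    if emit_all:
        full = dict(
            n_U=n_U, n_D=n_D, k_prime=k_prime, k_a=k_a,
            nU_adj=nU_adj, nD_adj=nD_adj,
            p_upper=p_upper, p_lower=p_lower, flagged=flagged,
        )
    return ScanResult(
        pair_config_label=pair_config.label,
        k=k,
        alpha=alpha,
        N=N,
        n_bins=n_bins,
        n_hypotheses=num_hypotheses(k),
        table=table,
        n_significant=len(table),
        provenance=provenance or {},
        full=full,
    )


def evaluate_pairs(
    corpus: Sequence[ExonRecord],
    pair_config: RegionPairConfig,
    motif_pairs: Sequence[tuple[str, str]],
    *,
    n_bins: int = 20,
    adjust: str = "down",
) -> pd.DataFrame:
    """Compute the co-occurrence statistic for a given list of motif pairs in
    one region pairing, without scanning the whole pair space."""
    if not motif_pairs:
        return pd.DataFrame(
            columns=["motif_u", "motif_d", "N", "n_Ui", "n_Dj", "k_prime",
                     "n_Dj_adj", "k_a", "p_upper", "p_lower"]
        )
    k = len(motif_pairs[0][0])
    regions_u = [extract_region(e, pair_config.upstream) for e in corpus]
    regions_d = [extract_region(e, pair_config.downstream) for e in corpus]
    keep = [
        i
        for i in range(len(corpus))
        if "N" not in regions_u[i] and "N" not in regions_d[i]
    ]
    kept = [corpus[i] for i in keep]
    regions_u = [regions_u[i] for i in keep]
    regions_d = [regions_d[i] for i in keep]
    N = len(kept)
    grid = build_gc_grid(kept, pair_config, n_bins)

    motifs_u = sorted({u for u, _ in motif_pairs})
    motifs_d = sorted({d for _, d in motif_pairs})
    pres_u = np.array(
        [[m in s for m in motifs_u] for s in regions_u], dtype=bool
    )
    pres_d = np.array(
        [[m in s for m in motifs_d] for s in regions_d], dtype=bool
    )
    tab_u = presence_table_from_matrix(pres_u, grid.row_of, grid.row_counts, k, "upstream")
    tab_d = presence_table_from_matrix(pres_d, grid.col_of, grid.col_counts, k, "downstream")
    k_prime = tab_u.q.T @ grid.K @ tab_d.q
    k_a = np.rint(pres_u.T.astype(np.float32) @ pres_d.astype(np.float32)).astype(np.int64)
    nU_adj, nD_adj = _adjusted_margins(N, tab_u.n, tab_d.n, k_prime, adjust)
    nD_adj = np.clip(nD_adj, k_a, N - nU_adj + k_a)

    ui = {m: i for i, m in enumerate(motifs_u)}
    di = {m: i for i, m in enumerate(motifs_d)}
    rows = []
    for u, d in motif_pairs:
        i, j = ui[u], di[d]
        if tab_u.n[i] == 0 or tab_d.n[j] == 0:
            pu, pl = 1.0, 1.0
        else:
            pu, pl = pair_pvalue(N, int(nU_adj[i, j]), int(nD_adj[i, j]), int(k_a[i, j]))
        rows.append(
            dict(
                motif_u=u, motif_d=d, N=N,
                n_Ui=int(tab_u.n[i]), n_Dj=int(tab_d.n[j]),
                k_prime=float(k_prime[i, j]), n_Dj_adj=int(nD_adj[i, j]),
                k_a=int(k_a[i, j]), p_upper=pu, p_lower=pl,
            )
        )
    return pd.DataFrame(rows)


def cross_region_pvalues(
    pairs: Sequence[tuple[str, str]],
    corpus: Sequence[ExonRecord],
    defining_config: RegionPairConfig,
    other_configs: Sequence[RegionPairConfig],
    *,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Evaluate discovered pairs in other regional combinations.

    For each pair the result carries its p_upper in every region plus a flag
    marking whether the null expected count there is within a factor of two of
    the defining region's — comparable statistical power."""
    frames = []
    defining = evaluate_pairs(corpus, defining_config, pairs, n_bins=n_bins)
    defining["region_pair"] = defining_config.label
    defining["within_factor_two"] = True
    def_kprime = dict(
        zip(zip(defining["motif_u"], defining["motif_d"]), defining["k_prime"])
    )
    frames.append(defining)
    for cfg in other_configs:
        df = evaluate_pairs(corpus, cfg, pairs, n_bins=n_bins)
        df["region_pair"] = cfg.label
        ref = np.array([def_kprime[(u, d)] for u, d in zip(df["motif_u"], df["motif_d"])])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ref > 0, df["k_prime"] / ref, np.inf)
        df["within_factor_two"] = (ratio >= 0.5) & (ratio <= 2.0)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
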