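"""Naive reference implementations used as independent oracles.

Everything here is deliberately loop-based and leans on scipy for the
hypergeometric distribution, staying independent of the vectorized code
paths it checks.
"""

import itertools

from scipy import stats

from coflank.exon_model import extract_region, gc_content


def all_kmers(k):
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def naive_equal_occupancy_bins(gc_values, ids, n_bins):
    order = sorted(range(len(gc_values)), key=lambda i: (gc_values[i], ids[i]))
    bins = [0] * len(gc_values)
    for rank, i in enumerate(order):
        bins[i] = rank * n_bins // len(gc_values)
    return bins


def naive_scan(corpus, pair_config, k, n_bins):
    """Loop-based GC-stratified co-occurrence scan.  Returns dict keyed by
    (motif_u, motif_d) with (n_U, n_D, k_prime, nD_adj, k_a, p_upper,
    p_lower)."""
    ups = [extract_region(e, pair_config.upstream) for e in corpus]
    downs = [extract_region(e, pair_config.downstream) for e in corpus]
    ids = [e.exon_id for e in corpus]
    N = len(corpus)
    rows = naive_equal_occupancy_bins([gc_content(s) for s in ups], ids, n_bins)
    cols = naive_equal_occupancy_bins([gc_content(s) for s in downs], ids, n_bins)
    row_size = [rows.count(b) for b in range(n_bins)]
    col_size = [cols.count(b) for b in range(n_bins)]
    K = [[0] * n_bins for _ in range(n_bins)]
    for y, x in zip(rows, cols):
        K[y][x] += 1

    kmers = all_kmers(k)
    pres_u = {m: [m in s for s in ups] for m in kmers}
    pres_d = {m: [m in s for s in downs] for m in kmers}

    out = {}
    for mu in kmers:
        n_u = sum(pres_u[mu])
        M_u = [0] * n_bins
        for i, p in enumerate(pres_u[mu]):
            M_u[rows[i]] += p
        q_u = [M_u[y] / row_size[y] for y in range(n_bins)]
        for md in kmers:
            n_d = sum(pres_d[md])
            M_d = [0] * n_bins
            for i, p in enumerate(pres_d[md]):
                M_d[cols[i]] += p
            q_d = [M_d[x] / col_size[x] for x in range(n_bins)]
            k_prime = sum(
                K[y][x] * q_u[y] * q_d[x]
                for y in range(n_bins)
                for x in range(n_bins)
            )
            k_a = sum(
                1 for i in range(N) if pres_u[mu][i] and pres_d[md][i]
            )
            if n_u == 0 or n_d == 0:
                out[(mu, md)] = (n_u, n_d, k_prime, 0, k_a, 1.0, 1.0)
                continue
            # round half to even after snapping float ties to 9 decimals
            nd_adj = int(min(max(round(round(N * k_prime / n_u, 9)), k_a), N - n_u + k_a))
            p_upper = stats.hypergeom.sf(k_a - 1, N, nd_adj, n_u)
            p_lower = stats.hypergeom.cdf(k_a, N, nd_adj, n_u)
            out[(mu, md)] = (n_u, n_d, k_prime, nd_adj, k_a, p_upper, p_lower)
    return out


def naive_coverage(seq, hexamers):
    covered = set()
    for i in range(len(seq) - 5):
        if seq[i : i + 6] in hexamers:
            covered.update(range(i, i + 6))
    return len(covered) / len(seq) if len(seq) >= 6 else 0.0
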