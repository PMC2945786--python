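"""Discover co-occurring motif pairs in a synthetic exon corpus.

Builds 5,000 exons whose two intronic flanks share GC content (r ~ 0.73, as
in real genomes), plants the pentamer pair TCCCT:GGAGG jointly into 30% of
the Up/Dp windows, and runs the GC-stratified co-occurrence scan over all
4^10 pentamer pairs.
"""

from coflank import CorpusConfig, PlantedPair, UPDP, filter_corpus, generate_corpus, scan_pairs

cfg = CorpusConfig(
    n_exons=5000,
    seed=42,
    planted=(PlantedPair("TCCCT", "GGAGG", "UpDp", f_both=0.30, f_u=0.02, f_d=0.02),),
)
corpus, truth = generate_corpus(cfg)
corpus, rejected = filter_corpus(corpus, UPDP, seed=42)
print(f"corpus: {len(corpus)} exons after filtering ({len(rejected)} rejected)")

result = scan_pairs(corpus, UPDP, k=5)
print(f"scanned {result.n_hypotheses:,} pentamer pairs at alpha = {result.alpha:.2e}")
print(f"{result.n_significant} significant pairs; top rows:")
print(result.table.head(5).to_string(index=False))

# The planted pair tops the list; the other significant pairs are
# overlap-shifted variants of it that genuinely co-occur in this corpus.
# k_a is the observed joint count, k_prime the GC-corrected expectation.
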