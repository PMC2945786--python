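"""Synergy index from minigene reporter band quantities.

Two transfection replicates of four constructs (no insertion, upstream
motif only, downstream only, both) give per-replicate skipping proportions;
the synergy index SI = W_UD - W_U * W_D is negative when the pair suppresses
exon skipping more than multiplicatively.
"""

import pandas as pd

from coflank import replicate_synergy, synergy_index

rows = []
for rep, jitter in ((1, -0.01), (2, +0.01)):
    for construct, skipped in [
        ("no-insertion", 0.98), ("U", 0.90), ("D", 0.90), ("UD", 0.55)
    ]:
        s = skipped + jitter
        rows.append(dict(construct=construct, replicate=rep,
                         included_molar=1 - s, skipped_molar=s))
bands = pd.DataFrame(rows)

out = replicate_synergy(bands)
print(out.to_string(index=False))
print(f"SI = {out.attrs['si_mean']:.3f} +- {out.attrs['si_sem']:.3f}")

single = synergy_index(0.98, 0.90, 0.90, 0.55)
print(f"single-point check: W_U = W_D = {single.w_u:.3f}, W_UD = {single.w_ud:.3f}, "
      f"SI = {single.si:.3f} -> {single.classification}")
# SI ~ -0.28: the pair reduces skipping ~1.5x more than the product of the
# single-motif effects predicts -- the motifs cooperate across the exon.
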