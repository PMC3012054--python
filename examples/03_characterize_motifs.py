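"""Characterize motifs: positional bias, co-occurrence/co-localization,
domain overlap, disorder, and similarity to a known-motif catalog.

Plants an N-terminally biased motif and a co-localized motif pair, then runs
each characterization statistic and prints what it measures.
"""

import numpy as np

from motifinfo import characterize, synth
from motifinfo.io import DisorderMask
from motifinfo.motif import build_profile, parse_motif

# --- positional bias: instances planted in the first 10% of each sequence
m = parse_motif("SP.[RK]")
prot = synth.random_proteome(300, 250, 40, seed=20)
beh = synth.random_class_profile(prot, [80, 220], seed=21)
prot, _ = synth.plant_motif(prot, beh, m, 0, 0.9, position_mode="nterm", seed=22)
prof = build_profile(prot, m, beh.ids)
bias = characterize.positional_bias(prof, beh, prot, n_rand=999, seed=23)
print(f"positional bias of {m}: MI={bias.mi_bits:.3f} bits, p={bias.empirical_p:.3g}")
print("  target-class histogram (10 bins N->C):", [int(c) for c in bias.histogram_targets])

# --- co-occurrence and co-localization of a planted pair at spacing 20
ma, mb = parse_motif("QW[AC]"), parse_motif("WQ[LM]")
prot2 = synth.random_proteome(600, 300, 40, seed=30)
beh2 = synth.random_class_profile(prot2, [150, 450], seed=31)
prot2, _ = synth.plant_pair(prot2, beh2, ma, mb, 0, spacing=20, jitter=1, penetrance=0.9, seed=32)
prot2, _ = synth.plant_motif(prot2, beh2, ma, 1, 0.5, seed=33)
prot2, _ = synth.plant_motif(prot2, beh2, mb, 1, 0.5, seed=34)
pa, pb = build_profile(prot2, ma, beh2.ids), build_profile(prot2, mb, beh2.ids)
mi, p, direction = characterize.cooccurrence(pa, pb, n_rand=999, seed=35)
cmi, cp = characterize.colocalization(pa, pb, beh2, n_rand=999, seed=36)
print(f"{ma} vs {mb}: {direction} (MI={mi:.3f} bits, p={p:.3g}); "
      f"co-localization p={cp:.3g} (planted spacing 20)")

# --- disorder: fraction of instances falling in disordered intervals
mask = DisorderMask({pid: [(0, len(prot.sequence(pid)) // 2)] for pid in prot.ids})
score = characterize.disorder_score(prof, mask, prot)
pct = characterize.kmer_disorder_percentile(score, m.width, mask, prot)
print(f"disorder score of {m}: {score:.2f} (beats {pct:.0f}% of same-width k-mers)")

# --- similarity to a known-motif catalog
catalog = [
    ("CDK substrate", parse_motif("[ST]P.[RK]"), "kinase"),
    ("NLS", parse_motif("K[KR].[KR]"), "nuclear import"),
]
hit = characterize.best_match(m, catalog)
print(f"best known match for {m}: {hit[1]} ({hit[0]}), similarity {hit[2]:.2f}")

# Small p-values above indicate position/spacing carry behavior information;
# the catalog match shows the discovered pattern corresponds to a known site.
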