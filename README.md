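# motifinfo

Information-theoretic discovery and characterization of short linear protein
motifs (SLiMs) from proteome-scale data.

## The problem

Short linear motifs — degenerate amino-acid patterns of roughly 2–10
residues such as the cyclin-dependent-kinase substrate site `SP.[RK]` or the
nuclear localization signal `K[KR].K` — mediate phosphorylation,
localization, degradation, and protein–protein interaction. They are hard to
find because they are short, degenerate, and scattered across thousands of
sequences. `motifinfo` is for computational biologists who have a proteome
(FASTA) and a per-protein *behavior* — an interactor list, localization
classes, or a quantitative measurement like half-life or abundance — and
want the sequence elements that explain it.

## The method

For a candidate motif M, the *motif profile* marks each protein that
contains at least one exact match. The motif is scored by the plug-in mutual
information (in bits) between this profile and the behavior profile B:

    MI(M; B) = Σ_{m,b} p(m,b) log₂[ p(m,b) / (p(m) p(b)) ]

Quantitative behaviors are first discretized into equally populated bins
(maximum-entropy binning; default 10), so binary, multi-class, and
quantitative data are handled uniformly, and over- and under-representation
are captured without a background model. Discovery is two-step: every
abundant exact k-mer is scored by MI, then informative seeds are grown into
degenerate patterns by a greedy search that tests residue-set changes at
each position and keeps changes that strictly increase MI. A motif is
reported only if its MI exceeds **all** of `n_rand` (default 10,000)
label-permutation null values — both as a seed and after refinement — and
survives a conditional-MI redundancy filter against previously accepted
motifs. Each reported motif carries a z-score, an empirical p-value, a
jackknife robustness score (0–10), per-class hypergeometric enrichment, and
a PWM built from its instances. Post-processing adds positional bias along
the normalized sequence, motif–motif co-occurrence and co-localization,
domain co-occurrence and overlap z-scores, flat-term (GO/Pfam-style)
enrichment, disorder scoring, and similarity to a known-motif catalog. See
`docs/methods.md` for the full model and numerical choices.

## Worked example

`examples/01_discover_planted_motif.py` builds a 2,000-protein synthetic
proteome, plants `SP.[RK]` into a 250-protein "interactor" class at 70%
penetrance, and runs discovery:

```
planted SP.[KR] into 172 interactors (165 more proteins match by chance)
SP.[KR]                      MI=0.171 bits  z= 343.0  p=0.001  robustness=10/10  carriers: 73% of interactors vs 9% of others  truth-Jaccard=1.00
```

The planted pattern is recovered exactly (truth-Jaccard 1.0 against the set
of proteins genuinely matching it): its presence is worth 0.171 bits about
interactor status, it beats all 1,000 permutation nulls (empirical
p = 1/1001), is significant in 10/10 jackknife subsamples, and shows the
asymmetric carrier rates (~73% of interactors vs ~9% of others) that make
such sites discoverable. `examples/02_quantitative_behavior.py` does the
same for a quantitative behavior (the recovered motif's per-bin enrichment
falls monotonically, Spearman ρ ≈ −0.97), and
`examples/03_characterize_motifs.py` walks through the characterization
statistics.

## Command line

The same pipeline is available as a thin CLI:

```sh
motifinfo simulate --n 2000 --motif "SP.[RK]" --target-size 250 --out sim/
motifinfo discover --fasta sim/proteome.fasta --behavior sim/behavior.tsv \
    --out run/ --seed 1 --k 3,4,5 --nrand 10000
motifinfo characterize --fasta sim/proteome.fasta --behavior sim/behavior.tsv \
    --motifs my_motifs.txt --out char/ --seed 1
```

`discover` writes `motifs.tsv` (motif, MI, z, empirical p, robustness,
carriers), `heatmap.tsv` (per-class signed enrichment with significance
flags), `instances.tsv`, per-motif PWM files, `interactions.tsv`,
`enrichment_table.tsv`, and per-motif position histograms. Quantitative
behaviors use `--quantitative --bins 10`. All outputs are deterministic
given `--seed`.

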