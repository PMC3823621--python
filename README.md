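# mirglia

Integrated miRNA–mRNA correlation analysis for two-condition activation
studies, built around the microglial polarization design: resting cells
(M0), LPS-driven classical activation (M1) and IL-4-driven alternative
activation (M2a), with paired mRNA and miRNA expression arrays on the same
samples (3 replicates per condition).

The package is for transcriptomics analysts who have paired log2
expression matrices and want candidate miRNA:target interactions with
transparent, reproducible statistics:

1. **Differential expression** per contrast: two-sided Student's t-test
   (pooled variance) on log2 expression, log2 fold change Δ = mean_t −
   mean_c, signed linear fold 2^|Δ|, Benjamini–Hochberg q across features.
2. **miRNA shortlist**: differentially expressed miRNAs whose mean linear
   expression exceeds 50% of the highest-expressing reference miRNA.
3. **Correlation screen**: Pearson r between each shortlisted miRNA and
   every gene over the pooled contrast samples; candidates need
   |r| > 0.5 **and** DE p < 10⁻⁴ (strict).
4. **Dual-database intersection**: candidates ∩ predictions(db A) ∩
   predictions(db B) form the interactome, each record classified as
   inversely (r < 0) or positively correlated, with overlap statistics.
5. **Enrichment**: one-sided hypergeometric over-representation
   P(X ≥ k) for a query of n genes from a universe of N containing K
   set members, BH-adjusted, pooled across miRNAs and ranked by
   −log10(p) against the p < 0.05 line at 1.30.

A planted-truth synthetic generator (`mirglia.simulate`) emulates the full
study design — condition effect sizes, repressive/activating miRNA→gene
edges, noisy prediction databases, decoy annotation sets — so every stage
is testable without any array downloads. A transcription of the published
112-gene miR-155 interactome table ships as a package fixture
(`mirglia.load_published_interactome()`).

## Worked example

The `analysis/` scripts run the whole study on a simulated dataset and
write their tables under `results/`:

```
python analysis/01_simulate.py          # paired dataset + databases + truth
python analysis/02_differential.py      # DE tables and up/down summary
python analysis/03_target_screen.py     # correlation -> intersection -> interactome
python analysis/04_enrichment.py        # pooled -log10(p) ranking
python analysis/05_published_interactome.py
python analysis/06_recovery_benchmark.py
```

Step 03 prints the screening funnel for the shortlisted miRNA:

```
shortlisted miRNAs: ['miR-155-like'] up, [] down
miR-155-like: 9 correlated+DE genes -> 8 in targets_mirandalike, 8 in
targets_targetscanlike -> 8 triple (1 positively, 7 inversely correlated)
```

i.e. nine genes passed both the correlation and DE filters, eight of them
were predicted by both databases, and seven of those eight are inversely
correlated with the miRNA — the canonical repression signature. Step 04
then ranks the annotation sets:

```
 * MIR_155_LIKE_PROGRAM (miR-155-like): -log10(p) = 10.63, k = 8/13
   DECOY_SET_00 (miR-155-like): -log10(p) = 1.06, k = 2/13
```

the planted regulatory program tops the ranking far above the 1.30
significance line while size-matched decoys stay below it. Step 05
re-applies the screen's filters and direction classifier to the published
112-gene table: all 112 candidates pass, splitting into 44 positively and
68 inversely correlated targets with extreme log2 fold changes +2.744 and
−3.370. Step 06 reports that the DE stage recovers the planted headline
folds (425×, 38.85×, 9.69×, 2.66×) within ~1.5% on average over 200
simulated replicates.

There is also a CLI (`mirglia simulate|de|targets|enrich|pipeline`) over
the same functions; `mirglia pipeline --config run.yaml` runs every stage
from one YAML file.

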