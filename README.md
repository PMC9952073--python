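# popscan

Population-genomic diversity, inbreeding, linkage disequilibrium,
selective-sweep scanning and genotype–trait association for biallelic SNP
data — the statistical layer a livestock or wild-population resequencing
study runs after variant calling. It is aimed at analysts who have a
multi-sample VCF, a sample→population panel, gene intervals in BED, and
(optionally) an F2 intercross trait table, and who want the standard
selection-signature workflow as a reproducible, tested library and CLI
rather than a chain of one-off tool invocations.

## What it computes

* **Site QC**: minor-allele-frequency and call-rate filters; SNP density per
  chromosome bin; a simplified exon/intron/upstream/downstream/intergenic
  classifier.
* **Diversity**: observed heterozygosity H_o, unbiased expected
  heterozygosity H_e = 2p̂q̂·n/(n−1), and nucleotide diversity
  π = 2j(n−j)/(n(n−1)) per site, aggregated genome-wide or per window
  (per-bp convention).
* **Inbreeding**: runs of homozygosity via the two-stage 50-SNP sliding-window
  scan (≤1 heterozygote and ≤5 missing calls per window, ≥100 kb, ≥1 SNP /
  50 kb, ≤1,000 kb gaps) and F_ROH = Σ L_ROH / L_AUTO.
* **LD**: genotype-dosage r², distance-binned decay curves, and greedy
  windowed pruning (50-SNP window, 5-SNP step, r² ≤ 0.2).
* **Sweep scan**: 40-kb windows sliding by 10 kb; two-population
  Weir–Cockerham F_ST combined as ratio-of-sums per window, Z-transformed;
  ROD = 1 − π_target/π_control and log2(π_control/π_target); windows in the
  top 5% of both statistics become candidates, are merged into regions, and
  are intersected with gene intervals to yield per-statistic and joint gene
  sets.
* **Association**: fixed-effect OLS for an F2 intercross,
  Y = μ + G + H + f (+ b(W − W̄)) + e, with Type III genotype F-tests,
  least-squares means and unadjusted LSD pairwise comparisons.
* **Simulation**: a Balding–Nichols generator with planted sweeps, planted
  homozygous tracts and an F2 trait simulator, all with ground truth — used
  by the test suite and usable as a stand-alone fixture factory.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

Generate a two-population dataset (15 samples each, 8,000 SNPs on a 3-Mb
chromosome, divergence F = 0.1) with a full sweep planted in `pop1` at
1.2–1.4 Mb, then run the whole pipeline:

```sh
popscan sim --out-dir demo --seed 5 --n-sites 8000 --samples-per-pop 15 \
    --chrom-length 3000000 --sweep 1200000 1400000 --n-genes 60

cat > demo/config.yaml <<EOF
vcf: demo/sim.vcf
panel: demo/panel.tsv
bed: demo/genes.bed
traits: demo/traits.tsv
target: pop1
control: pop2
out_dir: demo/run
ld_max_dist_bp: 50000
ld_bin_bp: 5000
EOF

popscan pipeline --config demo/config.yaml
```

The pipeline prints its sweep-stage summary:

```
{"n_candidates_diversity": 17, "n_candidates_fst": 15, "n_candidates_joint": 15, "n_genes_joint": 5, "n_regions": 1, "n_windows": 300}
```

Of the 300 windows scanned, 15 fall in the top 5% of both Z(F_ST) and ROD;
they merge into a single candidate region that brackets the planted sweep
and overlaps 5 genes (`demo/run/candidate_regions.bed`):

```
1	1210000	1400000	gene0012,gene0024,gene0028,gene0034,gene0057
```

`demo/run/diversity.tsv` holds the per-population summary — the target
population's diversity is depressed by the sweep:

```
population	Ho	He	pi
pop1	0.3297783855403489	0.3299196905384635	0.32991969053846343
pop2	0.3480368885291798	0.35018740012515276	0.35018740012515276
```

(H_o/H_e/π here are per-SNP-site averages on simulated common variants, so
they sit far above whole-genome per-bp values.) Other stage outputs land
beside these: `scan.tsv` (per-window F_ST/π/ROD/Z), `roh.hom.tsv` and
`roh_summary.tsv`, `ld_decay.tsv`, `genes_{fst,diversity,joint}.txt`,
`assoc.tsv`, and a `summary.json` plus per-stage `*.params.json` sidecars
recording the exact parameters used.

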