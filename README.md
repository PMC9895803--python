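# seedpurge

Tools for finding and removing a deleterious recessive allele from a crop
breeder-seed population with pooled whole-genome sequencing, and for planning
the purge that restores the stock to purity in a single generation.

Breeder seed is the foundation stock a variety is multiplied from, so a
spontaneous recessive mutation — invisible in heterozygous carriers — can
persist in it for decades, surfacing only as the occasional homozygous mutant
seedling. `seedpurge` implements the full analysis chain for one well-studied
case of this situation, a recessive lethal albino allele segregating in a
selfing rice population, and generalises each step:

1. **Two-pool linkage scan** (`poolscan`). Plants are pooled by phenotype
   (wild-type "green" vs mutant "albino") and each pool is sequenced. For a
   variant with pool allele depths (green_wt, green_mut, albino_wt,
   albino_mut), the *linkage percent* is

   ```
   100 · (green_wt + albino_mut) / (green_wt + green_mut + albino_wt + albino_mut)
   ```

   — the fraction of reads concordant with a fully linked recessive model.
   A causal variant scores 100; unlinked polymorphisms hover near 50. Sites
   are pre-filtered to a strict per-pool depth window (3 < reads < 100).
2. **Consequence prediction** (`consequence`). Variants are projected through
   a gene model onto the spliced CDS, translated, and classified
   (frameshift / missense / synonymous / in-frame indel / noncoding) with the
   first changed residue (e.g. R332P), the genomic position of any premature
   stop codon, and an impact tier (high / moderate / low / modifier).
3. **CAPS assay design** (`capsdesign`). A cleaved-amplified-polymorphic-
   sequence assay genotypes individual plants: a restriction enzyme (default
   Cfr10I, degenerate site R/CCGGY) cuts the PCR amplicon of one allele only,
   so homozygous wild-type (G), heterozygous (H) and homozygous mutant (A)
   plants give distinct gel band patterns. The module scans IUPAC recognition
   patterns on both strands, predicts digest fragments per genotype, and calls
   genotypes from observed band sizes with a configurable gel tolerance.
4. **Segregation statistics** (`mendel`). χ² goodness-of-fit of progeny counts
   against Mendelian ratios (3:1, 1:2:1), without continuity correction, plus
   incidence percentages and printed-table style p brackets.
5. **Purge planning** (`seedmgmt`). Under selfing with a recessive lethal, an
   albino incidence *a* implies carrier frequency *h = 4a* and allele
   frequency *q = 2a*; selection alone only halves *h* per generation
   (h′ = (h/2)/(1 − h/4)), whereas retaining only genotyped homozygous
   wild-type plants removes the allele in one step.
6. **Synthetic data** (`simdata`). A pool-seq generator reproducing the study
   design (13 green + 10 albino plants, ~10× per-pool depth, 216 unlinked
   background polymorphisms, carrier frequency 0.0544) writes standard
   two-sample VCFs with allele depths plus a truth table, and provides a
   verified gene fixture in which a single-C insertion in codon 332 causes
   the R332P frameshift and a premature TAG stop 23 nt downstream.

## Worked example

Simulate a clean dataset (no sequencing error, no carriers in the green
pool), scan it, annotate the top hit and design the genotyping assay:

```sh
$ printf 'error_rate: 0.0\ncarrier_freq: 0.0\n' > sim.yaml
$ seedpurge simulate --config sim.yaml --out-dir demo --seed 7
wrote 217 variants to demo/pools.vcf

$ seedpurge scan --vcf demo/pools.vcf --out demo/scan.tsv
217 variants (105 SNPs, 39 insertions, 73 deletions), 0 multi-allelic skipped, 1 candidate(s) at threshold 100.0

$ head -3 demo/scan.tsv | cut -f1-5,10-12
chrom   pos       ref  alt  var_class  linkage_percent  passed_depth  candidate
chr4    1993      G    GC   insertion  100.0            True          True
chr12   20222544  A    C    SNP        85.71            True          False

$ seedpurge annotate --gff demo/fixture_gene.gff3 --fasta demo/fixture_gene.fa \
      --vcf demo/pools.vcf --out demo/annot.tsv
SWLFIX1.1 frameshift R332P premature-stop@2017 impact=high

$ seedpurge caps --wild wild.fa --mutant mut.fa --out demo/caps.tsv
Cfr10I: G=(300,) H=(100, 200, 300) A=(100, 200) diagnostic=True
```

The scan recovers exactly one candidate at the 100% linkage threshold: the
causal single-C insertion (chr4:1993 G→GC), while the best unlinked site
scores 85.71. Annotation shows the insertion shifts the reading frame at
codon 332 (Arg→Pro) and truncates the protein at a new stop codon
(genomic position 2017, 23 nt past the insertion junction) — a
high-impact allele. The CAPS design confirms the mutant amplicon gains a
Cfr10I site: wild-type plants show one 300-bp band, mutants 100+200 bp,
heterozygotes all three.

Project how slowly selfing alone would dilute the allele, versus purging:

```sh
$ seedpurge project --h0 0.0544 --generations 3
 generation        h  expected_incidence
          0 0.054400            0.013600
          1 0.027575            0.006894
          2 0.013883            0.003471
          3 0.006966            0.001741
```

At the observed 1.36% albino incidence, 5.44% of plants are carriers; even
after three generations of selfing 0.7% still are. Genotyping with the CAPS
assay and retaining only G plants (`seedpurge purge`) eliminates the allele
immediately.

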