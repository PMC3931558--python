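# supmap

Forward simulation and pooled WGS/SNP mapping of suppressor screens in a
selfing nematode.

## The problem

Suppressor mutations — second-site lesions that restore viability to a mutant
— are hard to clone by classical mapping because they often have no phenotype
of their own. One-step mapping-by-sequencing solves this for *C. elegans*: the
suppressed mutant is crossed to the genetically divergent Hawaiian strain
(CB4856), F2 recombinants are selfed *en masse* under selection for
suppression, and the surviving pool is whole-genome sequenced once. Selection
drags the suppressor-linked chromosome region to fixation, so the causal
region reveals itself as a depletion of Hawaiian SNP alleles; the same
sequencing data are then scanned for the EMS-induced candidate mutation
inside that region.

No real sequencing data are required (or used) here: `supmap` simulates the
whole experiment — mutagenesis, backcrossing, the mapping cross, selection
and pooled read sampling — with a recorded ground truth, and implements the
downstream analysis, so that every stage of the protocol is testable at desk
scale. It is aimed at people designing such screens (how many F2s? what
coverage? what thresholds?) and at testing analysis code against a known
answer.

## The model in brief

* **Genetics.** Six chromosomes, one obligate crossover per chromosome per
  meiosis at a uniform position (complete interference; a Poisson(1) option
  exists). Markers are biallelic N2-vs-Hawaiian sites (default 20/Mb); EMS
  variants ride on haplotypes through every meiosis.
* **Selection.** A viability table over suppressor genotypes
  {sup/sup, sup/+, +/+} at the nonpermissive temperature: recessive
  (1, 0, 0) or semi-dominant (1, *h*, 0) with a brood-size multiplier for
  heterozygotes. En-masse propagation keeps the pool at constant size; its
  infinite-population limit is an exact 3-state selfing recursion
  (`selfing_recursion`), used as an independent oracle: with fully viable
  heterozygotes the suppressor frequency is 2/3 at the selected F2 and
  23/27 ≈ 0.852 two selfing generations later, versus fixation (1.0) for a
  recessive suppressor.
* **Sequencing.** Per site, depth ~ Poisson(18) and alt reads ~
  Binomial(depth, f′), f′ = f(1−e) + (1−f)e/3 with miscall rate e = 0.001.
* **Mapping.** Per-marker Hawaiian-allele frequency track → 500 kb windows
  (unweighted marker means) → contiguous runs of windows below the absence
  (0.10, recessive) or reduction (0.30, dominant) threshold → subtraction of
  the known introgression gaps (LG I 1.5–12.8 Mb, LG IV 0–15.8 Mb) → one
  unique interval, a linked/intragenic hit, or an unmapped outcome.
* **Candidates.** Parental subtraction, removal of variants shared across
  ≥ 2 strains, then missense/nonsense/splice-site variants strictly above
  85% (recessive) or 67% (semi-dominant) pool frequency inside the interval.

## Worked example

Run the desk-scale end-to-end pipeline (2 chromosomes × 2 Mb, 60 F2s):

```sh
$ supmap e2e --seed 5 --out demo
INFO supmap: outcome: extragenic_mapped; causal recovered: True
```

`demo/truth_check.json` compares the analysis against the simulation truth:

```json
{
  "causal_frequency_truth": 1.0,
  "causal_in_candidates": true,
  "interval_contains_causal": true,
  "n_unique_intervals": 1,
  "outcome": "extragenic_mapped"
}
```

The recessive suppressor went to fixation (frequency 1.0) in the sequenced
pool, mapping found exactly one unique low-Hawaiian-SNP interval
(`demo/intervals.tsv`; the LG I interval is flagged non-unique because it is
explained by the introgression gap):

```
chrom  start   end      mean_freq  n_markers  mode       unique
I      4572    937430   0.000      18         recessive  False
II     800772  1867709  0.037      29         recessive  True
```

and the candidate scan inside that interval (`demo/candidates.tsv`) contains
the true causal missense (first row; the others are linked EMS passengers
that hitchhiked through the backcrosses — real screens see the same, which
is why candidate lists have more than one entry):

```
chrom  pos      ref  alt  freq    gene       effect    interval_id
II     1200315  G    A    1.0000  sup_locus  missense  II:800772-1867709
II     1203124  C    T    1.0000  gene_003   missense  II:800772-1867709
II     1300340  G    T    0.9375  gene_001   missense  II:800772-1867709
...
```

Exit codes triage batch runs: 0 mapped, 3 linked-to-target, 4 unmapped,
2 input error. `supmap simulate` writes a full truth bundle (FASTA, GFF3,
marker TSV, gaps BED, pool and parental VCFs, truth JSON); `supmap map` and
`supmap candidates` consume those files independently. The library API
(`supmap.run_e2e`, `supmap.simulate_screen`, …) exposes the same pipeline
in memory — see `docs/methods.md` for the model details and parameter
meanings.

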