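# Methods

This note documents the models behind `supmap`, the parameters that matter,
and the choices made where the underlying protocol leaves the design open.

## The simulated experiment

The simulator (`supmap.sim`, `supmap.screen`) emulates a one-step
WGS/SNP-mapping suppressor screen in *C. elegans*:

1. **Strains.** A parental N2-like line homozygous for a temperature-
   sensitive lethal allele in a target gene, and an introgressed mapping
   strain carrying the same allele in a Hawaiian (CB4856-like) background.
   The introgressed strain is constructed directly as homozygous Hawaiian at
   every marker except inside the configured introgression gaps (LG I
   1.5–12.8 Mb and LG IV 0–15.8 Mb by default), which remain N2-type. This
   stands in for a sequence-verified introgression line; the generic
   backcross simulator (`backcross_series`, including gap clamping) is
   available and tested separately, but a literal introgression simulation
   would leave residual un-introgressed chunks that the gaps file could not
   declare, which is not the situation the analysis stage models.
2. **Mutagenesis.** EMS places one causal suppressor variant (a missense in
   the configured suppressor gene, forced to be a G:C→A:T transition) plus
   `n_passenger_ems` passengers. The alt-allele spectrum is 87% G:C→A:T
   transitions, the remainder uniform over other substitutions; the dose is
   not modeled, only the resulting load. Passengers land in coding sequence
   with probability 0.25 (roughly the coding fraction of the worm genome),
   else uniformly.
3. **Line establishment.** The mutant is driven to homozygosity at the
   suppressor (a selfing-to-fixation shortcut: one gamete carrying the
   required variants is doubled, so each heterozygous passenger fixes or is
   lost with probability 1/2), backcrossed four times to the unmutagenized
   parent while keeping the suppressor, and homozygosed again. Passengers
   linked to the suppressor hitchhike, exactly as in real screens.
4. **Mapping cross.** Suppressor line × introgressed strain → F1
   heterozygote → 250 F2 recombinants by selfing → viability selection →
   two further generations of en-masse selfing at constant pool size →
   the sequenced pool, with every true site frequency recorded.

### Meiosis

One obligate crossover per chromosome per meiosis, position uniform in base
pairs, then a random choice of product. Worm chromosomes are ~50 cM with
essentially complete interference, so this is the natural default; a
Poisson(1) crossover count is available (`crossover_model="poisson"`). The X
chromosome is treated as an autosome: after the F1, everything is
hermaphrodite selfing, and male X dosage does not affect pooled autosomal
frequencies.

### Selection and propagation

`SelectionModel` maps the suppressor genotype {sup/sup, sup/+, +/+} to a
survival probability at the nonpermissive temperature (everyone survives at
the permissive temperature) and to a relative brood size. This is a zygotic
abstraction of what is biologically a maternal-effect lethality (the
mother's genotype decides whether her brood lives); for the recessive case
the two give identical pool compositions, and for the semi-dominant case the
zygotic table is the definition adopted throughout, with the recursion below
as its exact limit.

En-masse propagation (`propagate_pool`) keeps the pool at constant size:
each offspring slot draws a parent with probability proportional to its
brood multiplier, then redraws that parent's selfed offspring until one
survives its viability draw. Every surviving parent therefore contributes an
equal number of viable offspring per unit brood weight. The deterministic
limit is the 3-state recursion `selfing_recursion`: with fully viable
heterozygotes and equal broods, genotype frequencies follow
s′ = s + h/3, h′ = 2h/3 from the selected-F2 state (1/3, 2/3), giving
suppressor allele frequencies 2/3 → 7/9 → 23/27 ≈ 0.852 across the two
extra generations, versus 1.0 throughout for a recessive suppressor. The
recursion is used as the independent oracle for the stochastic simulator.

Semi-dominant defaults are het survival 1.0 and het brood multiplier 0.5
(semi-dominant suppressors rescue heterozygotes but less productively);
both are knobs. An optional paternal-effect incompatibility locus (default
2.3 Mb on LG I, disabled by default) kills Hawaiian-homozygous zygotes sired
by heterozygous sperm — disabled in mapping runs because the LG I
introgression gap already masks that region.

### Homozygote preselection

`preselect_homozygotes` models plating F2 recombinants singly and keeping
those whose selfed brood beats a survivor threshold (default 60% of 40
progeny). It discriminates only when heterozygous broods fall below the
threshold (het survival ≲ 0.7), i.e. for weakly rescuing semi-dominant
suppressors — the case where unselected pooling fails. A preselected pool is
homozygous at the suppressor locus, so the pipeline maps it in absence mode
regardless of the dominance mode; candidate frequency thresholds still
follow the dominance mode. Whether the 120 plated F2s are drawn before or
after viability selection is configurable (`preselect_entry`); the default
is pre-selection, since F2 animals exist before their broods are scored.

## Pooled sequencing model

Per site: depth ~ Poisson(mean 18) — the genome-wide fold coverage of a
36-million-read, 50-nt library on a 100 Mb genome — or fixed depth for
deterministic tests; alt count ~ Binomial(depth, f′) with
f′ = f(1−e) + (1−f)·e/3 and e = 0.001 per-read miscall probability folding
base, strand and mapping error into one number. No read-level or
base-quality simulation. Markers and novel variants are emitted in one
VCF 4.2 file with per-sample `AD`/`DP` fields and an INFO flag
(`HAWAIIAN_MARKER`) separating the two classes, because the real protocol
scans the same pool for both.

## Mapping

The original interval definition is visual inspection of a SNP-frequency
plot; the caller here is this package's codification of it, with every
constant in `MappingParams` and recorded in output metadata:

* per-marker Hawaiian-allele frequency, markers below `min_depth` (4 reads)
  dropped and tallied;
* unweighted means over 500 kb tiling windows (one marker, one vote,
  matching the dot-per-SNP presentation of the frequency plots); windows
  with < 5 markers are uninformative;
* maximal runs of informative windows with mean ≤ threshold, bridging up to
  `merge_gap` = 1 intervening windows; bounds snap to the outermost
  sub-threshold marker positions (marker resolution, not window resolution);
  runs spanning < 500 kb are discarded;
* absence threshold 0.10 for recessive pools. The reduction cutoff for
  dominant/semi-dominant pools is **this package's default (0.30), not a
  protocol constant** — the protocol names the reduction criterion but no
  number;
* the `>20%` display filter reproduces the published plotting convention and
  is never used for calling;
* known introgression gaps (BED, 0-based half-open) are subtracted:
  contained intervals are non-unique, partial overlaps are trimmed to their
  largest residual and kept only if it spans ≥ `min_residual_span`
  (default = `min_interval_span`).

Outcomes: exactly one unique interval → `extragenic_mapped`; none, but a
qualifying new variant in the target gene → `linked_to_target`; neither →
`unmapped`; several → `ambiguous`, reported rather than silently resolved.

## Candidate identification

Pipeline order (recorded in metadata; the first two steps commute):
parental subtraction → cross-strain background removal ("common to multiple
strains" operationalized as present in ≥ 2 pools, configurable) → interval
restriction → effect and frequency filter. Thresholds are strict
inequalities (> 85% recessive, > 67% semi-dominant), so a frequency exactly
at the threshold is excluded. Effects: standard-genetic-code translation on
the coding strand of the single supplied transcript per gene; stop gain →
nonsense, amino-acid change → missense (stop loss is folded into missense),
silent → synonymous; the first/last two intronic bases → splice_site;
everything else → noncoding. Indels are out of scope throughout (EMS and
the filters handle SNVs only).

Background variants are simulated in two tiers: strain-fixed variants listed
in the parental VCF (caught by parental subtraction) and strain-fixed
variants shared across suppressor pools but absent from the parental record
(caught only by the cross-strain comparison) — so both filters do real work
in the end-to-end tests.

## What the generator does and does not emulate

It emulates: marker depletion by selection, hitchhiking passengers,
introgression-gap decoy intervals, background-variant contamination,
read-sampling noise at realistic coverage, and both dominance schemes with
and without preselection. It does not emulate: read alignment or variant
calling artifacts, non-uniform marker/recombination landscapes, multiple
isoforms, indels, or real Hawaiian SNP density (default 20 markers/Mb is
~10× sparser than reality, for desk-scale speed; density is a knob). Passing
tests therefore validate the genetics and the analysis logic, not robustness
to upstream bioinformatics noise.

## Problem sizes and numerics

Tests and the acceptance script run the full six-chromosome configuration
with 250 F2s and ~2,000 markers (a full screen plus analysis takes well
under a second), with replicate counts of 3–20 chosen so each suite stays in
the tens of seconds; the tiny two-chromosome preset is the unit-test
substrate. Stochastic assertions use replicate means with bands derived from
binomial/drift standard errors (e.g. pool-250 frequency vs the recursion
oracle within ±0.04 on the mean of five replicates). Degenerate inputs are
defined rather than crashed on: depth-0 sites carry an undefined frequency
and are retained in the VCF; extinct pools are returned empty with a
warning flag (the real screens lost three suppressors exactly this way);
an empty marker track yields an explicit no-informative-windows warning and
an `unmapped` outcome.

## Known limitations

* Zygotic rather than maternal-effect selection semantics (see above).
* The interval caller's constants are calibrated to the default marker
  density and window size; very sparse maps need rescaled `MappingParams`
  (the tiny preset shows how).
* One transcript per gene; no splice-isoform arbitration.
* The incompatibility locus model covers the paternal-effect rule only, not
  the full genetics of the incompatibility region.
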