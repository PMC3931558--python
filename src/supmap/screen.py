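"""End-to-end simulation of one suppressor screen and its mapping cross.

:func:`simulate_screen` wires together the pieces in :mod:`supmap.sim`:

1. build a sparse reference genome, synthetic gene models, and a Hawaiian
   marker map;
2. construct the parental temperature-sensitive line (target-gene lethal
   allele plus strain-fixed background variants), EMS-mutagenize it, fix the
   causal suppressor, and backcross the line to the parental strain;
3. construct the introgressed Hawaiian mapping strain (B-type markers
   everywhere except the configured introgression gaps);
4. cross, generate F2 recombinants, select (or preselect homozygotes), and
   self en masse for further generations;
5. return a truth-annotated bundle: final pool(s), variant sets, parental
   variants, and a truth record naming the causal locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .effects import GeneModel
from .genome import SparseGenome
from . import sim
from .sim import (DEFAULT_CHROM_LENGTHS, DEFAULT_INTROGRESSION_GAPS, EMSVariant,
                  Individual, MarkerMap, PopulationPool, SelectionModel)


@dataclass
class ScreenConfig:
    """Study conditions for one simulated screen.

    Defaults encode the protocol the package emulates: a six-chromosome
    ~100 Mb genome, 20 markers/Mb, 300 EMS passengers at an 87% G:C->A:T
    transition share, four backcross rounds, 250 F2 recombinants selfed en
    masse for two further generations, and the two introgression gaps on
    LG I and LG IV.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    marker_density: float = 20.0  # markers per Mb
    n_passenger_ems: int = 300
    ems_transition_fraction: float = 0.87
    coding_fraction: float = 0.25
    backcross_rounds: int = 4
    f2_pool_size: int = 250  # protocol range 160-300
    extra_selfing_generations: int = 2
    introgression_gaps: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_INTROGRESSION_GAPS))
    causal_chrom: str = "II"
    causal_pos: int = 7_000_000  # anchor of the causal (suppressor) gene
    target_chrom: str = "IV"
    target_pos: int = 11_000_000  # anchor of the target gene (inside the LG IV gap)
    intragenic: bool = False  # place the causal variant inside the target gene
    mode: str = "recessive"  # recessive | semidominant
    het_survival: float = 1.0
    het_brood: float = 0.5
    incompatibility_enabled: bool = False
    n_parental_background: int = 15
    n_shared_background: int = 20
    n_decoy_genes: int = 30
    n_background_lines: int = 2
    preselect: bool = False
    preselect_n_f2: int = 120
    preselect_threshold: float = 0.60
    preselect_progeny: int = 40
    preselect_entry: str = "pre_selection"  # or post_selection
    crossover_model: str = "obligate"
    seed: int = 0

    def __post_init__(self):
        if self.f2_pool_size <= 0:
            raise ValueError("f2_pool_size must be positive")
        for chrom, start, end in self.introgression_gaps:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"gap chromosome {chrom!r} unknown")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"gap {chrom}:{start}-{end} outside chromosome bounds")
        if self.mode not in ("recessive", "semidominant"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def selection_model(self) -> SelectionModel:
        if self.mode == "recessive":
            return SelectionModel.recessive(
                incompatibility_enabled=self.incompatibility_enabled)
        return SelectionModel.semidominant(
            het_survival=self.het_survival, het_brood=self.het_brood,
            incompatibility_enabled=self.incompatibility_enabled)


#: desk-scale preset used as the unit-test substrate
TINY_CONFIG = dict(
    chrom_lengths={"I": 2_000_000, "II": 2_000_000},
    marker_density=20.0,
    n_passenger_ems=40,
    backcross_rounds=2,
    f2_pool_size=60,
    introgression_gaps=[("I", 0, 1_000_000)],
    causal_chrom="II", causal_pos=1_200_000,
    target_chrom="I", target_pos=500_000,
    n_parental_background=4, n_shared_background=4,
    n_decoy_genes=4, n_background_lines=1,
)


def tiny_config(**overrides) -> ScreenConfig:
    kw = dict(TINY_CONFIG)
    kw.update(overrides)
    return ScreenConfig(**kw)


@dataclass
class ScreenBundle:
    """Truth-annotated output of one simulated screen."""

    config: ScreenConfig
    genome: SparseGenome
    marker_map: MarkerMap
    gene_models: list[GeneModel]
    target_gene: GeneModel
    causal_gene: GeneModel
    causal: EMSVariant
    lethal: EMSVariant  # the original target-gene allele (present in everyone)
    pool: PopulationPool
    line_variants: set[EMSVariant]  # variants segregating in / fixed in the pool
    parental_variants: set[EMSVariant]  # the unmutagenized parental line's set
    background_pools: list[set[EMSVariant]]  # other suppressor lines' variant sets
    truth: dict


def _place_genes(config: ScreenConfig, genome: SparseGenome, rng: np.random.Generator,
                 ) -> tuple[list[GeneModel], GeneModel, GeneModel]:
    genes: list[GeneModel] = []
    target = sim.make_gene("target", config.target_chrom, config.target_pos, genome, rng)
    genes.append(target)
    if config.intragenic:
        causal_gene = target
    else:
        causal_gene = sim.make_gene("sup_locus", config.causal_chrom, config.causal_pos,
                                    genome, rng)
        genes.append(causal_gene)
    chrom_names = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    p = lengths / lengths.sum()
    for i in range(config.n_decoy_genes):
        for _try in range(200):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=p))]
            anchor = int(rng.integers(1, config.chrom_lengths[chrom]))
            try:
                g = sim.make_gene(f"gene_{i:03d}", chrom, anchor, genome, rng)
            except ValueError:  # overlapped an existing segment; redraw
                continue
            genes.append(g)
            break
    return genes, target, causal_gene


def simulate_screen(config: ScreenConfig) -> ScreenBundle:
    """Deterministic given ``config.seed``; see module docstring for the steps."""
    rng = np.random.default_rng(config.seed)
    genome = SparseGenome(config.chrom_lengths, seed=int(rng.integers(2**31)))
    gene_models, target_gene, causal_gene = _place_genes(config, genome, rng)
    marker_map = sim.build_marker_map(config.chrom_lengths, config.marker_density, rng,
                                      genome=genome)
    model = config.selection_model()

    # the original lethal allele in the target gene, shared by every strain here
    pos, ref, alt = sim._pick_missense_transition(target_gene, genome,
                                                  marker_map.position_set(), rng)
    lethal = EMSVariant(target_gene.chrom, pos, ref, alt, "lethal", "missense")

    # strain-fixed background variants: some recorded in the parental VCF, some
    # only discoverable by comparing multiple suppressor pools
    taken = marker_map.position_set() | {lethal.key()[:2]}
    background = sim._draw_ems_variants(
        config.n_parental_background + config.n_shared_background,
        config.ems_transition_fraction, gene_models, genome, marker_map, rng,
        taken, config.coding_fraction, role="background")
    parental_bg = background[: config.n_parental_background]
    shared_bg = background[config.n_parental_background:]

    founder_variants = [lethal] + background
    parental = sim.make_founder(marker_map, False, founder_variants)
    introgressed = sim.clamp_gaps(
        sim.make_founder(marker_map, True, founder_variants, sex="male"),
        marker_map, config.introgression_gaps)

    # EMS mutagenesis, fixation of the suppressor, and backcrossing
    mutant, ems_variants = sim.mutagenize(
        parental, config.n_passenger_ems + 1, config.ems_transition_fraction,
        gene_models, genome, marker_map, rng, causal_gene=causal_gene,
        coding_fraction=config.coding_fraction)
    causal = next(v for v in ems_variants if v.role == "causal")
    line = sim.homozygose(mutant, [causal, lethal], marker_map, rng,
                          config.crossover_model)
    line = sim.backcross_series(line, parental, config.backcross_rounds, causal,
                                marker_map, rng, crossover_model=config.crossover_model)
    line = sim.homozygose(line, [causal, lethal], marker_map, rng,
                          config.crossover_model)

    # F1 hybrid and F2 recombinants
    f1 = Individual({c: (sim.meiosis(line, marker_map, rng, config.crossover_model)[c],
                         sim.meiosis(introgressed, marker_map, rng,
                                     config.crossover_model)[c])
                     for c in marker_map.chroms})

    if config.preselect:
        n_f2 = config.preselect_n_f2
        f2 = sim.self_cross(f1, n_f2, marker_map, rng, model, config.crossover_model)
        if config.preselect_entry == "post_selection":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f2 = sim.apply_selection(f2, model, causal, rng,
                                         marker_map=marker_map).individuals
        kept = sim.preselect_homozygotes(f2, model, causal, config.preselect_threshold,
                                         config.preselect_progeny, rng)
        pool0 = PopulationPool(kept, "F2", marker_map, causal, extinct=not kept)
        if pool0.extinct:
            warnings.warn("homozygote preselection kept no F2s", stacklevel=2)
    else:
        f2 = sim.self_cross(f1, config.f2_pool_size, marker_map, rng, model,
                            config.crossover_model)
        pool0 = sim.apply_selection(f2, model, causal, rng, marker_map=marker_map)
    pool = sim.propagate_pool(pool0, config.extra_selfing_generations, model,
                              config.f2_pool_size, rng, config.crossover_model)

    # cheap stand-ins for sibling suppressor lines (their variant *sets* only),
    # used by the cross-strain background-removal filter
    background_pools = []
    retain_p = 0.5 ** (config.backcross_rounds + 1)  # backcross + fixation
    for k in range(config.n_background_lines):
        n_keep = int(rng.binomial(config.n_passenger_ems, retain_p))
        own = sim._draw_ems_variants(
            n_keep + 1, config.ems_transition_fraction, gene_models, genome, marker_map,
            rng, marker_map.position_set() | {v.key()[:2] for v in founder_variants},
            config.coding_fraction, role="passenger")
        background_pools.append({lethal, *background, *own})

    line_variants = pool.variant_set() if pool.size else set(founder_variants) | {causal}
    truth = {
        "mode": config.mode,
        "seed": config.seed,
        "causal_chrom": causal.chrom,
        "causal_pos": causal.position,
        "causal_ref": causal.ref,
        "causal_alt": causal.alt,
        "causal_effect": causal.effect_truth,
        "causal_gene": causal_gene.gene_id,
        "target_gene": target_gene.gene_id,
        "target_chrom": target_gene.chrom,
        "target_start": target_gene.start,
        "target_end": target_gene.end,
        "intragenic": config.intragenic,
        "extinct": pool.extinct,
        "pool_size": pool.size,
        "causal_frequency": pool.variant_frequency(causal),
        "generation": pool.generation,
    }
    return ScreenBundle(config, genome, marker_map, gene_models, target_gene,
                        causal_gene, causal, lethal, pool, line_variants,
                        {lethal, *parental_bg}, background_pools, truth)
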