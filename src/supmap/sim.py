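"""Forward simulation of an EMS suppressor screen and its mapping cross.

The simulated protocol mirrors a one-step WGS/SNP suppressor-mapping
experiment in *C. elegans*: an EMS-mutagenized line carrying one causal
suppressor mutation (plus passenger mutations) in a temperature-sensitive
lethal background is crossed to an introgressed polymorphic (Hawaiian-like)
mapping strain; F2 recombinants self-fertilize en masse under selection for
suppression for two further generations; the surviving pool is harvested for
pooled sequencing.  Selection for the suppressor depletes Hawaiian markers
around the causal locus, which is what the mapping stage later detects.

Coordinates are 1-based base pairs throughout.  Marker alleles are stored as
booleans per haplotype: ``False`` = A-type (N2-like reference allele),
``True`` = B-type (Hawaiian-like allele).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .effects import Exon, GeneModel, classify_effect
from .genome import BASES, SparseGenome

TRANSITION = {"G": "A", "C": "T"}  # the G:C -> A:T transitions EMS favors

#: Chromosome sizes (bp).  LG I and LG IV match the sizes quoted for the
#: introgression gaps; the others are round approximations of the worm genome.
DEFAULT_CHROM_LENGTHS = {
    "I": 15_000_000,
    "II": 15_000_000,
    "III": 14_000_000,
    "IV": 17_500_000,
    "V": 21_000_000,
    "X": 18_000_000,
}

#: Regions of the introgressed mapping strain that failed to introgress and
#: therefore stay A-type: one flanking the target-gene locus on LG IV, one on
#: LG I around the N2/Hawaiian incompatibility locus.  (chrom, start, end),
#: half-open in bp: a 1-based position p lies in the gap iff start < p <= end.
DEFAULT_INTROGRESSION_GAPS = [("I", 1_500_000, 12_800_000), ("IV", 0, 15_800_000)]


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeMarkers:
    name: str
    length: int
    positions: np.ndarray  # int64, strictly increasing, 1-based
    allele_a: np.ndarray  # '<U1'
    allele_b: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError(f"marker positions on {self.name} not strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.length:
                raise ValueError(f"marker position outside chromosome {self.name}")
            if np.any(self.allele_a == self.allele_b):
                raise ValueError(f"allele_a == allele_b at a marker on {self.name}")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)


@dataclass
class MarkerMap:
    """Ordered biallelic strain-diagnostic sites per chromosome."""

    chroms: dict[str, ChromosomeMarkers]

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chroms.values())

    def position_set(self) -> set[tuple[str, int]]:
        return {(name, int(p)) for name, cm in self.chroms.items() for p in cm.positions}

    def marker_index(self, chrom: str, pos: int) -> int:
        """Index of the marker nearest ``pos`` on ``chrom``."""
        cm = self.chroms[chrom]
        if cm.n_markers == 0:
            raise ValueError(f"no markers on chromosome {chrom}")
        return int(np.argmin(np.abs(cm.positions - pos)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (name, int(p), a, b)
            for name, cm in self.chroms.items()
            for p, a, b in zip(cm.positions, cm.allele_a, cm.allele_b)
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])


def build_marker_map(chrom_lengths: dict[str, int], density: float,
                     rng: np.random.Generator | int, genome: SparseGenome | None = None,
                     ) -> MarkerMap:
    """Place ``round(density * Mb)`` markers per chromosome at uniform positions.

    ``density`` is markers per Mb.  When a genome is supplied, the A allele at
    each marker is the (committed) reference base, keeping the marker map and
    the reference sequence consistent.
    """
    if density <= 0:
        raise ValueError("marker density must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    chroms = {}
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        n = min(int(round(density * length / 1e6)), length)
        chosen: set[int] = set()
        while len(chosen) < n:
            draw = rng.integers(1, length + 1, size=n - len(chosen))
            chosen.update(int(p) for p in draw)
        positions = np.sort(np.fromiter(chosen, dtype=np.int64, count=len(chosen)))
        if positions.size > n:  # over-filled by the last batch
            positions = np.sort(rng.choice(positions, size=n, replace=False))
        if genome is not None:
            allele_a = np.array([genome.get_base(name, int(p)) for p in positions], dtype="<U1")
        else:
            allele_a = np.array([BASES[i] for i in rng.integers(4, size=n)], dtype="<U1")
        others = {b: [x for x in BASES if x != b] for b in BASES}
        allele_b = np.array(
            [others[a][i] for a, i in zip(allele_a, rng.integers(3, size=n))], dtype="<U1")
        chroms[name] = ChromosomeMarkers(name, int(length), positions, allele_a, allele_b)
    return MarkerMap(chroms)


# ---------------------------------------------------------------------------
# individuals and haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMSVariant:
    chrom: str
    position: int
    ref: str
    alt: str
    role: str  # causal | passenger | lethal | background
    effect_truth: str

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.alt)


@dataclass
class Haplotype:
    alleles: np.ndarray  # bool per marker; True = B-type (Hawaiian)
    variants: frozenset[EMSVariant] = frozenset()


@dataclass
class Individual:
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    sex: str = "hermaphrodite"

    def variant_dose(self, variant: EMSVariant) -> int:
        pair = self.haplotypes[variant.chrom]
        return int(variant in pair[0].variants) + int(variant in pair[1].variants)

    def marker_genotype(self, chrom: str, index: int) -> tuple[bool, bool]:
        pair = self.haplotypes[chrom]
        return bool(pair[0].alleles[index]), bool(pair[1].alleles[index])

    def all_variants(self) -> set[EMSVariant]:
        out: set[EMSVariant] = set()
        for pair in self.haplotypes.values():
            out |= pair[0].variants | pair[1].variants
        return out


def make_founder(marker_map: MarkerMap, b_type: bool | dict[str, np.ndarray],
                 variants: Iterable[EMSVariant] = (), sex: str = "hermaphrodite",
                 ) -> Individual:
    """Fully homozygous individual: all-A, all-B, or an explicit allele pattern."""
    by_chrom: dict[str, set[EMSVariant]] = {c: set() for c in marker_map.chroms}
    for v in variants:
        by_chrom[v.chrom].add(v)
    haps = {}
    for name, cm in marker_map.chroms.items():
        if isinstance(b_type, dict):
            pattern = np.asarray(b_type[name], dtype=bool)
        else:
            pattern = np.full(cm.n_markers, bool(b_type))
        vs = frozenset(by_chrom[name])
        haps[name] = (Haplotype(pattern.copy(), vs), Haplotype(pattern.copy(), vs))
    return Individual(haps, sex=sex)


# ---------------------------------------------------------------------------
# selection model
# ---------------------------------------------------------------------------

#: offspring genotype distribution (dose 2, 1, 0) from selfing a parent of
#: each suppressor dose — the Mendelian 1:2:1 table for heterozygotes.
SELF_TABLE = {2: (1.0, 0.0, 0.0), 1: (0.25, 0.5, 0.25), 0: (0.0, 0.0, 1.0)}


@dataclass
class SelectionModel:
    """Genotype -> viability/brood rules at the nonpermissive temperature.

    ``viability`` and ``brood_multiplier`` are keyed by suppressor allele dose
    (2 = sup/sup, 1 = sup/+, 0 = +/+).  At the permissive temperature every
    genotype survives.
    """

    mode: str  # recessive | semidominant | dominant
    viability: dict[int, float]
    brood_multiplier: dict[int, float]
    incompatibility_enabled: bool = False
    incompatibility_locus: tuple[str, int] = ("I", 2_300_000)

    def __post_init__(self):
        for d in (0, 1, 2):
            if not 0.0 <= self.viability[d] <= 1.0:
                raise ValueError("survival probabilities must lie in [0, 1]")
            if self.brood_multiplier[d] < 0:
                raise ValueError("brood multipliers must be non-negative")
        if self.mode == "recessive" and self.viability[1] != 0.0:
            raise ValueError("recessive mode requires sup/+ survival 0")

    def survival(self, dose: int, temperature: str = "nonpermissive") -> float:
        if temperature == "permissive":
            return 1.0
        return self.viability[dose]

    @classmethod
    def recessive(cls, **kw) -> "SelectionModel":
        return cls("recessive", {2: 1.0, 1: 0.0, 0: 0.0}, {2: 1.0, 1: 1.0, 0: 1.0}, **kw)

    @classmethod
    def semidominant(cls, het_survival: float = 1.0, het_brood: float = 0.5, **kw
                     ) -> "SelectionModel":
        return cls("semidominant", {2: 1.0, 1: het_survival, 0: 0.0},
                   {2: 1.0, 1: het_brood, 0: 1.0}, **kw)

    @classmethod
    def dominant(cls, **kw) -> "SelectionModel":
        return cls("dominant", {2: 1.0, 1: 1.0, 0: 0.0}, {2: 1.0, 1: 1.0, 0: 1.0}, **kw)


def selfing_recursion(genotype_freqs: tuple[float, float, float], generations: int,
                      model: SelectionModel) -> tuple[float, float, float]:
    """Exact infinite-population recursion for selfing under selection.

    ``genotype_freqs`` are the (sup/sup, sup/+, +/+) fractions among the
    current survivors.  Each generation, parents contribute viable selfed
    offspring in proportion to their brood multiplier; within a brood the
    offspring genotype distribution is the Mendelian selfing table
    renormalized over viable classes.  This is the deterministic limit of
    :func:`propagate_pool` and serves as its independent oracle.
    """
    state = np.asarray(genotype_freqs, dtype=float)
    if state.sum() <= 0:
        raise ValueError("genotype frequencies must sum to a positive value")
    state = state / state.sum()
    v = np.array([model.viability[2], model.viability[1], model.viability[0]])
    w = np.array([model.brood_multiplier[2], model.brood_multiplier[1],
                  model.brood_multiplier[0]])
    tables = np.array([SELF_TABLE[2], SELF_TABLE[1], SELF_TABLE[0]])
    for _ in range(generations):
        viable = tables * v  # per-parent distribution over viable offspring
        totals = viable.sum(axis=1)
        parent_w = state * w * (totals > 0)
        if parent_w.sum() == 0:
            raise ValueError("population extinct in recursion")
        parent_w = parent_w / parent_w.sum()
        cond = np.divide(viable, totals[:, None], out=np.zeros_like(viable),
                         where=totals[:, None] > 0)
        state = parent_w @ cond
    return tuple(state)


def allele_frequency(genotype_freqs: tuple[float, float, float]) -> float:
    s, h, _ = genotype_freqs
    return s + h / 2.0


def selected_f2_genotypes(model: SelectionModel) -> tuple[float, float, float]:
    """Genotype fractions among F2 survivors of an F1 heterozygote self."""
    raw = np.array(SELF_TABLE[1]) * np.array(
        [model.viability[2], model.viability[1], model.viability[0]])
    if raw.sum() == 0:
        raise ValueError("no viable F2 genotype under this model")
    return tuple(raw / raw.sum())


# ---------------------------------------------------------------------------
# meiosis and crosses
# ---------------------------------------------------------------------------

def meiosis(individual: Individual, marker_map: MarkerMap, rng: np.random.Generator,
            crossover_model: str = "obligate") -> dict[str, Haplotype]:
    """One gamete: per chromosome, crossover(s) between the parental haplotypes.

    ``obligate``: exactly one crossover at a position uniform on (0, length)
    — complete interference, matching ~50 cM worm chromosomes.  ``poisson``:
    Poisson(1) crossovers at uniform positions.
    """
    gamete = {}
    for name, cm in marker_map.chroms.items():
        h0, h1 = individual.haplotypes[name]
        if crossover_model == "obligate":
            breaks = np.array([rng.uniform(0, cm.length)])
        elif crossover_model == "poisson":
            k = rng.poisson(1.0)
            breaks = np.sort(rng.uniform(0, cm.length, size=k))
        else:
            raise ValueError(f"unknown crossover model {crossover_model!r}")
        start = int(rng.integers(2))
        hap_idx = (start + np.searchsorted(breaks, cm.positions)) % 2
        alleles = np.where(hap_idx == 0, h0.alleles, h1.alleles)
        variants: set[EMSVariant] = set()
        for j, hp in enumerate((h0, h1)):
            for v in hp.variants:
                k = int(np.searchsorted(breaks, v.position))
                if (start + k) % 2 == j:
                    variants.add(v)
        gamete[name] = Haplotype(alleles, frozenset(variants))
    return gamete


def _incompatibility_death(child: Individual, sperm_parent: Individual,
                           marker_map: MarkerMap, model: SelectionModel) -> bool:
    """Paternal-effect zygotic lethality: B/B embryos sired by a heterozygous
    parent's sperm die at the incompatibility locus."""
    chrom, pos = model.incompatibility_locus
    if chrom not in marker_map.chroms or marker_map.chroms[chrom].n_markers == 0:
        return False
    idx = marker_map.marker_index(chrom, pos)
    sire = sperm_parent.marker_genotype(chrom, idx)
    if sire[0] == sire[1]:  # homozygous sire: no effect
        return False
    g = child.marker_genotype(chrom, idx)
    return g[0] and g[1]


def cross(hermaphrodite: Individual, male: Individual, n_offspring: int,
          marker_map: MarkerMap, rng: np.random.Generator,
          selection_model: SelectionModel | None = None,
          crossover_model: str = "obligate") -> list[Individual]:
    """Independent gametes from each parent; incompatibility deaths removed."""
    if n_offspring < 0:
        raise ValueError("n_offspring must be non-negative")
    incompat = selection_model is not None and selection_model.incompatibility_enabled
    out = []
    for _ in range(n_offspring):
        gm = meiosis(hermaphrodite, marker_map, rng, crossover_model)
        gp = meiosis(male, marker_map, rng, crossover_model)
        child = Individual({c: (gm[c], gp[c]) for c in marker_map.chroms})
        if incompat and _incompatibility_death(child, male, marker_map, selection_model):
            continue
        out.append(child)
    return out


def self_cross(individual: Individual, n_offspring: int, marker_map: MarkerMap,
               rng: np.random.Generator, selection_model: SelectionModel | None = None,
               crossover_model: str = "obligate") -> list[Individual]:
    return cross(individual, individual, n_offspring, marker_map, rng,
                 selection_model, crossover_model)


def backcross_series(mutant_line: Individual, recurrent_parent: Individual, rounds: int,
                     keep_variant: EMSVariant | None, marker_map: MarkerMap,
                     rng: np.random.Generator,
                     introgression_gaps: list[tuple[str, int, int]] | None = None,
                     crossover_model: str = "obligate", max_tries: int = 10_000,
                     ) -> Individual:
    """Backcross ``rounds`` times to ``recurrent_parent``, keeping ``keep_variant``.

    Each round takes one gamete from the current line (redrawn until it
    carries the kept variant) and one from the recurrent parent; unlinked
    heterozygous passengers are transmitted with probability 1/2 per round.
    Configured introgression gaps are clamped A-type in the product, modeling
    regions that fail to introgress.
    """
    if rounds < 0:
        raise ValueError("rounds must be non-negative")
    current = mutant_line
    for _ in range(rounds):
        for _try in range(max_tries):
            g_line = meiosis(current, marker_map, rng, crossover_model)
            if keep_variant is None or keep_variant in g_line[keep_variant.chrom].variants:
                break
        else:
            raise RuntimeError("could not draw a gamete carrying the kept variant")
        g_rec = meiosis(recurrent_parent, marker_map, rng, crossover_model)
        current = Individual({c: (g_line[c], g_rec[c]) for c in marker_map.chroms})
    if introgression_gaps:
        current = clamp_gaps(current, marker_map, introgression_gaps)
    return current


def clamp_gaps(individual: Individual, marker_map: MarkerMap,
               gaps: list[tuple[str, int, int]]) -> Individual:
    """Force markers inside the gaps to the A-type allele on both haplotypes."""
    haps = {}
    for name, cm in marker_map.chroms.items():
        pair = individual.haplotypes[name]
        mask = np.zeros(cm.n_markers, dtype=bool)
        for chrom, start, end in gaps:
            if chrom == name:
                mask |= (cm.positions > start) & (cm.positions <= end)
        new_pair = tuple(
            Haplotype(np.where(mask, False, hp.alleles), hp.variants) for hp in pair)
        haps[name] = new_pair
    return Individual(haps, sex=individual.sex)


def homozygose(individual: Individual, required: Iterable[EMSVariant], marker_map: MarkerMap,
               rng: np.random.Generator, crossover_model: str = "obligate",
               max_tries: int = 10_000) -> Individual:
    """Selfing-to-fixation shortcut: double one gamete that carries every
    required variant.  Heterozygous passengers fix or are lost with
    probability 1/2 each, as under selfing."""
    required = list(required)
    for _ in range(max_tries):
        g = meiosis(individual, marker_map, rng, crossover_model)
        if all(v in g[v.chrom].variants for v in required):
            return Individual({c: (g[c], Haplotype(g[c].alleles.copy(), g[c].variants))
                               for c in marker_map.chroms})
    raise RuntimeError("could not draw a gamete carrying all required variants")


# ---------------------------------------------------------------------------
# population pool
# ---------------------------------------------------------------------------

@dataclass
class PopulationPool:
    individuals: list[Individual]
    generation: str
    marker_map: MarkerMap
    causal: EMSVariant | None = None
    extinct: bool = False

    @property
    def size(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.size

    def b_frequencies(self) -> dict[str, np.ndarray]:
        """True B-allele (Hawaiian) frequency per marker."""
        out = {}
        for name, cm in self.marker_map.chroms.items():
            if self.size == 0:
                out[name] = np.full(cm.n_markers, np.nan)
                continue
            total = np.zeros(cm.n_markers, dtype=np.int64)
            for ind in self.individuals:
                pair = ind.haplotypes[name]
                total += pair[0].alleles.astype(np.int64) + pair[1].alleles.astype(np.int64)
            out[name] = total / self.n_haplotypes
        return out

    def variant_frequency(self, variant: EMSVariant) -> float:
        if self.size == 0:
            return float("nan")
        return sum(ind.variant_dose(variant) for ind in self.individuals) / self.n_haplotypes

    def genotype_counts(self, variant: EMSVariant) -> dict[int, int]:
        counts = {0: 0, 1: 0, 2: 0}
        for ind in self.individuals:
            counts[ind.variant_dose(variant)] += 1
        return counts

    def variant_set(self) -> set[EMSVariant]:
        out: set[EMSVariant] = set()
        for ind in self.individuals:
            out |= ind.all_variants()
        return out


def apply_selection(individuals: list[Individual], model: SelectionModel,
                    causal: EMSVariant, rng: np.random.Generator,
                    temperature: str = "nonpermissive", generation: str = "F2",
                    marker_map: MarkerMap | None = None) -> PopulationPool:
    """Bernoulli survival by suppressor genotype; empty outcomes are flagged."""
    if not individuals:
        raise ValueError("population is empty")
    if marker_map is None:
        raise ValueError("marker_map is required")
    survivors = [ind for ind in individuals
                 if rng.random() < model.survival(ind.variant_dose(causal), temperature)]
    pool = PopulationPool(survivors, generation, marker_map, causal,
                          extinct=len(survivors) == 0)
    if pool.extinct:
        warnings.warn("selection left no survivors (pool extinct)", stacklevel=2)
    return pool


def _generation_number(label: str) -> int:
    try:
        return int(label.lstrip("F"))
    except ValueError:
        return 0


def propagate_pool(pool: PopulationPool, generations: int, model: SelectionModel,
                   pool_size: int, rng: np.random.Generator,
                   crossover_model: str = "obligate", max_tries: int = 1000,
                   ) -> PopulationPool:
    """Self the pool en masse for ``generations`` at constant size.

    Each offspring slot draws a parent with probability proportional to its
    brood multiplier, then redraws that parent's selfed offspring until one
    survives the viability draw — every surviving parent therefore
    contributes an equal number of viable offspring per brood weight, the
    scheme whose infinite-population limit is :func:`selfing_recursion`.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    if pool.extinct or pool.size == 0:
        return pool
    causal = pool.causal
    gen_no = _generation_number(pool.generation)
    current = pool.individuals
    for g in range(generations):
        doses = [ind.variant_dose(causal) for ind in current]
        weights = np.array([
            model.brood_multiplier[d] if _viable_brood(model, d) else 0.0 for d in doses])
        if weights.sum() == 0:
            warnings.warn("no parent can produce viable offspring (pool extinct)",
                          stacklevel=2)
            return PopulationPool([], f"F{gen_no + g + 1}", pool.marker_map, causal,
                                  extinct=True)
        cum = np.cumsum(weights) / weights.sum()
        nxt: list[Individual] = []
        for _slot in range(pool_size):
            parent = current[int(np.searchsorted(cum, rng.random()))]
            for _try in range(max_tries):
                children = self_cross(parent, 1, pool.marker_map, rng, model,
                                      crossover_model)
                if not children:  # incompatibility death
                    continue
                child = children[0]
                if rng.random() < model.survival(child.variant_dose(causal)):
                    nxt.append(child)
                    break
        if not nxt:
            warnings.warn("propagation produced no survivors (pool extinct)", stacklevel=2)
            return PopulationPool([], f"F{gen_no + g + 1}", pool.marker_map, causal,
                                  extinct=True)
        current = nxt
    return PopulationPool(current, f"F{gen_no + generations}", pool.marker_map, causal)


def _viable_brood(model: SelectionModel, dose: int) -> bool:
    table = SELF_TABLE[dose]
    v = (model.viability[2], model.viability[1], model.viability[0])
    return sum(t * s for t, s in zip(table, v)) > 0


def preselect_homozygotes(f2_individuals: list[Individual], model: SelectionModel,
                          causal: EMSVariant, survivor_threshold: float,
                          progeny_per_f2: int, rng: np.random.Generator,
                          ) -> list[Individual]:
    """Keep F2s whose simulated selfed brood beats the survival threshold.

    Mirrors plating F2 recombinants singly and scoring survivor fractions
    among their progeny; for semi-dominant suppressors with het brood
    survival below the threshold this enriches sup/sup homozygotes.  Brood
    genotypes are drawn from the Mendelian selfing table (incompatibility is
    ignored here; broods are scored at the suppressor locus only).
    """
    if progeny_per_f2 <= 0:
        raise ValueError("progeny_per_f2 must be positive")
    if not 0.0 < survivor_threshold < 1.0:
        raise ValueError("survivor_threshold must lie in (0, 1)")
    kept = []
    for ind in f2_individuals:
        dose = ind.variant_dose(causal)
        counts = rng.multinomial(progeny_per_f2, SELF_TABLE[dose])
        survivors = sum(
            rng.binomial(int(n), model.viability[d]) for n, d in zip(counts, (2, 1, 0)))
        if survivors / progeny_per_f2 > survivor_threshold:
            kept.append(ind)
    return kept


# ---------------------------------------------------------------------------
# mutagenesis
# ---------------------------------------------------------------------------

def make_gene(gene_id: str, chrom: str, anchor: int, genome: SparseGenome,
              rng: np.random.Generator, strand: str | None = None, n_exons: int = 3,
              exon_len: int = 150, intron_len: int = 60) -> GeneModel:
    """Commit a synthetic gene (coding exons + GT..AG introns) around ``anchor``."""
    if strand is None:
        strand = "+-"[rng.integers(2)]
    codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    codons = [c for c in codons if str(Seq(c).translate()) != "*"]
    cds_len = n_exons * exon_len
    cds = "".join(codons[i] for i in rng.integers(len(codons), size=cds_len // 3))
    pieces, exon_offsets, off = [], [], 0
    for i in range(n_exons):
        exon_offsets.append(off)
        pieces.append(cds[i * exon_len : (i + 1) * exon_len])
        off += exon_len
        if i < n_exons - 1:
            intron = "GT" + "".join(BASES[j] for j in rng.integers(4, size=intron_len - 4)) + "AG"
            pieces.append(intron)
            off += intron_len
    segment = "".join(pieces)
    if strand == "-":
        segment = str(Seq(segment).reverse_complement())
        span = len(segment)
        exon_offsets = [span - (o + exon_len) for o in reversed(exon_offsets)]
    start = max(1, min(anchor, genome.chrom_lengths[chrom] - len(segment)))
    genome.add_segment(chrom, start, segment)
    exons = [Exon(start + o, start + o + exon_len - 1) for o in exon_offsets]
    return GeneModel(gene_id, chrom, strand, exons)


def _pick_missense_transition(gene: GeneModel, genome: SparseGenome,
                              forbidden: set[tuple[str, int]], rng: np.random.Generator,
                              ) -> tuple[int, str, str]:
    """A CDS position in ``gene`` where the G:C->A:T transition is missense."""
    coding_positions = [p for e in gene.exons for p in range(e.start, e.end + 1)]
    for p in rng.permutation(len(coding_positions)):
        pos = coding_positions[int(p)]
        if (gene.chrom, pos) in forbidden:
            continue
        ref = genome.get_base(gene.chrom, pos)
        if ref not in TRANSITION:
            continue
        alt = TRANSITION[ref]
        if classify_effect(gene.chrom, pos, ref, alt, [gene], genome) == "missense":
            return pos, ref, alt
    raise RuntimeError(f"no missense transition site available in {gene.gene_id}")


def mutagenize(individual: Individual, n_variants: int, transition_fraction: float,
               gene_models: list[GeneModel], genome: SparseGenome, marker_map: MarkerMap,
               rng: np.random.Generator, causal_gene: GeneModel | None = None,
               coding_fraction: float = 0.25, role: str = "passenger",
               ) -> tuple[Individual, list[EMSVariant]]:
    """EMS mutagenesis: one causal variant (a missense in ``causal_gene``) plus
    ``n_variants - 1`` passengers, all heterozygous on one haplotype.

    Alt alleles follow the EMS spectrum: a G:C->A:T transition with
    probability ``transition_fraction``, otherwise a uniform draw over the
    remaining substitutions.  Passenger positions fall in coding sequence
    with probability ``coding_fraction``, else uniformly along the genome.
    Variant positions never collide with marker positions.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be at least 1 (the causal variant)")
    forbidden = marker_map.position_set()
    variants: list[EMSVariant] = []
    if causal_gene is not None:
        if causal_gene.chrom not in marker_map.chroms:
            raise ValueError(f"causal locus chromosome {causal_gene.chrom!r} is not "
                             "part of the genome")
        pos, ref, alt = _pick_missense_transition(causal_gene, genome, forbidden, rng)
        variants.append(EMSVariant(causal_gene.chrom, pos, ref, alt, "causal", "missense"))
        forbidden.add((causal_gene.chrom, pos))
        n_passengers = n_variants - 1
    else:
        n_passengers = n_variants
    variants.extend(
        _draw_ems_variants(n_passengers, transition_fraction, gene_models, genome,
                           marker_map, rng, forbidden, coding_fraction, role))
    haps = {c: pair for c, pair in individual.haplotypes.items()}
    by_chrom: dict[str, set[EMSVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, set()).add(v)
    for c, vs in by_chrom.items():
        h0, h1 = haps[c]
        haps[c] = (Haplotype(h0.alleles, h0.variants | vs), h1)
    return Individual(haps, sex=individual.sex), variants


def _draw_ems_variants(n: int, transition_fraction: float, gene_models: list[GeneModel],
                       genome: SparseGenome, marker_map: MarkerMap,
                       rng: np.random.Generator, forbidden: set[tuple[str, int]],
                       coding_fraction: float, role: str, max_tries: int = 1000,
                       ) -> list[EMSVariant]:
    chrom_names = marker_map.chrom_names
    lengths = np.array([marker_map.chroms[c].length for c in chrom_names], dtype=float)
    chrom_p = lengths / lengths.sum()
    out = []
    for _ in range(n):
        is_transition = rng.random() < transition_fraction
        for _try in range(max_tries):
            if gene_models and rng.random() < coding_fraction:
                g = gene_models[int(rng.integers(len(gene_models)))]
                exon = g.exons[int(rng.integers(len(g.exons)))]
                chrom = g.chrom
                pos = int(rng.integers(exon.start, exon.end + 1))
                ref = genome.get_base(chrom, pos)
            else:
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                pos = int(rng.integers(1, marker_map.chroms[chrom].length + 1))
                ref = (genome.ensure_base(chrom, pos, "GC") if is_transition
                       else genome.get_base(chrom, pos))
            if (chrom, pos) in forbidden:
                continue
            if is_transition and ref not in TRANSITION:
                continue
            break
        else:
            raise RuntimeError("could not place an EMS variant")
        if is_transition:
            alt = TRANSITION[ref]
        else:
            choices = [b for b in BASES if b != ref and TRANSITION.get(ref) != b]
            alt = choices[int(rng.integers(len(choices)))]
        effect = classify_effect(chrom, pos, ref, alt, gene_models, genome)
        out.append(EMSVariant(chrom, pos, ref, alt, role, effect))
        forbidden.add((chrom, pos))
    return out
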