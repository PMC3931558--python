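"""Pooled-sequencing evidence: read depths and allele counts per site.

Converts a population pool's true site frequencies into the kind of evidence
a pooled short-read experiment yields (~18-fold coverage by default): per
site, a depth drawn from the depth model and an alt read count drawn
binomially from the error-folded allele frequency.  No read-level simulation
is performed — depth and miscall probability summarize the upstream pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import PopulationPool


def fold_coverage(n_reads: float, read_length: float, genome_size: float) -> float:
    """Sequencing fold coverage = reads x read length / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_reads < 0 or read_length <= 0:
        raise ValueError("read count must be non-negative and read length positive")
    return n_reads * read_length / genome_size


@dataclass
class SeqParams:
    mean_depth: float = 18.0  # reads per site
    base_error: float = 0.001  # per-read miscall probability
    depth_model: str = "poisson"  # poisson | fixed

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.base_error <= 0.25:
            raise ValueError("base_error must lie in [0, 0.25]")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")


@dataclass
class SiteCounts:
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    is_marker: bool

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def frequency(self) -> float:
        if self.depth == 0:
            return float("nan")
        return self.alt_count / self.depth


def sample_site_counts(chrom: str, pos: int, ref: str, alt: str, true_freq: float,
                       params: SeqParams, rng: np.random.Generator,
                       is_marker: bool = False) -> SiteCounts:
    """Depth ~ depth model; alt count ~ Binomial(depth, f') with the true
    frequency folded against the miscall rate: f' = f(1-e) + (1-f)e/3."""
    if not 0.0 <= true_freq <= 1.0:
        raise ValueError("true_freq must lie in [0, 1]")
    if params.depth_model == "poisson":
        depth = int(rng.poisson(params.mean_depth))
    else:
        depth = int(round(params.mean_depth))
    e = params.base_error
    f = true_freq * (1.0 - e) + (1.0 - true_freq) * e / 3.0
    alt_count = int(rng.binomial(depth, f)) if depth > 0 else 0
    return SiteCounts(chrom, pos, ref, alt, depth - alt_count, alt_count, is_marker)


def sample_pool_sites(pool: PopulationPool, params: SeqParams, rng: np.random.Generator,
                      extra_fixed_variants=()) -> list[SiteCounts]:
    """Sequencing evidence for every marker and every segregating variant.

    ``extra_fixed_variants`` are variants fixed in the pool's genetic
    background (frequency 1) that individuals do not carry explicitly.
    """
    sites: list[SiteCounts] = []
    bfreq = pool.b_frequencies()
    chrom_order = {c: i for i, c in enumerate(pool.marker_map.chrom_names)}
    for name, cm in pool.marker_map.chroms.items():
        for j in range(cm.n_markers):
            sites.append(sample_site_counts(
                name, int(cm.positions[j]), str(cm.allele_a[j]), str(cm.allele_b[j]),
                float(bfreq[name][j]), params, rng, is_marker=True))
    variants = sorted(pool.variant_set() | set(extra_fixed_variants),
                      key=lambda v: (chrom_order[v.chrom], v.position))
    for v in variants:
        freq = 1.0 if v in extra_fixed_variants else pool.variant_frequency(v)
        sites.append(sample_site_counts(v.chrom, v.position, v.ref, v.alt, freq,
                                        params, rng, is_marker=False))
    sites.sort(key=lambda s: (chrom_order[s.chrom], s.pos))
    return sites
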