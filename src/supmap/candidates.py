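"""Candidate-mutation identification inside mapped intervals.

Pipeline order (recorded in run metadata): parental subtraction ->
cross-strain background removal -> interval restriction -> allele-frequency
threshold and effect-class filter.  Thresholds are strict: a recessive
candidate needs frequency > 0.85, a semi-dominant one > 0.67.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import pandas as pd

from .effects import GeneModel, classify_effect
from .mapping import IntervalCall

VariantKey = tuple[str, int, str]  # (chrom, pos, alt)


@dataclass
class FilterPolicy:
    recessive_min_freq: float = 0.85
    semidominant_min_freq: float = 0.67
    allowed_effects: frozenset[str] = frozenset({"missense", "nonsense", "splice_site"})
    background_min_strains: int = 2  # "multiple strains" operationalized as >= 2

    def __post_init__(self):
        if not 0.0 < self.semidominant_min_freq < self.recessive_min_freq <= 1.0:
            raise ValueError("need 0 < semidominant_min_freq < recessive_min_freq <= 1")

    def min_freq(self, mode: str) -> float:
        if mode == "recessive":
            return self.recessive_min_freq
        if mode in ("semidominant", "dominant"):
            return self.semidominant_min_freq
        raise ValueError(f"unknown mode {mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_effects"] = sorted(self.allowed_effects)
        return d


def _keys(df: pd.DataFrame) -> pd.Series:
    return pd.Series(list(zip(df["chrom"], df["pos"], df["alt"])), index=df.index)


def novel_variants(pool_df: pd.DataFrame) -> pd.DataFrame:
    """Non-marker sites with defined frequency (depth > 0)."""
    df = pool_df[(~pool_df["is_marker"]) & (pool_df["depth"] > 0)]
    return df.reset_index(drop=True)


def subtract_parental(variants: pd.DataFrame, parental: set[VariantKey]) -> pd.DataFrame:
    """Drop every variant present in the unmutagenized parental strain."""
    if variants.empty or not parental:
        return variants.reset_index(drop=True)
    keep = ~_keys(variants).isin(parental)
    return variants[keep.to_numpy()].reset_index(drop=True)


def remove_background(variants: pd.DataFrame, other_pools: list[set[VariantKey]],
                      min_strains: int = 2) -> pd.DataFrame:
    """Drop variants found in >= ``min_strains`` pools, counting the focal one.

    Variants shared across independently derived suppressor strains are
    strain background, not induced candidates.
    """
    if not other_pools:
        warnings.warn("no other pools supplied; background removal is a pass-through",
                      stacklevel=2)
        return variants.reset_index(drop=True)
    if variants.empty:
        return variants.reset_index(drop=True)
    counts = _keys(variants).map(
        lambda k: 1 + sum(k in pool for pool in other_pools))
    return variants[(counts < min_strains).to_numpy()].reset_index(drop=True)


def annotate_effects(variants: pd.DataFrame, gene_models: list[GeneModel],
                     genome) -> pd.DataFrame:
    """Add ``effect`` and ``gene`` columns via the effect classifier."""
    effects, gene_ids = [], []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for row in variants.itertuples():
        models = by_chrom.get(row.chrom, [])
        effects.append(classify_effect(row.chrom, int(row.pos), row.ref, row.alt,
                                       models, genome))
        gene = next((g.gene_id for g in models if g.contains(int(row.pos))), None)
        gene_ids.append(gene)
    out = variants.copy()
    out["effect"] = effects
    out["gene"] = gene_ids
    return out


def filter_candidates(variants: pd.DataFrame, interval: IntervalCall, mode: str,
                      policy: FilterPolicy) -> pd.DataFrame:
    """Variants inside the interval with an allowed effect class and pool
    frequency strictly above the mode's threshold, sorted by position."""
    if variants.empty:
        return variants.reset_index(drop=True)
    thr = policy.min_freq(mode)
    mask = (
        (variants["chrom"] == interval.chrom)
        & (variants["pos"] >= interval.start)
        & (variants["pos"] <= interval.end)
        & (variants["effect"].isin(policy.allowed_effects))
        & (variants["freq"] > thr)
    )
    return variants[mask].sort_values("pos").reset_index(drop=True)


def detect_intragenic(variants: pd.DataFrame, target_gene: GeneModel, mode: str,
                      policy: FilterPolicy) -> pd.DataFrame:
    """Qualifying new variants inside the target gene itself — reported even
    when no unique extragenic interval exists (linked/intragenic suppressors)."""
    if variants.empty:
        return variants.reset_index(drop=True)
    thr = policy.min_freq(mode)
    mask = (
        (variants["chrom"] == target_gene.chrom)
        & (variants["pos"] >= target_gene.start)
        & (variants["pos"] <= target_gene.end)
        & (variants["effect"].isin(policy.allowed_effects))
        & (variants["freq"] > thr)
    )
    return variants[mask].sort_values("pos").reset_index(drop=True)


REPORT_COLUMNS = ["chrom", "pos", "ref", "alt", "freq", "gene", "effect", "interval_id"]


def report_table(candidates: pd.DataFrame, outcome: str, run_metadata: dict,
                 truth: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Candidate table plus a run report (with truth comparison when known)."""
    table = candidates.copy()
    if table.empty:
        table = pd.DataFrame(columns=REPORT_COLUMNS)
    else:
        if "interval_id" not in table:
            table["interval_id"] = None
        table = table[REPORT_COLUMNS]
    report = {
        "outcome": outcome,
        "n_candidates": int(len(table)),
        "metadata": run_metadata,
    }
    if truth is not None:
        causal_key = (truth["causal_chrom"], truth["causal_pos"], truth["causal_alt"])
        found = bool(len(table)) and any(
            (row.chrom, int(row.pos), row.alt) == causal_key
            for row in table.itertuples())
        report["truth"] = {
            "causal_chrom": truth["causal_chrom"],
            "causal_pos": truth["causal_pos"],
            "causal_in_candidates": found,
        }
    return table, report
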