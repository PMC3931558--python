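"""High-level pipeline glue: simulate -> sequence -> map -> candidates.

These functions operate on in-memory objects; :mod:`supmap.cli` adds the
file-based entry points around them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import candidates as cand
from . import mapping, pool_seq
from .mapping import MappingParams
from .candidates import FilterPolicy
from .pool_seq import SeqParams
from .screen import ScreenBundle, ScreenConfig, simulate_screen


def sequence_pool(bundle: ScreenBundle, seq_params: SeqParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Pooled sequencing evidence for the bundle's final pool, as a DataFrame
    matching :func:`supmap.io.read_pool_vcf` output."""
    sites = pool_seq.sample_pool_sites(bundle.pool, seq_params, rng)
    rows = [(s.chrom, s.pos, s.ref, s.alt, s.ref_count, s.alt_count, s.depth,
             s.frequency, s.is_marker) for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ref_count",
                                       "alt_count", "depth", "freq", "is_marker"])


def run_mapping(pool_df: pd.DataFrame, markers_df: pd.DataFrame,
                gaps: list[tuple[str, int, int]], mode: str, params: MappingParams,
                chrom_lengths: dict[str, int], target_gene_hits: int = 0) -> dict:
    """Frequency track -> windows -> interval calls -> gap subtraction -> outcome."""
    track, coverage = mapping.marker_frequencies(pool_df, markers_df, params.min_depth)
    windows = mapping.window_stats(track, params, chrom_lengths)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        called = mapping.call_intervals(windows, track, mode, params)
    min_residual = (params.min_residual_span if params.min_residual_span is not None
                    else params.min_interval_span)
    intervals = mapping.subtract_known_gaps(called, gaps, min_residual)
    outcome, details = mapping.classify_outcome(intervals, target_gene_hits)
    return {
        "track": track,
        "display_track": mapping.display_filter(track, params.display_min_freq),
        "windows": windows,
        "intervals": intervals,
        "outcome": outcome,
        "outcome_details": details,
        "coverage_report": coverage,
        "warnings": [str(w.message) for w in caught],
        "params": params,
    }


def run_candidates(pool_df: pd.DataFrame, parental_keys: set, other_pool_keys: list,
                   intervals, mode: str, policy: FilterPolicy, gene_models, genome,
                   target_gene=None, truth: dict | None = None) -> dict:
    """Parental subtraction -> background removal -> effect annotation ->
    interval/threshold filter (+ intragenic scan of the target gene)."""
    stage_counts = {}
    variants = cand.novel_variants(pool_df)
    stage_counts["novel"] = len(variants)
    variants = cand.subtract_parental(variants, parental_keys)
    stage_counts["after_parental_subtraction"] = len(variants)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variants = cand.remove_background(variants, other_pool_keys,
                                          policy.background_min_strains)
    stage_counts["after_background_removal"] = len(variants)
    variants = cand.annotate_effects(variants, gene_models, genome)

    unique = [iv for iv in intervals if iv.unique]
    pieces = []
    for i, iv in enumerate(unique):
        hits = cand.filter_candidates(variants, iv, mode, policy)
        hits["interval_id"] = f"{iv.chrom}:{iv.start}-{iv.end}"
        pieces.append(hits)
    in_interval = (pd.concat(pieces, ignore_index=True) if pieces
                   else variants.iloc[0:0].assign(interval_id=None))
    stage_counts["in_interval_candidates"] = len(in_interval)

    intragenic = variants.iloc[0:0]
    if target_gene is not None:
        intragenic = cand.detect_intragenic(variants, target_gene, mode, policy)
        intragenic = intragenic.assign(interval_id="target_gene")
    candidate_table = (pd.concat([in_interval, intragenic], ignore_index=True)
                       .drop_duplicates(subset=["chrom", "pos", "alt"])
                       if len(in_interval) or len(intragenic) else in_interval)

    outcome, details = mapping.classify_outcome(intervals, len(intragenic))
    metadata = {
        "mode": mode,
        "policy": policy.to_dict(),
        "stage_counts": stage_counts,
        "pipeline_order": ["parental_subtraction", "background_removal",
                           "interval_restriction", "threshold_and_effect"],
    }
    table, report = cand.report_table(candidate_table, outcome, metadata, truth)
    report["outcome_details"] = details
    return {
        "candidates": table,
        "intragenic": intragenic,
        "report": report,
        "outcome": outcome,
        "stage_counts": stage_counts,
    }


def run_e2e(config: ScreenConfig, seq_params: SeqParams | None = None,
            mapping_params: MappingParams | None = None,
            policy: FilterPolicy | None = None) -> dict:
    """Full desk-scale experiment: simulate the screen, sample pooled reads,
    map intervals, and call candidates, with truth comparison."""
    seq_params = seq_params or SeqParams()
    mapping_params = mapping_params or MappingParams()
    policy = policy or FilterPolicy()
    bundle = simulate_screen(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    pool_df = sequence_pool(bundle, seq_params, rng)
    markers_df = bundle.marker_map.to_dataframe()
    # a preselected pool is homozygous at the suppressor locus, so its mapping
    # signature is absence of Hawaiian markers regardless of dominance; the
    # candidate frequency threshold still follows the dominance mode
    mapping_mode = "recessive" if config.preselect else config.mode
    mapped = run_mapping(pool_df, markers_df, config.introgression_gaps, mapping_mode,
                         mapping_params, config.chrom_lengths)
    parental_keys = {v.key() for v in bundle.parental_variants}
    other_keys = [{v.key() for v in s} for s in bundle.background_pools]
    called = run_candidates(pool_df, parental_keys, other_keys, mapped["intervals"],
                            config.mode, policy, bundle.gene_models, bundle.genome,
                            target_gene=bundle.target_gene, truth=bundle.truth)
    unique = [iv for iv in mapped["intervals"] if iv.unique]
    truth_check = {
        "causal_frequency_truth": bundle.truth["causal_frequency"],
        "n_unique_intervals": len(unique),
        "interval_contains_causal": any(
            iv.contains(bundle.causal.chrom, bundle.causal.position) for iv in unique),
        "causal_in_candidates": called["report"].get("truth", {}).get(
            "causal_in_candidates", False),
        "outcome": called["outcome"],
    }
    return {"bundle": bundle, "pool_df": pool_df, "mapping": mapped,
            "candidates": called, "truth_check": truth_check}
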