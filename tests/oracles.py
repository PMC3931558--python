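"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results through a different code path than the
package: the interval oracle scans windows directly, and the effect oracle
mutates the full chromosome string and re-translates the spliced transcript.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from supmap.effects import GeneModel
from supmap.mapping import MappingParams


def interval_oracle(windows: pd.DataFrame, track: pd.DataFrame, mode: str,
                    params: MappingParams) -> list[tuple[str, int, int]]:
    """Exhaustive low-window grouping, independent of the package's caller."""
    thr = (params.absence_threshold if mode == "recessive"
           else params.reduction_threshold)
    out = []
    for chrom in windows["chrom"].unique():
        sub = windows[windows["chrom"] == chrom]
        low = sorted(int(w) for w in sub[
            sub["informative"] & (sub["mean_freq"] <= thr)]["window"])
        if not low:
            continue
        groups, cur = [], [low[0]]
        for w in low[1:]:
            if w - cur[-1] <= params.merge_gap + 1:
                cur.append(w)
            else:
                groups.append(cur)
                cur = [w]
        groups.append(cur)
        tsub = track[track["chrom"] == chrom]
        for grp in groups:
            members = set(grp)
            positions = [
                int(p) for p, f in zip(tsub["pos"], tsub["freq"])
                if ((p - 1) // params.window_size) in members and f <= thr]
            if not positions:
                continue
            start, end = min(positions), max(positions)
            if end - start >= params.min_interval_span:
                out.append((chrom, start, end))
    return out


def effect_oracle(chrom_seq: str, chrom: str, pos: int, alt: str,
                  genes: list[GeneModel]) -> str:
    """Classify by mutating the chromosome string and re-translating."""
    for g in genes:
        if g.chrom != chrom or not (g.start <= pos <= g.end):
            continue
        in_exon = any(e.start <= pos <= e.end for e in g.exons)
        if not in_exon:
            for a, b in zip(g.exons, g.exons[1:]):
                if a.end < pos <= a.end + 2 or b.start - 2 <= pos < b.start:
                    return "splice_site"
            return "noncoding"
        mutant = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]

        def protein(seq: str) -> str:
            cds = "".join(seq[e.start - 1 : e.end] for e in g.exons)
            if g.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            return str(Seq(cds).translate())

        p_ref, p_alt = protein(chrom_seq), protein(mutant)
        if p_alt == p_ref:
            return "synonymous"
        changed = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
        if any(b == "*" for _, b in changed):
            return "nonsense"
        return "missense"
    return "noncoding"


def random_track(rng: np.random.Generator, n_windows: int, window_size: int,
                 chrom: str = "I") -> pd.DataFrame:
    """A synthetic frequency track spanning ``n_windows`` tiles with random
    marker counts and a mixture of high, low, and intermediate frequencies."""
    rows = []
    for w in range(n_windows):
        n = int(rng.integers(0, 9))
        base = rng.choice([0.02, 0.2, 0.5])
        for _ in range(n):
            pos = int(rng.integers(w * window_size + 1, (w + 1) * window_size + 1))
            freq = float(np.clip(base + rng.normal(0, 0.05), 0, 1))
            rows.append((chrom, pos, freq, 18))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "freq", "depth"])
    return df.drop_duplicates("pos").sort_values("pos").reset_index(drop=True)
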