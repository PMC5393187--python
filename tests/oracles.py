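"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written as naively as possible and never imports the
implementation paths it checks (only shared plain data types).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_window_counts(protein: str, width: int, members: set[str]) -> list[int]:
    out = []
    for s in range(len(protein) - width + 1):
        out.append(sum(1 for aa in protein[s:s + width] if aa in members))
    return out


def brute_find_tracts(
    protein: str, width: int, members: set[str], min_count: int, radius: int
) -> list[tuple[int, int, int]]:
    """Greedy selection by repeated global-max scan.

    Returns (start, count, last_target_res) triples sorted by start.
    """
    counts = brute_window_counts(protein, width, members)
    candidates = {s: c for s, c in enumerate(counts) if c >= min_count}
    kept = []
    while candidates:
        best = max(candidates, key=lambda s: (candidates[s], -s))
        kept.append(best)
        candidates = {
            s: c for s, c in candidates.items() if abs(s - best) > radius
        }
    result = []
    for s in sorted(kept):
        last = max(
            i for i in range(s, s + width) if protein[i] in members
        )
        result.append((s, counts[s], last))
    return result


def brute_control_windows(
    protein: str, width: int, members: set[str], max_count: int
) -> list[tuple[int, int]]:
    counts = brute_window_counts(protein, width, members)
    return [(s, c) for s, c in enumerate(counts) if c <= max_count]


def brute_regions(
    n_codons: int, last_target_res: int,
    post_offset: int = 40, stop_trim: int = 20, start_trim: int = 20,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """(pre, post) nt intervals or None when unanalyzable."""
    post_start = last_target_res + 1 + post_offset
    post_end = n_codons - 1 - stop_trim
    if post_start >= post_end or start_trim >= post_start:
        return None
    return (3 * start_trim, 3 * post_start), (3 * post_start, 3 * post_end)


def brute_included_set(
    records,
    wt_totals: dict[str, int],
    protein_lengths: dict[str, int],
    n_codons: dict[str, int],
    min_reads_wt: int = 25,
    terminal_fraction: float = 0.05,
    min_codons_to_stop: int = 30,
    outlier_sd: float = 2.0,
    reference_ratios=None,
) -> set[int]:
    """Indices of records surviving all four filters, recomputed naively.

    Each record needs attributes transcript_id, tract (start_res, end_res)
    and ratio (None when undefined).
    """
    survivors_pre_sd = []
    for i, r in enumerate(records):
        tid = r.transcript_id
        if r.ratio is None:
            continue
        if wt_totals.get(tid, 0) < min_reads_wt:
            continue
        n = protein_lengths[tid]
        if r.tract.start_res < terminal_fraction * n:
            continue
        if r.tract.start_res + r.tract.width > (1 - terminal_fraction) * n:
            continue
        if (n_codons[tid] - 1) - (r.tract.start_res + r.tract.width) < min_codons_to_stop:
            continue
        survivors_pre_sd.append(i)
    if reference_ratios is None:
        ref = [records[i].ratio for i in survivors_pre_sd]
    else:
        ref = list(reference_ratios)
    if len(ref) >= 2:
        mean = sum(ref) / len(ref)
        sd = math.sqrt(sum((x - mean) ** 2 for x in ref) / len(ref))
        cutoff = mean + outlier_sd * sd
    else:
        cutoff = math.inf
    return {i for i in survivors_pre_sd if records[i].ratio <= cutoff}


def pooled_ttest(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance t-test from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA from sums of squares."""
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return f, p


def ks_distance(a, b) -> float:
    return float(stats.ks_2samp(a, b).statistic)
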