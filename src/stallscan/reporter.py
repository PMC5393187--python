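"""Reporter-specific metrics: post-stall occupancy, mRNA abundance,
flow-cytometry normalization and read-through ratios, group statistics."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisParams, CoverageTrack, ReporterLayout

FLOW_COLUMNS = ["sample", "replicate", "gfp", "rfp", "ssc"]


def relative_post_stall_occupancy(
    track: CoverageTrack, layout: ReporterLayout, params: AnalysisParams
) -> float:
    """Reads/base in the actively-translating RFP region over total reads/base.

    The first and last ``stop_trim`` codons of the ORF are excluded from the
    denominator; the numerator is the RFP region intersected with
    [stall end + post_offset codons, n_codons - stop_trim), i.e. the 40
    codons of cycloheximide pile-up past the stall are excluded.
    """
    n_codons = len(track) // 3
    denom_lo, denom_hi = params.start_trim, n_codons - params.stop_trim
    if denom_hi <= denom_lo:
        raise ValueError("trimmed ORF region is empty")
    num_lo = max(layout.rfp_region[0], layout.stall_region[1] + params.post_offset)
    num_hi = min(layout.rfp_region[1], denom_hi)
    if num_hi <= num_lo:
        raise ValueError("post-stall RFP region is empty after exclusions")

    counts = track.counts
    denom_reads = float(counts[3 * denom_lo:3 * denom_hi].sum())
    if denom_reads == 0:
        raise ValueError(f"{track.transcript_id}: no reads in trimmed ORF")
    denom_density = denom_reads / (3 * (denom_hi - denom_lo))
    num_density = float(counts[3 * num_lo:3 * num_hi].sum()) / (3 * (num_hi - num_lo))
    return num_density / denom_density


def post_stall_drop(stall_value: float, nonstall_value: float) -> float:
    """Percent drop of the stalling reporter relative to the nonstalling one."""
    if nonstall_value <= 0:
        raise ValueError("nonstalling reference value must be positive")
    return 100.0 * (1.0 - stall_value / nonstall_value)


def reporter_mrna_abundance(
    reporter_track: CoverageTrack,
    transcriptome_tracks: Mapping[str, CoverageTrack],
    min_expressed: int = 100,
) -> float:
    """Length-normalized reporter reads over the transcriptome median.

    Requires at least ``min_expressed`` CDS with nonzero reads so the median
    is meaningful.
    """
    densities = np.array(
        [t.total_reads / len(t) for t in transcriptome_tracks.values()],
        dtype=float,
    )
    if (densities > 0).sum() < min_expressed:
        raise ValueError(
            f"fewer than {min_expressed} expressed CDS in the transcriptome"
        )
    med = float(np.median(densities))
    if med == 0:
        raise ValueError("median transcriptome density is zero")
    return (reporter_track.total_reads / len(reporter_track)) / med


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

def _check_flow(events: pd.DataFrame) -> None:
    missing = [c for c in FLOW_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"flow table missing columns {missing}")
    for c in ("gfp", "rfp", "ssc"):
        if (events[c] <= 0).any():
            raise ValueError(f"non-positive values in channel {c}")


def normalize_flow(
    events: pd.DataFrame,
    blank: pd.DataFrame,
    geometric: bool = False,
) -> pd.DataFrame:
    """Side-scatter normalize per event, then normalize to the blank strain.

    Per event each fluorescence channel is divided by side scatter; per
    (sample, replicate) the mean of that quantity is divided by the blank's
    mean. Returns rows of (sample, replicate, gfp_norm, rfp_norm).
    ``geometric=True`` switches both means to geometric.
    """
    if blank is None or len(blank) == 0:
        raise ValueError("blank (no-reporter control) sample is required")
    _check_flow(events)
    _check_flow(blank)

    def _mean(x: np.ndarray) -> float:
        return float(np.exp(np.mean(np.log(x)))) if geometric else float(np.mean(x))

    blank_gfp = _mean((blank["gfp"] / blank["ssc"]).to_numpy())
    blank_rfp = _mean((blank["rfp"] / blank["ssc"]).to_numpy())

    rows = []
    for (sample, rep), grp in events.groupby(["sample", "replicate"], sort=True):
        rows.append({
            "sample": sample,
            "replicate": rep,
            "gfp_norm": _mean((grp["gfp"] / grp["ssc"]).to_numpy()) / blank_gfp,
            "rfp_norm": _mean((grp["rfp"] / grp["ssc"]).to_numpy()) / blank_rfp,
        })
    return pd.DataFrame(rows)


def readthrough_ratio(
    stall_summary: Mapping[str, float], nonstall_summary: Mapping[str, float]
) -> float:
    """RFP/GFP of the stalling reporter as a percentage of the nonstalling one."""
    for s in (stall_summary, nonstall_summary):
        if s["gfp_norm"] <= 0:
            raise ValueError("normalized GFP must be positive")
        if s["rfp_norm"] < 0:
            raise ValueError("normalized RFP must be non-negative")
    stall = stall_summary["rfp_norm"] / stall_summary["gfp_norm"]
    nonstall = nonstall_summary["rfp_norm"] / nonstall_summary["gfp_norm"]
    if nonstall <= 0:
        raise ValueError("nonstalling RFP/GFP must be positive")
    return 100.0 * stall / nonstall


def sample_summary(normalized: pd.DataFrame, sample: str) -> dict[str, float]:
    """Mean normalized channels across a sample's replicates."""
    grp = normalized[normalized["sample"] == sample]
    if grp.empty:
        raise KeyError(f"sample {sample!r} not in normalized table")
    return {
        "gfp_norm": float(grp["gfp_norm"].mean()),
        "rfp_norm": float(grp["rfp_norm"].mean()),
    }


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_stats(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Mean +/- SEM per group, one-way ANOVA, Tukey HSD pairwise table.

    Groups with fewer than 2 replicates are dropped from inference with a
    warning. When every group is a constant with zero variance the ANOVA is
    degenerate; F is reported as 0 with p = 1 and all pairs non-significant.
    """
    groups = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has <2 replicates; dropped from inference")
            continue
        groups[name] = arr
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >=2 replicates")

    summary = pd.DataFrame([
        {
            "group": name,
            "n": arr.size,
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)),
        }
        for name, arr in groups.items()
    ])

    names = sorted(groups)
    arrays = [groups[n] for n in names]
    pooled_var = np.concatenate(arrays).var(ddof=0)
    within_var = sum(a.var(ddof=0) * a.size for a in arrays)
    if within_var == 0 and all(
        a.mean() == arrays[0].mean() for a in arrays
    ):
        warnings.warn("all groups identical constants; ANOVA degenerate")
        f_stat, p_value = 0.0, 1.0
        pairs = pd.DataFrame([
            {"group1": g1, "group2": g2, "meandiff": 0.0, "p_adj": 1.0,
             "lower": 0.0, "upper": 0.0, "reject": False}
            for i, g1 in enumerate(names) for g2 in names[i + 1:]
        ])
        return {"summary": summary, "anova_F": f_stat, "anova_p": p_value,
                "tukey": pairs}

    f_stat, p_value = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    ci = tk.confidence_interval()
    pairs = []
    for i, g1 in enumerate(names):
        for j in range(i + 1, len(names)):
            g2 = names[j]
            pairs.append({
                "group1": g1,
                "group2": g2,
                "meandiff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(tk.pvalue[i, j]),
                "lower": float(ci.low[i, j]),
                "upper": float(ci.high[i, j]),
                "reject": bool(tk.pvalue[i, j] < 0.05),
            })
    return {
        "summary": summary,
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "tukey": pd.DataFrame(pairs),
    }
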