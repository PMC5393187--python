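"""Pre/post-tract occupancy ratios, filters, metaprofiles, matched controls.

Region conventions (codon coordinates, then converted to nt):

* post region: ``[last_target_res + 1 + post_offset, n_codons - 1 - stop_trim)``
  — starts 40 codons past the last target residue (skipping the
  cycloheximide pile-up) and stops 20 codons before the stop codon;
* pre region: ``[start_trim, post_start)`` — from 20 codons after the start
  to the beginning of the post region, tract and pile-up zone included.

The occupancy ratio is (post reads / post length) / (pre reads / pre length).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisParams, CoverageTrack, Transcript, TractWindow

logger = logging.getLogger(__name__)

FILTER_NAMES = ("min_reads_wt", "terminal_5pct", "dist_to_stop", "control_sd_outlier")


@dataclass(frozen=True)
class RegionPair:
    """Pre/post nt intervals on one transcript; pre.end == post.start."""

    pre: tuple[int, int]
    post: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pre[1] != self.post[0]:
            raise ValueError("pre region must end where post region starts")


@dataclass
class OccupancyRecord:
    transcript_id: str
    tract: TractWindow
    pre_density: float | None = None
    post_density: float | None = None
    ratio: float | None = None
    filters: dict[str, bool] = field(default_factory=dict)
    exclusion_reason: str | None = None

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None and all(self.filters.values())


@dataclass(frozen=True)
class MetaProfile:
    offsets: np.ndarray           # -flank .. +flank inclusive
    mean_frequency: np.ndarray
    n_windows: int


def define_regions(
    tract: TractWindow, transcript: Transcript, params: AnalysisParams
) -> RegionPair | None:
    """Pre/post nt intervals for one tract; None when unanalyzable.

    A tract is unanalyzable when the post region (or the pre region) is
    empty, e.g. the tract sits too close to the stop codon. Control windows
    with no target-class residue (last_target_res = -1) are anchored at the
    window's last residue instead.
    """
    anchor = tract.last_target_res if tract.last_target_res >= 0 else tract.end_res - 1
    post_start_codon = anchor + 1 + params.post_offset
    post_end_codon = transcript.n_codons - 1 - params.stop_trim
    pre_start_codon = params.start_trim
    if post_start_codon >= post_end_codon or pre_start_codon >= post_start_codon:
        return None
    return RegionPair(
        pre=(3 * pre_start_codon, 3 * post_start_codon),
        post=(3 * post_start_codon, 3 * post_end_codon),
    )


def occupancy_ratio(
    track: CoverageTrack, regions: RegionPair, tract: TractWindow
) -> OccupancyRecord:
    """Length-normalized post reads over length-normalized pre reads."""
    pre_reads = float(track.counts[regions.pre[0]:regions.pre[1]].sum())
    post_reads = float(track.counts[regions.post[0]:regions.post[1]].sum())
    pre_density = pre_reads / (regions.pre[1] - regions.pre[0])
    post_density = post_reads / (regions.post[1] - regions.post[0])
    rec = OccupancyRecord(
        transcript_id=track.transcript_id,
        tract=tract,
        pre_density=pre_density,
        post_density=post_density,
    )
    if pre_density == 0:
        rec.exclusion_reason = "zero_pre"
    else:
        rec.ratio = post_density / pre_density
    return rec


def score_windows(
    windows: Sequence[TractWindow],
    tracks: Mapping[str, CoverageTrack],
    transcripts: Sequence[Transcript],
    params: AnalysisParams,
) -> list[OccupancyRecord]:
    """define_regions + occupancy_ratio over a window collection.

    Unanalyzable windows yield records flagged ``empty_region``; windows on
    transcripts without coverage are flagged ``no_track``.
    """
    by_id = {t.id: t for t in transcripts}
    records = []
    for w in windows:
        transcript = by_id[w.transcript_id]
        track = tracks.get(w.transcript_id)
        if track is None:
            rec = OccupancyRecord(w.transcript_id, w, exclusion_reason="no_track")
        else:
            regions = define_regions(w, transcript, params)
            if regions is None:
                rec = OccupancyRecord(w.transcript_id, w, exclusion_reason="empty_region")
            else:
                rec = occupancy_ratio(track, regions, w)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _passes_min_reads_wt(
    rec: OccupancyRecord, wt_tracks: Mapping[str, CoverageTrack], params: AnalysisParams
) -> bool:
    wt = wt_tracks.get(rec.transcript_id)
    if wt is None:
        logger.warning("%s: no wt track, read filter fails closed", rec.transcript_id)
        return False
    return wt.total_reads >= params.min_transcript_reads_wt


def _passes_terminal(rec: OccupancyRecord, transcript: Transcript, params: AnalysisParams) -> bool:
    n = len(transcript.protein)
    frac = params.terminal_fraction
    return not (rec.tract.start_res < frac * n or rec.tract.end_res > (1 - frac) * n)


def _passes_dist_to_stop(rec: OccupancyRecord, transcript: Transcript, params: AnalysisParams) -> bool:
    gap = (transcript.n_codons - 1) - rec.tract.end_res
    return gap >= params.min_codons_to_stop


def apply_filters(
    records: Sequence[OccupancyRecord],
    wt_tracks: Mapping[str, CoverageTrack],
    transcripts: Sequence[Transcript],
    params: AnalysisParams,
    reference_ratios: Sequence[float] | None = None,
) -> list[OccupancyRecord]:
    """Evaluate the four exclusion filters, recording per-filter flags.

    Filters, in order: transcript received >= 25 reads in the wt sample;
    tract not in the first or last 5% of the transcript; >= 30 codons
    between tract end and stop; ratio not more than 2 SD above the mean of
    the control-ratio distribution. The SD filter runs last; its reference
    distribution is ``reference_ratios`` when given, otherwise the ratios of
    the records themselves that pass the first three filters. Records keep
    their flags for audit even when excluded.
    """
    by_id = {t.id: t for t in transcripts}
    for rec in records:
        transcript = by_id[rec.transcript_id]
        rec.filters["min_reads_wt"] = _passes_min_reads_wt(rec, wt_tracks, params)
        rec.filters["terminal_5pct"] = _passes_terminal(rec, transcript, params)
        rec.filters["dist_to_stop"] = _passes_dist_to_stop(rec, transcript, params)

    def _pre_sd_ok(r: OccupancyRecord) -> bool:
        return (r.exclusion_reason is None
                and r.ratio is not None
                and all(r.filters[f] for f in FILTER_NAMES[:3]))

    if reference_ratios is None:
        ref = np.array([r.ratio for r in records if _pre_sd_ok(r)], dtype=float)
    else:
        ref = np.asarray(reference_ratios, dtype=float)

    if ref.size >= 2:
        cutoff = float(ref.mean() + params.outlier_sd * ref.std(ddof=0))
    else:
        cutoff = np.inf
        logger.warning("reference distribution too small; SD filter is a no-op")

    for rec in records:
        if rec.ratio is None:
            rec.filters["control_sd_outlier"] = False
        else:
            rec.filters["control_sd_outlier"] = rec.ratio <= cutoff
    return list(records)


def included_ratios(records: Sequence[OccupancyRecord]) -> np.ndarray:
    return np.array([r.ratio for r in records if r.included], dtype=float)


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------

def metaprofile(
    tracks: Mapping[str, CoverageTrack],
    tracts: Sequence[TractWindow],
    params: AnalysisParams,
) -> MetaProfile:
    """Mean read-frequency profile around tract centers, +/- flank nt.

    The tract center is the first nt of the codon at ``start_res + width/2``.
    Windows extending past the transcript ends or with fewer than
    ``min_window_reads`` reads are excluded; each surviving window's counts
    are normalized to sum to 1 before averaging.
    """
    flank = params.flank
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(offsets.size, dtype=float)
    n_kept = n_edge = n_low = n_missing = 0
    for w in tracts:
        track = tracks.get(w.transcript_id)
        if track is None:
            n_missing += 1
            continue
        center = 3 * (w.start_res + w.width // 2)
        lo, hi = center - flank, center + flank + 1
        if lo < 0 or hi > len(track):
            n_edge += 1
            continue
        window = track.counts[lo:hi].astype(float)
        total = window.sum()
        if total < params.min_window_reads:
            n_low += 1
            continue
        acc += window / total
        n_kept += 1
    if n_kept == 0:
        raise ValueError(
            "no windows survive metaprofile exclusions "
            f"(missing track: {n_missing}, past transcript edge: {n_edge}, "
            f"<{params.min_window_reads} reads: {n_low})"
        )
    return MetaProfile(offsets=offsets, mean_frequency=acc / n_kept, n_windows=n_kept)


def metaprofile_to_frame(profile: MetaProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "offset": profile.offsets,
        "mean_frequency": profile.mean_frequency,
        "n_windows": profile.n_windows,
    })


# ---------------------------------------------------------------------------
# matched-control sampling
# ---------------------------------------------------------------------------

def _feature_frame(
    records: Sequence[OccupancyRecord],
    transcripts_by_id: Mapping[str, Transcript],
    tracks: Mapping[str, CoverageTrack],
) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        t = transcripts_by_id[r.transcript_id]
        n_res = len(t.protein)
        track = tracks.get(r.transcript_id)
        if track is not None:
            lo, hi = 3 * r.tract.start_res, 3 * r.tract.end_res
            reads = float(track.counts[lo:hi].sum())
        else:
            reads = 0.0
        rows.append({
            "index": i,
            "relative_position": r.tract.start_res / n_res,
            "transcript_length": float(n_res),
            "window_reads": reads,
        })
    return pd.DataFrame(rows)


MATCH_FEATURES = ("relative_position", "transcript_length", "window_reads")


def sample_matched_controls(
    tract_records: Sequence[OccupancyRecord],
    control_records: Sequence[OccupancyRecord],
    transcripts: Sequence[Transcript],
    tracks: Mapping[str, CoverageTrack],
    n: int,
    seed: int,
    features: Sequence[str] = MATCH_FEATURES,
) -> list[OccupancyRecord]:
    """Draw n controls matching the tract feature distribution.

    Stratified resampling: each feature is binned into deciles (edges from
    the tract distribution); every joint bin receives a quota proportional
    to its tract occupancy (largest-remainder rounding) and controls are
    drawn from the same joint bin without replacement, falling back to
    with-replacement draws when a bin is short and to progressively coarser
    bins (features relaxed from the last backwards, logged) when a bin is
    empty. Deterministic for a fixed seed; when the control pool equals the
    tract set and ``n`` is its size the result is that exact multiset.
    """
    if not control_records:
        raise ValueError("empty control pool")
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in transcripts}
    tf = _feature_frame(tract_records, by_id, tracks)
    cf = _feature_frame(control_records, by_id, tracks)

    # decile edges from the tract distribution, per feature
    edges = {}
    for f in features:
        qs = np.quantile(tf[f].to_numpy(), np.linspace(0, 1, 11))
        edges[f] = np.unique(qs[1:-1])
    for frame in (tf, cf):
        for f in features:
            frame[f + "_bin"] = np.searchsorted(edges[f], frame[f].to_numpy(), side="right")

    bin_cols = [f + "_bin" for f in features]

    def _key(k) -> tuple:
        return k if isinstance(k, tuple) else (k,)

    control_index = {
        _key(k): grp["index"].to_numpy() for k, grp in cf.groupby(bin_cols)
    }
    # progressively coarser indexes for fallback (drop trailing features)
    coarser: list[tuple[int, dict]] = []
    for depth in range(len(features) - 1, 0, -1):
        coarser.append((depth, {
            _key(k): grp["index"].to_numpy()
            for k, grp in cf.groupby(bin_cols[:depth])
        }))
    all_controls = cf["index"].to_numpy()

    # largest-remainder quotas proportional to tract bin occupancy
    tract_bin_counts = tf.groupby(bin_cols).size()
    keys = [_key(k) for k in tract_bin_counts.index]
    shares = tract_bin_counts.to_numpy() * n / len(tf)
    quotas = np.floor(shares).astype(int)
    remainder = n - quotas.sum()
    if remainder > 0:
        order = np.argsort(-(shares - quotas), kind="stable")
        quotas[order[:remainder]] += 1

    chosen: list[int] = []
    n_widened = n_replacement = 0
    for key, quota in zip(keys, quotas):
        if quota == 0:
            continue
        pool = control_index.get(key)
        if pool is None:
            n_widened += 1
            for depth, idx in coarser:
                pool = idx.get(key[:depth])
                if pool is not None:
                    break
            if pool is None:
                pool = all_controls
        if quota <= len(pool):
            picked = rng.choice(pool, size=quota, replace=False)
        else:
            n_replacement += 1
            picked = np.concatenate([
                pool, rng.choice(pool, size=quota - len(pool), replace=True)
            ])
        chosen.extend(int(i) for i in picked)
    if n_widened or n_replacement:
        logger.info(
            "matched sampling: %d bins widened, %d bins drawn with replacement",
            n_widened, n_replacement,
        )
    return [control_records[i] for i in chosen]


# ---------------------------------------------------------------------------
# group statistics and reporting
# ---------------------------------------------------------------------------

def compare_occupancy(
    tract_ratios: Sequence[float], control_ratios: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided pooled-variance Student's t-test between ratio groups.

    Returns (t, p, (tract mean, control mean)). Degenerate identical
    zero-variance groups yield t=0, p=1 with a warning.
    """
    a = np.asarray(tract_ratios, dtype=float)
    b = np.asarray(control_ratios, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    means = (float(a.mean()), float(b.mean()))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        warnings.warn("identical zero-variance groups; returning t=0, p=1")
        return 0.0, 1.0, means
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), means


def dropoff_report(
    records_by_group: Mapping[str, tuple[Sequence[OccupancyRecord], Sequence[OccupancyRecord]]],
    pooled: bool = True,
) -> pd.DataFrame:
    """Per-group (and pooled) drop-off summary versus matched controls.

    ``records_by_group`` maps group name to (tract records, control
    records); only included records contribute. Percent drop is
    ``100 * (1 - mean(tract ratios) / mean(control ratios))``; the
    ratio-of-means variant is emitted alongside.
    """
    def _row(name, trecs, crecs):
        tr = included_ratios(trecs)
        cr = included_ratios(crecs)
        genes = {r.transcript_id for r in trecs if r.included}
        row = {
            "group": name,
            "n_windows": int(tr.size),
            "n_genes": len(genes),
            "mean_ratio": float(tr.mean()) if tr.size else np.nan,
            "mean_control_ratio": float(cr.mean()) if cr.size else np.nan,
        }
        if tr.size and cr.size and cr.mean() > 0:
            row["percent_drop"] = 100.0 * (1.0 - tr.mean() / cr.mean())
        else:
            row["percent_drop"] = np.nan
        # ratio-of-means alternative: aggregate densities first, then ratio
        def _agg(recs):
            pre = np.array([r.pre_density for r in recs if r.included])
            post = np.array([r.post_density for r in recs if r.included])
            return post.mean() / pre.mean() if pre.size and pre.mean() > 0 else np.nan
        at, ac = _agg(trecs), _agg(crecs)
        row["percent_drop_ratio_of_means"] = (
            100.0 * (1.0 - at / ac) if np.isfinite(at) and np.isfinite(ac) and ac > 0
            else np.nan
        )
        return row

    rows = [_row(g, t, c) for g, (t, c) in records_by_group.items()]
    if pooled and len(records_by_group) > 1:
        all_t = [r for t, _ in records_by_group.values() for r in t]
        all_c = [r for _, c in records_by_group.values() for r in c]
        rows.append(_row("pooled", all_t, all_c))
    return pd.DataFrame(rows)
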