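"""Sliding-window residue-composition scan and tract selection.

A "tract" is a fixed-width window (default 10 residues) containing at least
``min_count`` residues of the target class; overlapping candidates within the
non-overlap radius are thinned greedily, keeping the highest count (ties to
the smallest start). Control windows are every position with at most
``control_max_basic`` target residues, with no thinning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AnalysisParams, CoverageTrack, Transcript, TractWindow


@dataclass(frozen=True)
class ResidueClassSpec:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("residue class has no members")


BASIC = ResidueClassSpec("basic", frozenset("KR"))
ACIDIC = ResidueClassSpec("acidic", frozenset("DE"))

CLASSES = {"basic": BASIC, "acidic": ACIDIC}


def window_counts(protein: str, width: int, cls: ResidueClassSpec) -> np.ndarray:
    """Count of target-class residues in each width-residue window.

    Returns one count per start position (length ``len(protein) - width + 1``);
    empty for proteins shorter than the window.
    """
    n = len(protein)
    if n < width:
        return np.zeros(0, dtype=np.int64)
    is_member = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)
    mask = np.zeros(256, dtype=np.int64)
    for aa in cls.members:
        mask[ord(aa)] = 1
    hits = mask[is_member]
    csum = np.concatenate([[0], np.cumsum(hits)])
    return csum[width:] - csum[:n - width + 1]


def _last_member_index(protein: str, start: int, width: int, cls: ResidueClassSpec) -> int:
    for i in range(start + width - 1, start - 1, -1):
        if protein[i] in cls.members:
            return i
    raise ValueError("window contains no target-class residue")


def find_tracts(
    protein: str,
    params: AnalysisParams,
    cls: ResidueClassSpec,
    min_count: int,
    transcript_id: str = "",
) -> list[TractWindow]:
    """Select non-overlapping windows with >= min_count target residues.

    Greedy selection: repeatedly keep the candidate with the globally
    highest count (ties broken by smallest start), discard all candidates
    whose start lies within ``nonoverlap_distance`` of a kept start, recurse.
    The result is sorted by start.
    """
    width = params.window_width
    if not (1 <= min_count <= width):
        raise ValueError(f"min_count must lie in [1, {width}]")
    counts = window_counts(protein, width, cls)
    cand = np.nonzero(counts >= min_count)[0]
    if cand.size == 0:
        return []
    # sort by (-count, start) so the greedy pass is a single scan
    order = np.lexsort((cand, -counts[cand]))
    kept: list[int] = []
    for s in cand[order]:
        if all(abs(int(s) - k) > params.nonoverlap_distance for k in kept):
            kept.append(int(s))
    kept.sort()
    return [
        TractWindow(
            transcript_id=transcript_id,
            start_res=s,
            width=width,
            n_target_residues=int(counts[s]),
            residue_class=cls.name,
            last_target_res=_last_member_index(protein, s, width, cls),
            window_class="tract",
        )
        for s in kept
    ]


def find_control_windows(
    protein: str,
    params: AnalysisParams,
    cls: ResidueClassSpec,
    transcript_id: str = "",
) -> list[TractWindow]:
    """Every window position with <= control_max_basic target residues.

    No non-overlap thinning is applied; adjacent control windows overlap.
    Windows with zero target residues record ``last_target_res = -1``.
    """
    width = params.window_width
    counts = window_counts(protein, width, cls)
    out = []
    for s in np.nonzero(counts <= params.control_max_basic)[0]:
        s = int(s)
        if counts[s] > 0:
            last = _last_member_index(protein, s, width, cls)
        else:
            last = -1
        out.append(TractWindow(
            transcript_id=transcript_id,
            start_res=s,
            width=width,
            n_target_residues=int(counts[s]),
            residue_class=cls.name,
            last_target_res=last,
            window_class="control",
        ))
    return out


def scan_transcriptome(
    transcripts: Sequence[Transcript],
    params: AnalysisParams,
    cls: ResidueClassSpec,
    min_count: int,
) -> list[TractWindow]:
    """find_tracts over a whole transcriptome, order preserved."""
    tracts: list[TractWindow] = []
    for t in transcripts:
        tracts.extend(find_tracts(t.protein, params, cls, min_count, t.id))
    return tracts


def tracts_to_frame(tracts: Sequence[TractWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": w.transcript_id,
                "start_res": w.start_res,
                "count": w.n_target_residues,
                "last_target_res": w.last_target_res,
                "class": w.residue_class,
                "window_class": w.window_class,
            }
            for w in tracts
        ],
        columns=[
            "transcript_id", "start_res", "count",
            "last_target_res", "class", "window_class",
        ],
    )


def dose_series(
    transcripts: Sequence[Transcript],
    tracks: dict[str, CoverageTrack],
    params: AnalysisParams,
    cls: ResidueClassSpec,
    thresholds: Sequence[int],
) -> pd.DataFrame:
    """Mean post/pre occupancy ratio as a function of the tract threshold.

    For each threshold the tract scan is rerun with ``min_count=threshold``
    and analyzable tracts are scored with the pre/post region ratio; rows are
    (threshold, mean_ratio, n_windows). Thresholds must be ascending and
    within [1, window width].
    """
    from .occupancy import define_regions, occupancy_ratio

    thresholds = list(thresholds)
    if any(t < 1 or t > params.window_width for t in thresholds):
        raise ValueError("thresholds must lie in [1, window_width]")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")

    by_id = {t.id: t for t in transcripts}
    rows = []
    for thr in thresholds:
        ratios = []
        for w in scan_transcriptome(transcripts, params, cls, thr):
            transcript = by_id[w.transcript_id]
            track = tracks.get(w.transcript_id)
            if track is None:
                continue
            regions = define_regions(w, transcript, params)
            if regions is None:
                continue
            rec = occupancy_ratio(track, regions, w)
            if rec.ratio is not None:
                ratios.append(rec.ratio)
        rows.append({
            "threshold": thr,
            "mean_ratio": float(np.mean(ratios)) if ratios else np.nan,
            "n_windows": len(ratios),
        })
    return pd.DataFrame(rows)
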