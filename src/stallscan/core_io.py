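"""Domain types, coordinate conventions, and file I/O.

Coordinate conventions used throughout the package:

* all intervals are 0-based, half-open;
* codon index ``i`` maps to nucleotides ``[3*i, 3*i + 3)``;
* the CDS nucleotide sequence includes the stop codon, the derived protein
  does not, so ``n_codons = n_nt / 3`` and ``len(protein) = n_codons - 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


class EmptyLibraryError(ValueError):
    """Raised when an operation requires a library with mapped reads."""


@dataclass(frozen=True)
class AnalysisParams:
    """All numeric thresholds of the occupancy analysis.

    Defaults follow the published analysis: 10-residue windows, six or more
    basic residues to call a tract (raised to 8 for the drop-off comparison),
    two or fewer for controls, a 50-residue non-overlap radius, +/-150 nt
    metaprofile flanks, and the read-count / position / distance-to-stop
    exclusion rules.
    """

    window_width: int = 10
    tract_min_basic: int = 6
    control_max_basic: int = 2
    nonoverlap_distance: int = 50
    flank: int = 150
    min_window_reads: int = 10
    min_transcript_reads_wt: int = 25
    terminal_fraction: float = 0.05
    min_codons_to_stop: int = 30
    post_offset: int = 40
    stop_trim: int = 20
    start_trim: int = 20
    outlier_sd: float = 2.0
    footprint_len: int = 28
    psite_offset: int = 15

    def __post_init__(self) -> None:
        for name in (
            "window_width", "tract_min_basic", "control_max_basic",
            "nonoverlap_distance", "flank", "min_window_reads",
            "min_transcript_reads_wt", "min_codons_to_stop", "post_offset",
            "stop_trim", "start_trim", "footprint_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.terminal_fraction < 0.5):
            raise ValueError("terminal_fraction must lie in (0, 0.5)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be strictly positive")
        if self.psite_offset < 0:
            raise ValueError("psite_offset must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisParams":
        return cls(**json.loads(Path(path).read_text()))

    def evolve(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Transcript:
    """One coding sequence: nucleotides (stop included) plus derived protein."""

    id: str
    cds_nt: str
    protein: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.cds_nt) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")
        if not self.protein:
            aa = str(Seq(self.cds_nt[:-3]).translate())
            object.__setattr__(self, "protein", aa)
        bad = set(self.protein) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residues {sorted(bad)} in protein"
            )

    @property
    def n_nt(self) -> int:
        return len(self.cds_nt)

    @property
    def n_codons(self) -> int:
        """Total codon count, stop codon included."""
        return len(self.cds_nt) // 3


@dataclass
class CoverageTrack:
    """Per-nucleotide footprint counts on one transcript.

    ``library_total`` is the number of retained footprints in the whole
    sample, shared by all tracks of that sample.
    """

    transcript_id: str
    counts: np.ndarray
    library_total: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError(f"{self.transcript_id}: negative counts")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class TractWindow:
    """A selected fixed-width residue window, tract- or control-class."""

    transcript_id: str
    start_res: int
    width: int
    n_target_residues: int
    residue_class: str          # "basic" or "acidic"
    last_target_res: int        # 0-based residue index on the transcript
    window_class: str           # "tract" or "control"

    @property
    def end_res(self) -> int:
        return self.start_res + self.width


@dataclass(frozen=True)
class ReporterLayout:
    """Codon intervals of the GFP / stall / RFP segments of a reporter ORF."""

    transcript_id: str
    gfp_region: tuple[int, int]
    stall_region: tuple[int, int]
    rfp_region: tuple[int, int]

    def __post_init__(self) -> None:
        g, s, r = self.gfp_region, self.stall_region, self.rfp_region
        for name, (a, b) in (("gfp", g), ("stall", s), ("rfp", r)):
            if not (0 <= a < b):
                raise ValueError(f"{name} region {a, b} is empty or negative")
        if not (g[1] <= s[0] and s[1] <= r[0]):
            raise ValueError("regions must be disjoint and ordered gfp < stall < rfp")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "transcript_id": self.transcript_id,
            "gfp_region": list(self.gfp_region),
            "stall_region": list(self.stall_region),
            "rfp_region": list(self.rfp_region),
        }, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReporterLayout":
        d = json.loads(Path(path).read_text())
        return cls(
            transcript_id=d["transcript_id"],
            gfp_region=tuple(d["gfp_region"]),
            stall_region=tuple(d["stall_region"]),
            rfp_region=tuple(d["rfp_region"]),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_transcriptome(fasta_path: str | Path) -> list[Transcript]:
    """Read a CDS FASTA into validated :class:`Transcript` records.

    Records whose length is not a multiple of 3, or whose translation
    contains non-canonical residues (internal stops, ambiguity codes), are
    skipped with a logged reason. Ordering follows the file.
    """
    transcripts: list[Transcript] = []
    n_skipped = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            transcripts.append(Transcript(id=rec.id, cds_nt=seq))
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping record: %s", exc)
    logger.info(
        "loaded %d transcripts (%d skipped)", len(transcripts), n_skipped
    )
    return transcripts


def write_transcriptome(transcripts: Iterable[Transcript], fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.cds_nt), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def load_footprints(
    bed_path: str | Path,
    transcripts: Sequence[Transcript],
    params: AnalysisParams,
) -> dict[str, CoverageTrack]:
    """Tally footprints from a transcript-relative BED into coverage tracks.

    Each footprint contributes one count at ``start + psite_offset``.
    Footprints on unknown transcripts or whose assigned position falls
    outside the CDS are dropped and counted; negative coordinates are fatal.
    """
    by_id = {t.id: t for t in transcripts}
    arrays = {t.id: np.zeros(t.n_nt, dtype=np.int64) for t in transcripts}

    n_input = n_dropped = 0
    try:
        bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
        bed = bed.iloc[:, :3].copy()
        bed.columns = ["chrom", "start", "end"]
        bed["chrom"] = bed["chrom"].astype(str)
        bed[["start", "end"]] = bed[["start", "end"]].astype(np.int64)
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=["chrom", "start", "end"])

    if len(bed) and (bed["start"].min() < 0 or bed["end"].min() < 0):
        raise ValueError("negative coordinates in BED input")

    n_input = len(bed)
    for tid, grp in bed.groupby("chrom", sort=False):
        track = arrays.get(tid)
        if track is None:
            n_dropped += len(grp)
            logger.warning("%d footprints on unknown transcript %s", len(grp), tid)
            continue
        pos = grp["start"].to_numpy() + params.psite_offset
        inside = (pos >= 0) & (pos < len(track))
        n_dropped += int((~inside).sum())
        np.add.at(track, pos[inside], 1)

    library_total = n_input - n_dropped
    logger.info(
        "tallied %d footprints (%d dropped of %d)", library_total, n_dropped, n_input
    )
    return {
        tid: CoverageTrack(tid, counts, library_total=library_total)
        for tid, counts in arrays.items()
    }


def write_footprints(bed_rows: pd.DataFrame, bed_path: str | Path) -> None:
    """Write a footprint table (chrom/start/end[/name/score/strand]) as BED."""
    cols = [c for c in BED_COLUMNS if c in bed_rows.columns]
    bed_rows[cols].to_csv(bed_path, sep="\t", header=False, index=False)


def write_coverage_tsv(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    """Sparse per-position coverage export: transcript_id, pos, count."""
    frames = []
    for tid in sorted(tracks):
        counts = tracks[tid].counts
        nz = np.nonzero(counts)[0]
        frames.append(pd.DataFrame(
            {"transcript_id": tid, "pos": nz, "count": counts[nz]}
        ))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["transcript_id", "pos", "count"]))
    out.to_csv(path, sep="\t", index=False)


def load_coverage_tsv(
    path: str | Path,
    transcripts: Sequence[Transcript],
    library_total: int | None = None,
) -> dict[str, CoverageTrack]:
    df = pd.read_csv(path, sep="\t")
    arrays = {t.id: np.zeros(t.n_nt, dtype=np.int64) for t in transcripts}
    for tid, grp in df.groupby("transcript_id", sort=False):
        if tid not in arrays:
            logger.warning("coverage for unknown transcript %s ignored", tid)
            continue
        arrays[tid][grp["pos"].to_numpy()] = grp["count"].to_numpy()
    total = int(df["count"].sum()) if library_total is None else library_total
    return {
        tid: CoverageTrack(tid, counts, library_total=total)
        for tid, counts in arrays.items()
    }


# ---------------------------------------------------------------------------
# track arithmetic
# ---------------------------------------------------------------------------

def pool_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Position-wise sum of replicate tracks on one transcript."""
    if not tracks:
        raise ValueError("nothing to pool")
    first = tracks[0]
    for t in tracks[1:]:
        if t.transcript_id != first.transcript_id:
            raise ValueError(
                f"cannot pool {t.transcript_id} with {first.transcript_id}"
            )
        if len(t) != len(first):
            raise ValueError(f"{t.transcript_id}: length mismatch while pooling")
    counts = np.sum([t.counts for t in tracks], axis=0)
    return CoverageTrack(
        first.transcript_id, counts,
        library_total=sum(t.library_total for t in tracks),
    )


def pool_samples(
    samples: Sequence[Mapping[str, CoverageTrack]],
) -> dict[str, CoverageTrack]:
    """Pool whole samples (dicts of tracks keyed by transcript id)."""
    if not samples:
        raise ValueError("nothing to pool")
    ids = set(samples[0])
    for s in samples[1:]:
        if set(s) != ids:
            raise ValueError("samples cover different transcript sets")
    return {tid: pool_tracks([s[tid] for s in samples]) for tid in ids}


def rpkm_track(track: CoverageTrack) -> np.ndarray:
    """Per-nucleotide RPKM values.

    Each position is treated as its own 1-nt region, so the mean over any
    region equals that region's RPKM (reads / region-kb / library-millions).
    """
    if track.library_total <= 0:
        raise EmptyLibraryError(
            f"{track.transcript_id}: library_total is zero, cannot compute RPKM"
        )
    return track.counts * 1e9 / track.library_total


def region_rpkm(track: CoverageTrack, start: int, end: int) -> float:
    """RPKM of the nt interval [start, end)."""
    if end <= start:
        raise ValueError("empty region")
    if track.library_total <= 0:
        raise EmptyLibraryError(
            f"{track.transcript_id}: library_total is zero, cannot compute RPKM"
        )
    reads = float(track.counts[start:end].sum())
    return reads * 1e9 / ((end - start) * track.library_total)
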