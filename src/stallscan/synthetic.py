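"""Seeded generators for every input the pipeline consumes.

Transcriptomes with planted basic/acidic tracts, Poisson footprint coverage
with a dip at the tract, a pile-up downstream and a reduced post-tract rate,
reporter coverage with a known read-through fraction, log-normal flow
events, and multinomial spectral-count tables. Every generator is a pure
function of its spec and seed; truth tables record what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnalysisParams, CoverageTrack, ReporterLayout, Transcript
from .ipms import SAMPLE_ROLES, SpectralCountTable

# background alphabet excludes K/R and D/E so planted tracts are the only
# tract-class windows and every background window is a valid control
BACKGROUND_AA = "ACFGHILMNPQSTVWY"

# one codon per amino acid keeps generation deterministic and round-trippable
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"

TRUTH_COLUMNS = [
    "transcript_id", "start_res", "width", "n_target",
    "residue_class", "last_target_res",
]


@dataclass(frozen=True)
class StallModel:
    """Piecewise-constant footprint rate model around one planted tract."""

    lambda_pre: float = 0.5        # expected footprints per nt upstream
    dip_factor: float = 1.0        # multiplier over the tract window, <= 1
    pileup_amplitude: float = 1.0  # multiplier over the pile-up zone, >= 1
    pileup_len: int = 40           # codons of pile-up past the last target residue
    readthrough: float = 1.0       # fraction of ribosomes continuing past

    def __post_init__(self) -> None:
        if self.lambda_pre < 0:
            raise ValueError("lambda_pre must be non-negative")
        if not (0.0 <= self.readthrough <= 1.0):
            raise ValueError("readthrough must lie in [0, 1]")
        if self.dip_factor < 0 or self.pileup_amplitude < 0:
            raise ValueError("rate multipliers must be non-negative")
        if self.pileup_len < 0:
            raise ValueError("pileup_len must be non-negative")


@dataclass(frozen=True)
class TractSpec:
    """What to plant: class, residues per window, tracts per transcript."""

    residue_class: str = "basic"         # "basic" or "acidic"
    n_target: int = 10                   # target residues in the planted window
    width: int = 10
    count_per_transcript: int = 1
    min_margin: int = 30                 # codons kept clear of both ends

    def __post_init__(self) -> None:
        if self.residue_class not in ("basic", "acidic"):
            raise ValueError("residue_class must be 'basic' or 'acidic'")
        if not (1 <= self.n_target <= self.width):
            raise ValueError("n_target must lie in [1, width]")


def protein_to_cds(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + STOP_CODON


def make_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    tract_spec: TractSpec | None,
    seed: int,
    id_prefix: str = "synth",
) -> tuple[list[Transcript], pd.DataFrame]:
    """Random CDS with planted tracts; returns (transcripts, truth table).

    Protein lengths are uniform over ``length_range`` (in residues, >= 100).
    The planted window puts ``n_target`` target residues as a run at the
    window start; its position is uniform within the margins. The background
    alphabet contains no K/R/D/E, so no accidental tract can arise and the
    truth table is exhaustive.
    """
    lo, hi = length_range
    if lo < 100:
        raise ValueError("transcripts must be at least 100 codons")
    rng = np.random.default_rng(seed)
    bg = np.array(list(BACKGROUND_AA))

    transcripts: list[Transcript] = []
    truth_rows = []
    for i in range(n_transcripts):
        tid = f"{id_prefix}{i:05d}"
        n_res = int(rng.integers(lo, hi + 1))
        protein = rng.choice(bg, size=n_res)
        if tract_spec is not None:
            target_aa = "K" if tract_spec.residue_class == "basic" else "D"
            w = tract_spec.width
            margin = tract_spec.min_margin
            if n_res < tract_spec.count_per_transcript * (w + 60) + 2 * margin:
                raise ValueError(
                    f"transcript of {n_res} residues cannot hold "
                    f"{tract_spec.count_per_transcript} tracts"
                )
            placed: list[int] = []
            for _ in range(tract_spec.count_per_transcript):
                for _attempt in range(1000):
                    s = int(rng.integers(margin, n_res - w - margin + 1))
                    if all(abs(s - p) > 60 for p in placed):
                        placed.append(s)
                        break
                else:
                    raise ValueError("could not place non-overlapping tracts")
            for s in sorted(placed):
                protein[s:s + tract_spec.n_target] = target_aa
                truth_rows.append({
                    "transcript_id": tid,
                    "start_res": s,
                    "width": w,
                    "n_target": tract_spec.n_target,
                    "residue_class": tract_spec.residue_class,
                    "last_target_res": s + tract_spec.n_target - 1,
                })
        seq = "".join(protein)
        transcripts.append(Transcript(id=tid, cds_nt=protein_to_cds(seq), protein=seq))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return transcripts, truth


def _rate_profile(
    n_nt: int, tract_rows: pd.DataFrame, model: StallModel
) -> np.ndarray:
    rate = np.full(n_nt, model.lambda_pre, dtype=float)
    for row in tract_rows.itertuples():
        t_lo, t_hi = 3 * row.start_res, 3 * (row.start_res + row.width)
        p_lo = 3 * (row.last_target_res + 1)
        p_hi = min(3 * (row.last_target_res + 1 + model.pileup_len), n_nt)
        rate[t_lo:t_hi] *= model.dip_factor
        rate[p_lo:p_hi] *= model.pileup_amplitude
        rate[p_hi:] *= model.readthrough
    return rate


def simulate_footprints(
    transcripts: Sequence[Transcript],
    truth: pd.DataFrame,
    model: StallModel | Mapping[str, StallModel],
    seed: int,
    params: AnalysisParams | None = None,
    depth: float = 1.0,
) -> pd.DataFrame:
    """Poisson footprints under the piecewise stall model; returns BED rows.

    Per-nucleotide counts are drawn at rate lambda_pre (times the dip,
    pile-up and read-through multipliers around each planted tract, times
    ``depth``) and expanded into footprint intervals positioned so that
    P-site assignment at ``params.psite_offset`` recovers the sampled
    nucleotide. Positions closer to the 5' end than the offset are skipped
    (their BED start would be negative).

    ``model`` may be one shared :class:`StallModel` or a per-transcript-id
    mapping; transcripts absent from both the mapping and the truth table
    get a uniform rate.
    """
    params = params or AnalysisParams()
    rng = np.random.default_rng(seed)
    default_model = model if isinstance(model, StallModel) else StallModel()
    per_id = model if isinstance(model, Mapping) else {}

    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    for t in transcripts:
        m = per_id.get(t.id, default_model)
        rows = truth[truth["transcript_id"] == t.id] if len(truth) else truth
        rate = _rate_profile(t.n_nt, rows, m) * depth
        counts = rng.poisson(rate)
        pos = np.repeat(np.arange(t.n_nt), counts)
        pos = pos[pos >= params.psite_offset]
        if pos.size:
            chroms.append(np.full(pos.size, t.id, dtype=object))
            starts.append(pos - params.psite_offset)
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts)
    return pd.DataFrame({
        "chrom": chrom,
        "start": start,
        "end": start + params.footprint_len,
        "name": ".",
        "score": 0,
        "strand": "+",
    })


def tracks_from_rates(
    transcripts: Sequence[Transcript],
    truth: pd.DataFrame,
    model: StallModel | Mapping[str, StallModel],
    seed: int,
    depth: float = 1.0,
) -> dict[str, CoverageTrack]:
    """Poisson coverage tracks drawn directly, bypassing BED expansion.

    Same statistical model as :func:`simulate_footprints` without the
    footprint-interval round trip; convenient for large simulations.
    """
    rng = np.random.default_rng(seed)
    default_model = model if isinstance(model, StallModel) else StallModel()
    per_id = model if isinstance(model, Mapping) else {}
    raw = {}
    for t in transcripts:
        m = per_id.get(t.id, default_model)
        rows = truth[truth["transcript_id"] == t.id] if len(truth) else truth
        raw[t.id] = rng.poisson(_rate_profile(t.n_nt, rows, m) * depth)
    total = int(sum(c.sum() for c in raw.values()))
    return {
        tid: CoverageTrack(tid, counts, library_total=total)
        for tid, counts in raw.items()
    }


# ---------------------------------------------------------------------------
# reporter
# ---------------------------------------------------------------------------

def make_reporter_transcript(layout: ReporterLayout, tail_codons: int = 30) -> Transcript:
    """A reporter CDS matching the layout: arginine stall, neutral elsewhere."""
    n_res = layout.rfp_region[1] + tail_codons
    protein = np.full(n_res, "G", dtype="<U1")
    # deterministic varied background so the sequence is not one homopolymer
    bg = np.array(list(BACKGROUND_AA))
    protein[:] = bg[np.arange(n_res) % len(bg)]
    s_lo, s_hi = layout.stall_region
    protein[s_lo:s_hi] = "R"
    seq = "".join(protein)
    return Transcript(
        id=layout.transcript_id, cds_nt=protein_to_cds(seq), protein=seq
    )


def simulate_reporter(
    layout: ReporterLayout,
    model: StallModel,
    seed: int,
    params: AnalysisParams | None = None,
    depth: float = 1.0,
) -> tuple[Transcript, pd.DataFrame]:
    """Reporter transcript plus simulated footprint BED rows.

    The stall model is anchored at the layout's stall region: base rate
    upstream, dip over the stall, pile-up for ``pileup_len`` codons past it,
    read-through rate beyond.
    """
    transcript = make_reporter_transcript(layout)
    s_lo, s_hi = layout.stall_region
    truth = pd.DataFrame([{
        "transcript_id": transcript.id,
        "start_res": s_lo,
        "width": s_hi - s_lo,
        "n_target": s_hi - s_lo,
        "residue_class": "basic",
        "last_target_res": s_hi - 1,
    }], columns=TRUTH_COLUMNS)
    bed = simulate_footprints([transcript], truth, model, seed, params, depth)
    return transcript, bed


# ---------------------------------------------------------------------------
# RNA-seq, flow, IP-MS
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    transcripts: Sequence[Transcript],
    abundance: Mapping[str, float] | float,
    seed: int,
    base_rate: float = 0.2,
) -> dict[str, CoverageTrack]:
    """Uniform Poisson RNA-seq coverage scaled by per-transcript abundance."""
    rng = np.random.default_rng(seed)
    raw = {}
    for t in transcripts:
        mult = abundance if isinstance(abundance, (int, float)) else abundance.get(t.id, 1.0)
        raw[t.id] = rng.poisson(base_rate * mult, size=t.n_nt)
    total = int(sum(c.sum() for c in raw.values()))
    return {
        tid: CoverageTrack(tid, counts, library_total=total)
        for tid, counts in raw.items()
    }


@dataclass(frozen=True)
class FlowStrainSpec:
    gfp: float
    rfp: float
    ssc: float = 100.0
    cv: float = 0.3


def simulate_flow(
    strain_specs: Mapping[str, FlowStrainSpec],
    n_events: int,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Log-normal flow events per strain and replicate.

    Channel arithmetic means equal the spec values; ``cv`` sets the
    coefficient of variation of every channel.
    """
    rng = np.random.default_rng(seed)
    sigma2 = {s: np.log(1 + spec.cv ** 2) for s, spec in strain_specs.items()}
    rows = []
    for strain in strain_specs:
        spec = strain_specs[strain]
        s2 = sigma2[strain]
        for rep in range(1, replicates + 1):
            for channel, mean in (("gfp", spec.gfp), ("rfp", spec.rfp), ("ssc", spec.ssc)):
                vals = rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), size=n_events)
                rows.append(pd.DataFrame({
                    "sample": strain, "replicate": rep, "channel": channel, "value": vals,
                    "event": np.arange(n_events),
                }))
    long = pd.concat(rows, ignore_index=True)
    wide = long.pivot_table(
        index=["sample", "replicate", "event"], columns="channel", values="value"
    ).reset_index()
    wide.columns.name = None
    return wide[["sample", "replicate", "gfp", "rfp", "ssc"]]


def simulate_ipms(
    proteins: Sequence[str],
    true_enrichment: Sequence[float],
    totals: Sequence[int],
    seed: int,
    baseline_weights: Sequence[float] | None = None,
) -> SpectralCountTable:
    """Multinomial spectral counts with bait probabilities tilted by enrichment.

    ``totals`` are the per-sample spectral totals (bait_rep1, bait_rep2,
    untagged_control); the control draws from the baseline weights, baits
    from baseline x enrichment.
    """
    if len(true_enrichment) != len(proteins):
        raise ValueError("enrichment vector and protein list disagree")
    if len(totals) != len(SAMPLE_ROLES):
        raise ValueError(f"need {len(SAMPLE_ROLES)} sample totals")
    rng = np.random.default_rng(seed)
    w = (np.ones(len(proteins)) if baseline_weights is None
         else np.asarray(baseline_weights, dtype=float))
    e = np.asarray(true_enrichment, dtype=float)
    p_ctrl = w / w.sum()
    p_bait = (w * e) / (w * e).sum()
    counts = np.column_stack([
        rng.multinomial(totals[0], p_bait),
        rng.multinomial(totals[1], p_bait),
        rng.multinomial(totals[2], p_ctrl),
    ])
    return SpectralCountTable(proteins=list(proteins), counts=counts)
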