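import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from stallscan import AnalysisParams, CoverageTrack, Transcript
from stallscan.synthetic import protein_to_cds


@pytest.fixture
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_transcript(tid: str, protein: str) -> Transcript:
    return Transcript(id=tid, cds_nt=protein_to_cds(protein), protein=protein)


def uniform_track(transcript: Transcript, per_nt: int, library_total=None) -> CoverageTrack:
    counts = np.full(transcript.n_nt, per_nt, dtype=np.int64)
    total = int(counts.sum()) if library_total is None else library_total
    return CoverageTrack(transcript.id, counts, library_total=total)


@pytest.fixture
def simple_transcript() -> Transcript:
    # 300 background residues with a 10-K run at residues 100..109
    protein = "A" * 100 + "K" * 10 + "A" * 190
    return make_transcript("t1", protein)
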