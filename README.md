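# stallscan

Analysis toolkit for ribosome-profiling studies of translation arrest at
polybasic-encoding tracts, plus the companion reporter, flow-cytometry and
IP-MS computations. The package covers:

- **Tract discovery** — sliding 10-residue composition scan for windows with
  ≥ k lysines/arginines (or aspartates/glutamates), greedy non-overlap
  selection within a 50-residue radius, and enumeration of ≤ 2-residue
  control windows.
- **Occupancy analysis** — post/pre-tract density ratios with the standard
  region definitions (post region from 40 codons past the last basic residue
  to 20 codons before the stop; pre region from 20 codons after the start),
  read-count / terminal-position / distance-to-stop / 2-SD outlier filters,
  ±150 nt metaprofiles, matched-control resampling, pooled-variance t-tests
  and drop-off reports.
- **Reporter metrics** — relative post-stall occupancy (RFP-region density
  over trimmed-ORF density, pile-up zone excluded), post-stall drop,
  reporter mRNA abundance vs the transcriptome median, side-scatter and
  blank-normalized flow summaries, RFP/GFP read-through ratios, and
  ANOVA + Tukey HSD group statistics.
- **IP-MS enrichment** — pseudocounted, total-normalized bait/control
  spectral-count enrichment and interactor ranking.
- **Synthetic data** — seeded generators for every input: transcriptomes
  with planted tracts, Poisson footprint coverage with a dip at the tract, a
  40-codon downstream pile-up and a reduced post-tract rate, reporter
  coverage with known read-through, log-normal flow events, and multinomial
  spectral-count tables, each with a machine-readable truth table.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, region arithmetic, filter suite, parameter-recovery and
monotonicity checks); the rest are per-module unit and property tests.

## CLI

All functionality is exposed through the `stallscan` command:

```sh
stallscan io validate --fasta cds.fasta --bed footprints.bed
stallscan tracts --fasta cds.fasta --residue-class basic --min-count 8 --out tracts.tsv
stallscan occupancy --fasta cds.fasta --bed s1.bed --bed s2.bed \
    --wt-bed wt.bed --min-count 8 --out report.tsv
stallscan reporter --fasta rep.fasta --bed rep.bed --layout layout.json
stallscan flow --events events.tsv --blank blank --out summary.tsv
stallscan ipms --table counts.tsv --out ranked.tsv
stallscan simulate transcriptome --spec spec.json --seed 1 --out data/
```

Inputs are plain text: CDS FASTA (stop codon included), transcript-relative
BED6 footprints (one count assigned at 5′ end + P-site offset, default
15 nt), TSV coverage/flow/spectral-count tables, and JSON for analysis
parameters and reporter layouts. Coordinates are 0-based half-open
throughout; codon *i* maps to nucleotides `[3i, 3i+3)`.

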