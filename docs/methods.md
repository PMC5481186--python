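# Methods

## The biological model

A PIWI-clade slicer guided by a piRNA cleaves a complementary target RNA
between the positions paired to guide nucleotides 10 and 11, i.e. 10 nt
downstream of the guide 5′ end. The package models the downstream fate of
both cleavage fragments on an artificial precursor:

* the **downstream fragment** either matures (probability
  `conversion_efficiency`) into a secondary piRNA (5′ end at the cleavage
  site, length 24–30 nt) followed by phased trail piRNAs, each starting at
  the previous fragment's one-past-3′ coordinate; or persists as a
  **pre-piRNA intermediate**, which the 51-cycle sequencing strategy
  records as a maximum-length 51-nt read;
* the **upstream fragment** is trimmed to a fixed slicer footprint of
  `guide_length − cleavage_offset` = 16 nt whose 3′ end lies exactly at
  the cleavage site (the by-product). The trimming nuclease is unknown, so
  it is modeled as deterministic.

Libraries additionally contain a 21–23-nt contaminant class emulating
co-purifying miRNAs; these are random sequences verified not to occur in
the reporter (or its reverse complement), mirroring real contaminants that
map elsewhere in the genome.

## Coordinate and distance conventions

All coordinates are 0-based, half-open `[start, end)`; a read's 3′-end
coordinate is one-past-last. A minus-strand read's 5′ nucleotide sits at
plus coordinate `end − 1`. For a site whose guide 5′ end pairs with
precursor coordinate `q`, the distance origin is `q + 1`; distances are
`d5 = start − origin` and `d3 = end − origin`. This single convention makes
the secondary-piRNA 5′ end and the by-product 3′ end both register at
**−10**, and makes the ping-pong score peak at **Δ = 9** for a 10-nt 5′
overlap (`score(Δ) = Σᵢ M(i)·N(i+Δ)` with minus-strand 5′ ends expressed
as `end − 1`). In the 3′-to-5′ end-distance variant the 3′ position is the
coordinate of the 3′-most nucleotide (`end − 1` on plus), so the by-product
3′ ends register against the guide 5′ ends at Δ = 10; tests derive this
expectation analytically from the site geometry before running.

## Simulation parameters

| parameter | default | why |
|---|---|---|
| `n_sites` | 35 | binding-site count of the reporter construct |
| `guide_length` | 26 nt | typical MILI piRNA length |
| `cleavage_offset` | 10 nt | slicing 10 nt downstream of the guide 5′ end |
| by-product length | 16 nt | derived: `guide_length − cleavage_offset` |
| `max_read_length` | 51 nt | maximum sequencing length; intermediates appear as 51-mers |
| `secondary_length_probs` | 24–30 nt, mode 26 | MILI piRNA size profile; trails use the same law (no separate law is established) |
| `trail_mean` / `trail_max` | 2 / 4 | trail count per event ~ geometric(mean 2), capped at 4 so a phased run always fits between neighbouring sites; the true number per event is not established, this is a modeling choice |
| `spacer_length` | 300 nt | inter-site spacing; ≥ max read length so neighbouring sites cannot be confused, and large enough to hold a full phased run |
| `intermediate_length` | 80 nt | any value > 51 behaves identically after sequencing truncation |
| `mirna_fraction` | 0.15 | a visible contaminant peak without dominating the library; lengths 21–23 with mode 22, 23-mers present so the 23-nt normalizer is never zero |
| `conversion_efficiency` | 0.8 (control) / 0.15 (mutant-like) | genotype knob: the mutant still produces some piRNAs but accumulates intermediates |
| `u1_bias` | 0.8 | P(next phased 5′ nucleotide is U); realized by biasing the previous fragment's 3′-end choice among 24–30 toward positions followed by U |
| `depth` | 30,000 reads/library | comfortably above the ≥20,000 needed for stable histograms, while keeping runs in seconds |
| genic enrichment | 5.0 | configured fold change of the mutant's sense genic piRNA occupancy |

Sequencing is modeled as `insert + barcode + adapter` truncated at
`max_read_length`, constant quality "I", no error model — the downstream
analysis keeps only perfect matches, so errors would only remove reads.

## Analysis defaults

Minimum read length 15 nt after adapter clipping; reporter alignment with
0 mismatches; targeting-read alignment with ≤3 mismatches, none at read
positions 2–10; piRNA band 24–30 nt; Δ window [−20, 30]; sharing criteria
0.25 rpm presence and 3-fold preference, applied in order (MILI-specific,
MIWI-specific, both, helicase-specific, unclassified — the last category
is literal set-exclusion, no minimum is imposed on the excluded columns);
per-feature comparisons keep features with ≥10 rpm in either library and
report the median of finite ratios (zero-denominator features are flagged
infinite and excluded from the median); normalizer length 23 nt exactly
(even though the contaminant mode is 22 nt), configurable; rpm denominators
are reads mapped to the analysis reference set, recorded per output.

Tie-breaks and degenerate inputs: the aligner prefers fewer mismatches,
then smaller start, then '+' over '−' (and reference-id order across
references); modal lengths break ties toward the smaller length; a read
equidistant between two sites is assigned to the upstream site; empty
inputs yield empty/zero outputs with warnings, and undefined ratios or
correlations return NaN with a warning rather than raising.

## Design choices that were genuinely open

* **Trail-classification window.** A trail piRNA is a 24–30-nt read whose
  5′ end lies in `(−10, 150]` downstream of a site origin. The window is
  sized to cover a maximal phased run (secondary + 4 trails of ≤30 nt)
  given the generator's trail law; with a much narrower window, genuine
  late trails in a phased run would be discarded as "other". It is
  configurable for data with different phasing depth.
* **Per-library FASTQ files.** Barcodes are inline at the read 3′ end, so
  maximum-length reads never sequence their barcode and pooled
  demultiplexing would silently drop the 51-mer intermediates (real
  protocols resolve this with separate index reads). The pipeline
  therefore keeps one FASTQ per library, with the manifest mapping file to
  library; `demultiplex` remains available for genuinely pooled input and
  conserves total read count into an "undetermined" bin.
* **Targeting weights from geometry.** The simulator does not emit guide
  reads (guides are endogenous, not reporter products), so pipeline
  ping-pong uses minus-strand 5′-end weights placed at each site's `q`
  coordinate — exactly where targeting guide reads would map.
* **Exact-match trimming.** The adapter clipper removes the longest read
  suffix matching an adapter prefix (minimum overlap 3, configurable), or
  truncates at an internal full-adapter occurrence; no mismatch tolerance,
  which is exact on error-free reads.

## What the simulation does and does not capture

The generator reproduces the *geometry* of slicer products — end positions,
lengths, phasing, class mixture, genotype contrast — with exact, noiseless
placement. It does not model sequencing error, ligation bias, 3′-end
trimming heterogeneity of mature piRNAs, repeat multi-mapping, or genome-
scale annotation complexity. Passing tests therefore demonstrate that the
statistics recover the known geometry from well-formed libraries, not that
they are robust to every artifact of real data. The observed endogenous
trail 5′-end spread (peaks over a range of downstream positions) likely
reflects heterogeneity beyond pure length variation and is not a target of
the simulation.

## Problem sizes

Default analyses use two libraries of ~30,000 reads on a ~11.7-kb reporter
with 35 sites, chosen so every histogram bin that matters holds hundreds of
reads; property suites use ~10³ randomized instances against brute-force
oracles. The full test suite and the acceptance script each complete in
well under a minute on one CPU.
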