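# Methods

## Recombination model

Recombination between `attP` and `attB` is modelled purely at sequence level:
the integrase is assumed to act exactly once, site-specifically, and
conservatively (no base gained or lost at either junction), which is what
end-point genotyping assays can see. Kinetics, protein binding, cooperativity
and excisionase-mediated reversal are out of scope.

**Crossover convention.** Strand exchange happens within the 2-nt `GT` core
present in both sites. Because end-point assays cannot resolve base-level
junction chemistry (the real reaction uses a 2-nt staggered cut), the package
fixes a single convention — *cut after the core*, i.e. the junction falls at
the 3' end of the core read in site orientation — and derives everything from
it. All invariants the tests rely on (length conservation, hybrid core
preservation, round-trip re-integration) are independent of this choice; only
the exact junction coordinate would shift under a different convention.

**Hybrids.** `attL = attB[:coreB+2) + attP[coreP+2:)` and
`attR = attP[:coreP+2) + attB[coreB+2:)`. Which hybrid stays at the genomic
locus is computed from placement order (the retained hybrid takes its
upstream arm from the upstream site), not hard-coded: with `attP` upstream of
`attB` on the plus strand the locus keeps `attR`.

**Outcome classification.** Same molecule + same strand → excision; same
molecule + opposite strands → inversion; different molecules with at least
one circular → integration; two linear molecules → no productive outcome.
Only excision is materialised as sequences; inversion/integration products
are classified but not constructed, since excision is the assayed event.

**Coordinates.** 0-based half-open internally everywhere; GFF3 output
converts to 1-based inclusive. Features that span an excision junction are
split into both products and flagged `split`; a hybrid-site annotation on the
released circle may wrap the origin (`end < start` flags the wrap).

## Fixture constructs

The package ships deterministic synthetic constructs emulating a
promoter–stuffer–reporter excision target and a recombinase expression
T-DNA. The published sizes are generated by construction:

| quantity | value |
|---|---|
| attP / attB / retained hybrid | 51 / 42 / 47 bp (cores at offsets 25 / 20) |
| target PCR (primers e/f), unexcised / excised | 1230 / 430 bp |
| recombinase PCR (primers g/h) | 720 bp |
| EcoRV probe-positive fragment, unexcised / excised | 1600 / 950 bp |

The stuffer is **754 bp**, not a round 760: conservative excision forces
`unexcised − excised = stuffer + attP + attB − hybrid`, and
`1230 − 430 = 800 = 754 + 51 + 42 − 47`. A 760 bp stuffer is arithmetically
incompatible with those product sizes, and the product sizes are the
quantities the diagnostics are validated against, so they win. Three EcoRV
sites are placed so that the probe-positive fragment is bounded inside the
stuffer before excision (1600 bp) and upstream of the former `attP` site
after it (950 bp).

The real Bxb1 site sequences are not hard-coded anywhere in the analysis
path; the fixture `attP`/`attB` are synthetic stand-ins that share a 20 bp
core (central `GT` at query offset 9), mirroring the fact that the core
region is conserved between the natural sites. Users supply real site
sequences via the JSON site-spec config. Background sequence is drawn i.i.d.
from a seeded generator and then *scrubbed*: stray occurrences of any primer,
its reverse complement, or a diagnostic restriction site are mutated away —
including occurrences that would only arise across the excision junction —
so each diagnostic motif occurs exactly where the layout places it.

## In-silico diagnostics

PCR uses exact full-length primer matching only (screening primers are exact
construct sequences; no mismatch/thermodynamic model) and reports one product
per convergent pair within `max_product`, on either strand, counting both
primer footprints. Digestion places fragment boundaries at the
recognition-site start (blunt model) after scanning both strands; fragment
*lengths* — the gel-readable quantity — are invariant to the within-site cut
offset, which is retained in the enzyme spec for future use. Southern
prediction reports fragments overlapping the probe interval by ≥ 50 bp by
default, a proxy for hybridization signal; there is no melting or efficiency
model.

## Cryptic-site scanner

The scan is an exhaustive, gapless, both-strand Hamming comparison of every
window against the query (vectorised over windows), not a heuristic aligner:
identity = exact positional matches / query length, no gaps. Design choices:

* `> 0.60` is a strict inequality by default (configurable to `>=`).
* Windows containing non-ACGT letters are skipped and counted, never scored.
* Overlapping same-strand windows for one query merge to the best-scoring
  window (ties: leftmost), because a cryptic-site inventory counts loci.
* The conserved-core scan (default budget: ≤ 2 mismatches over 20 bp)
  extends each hit to the full-site frame by aligning the GT cores and
  annotates overall identity to each site; frames running off a sequence end
  are scored over the truncated overlap and flagged.
* Pair analysis enumerates attP-like × attB-like hits per sequence, labels
  direct/inverted orientation by strand equality, measures the gap between
  nearest edges, optionally requires intact GT cores in both hits, and
  predicts the outcome (direct → excision, inverted → inversion).

Gapped (BLAST-style) hits are deliberately out of scope; the scan semantics
are those of positional pattern matching. Scanning a real genome assembly is
a documented recipe (`attkit scan --fasta <genome.fa> --sites <sites.json>`),
not a packaged result, since inventories depend on the assembly version.

## Genotype classification and tallies

Each plant contributes three booleans: excision band, unexcised band,
recombinase band. All eight patterns are biologically observable (e.g. both
target bands in one plant indicates mosaic or multi-copy tissue). Derived
categories are pure boolean functions (e.g. *excised-only* = excision band
and no unexcised band), tallied per family under the column scheme of the
relevant screening generation. Aggregates are exact rationals; formatting
follows the tables' mixed convention (integer percent by default, one
decimal where the source value carries one). The packaged TSVs transcribe
the published family counts; per-plant records are not reconstructable from
counts, so count tables feed the aggregate path directly while simulated
per-plant records exercise the classification path.

## Population simulation

A single-locus target and (by default) single-locus recombinase transgene
segregate independently and Mendelian-ly: hemizygous loci transmit to half
the gametes, homozygous to all; selfing draws two gametes, outcrossing one.
Each inherited target allele is already excised (a germline event in the
parent) with probability `p_germline_excision`; a recombinase-positive,
target-carrying plant additionally shows a de novo excision band with
probability `p_somatic_excision`. Mosaicism is modelled only as that
whole-plant boolean — the assay is a leaf-DNA PCR, not a per-cell readout.
Parental zygosity is an explicit parameter rather than an assumption, because
observed transmission fractions in real screens (0.65–0.95 target-positive
backcross progeny) do not fit a single Mendelian model; multi-copy insertion,
linked loci, and transmission distortion are not modelled.

`estimate_excision_efficiency` estimates the germline rate as the
excised-only fraction among *recombinase-negative, target-positive* progeny —
the subset where no de novo event can confound the call — with a Wilson score
interval. On simulated backcrosses at n = 5000 the interval covers the true
rate in ≥ 93% of 200 replicates (checked in the acceptance suite).

## Synthetic genomes: what they do and do not emulate

`generate_genome` produces i.i.d. background at a chosen GC fraction with
queries planted at exact mismatch counts (mutation positions uniform outside
the GT core, or forced into it to destroy the core) and a truth table. This
is adequate for validating a Hamming scanner — recall/precision against
truth, threshold edges, strand symmetry — but deliberately lacks repeats,
segmental duplications, compositional heterogeneity and ambiguity runs of
real genomes, so passing tests bound algorithmic correctness, not real-genome
hit inventories.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed + config ⇒ byte-identical FASTA/BED/TSV outputs (asserted in tests).
* Scanner correctness is checked against an independent naive per-window
  rescan on ~1000 random genome/query trials, most at 0.06–1.2 kb with a
  handful up to 50 kb — sizes chosen to exercise the bound thoroughly while
  keeping the suite quick.
* Hypothesis-based property tests run derandomised.
* Degenerate inputs: abutting att sites release a circle containing only the
  hybrid; a query longer than every sequence returns an empty result with a
  warning; a zero denominator in an aggregate raises; IUPAC-degenerate
  primers are rejected rather than partially supported.

## Known limitations

* No inversion/integration product construction; no recombination-efficiency
  prediction for cryptic sites.
* Exact-match PCR only; no probe thermodynamics; blunt digestion model.
* Single-locus transgene genetics; no linkage, no copy-number variation
  within a locus, no per-cell mosaicism.
* The scanner is gapless by design; indel-containing att-like loci would be
  fragmented or missed.
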