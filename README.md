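# attkit

Sequence-level modelling and screening analytics for serine-integrase
(Bxb1) `attP`/`attB` transgene excision.

## What this is for

Large serine recombinases such as the mycobacteriophage Bxb1 integrase
recombine a phage attachment site (`attP`, 51 bp here) with a bacterial
attachment site (`attB`, 42 bp), exchanging strands at a 2-nt `GT` crossover
core shared by both sites and leaving the hybrid sites `attL` and `attR`.
When the two sites flank a DNA segment in direct orientation the reaction
excises that segment as a circle, conservatively — no bases gained or lost —
and irreversibly (no excisionase). Plant biotechnologists exploit this to
delete selectable-marker genes or stuffer fragments from transgenic lines and
to ask whether the deletion happened in the germline, so that progeny inherit
the excised locus without the recombinase transgene.

`attkit` provides the computational side of such a marker-removal programme:

* **Recombination model** — hybrid-site synthesis
  (`attL = attB[:core] + attP[core:]`, `attR = attP[:core] + attB[core:]`),
  outcome classification (excision / inversion / integration) from relative
  site orientation and molecule topology, and conservative excision applied to
  an annotated sequence, with features re-coordinated and junction-spanning
  features split and flagged.
* **In-silico diagnostics** — exact-match PCR product prediction,
  restriction digestion, and Southern probe-positive fragment prediction on
  annotated constructs.
* **Cryptic-site scanner** — exhaustive gapless (Hamming) scans of both
  genome strands for att-like sequences above an identity threshold or within
  a mismatch budget of the 20-bp conserved core, GT-core flagging, and
  direct-orientation pair analysis to assess off-target excision potential.
* **Genotype tally** — classification of per-plant PCR band calls
  (excision band / unexcised band / recombinase band) into screening-table
  categories, family tallies, and exact-rational aggregates. The published
  screening-count tables for the retransformant (TR1), backcross (BC1/S1) and
  manual-cross (MC1) generations ship as package data.
* **Synthetic data** — deterministic fixture constructs reproducing the
  published diagnostic sizes, seeded genomes with att-like sites planted at
  controlled mismatch counts plus a truth table, and Mendelian
  screening-population simulation with germline/somatic excision
  probabilities, including a Wilson-interval estimator that recovers the
  germline excision rate from recombinase-free progeny.

## Worked example

```python
>>> import attkit as ak
>>> from attkit.synthetic import PRIMER_E, PRIMER_F, ECORV

>>> target = ak.make_fixture_construct("unexcised")
>>> p, b = ak.fixture_placements()
>>> ak.classify_outcome(p, b).kind.value
'excision'
>>> remaining, circle = ak.excise(target, p, b)
>>> len(target), len(remaining), len(circle)
(4100, 3300, 800)

>>> [pr.length for pr in ak.insilico_pcr(target, PRIMER_E, PRIMER_F)]
[1230]
>>> [pr.length for pr in ak.insilico_pcr(remaining, PRIMER_E, PRIMER_F)]
[430]

>>> probe = remaining.feature("GUS1350_probe")
>>> ak.southern_fragments(ak.digest(remaining, [ECORV]),
...                       (probe.start, probe.end), len(remaining))
[950]
```

The target-locus PCR (primers `e`/`f`) spans the att-flanked stuffer: 1230 bp
while the stuffer is present, 430 bp after excision, because the 800 bp
`attP`–stuffer–`attB` segment collapses to the 47 bp retained `attR` hybrid
(base count conserved: 3300 + 800 = 4100). The EcoRV/probe prediction drops
from 1600 bp to 950 bp for the same reason — the diagnostic band shift a
Southern blot reads out.

Screen statistics from the packaged backcross table:

```python
>>> rows = ak.load_table("bc1")
>>> res = ak.aggregate(rows, "excision_positive", "target_positive")
>>> res.numerator, res.denominator, res.formatted(1)
(528, 677, '78.0%')
```

i.e. 78.0% of backcross progeny that inherited the target locus show the
excision band.

A console script exposes the same operations
(`attkit pcr|digest|southern|excise|scan|pairs|tally|make-genome|simulate|fixtures`);
run `attkit --help`.

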