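"""In-silico molecular diagnostics on annotated constructs.

Three assays mirror the bench screen for recombinase-mediated excision:

* PCR product prediction from a convergent primer pair (exact full-length
  primer binding, no mismatch model — screening primers are exact construct
  sequences).
* Restriction digestion with config-defined enzymes.  Fragment boundaries are
  placed at the recognition-site start (blunt model); fragment *lengths* are
  independent of the within-site cut offset, which is what gels report.
* Southern prediction: digestion fragments that overlap a labelled probe by at
  least a minimum overlap are the bands the probe lights up.
"""

from __future__ import annotations

from dataclasses import dataclass

from .recombination import AnnotatedSequence, reverse_complement

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide primer (15-40 nt, plain ACGT)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        bad = set(seq) - _ACGT
        if bad:
            raise ValueError(
                f"primer {self.name!r}: unsupported alphabet {sorted(bad)} "
                "(degenerate IUPAC letters are not supported)"
            )
        if not 15 <= len(seq) <= 40:
            raise ValueError(f"primer {self.name!r}: length must be 15-40 nt")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease defined by its recognition sequence."""

    name: str
    recognition: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4 or set(rec) - _ACGT:
            raise ValueError(f"enzyme {self.name!r}: recognition must be >=4 nt ACGT")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"enzyme {self.name!r}: cut_offset outside recognition")


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int
    length: int


@dataclass(frozen=True)
class PcrProduct:
    length: int
    start: int
    end: int
    fwd: str
    rev: str


def find_occurrences(seq: str, pattern: str) -> list[int]:
    """All (overlapping) start positions of ``pattern`` in ``seq``."""
    out, i = [], seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def _search_space(template: AnnotatedSequence) -> tuple[str, int]:
    """Sequence to scan and the coordinate modulus (doubled when circular)."""
    if template.topology == "circular":
        return template.sequence + template.sequence, len(template.sequence)
    return template.sequence, len(template.sequence)


def _convergent_products(
    seq: str, n: int, circular: bool, fwd: Primer, rev: Primer, max_product: int
) -> list[PcrProduct]:
    rev_rc = reverse_complement(rev.sequence)
    products = []
    for i in find_occurrences(seq, fwd.sequence):
        if i >= n:
            continue
        for j in find_occurrences(seq, rev_rc):
            end = j + len(rev)
            length = end - i
            if j < i or length > max_product:
                continue
            if end <= i + len(fwd):
                continue  # primers not convergent around a real template span
            if circular and length > n:
                continue
            products.append(PcrProduct(length, i, end, fwd.name, rev.name))
    return products


def insilico_pcr(
    template: AnnotatedSequence,
    fwd: Primer,
    rev: Primer,
    max_product: int = 10000,
) -> list[PcrProduct]:
    """Predict PCR products for a primer pair on a template.

    Primers bind by exact full-length match only.  A product is reported for
    every convergent arrangement — forward primer on the plus strand with the
    reverse primer's binding site (its reverse complement) downstream, and the
    mirror-image arrangement on the minus strand — with span <= max_product.
    Product length includes both primer footprints.  Ambiguous (multiply
    binding) primers yield one entry per convergent pair.
    """
    seq, n, circular = *_search_space(template), template.topology == "circular"
    products = _convergent_products(seq, n, circular, fwd, rev, max_product)
    if fwd.sequence != rev.sequence:
        # the symmetric arrangement: amplicon read off the minus strand
        products += _convergent_products(seq, n, circular, rev, fwd, max_product)
    # deduplicate identical intervals found via both orientations
    seen, unique = set(), []
    for p in sorted(products, key=lambda p: (p.start, p.end)):
        if (p.start % n, p.end) not in seen:
            seen.add((p.start % n, p.end))
            unique.append(p)
    return unique


def cut_positions(template: AnnotatedSequence, enzymes: list[RestrictionEnzyme]) -> list[int]:
    """Plus-strand cut coordinates (blunt model: recognition-site start).

    Both strands are scanned; for non-palindromic recognition sequences the
    reverse-complement occurrences contribute their own site starts.
    """
    seq, n = _search_space(template)
    cuts: set[int] = set()
    for enz in enzymes:
        for pat in {enz.recognition, reverse_complement(enz.recognition)}:
            for i in find_occurrences(seq, pat):
                if i < n:
                    cuts.add(i % n)
    return sorted(cuts)


def digest(
    template: AnnotatedSequence, enzymes: list[RestrictionEnzyme]
) -> list[Fragment]:
    """Digest a template, returning fragments that partition the sequence.

    A linear molecule with k cut sites yields k+1 fragments (zero-length end
    fragments from a cut at position 0 are dropped); a circular molecule
    yields k fragments, or the intact circle when k == 0.
    """
    n = len(template.sequence)
    cuts = cut_positions(template, enzymes)
    frags: list[Fragment] = []
    if template.topology == "linear":
        bounds = [0] + cuts + [n]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                frags.append(Fragment(a, b, b - a))
    else:
        if not cuts:
            return [Fragment(0, n, n)]
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + n]):
            frags.append(Fragment(a, b % n if b != cuts[0] + n else cuts[0], b - a))
    return frags


def southern_fragments(
    fragments: list[Fragment],
    probe: tuple[int, int],
    template_length: int | None = None,
    min_overlap: int = 50,
) -> list[int]:
    """Lengths of digestion fragments a probe hybridizes to.

    A fragment is probe-positive when its interval overlaps the probe interval
    by at least ``min_overlap`` bp.  Wrapping fragments from circular digests
    are handled piecewise when ``template_length`` is given.
    """
    pstart, pend = probe
    if pstart < 0 or pend <= pstart:
        raise ValueError("probe interval is empty or out of bounds")
    if template_length is not None and pend > template_length:
        raise ValueError("probe interval outside sequence bounds")
    out = []
    for f in fragments:
        pieces = [(f.start, f.end)]
        if f.end <= f.start:  # wrapping circular fragment
            if template_length is None:
                raise ValueError("wrapping fragment requires template_length")
            pieces = [(f.start, template_length), (0, f.end)]
        overlap = sum(
            max(0, min(e, pend) - max(s, pstart)) for s, e in pieces
        )
        if overlap >= min_overlap:
            out.append(f.length)
    return out
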