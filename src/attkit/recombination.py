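"""Sequence-level model of serine-integrase attP x attB recombination.

Large serine recombinases such as Bxb1 recombine a phage attachment site
(attP) with a bacterial attachment site (attB).  Strand exchange happens at a
2-nt crossover core (``GT`` in Bxb1) present in both sites, and produces the
hybrid sites attL and attR.  The reaction is conservative: no bases are gained
or lost.  Depending on the relative orientation and topology of the two sites
the reaction excises, inverts, or integrates the intervening DNA.

The crossover convention used throughout is "cut after the core": the junction
falls at the 3' end of the 2-nt core, read in site orientation.  Base-level
junction chemistry is not resolved by end-point assays, so the convention is
fixed here and all conservation/round-trip invariants are independent of it.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RecombinationError(ValueError):
    """Raised for invalid site configurations or core mismatches."""


class CoreMismatchError(RecombinationError):
    """An att site does not carry the expected dinucleotide crossover core."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttSiteSpec:
    """A recombinase recognition site.

    Parameters
    ----------
    name:
        Site label, conventionally one of ``attP``, ``attB``, ``attL``,
        ``attR``.
    sequence:
        Site sequence over {A,C,G,T}, read in site orientation.
    core_offset:
        0-based index of the first base of the 2-nt crossover core.
    minimal_length:
        Length in bp of the minimal functional site (<= full length); purely
        descriptive, defaults to the full length.
    """

    name: str
    sequence: str
    core_offset: int
    minimal_length: Optional[int] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - VALID_BASES:
            raise ValueError(f"site {self.name!r}: sequence must be non-empty ACGT")
        if not 0 <= self.core_offset <= len(seq) - 2:
            raise ValueError(
                f"site {self.name!r}: core_offset {self.core_offset} outside sequence"
            )
        if self.minimal_length is None:
            object.__setattr__(self, "minimal_length", len(seq))
        elif self.minimal_length > len(seq):
            raise ValueError(f"site {self.name!r}: minimal_length exceeds full length")

    @property
    def full_length(self) -> int:
        return len(self.sequence)

    @property
    def core(self) -> str:
        return self.sequence[self.core_offset : self.core_offset + 2]

    @property
    def core_end(self) -> int:
        return self.core_offset + 2

    def require_core(self, core: str = "GT") -> None:
        if self.core != core:
            raise CoreMismatchError(
                f"site {self.name!r} carries core {self.core!r} at offset "
                f"{self.core_offset}, expected {core!r}"
            )


@dataclass(frozen=True)
class Feature:
    """A named, stranded interval on a sequence (0-based half-open)."""

    name: str
    start: int
    end: int
    strand: str = "+"
    split: bool = False  # set when excision cut through the feature


@dataclass
class AnnotatedSequence:
    """A linear or circular DNA sequence with named stranded features.

    For circular topology a feature may wrap the origin, in which case
    ``end < start`` and the feature is flagged by that inversion alone.
    """

    seq_id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start <= n and 0 <= f.end <= n):
                raise ValueError(f"feature {f.name!r} outside [0, {n})")
            if self.topology == "linear" and f.end < f.start:
                raise ValueError(f"feature {f.name!r} wraps on a linear sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]


@dataclass(frozen=True)
class SitePlacement:
    """An att site placed on a sequence."""

    site: AttSiteSpec
    seq_id: str
    start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("placement start must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        return self.start + self.site.full_length

    def cut_position(self) -> int:
        """Plus-strand coordinate of the junction ("cut after core").

        On the plus strand the junction is the base after the core; on the
        minus strand the site reads right-to-left, so the same junction maps
        to the left edge of the core's plus-strand image.
        """
        if self.strand == "+":
            return self.start + self.site.core_end
        return self.end - self.site.core_end


class OutcomeKind(str, enum.Enum):
    EXCISION = "excision"
    INVERSION = "inversion"
    INTEGRATION = "integration"
    NONE = "none"


@dataclass(frozen=True)
class RecombinationOutcome:
    kind: OutcomeKind
    retained_hybrid: Optional[str] = None
    released_hybrid: Optional[str] = None


# ---------------------------------------------------------------------------
# Hybrid site synthesis
# ---------------------------------------------------------------------------

def make_hybrid_sites(
    attP: AttSiteSpec, attB: AttSiteSpec, core: str = "GT"
) -> tuple[AttSiteSpec, AttSiteSpec]:
    """Build the attL/attR hybrid sites produced by attP x attB recombination.

    With the cut-after-core convention, attL carries the attB left arm
    (through the core) joined to the attP right arm, and attR the attP left
    arm joined to the attB right arm:

        attL = attB[0:coreB+2) + attP[coreP+2:)
        attR = attP[0:coreP+2) + attB[coreB+2:)

    Both hybrids retain an unchanged core at the donor arm's offset, and the
    hybrid lengths sum to the input lengths (conservative exchange).

    Raises
    ------
    CoreMismatchError
        If either input lacks the expected core at its stated offset.
    """
    attP.require_core(core)
    attB.require_core(core)
    attL = AttSiteSpec(
        name="attL",
        sequence=attB.sequence[: attB.core_end] + attP.sequence[attP.core_end :],
        core_offset=attB.core_offset,
    )
    attR = AttSiteSpec(
        name="attR",
        sequence=attP.sequence[: attP.core_end] + attB.sequence[attB.core_end :],
        core_offset=attP.core_offset,
    )
    return attL, attR


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def classify_outcome(
    p: SitePlacement,
    b: SitePlacement,
    topology_p: str = "linear",
    topology_b: str = "linear",
) -> RecombinationOutcome:
    """Classify the recombination outcome for one attP and one attB placement.

    Two sites on the same molecule recombine in cis: direct repeats (same
    strand) excise the intervening DNA, inverted repeats (opposite strands)
    invert it.  Sites on different molecules recombine in trans only when at
    least one molecule is circular, integrating it into the other; two linear
    molecules merely exchange arms, which is not a productive outcome here.
    """
    labels = {p.site.name, b.site.name}
    if labels != {"attP", "attB"}:
        raise RecombinationError(
            f"classification requires one attP and one attB placement, got {labels}"
        )
    if p.seq_id == b.seq_id:
        if max(p.start, b.start) < min(p.end, b.end):
            raise RecombinationError("att site placements overlap")
        if p.strand == b.strand:
            left, right = (p, b) if p.start < b.start else (b, p)
            # the retained hybrid takes its left arm from the left site
            # (read on the sites' strand: the first-encountered site)
            first = left if p.strand == "+" else right
            retained = "attR" if first.site.name == "attP" else "attL"
            released = "attL" if retained == "attR" else "attR"
            return RecombinationOutcome(OutcomeKind.EXCISION, retained, released)
        return RecombinationOutcome(OutcomeKind.INVERSION, "attL", "attR")
    if topology_p == "circular" or topology_b == "circular":
        return RecombinationOutcome(OutcomeKind.INTEGRATION, "attL", "attR")
    return RecombinationOutcome(OutcomeKind.NONE)


# ---------------------------------------------------------------------------
# Excision
# ---------------------------------------------------------------------------

def _relocate_features(
    feats: list[Feature],
    cut_left: int,
    cut_right: int,
    skip: tuple[tuple[int, int], ...],
) -> tuple[list[Feature], list[Feature]]:
    """Split a feature list at two cut positions into (remaining, circle)."""
    removed = cut_right - cut_left
    remaining: list[Feature] = []
    circle: list[Feature] = []
    for f in feats:
        if (f.start, f.end) in skip:
            continue
        if f.end <= cut_left:
            remaining.append(f)
        elif f.start >= cut_right:
            remaining.append(replace(f, start=f.start - removed, end=f.end - removed))
        elif f.start >= cut_left and f.end <= cut_right:
            circle.append(replace(f, start=f.start - cut_left, end=f.end - cut_left))
        else:
            # feature crosses a junction: split and flag both parts
            if f.start < cut_left:
                remaining_part = replace(f, end=cut_left, split=True)
                remaining.append(remaining_part)
                circle.append(
                    replace(f, start=0, end=min(f.end, cut_right) - cut_left, split=True)
                )
            if f.end > cut_right:
                circle.append(
                    replace(
                        f,
                        start=max(f.start, cut_left) - cut_left,
                        end=cut_right - cut_left,
                        split=True,
                    )
                )
                remaining.append(
                    replace(f, start=cut_left, end=f.end - removed, split=True)
                )
    return remaining, circle


def excise(
    seq: AnnotatedSequence, p: SitePlacement, b: SitePlacement
) -> tuple[AnnotatedSequence, AnnotatedSequence]:
    """Apply conservative excision between two directly oriented att sites.

    Returns the remaining (chromosomal) sequence carrying one hybrid site and
    the released circle carrying the other hybrid plus the inter-site segment.
    The total base count is conserved exactly.  Features falling wholly in the
    released segment move to the circle; features spanning a junction are
    split and flagged.  The two att-site features themselves (if annotated at
    exactly the placement intervals) are replaced by the hybrid annotations.

    Raises
    ------
    RecombinationError
        If the placements do not classify as excision on this sequence.
    """
    outcome = classify_outcome(p, b, seq.topology, seq.topology)
    if outcome.kind is not OutcomeKind.EXCISION:
        raise RecombinationError(
            f"placements produce {outcome.kind.value}, not excision"
        )
    if p.seq_id != seq.seq_id or b.seq_id != seq.seq_id:
        raise RecombinationError("placements do not reference this sequence")
    if max(p.end, b.end) > len(seq):
        raise RecombinationError("placement outside sequence bounds")

    left, right = (p, b) if p.start < b.start else (b, p)
    cut_left = left.cut_position()
    cut_right = right.cut_position()
    s = seq.sequence
    remaining_seq = s[:cut_left] + s[cut_right:]
    circle_seq = s[cut_left:cut_right]
    strand = p.strand

    retained_len = (cut_left - left.start) + (right.end - cut_right)
    released_len = (left.end - cut_left) + (cut_right - right.start)

    remaining_feats, circle_feats = _relocate_features(
        seq.features,
        cut_left,
        cut_right,
        skip=((p.start, p.end), (b.start, b.end)),
    )
    remaining_feats.append(
        Feature(outcome.retained_hybrid, left.start, left.start + retained_len, strand)
    )
    # released hybrid wraps the circle origin: right site's kept arm at the
    # end of the segment joined to left site's kept arm at the start
    n_circle = len(circle_seq)
    if released_len >= n_circle:
        circle_feats.append(Feature(outcome.released_hybrid, 0, n_circle, strand))
    else:
        circle_feats.append(
            Feature(
                outcome.released_hybrid,
                n_circle - (cut_right - right.start),
                left.end - cut_left,
                strand,
            )
        )
    remaining = AnnotatedSequence(
        seq_id=seq.seq_id, sequence=remaining_seq,
        topology=seq.topology, features=remaining_feats,
    )
    released = AnnotatedSequence(
        seq_id=f"{seq.seq_id}_excised_circle", sequence=circle_seq,
        topology="circular", features=circle_feats,
    )
    return remaining, released
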