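"""Genome scanner for cryptic (att-like) recombinase recognition sites.

Endogenous genomic sequences resembling attP/attB could in principle act as
recombination substrates, so a safety/targeting analysis scans the genome for
them.  Two complementary searches are implemented natively as exhaustive
gapless (Hamming) window scans of both strands:

* full-site identity scan — every window whose positional identity to the
  full att site exceeds a threshold (default: strictly greater than 0.60);
* conserved-core scan — windows within a mismatch budget (default 2) of the
  20-bp core shared by attP and attB, extended to the full-site frame and
  annotated with overall identity to each site.

Hits are flagged for an intact "GT" crossover core, since recombination
requires it, and candidate attP/attB hit pairs on one chromosome are ranked by
distance and orientation to predict whether an excision could occur.

Windows containing non-ACGT letters are skipped (counted, not scored) to
avoid inflating identity across ambiguity codes.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .recombination import AttSiteSpec, OutcomeKind, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanQuery:
    """A scan query: a sequence, a scoring mode, and a threshold.

    In ``identity`` mode the threshold is the fraction of matching positions a
    window must exceed (strict ``>`` by default, see :func:`scan`).  In
    ``core_mismatch`` mode it is the maximum Hamming distance allowed.
    ``core_offset`` marks the first base of the GT crossover core within the
    query, used to flag hits whose core is intact.
    """

    name: str
    sequence: str
    mode: Literal["identity", "core_mismatch"] = "identity"
    threshold: float = 0.60
    core_offset: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.mode == "identity":
            if not 0 < self.threshold <= 1:
                raise ValueError("identity threshold must be in (0, 1]")
        elif self.mode == "core_mismatch":
            if self.threshold < 0 or self.threshold != int(self.threshold):
                raise ValueError("core_mismatch threshold must be an integer >= 0")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.core_offset is not None and not (
            0 <= self.core_offset <= len(self.sequence) - 2
        ):
            raise ValueError("core_offset outside query")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_site(
        cls, site: AttSiteSpec, threshold: float = 0.60, suffix: str = "_full"
    ) -> "ScanQuery":
        return cls(
            name=site.name + suffix,
            sequence=site.sequence,
            mode="identity",
            threshold=threshold,
            core_offset=site.core_offset,
        )


@dataclass(frozen=True)
class ScanHit:
    """One genomic window matching a query (coordinates 0-based half-open)."""

    query: str
    seq_id: str
    start: int
    end: int
    strand: str
    matches: int
    identity: float
    core_mismatches: Optional[int] = None
    has_gt_core: bool = False
    truncated: bool = False
    site_identities: Optional[Mapping[str, float]] = None


@dataclass(frozen=True)
class SitePair:
    """A candidate attP-like/attB-like hit pair on one sequence."""

    hitP: ScanHit
    hitB: ScanHit
    orientation: Literal["direct", "inverted"]
    distance: int
    predicted_outcome: str


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------

def _window_matches(seq_arr: np.ndarray, query: str) -> np.ndarray:
    """Positional match counts for every window of len(query) (vectorized)."""
    L = len(query)
    n = len(seq_arr) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(n, dtype=np.int32)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    for j in range(L):
        counts += seq_arr[j : j + n] == q[j]
    return counts


def _valid_windows(seq_arr: np.ndarray, L: int) -> np.ndarray:
    """Boolean mask of windows composed purely of A/C/G/T."""
    ok = np.isin(seq_arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(seq_arr) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    bad = np.cumsum(~ok)
    return (bad[L - 1 :] - np.concatenate(([0], bad[:-1]))[: n]) == 0


def _gt_core_intact(window: str, strand: str, core_offset: Optional[int]) -> bool:
    if core_offset is None:
        return False
    w = window if strand == "+" else reverse_complement(window)
    return w[core_offset : core_offset + 2] == "GT"


def merge_hits(hits: Sequence[ScanHit]) -> list[ScanHit]:
    """Collapse overlapping same-query, same-strand windows to one locus.

    A cryptic-site inventory counts loci, not windows, so chains of mutually
    overlapping windows are merged keeping the best-scoring window (ties:
    leftmost).
    """
    out: list[ScanHit] = []
    keyfn = lambda h: (h.query, h.seq_id, h.strand)
    for key in sorted({keyfn(h) for h in hits}):
        group = sorted((h for h in hits if keyfn(h) == key), key=lambda h: h.start)
        cluster: list[ScanHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.start >= cluster_end:
                out.append(max(cluster, key=lambda c: (c.matches, -c.start)))
                cluster = []
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
        if cluster:
            out.append(max(cluster, key=lambda c: (c.matches, -c.start)))
    return sorted(out, key=lambda h: (h.seq_id, h.start, h.strand, h.query))


def scan(
    genome: Mapping[str, str],
    query: ScanQuery,
    *,
    strict: bool = True,
    merge: bool = True,
) -> list[ScanHit]:
    """Exhaustive gapless scan of both strands of every genome sequence.

    Every window of the query length whose identity exceeds the query
    threshold (``>`` when ``strict``, the scan default, else ``>=``) is
    reported; in ``core_mismatch`` mode the criterion is Hamming distance <=
    threshold.  Identity is exact positional matches / query length, no gaps.
    Overlapping same-strand hits are merged into loci unless ``merge=False``.
    """
    L = len(query)
    cmp = operator.gt if strict else operator.ge
    hits: list[ScanHit] = []
    any_fit = False
    skipped = 0
    queries = {"+": query.sequence, "-": reverse_complement(query.sequence)}
    for seq_id, seq in genome.items():
        seq = seq.upper()
        if len(seq) < L:
            continue
        any_fit = True
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        valid = _valid_windows(arr, L)
        skipped += int((~valid).sum())
        for strand, qseq in queries.items():
            counts = _window_matches(arr, qseq)
            if query.mode == "identity":
                keep = cmp(counts / L, query.threshold)
            else:
                keep = (L - counts) <= int(query.threshold)
            for i in np.flatnonzero(keep & valid):
                i = int(i)
                window = seq[i : i + L]
                m = int(counts[i])
                hits.append(
                    ScanHit(
                        query=query.name,
                        seq_id=seq_id,
                        start=i,
                        end=i + L,
                        strand=strand,
                        matches=m,
                        identity=m / L,
                        core_mismatches=(L - m) if query.mode == "core_mismatch" else None,
                        has_gt_core=_gt_core_intact(window, strand, query.core_offset),
                    )
                )
    if not any_fit:
        logger.warning("query %s is longer than every genome sequence", query.name)
    if skipped:
        logger.info("skipped %d windows containing non-ACGT letters", skipped)
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand, h.query))
    return merge_hits(hits) if merge else hits


# ---------------------------------------------------------------------------
# Conserved-core scan with full-site frame extension
# ---------------------------------------------------------------------------

def _frame_identity(
    seq: str, hit_start: int, hit_end: int, strand: str, site: AttSiteSpec, offset_in_site: int
) -> tuple[float, bool]:
    """Identity of the full-site frame around a core hit to ``site``.

    ``offset_in_site`` is where the core query begins within the site.  When
    the extension runs off the sequence end the identity is computed over the
    truncated overlap and the hit flagged.
    """
    L_site = site.full_length
    left_ext = offset_in_site
    right_ext = L_site - offset_in_site - (hit_end - hit_start)
    if strand == "+":
        fstart, fend = hit_start - left_ext, hit_end + right_ext
    else:
        fstart, fend = hit_start - right_ext, hit_end + left_ext
    cstart, cend = max(0, fstart), min(len(seq), fend)
    truncated = (cstart, cend) != (fstart, fend)
    window = seq[cstart:cend]
    if strand == "-":
        window = reverse_complement(window)
        site_seq = site.sequence[fend - cend : fend - cend + len(window)]
    else:
        site_seq = site.sequence[cstart - fstart : cstart - fstart + len(window)]
    matches = sum(a == b for a, b in zip(window, site_seq))
    denom = len(window) if truncated else L_site
    return (matches / denom if denom else 0.0), truncated


def core_scan(
    genome: Mapping[str, str],
    core_query: ScanQuery,
    full_sites: Mapping[str, AttSiteSpec],
    max_mismatch: int = 2,
) -> list[ScanHit]:
    """Scan for the conserved core, then annotate full-site-frame identities.

    Hits within ``max_mismatch`` Hamming distance of the core are extended to
    each full site's frame (aligning the core's position within the site) and
    annotated with overall identity to every site in ``full_sites``.
    """
    if core_query.core_offset is None:
        raise ValueError("core query must declare its GT core offset")
    cq = replace(core_query, mode="core_mismatch", threshold=float(max_mismatch))
    hits = scan(genome, cq, merge=True)
    out = []
    for h in hits:
        seq = genome[h.seq_id].upper()
        idents: dict[str, float] = {}
        truncated = False
        for label, site in full_sites.items():
            offset_in_site = site.core_offset - core_query.core_offset
            if offset_in_site < 0 or offset_in_site + len(core_query) > site.full_length:
                raise ValueError(
                    f"core query does not fit inside site {label!r} at the GT core"
                )
            ident, trunc = _frame_identity(seq, h.start, h.end, h.strand, site, offset_in_site)
            idents[label] = ident
            truncated = truncated or trunc
        out.append(replace(h, site_identities=idents, truncated=truncated))
    return out


# ---------------------------------------------------------------------------
# Pair analysis
# ---------------------------------------------------------------------------

def find_pairs(
    hitsP: Sequence[ScanHit],
    hitsB: Sequence[ScanHit],
    require_gt: bool = False,
    max_distance: Optional[int] = None,
) -> list[SitePair]:
    """All attP-like x attB-like hit pairs on a shared sequence.

    Pairs are annotated direct/inverted by strand equality; the distance is
    the gap between nearest site edges (0 when overlapping).  Direct pairs
    could excise the intervening DNA, inverted pairs invert it.  Results are
    sorted by distance ascending.
    """
    pairs = []
    for hp in hitsP:
        for hb in hitsB:
            if hp.seq_id != hb.seq_id:
                continue
            if require_gt and not (hp.has_gt_core and hb.has_gt_core):
                continue
            distance = max(0, max(hp.start, hb.start) - min(hp.end, hb.end))
            if max_distance is not None and distance > max_distance:
                continue
            direct = hp.strand == hb.strand
            pairs.append(
                SitePair(
                    hitP=hp,
                    hitB=hb,
                    orientation="direct" if direct else "inverted",
                    distance=distance,
                    predicted_outcome=(
                        OutcomeKind.EXCISION.value if direct else OutcomeKind.INVERSION.value
                    ),
                )
            )
    pairs.sort(key=lambda p: (p.distance, p.hitP.seq_id, p.hitP.start, p.hitB.start))
    return pairs
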