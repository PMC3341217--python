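"""Synthetic inputs: fixture constructs, planted genomes, simulated screens.

Three generators produce every input the analysis needs, so the whole pipeline
is testable without downloads:

* ``make_fixture_construct`` — deterministic annotated T-DNA constructs for a
  promoter/stuffer/reporter excision target (attP-stuffer-attB between a 35S
  promoter and a gusA reporter, with hptII selection) and a recombinase
  expression construct (OXS3 promoter driving the integrase, nptII selection).
  Element lengths are chosen so the diagnostic assays reproduce the published
  sizes exactly: 1230/430 bp target-locus PCR products (unexcised/excised),
  a 720 bp recombinase-gene product, and 1600/950 bp EcoRV Southern fragments.
* ``generate_genome`` — i.i.d. background DNA with att-like sequences planted
  at controlled mismatch counts/strands plus a truth table, for scanner
  validation.
* ``simulate_population`` — Mendelian transmission of a single-locus target
  and recombinase transgene through the screening generations (TR1 secondary
  transformants, BC1 backcross, S1 self, MC1 manual cross), with germline and
  somatic excision probabilities, emitting per-plant PCR band calls.

All generators are seeded and byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.stats import norm

from .assays import Primer, RestrictionEnzyme, find_occurrences
from .recombination import (
    AnnotatedSequence,
    AttSiteSpec,
    Feature,
    SitePlacement,
    reverse_complement,
)
from .scanner import ScanQuery
from .tally import PlantRecord, classify

# ---------------------------------------------------------------------------
# Reference-style fixture att sites
#
# The real Bxb1 site sequences are supplied by users via config; the package
# ships synthetic stand-ins with the documented geometry: a 51 bp attP and a
# 42 bp attB sharing a 20 bp conserved core whose central GT dinucleotide sits
# at offsets 25 and 20 respectively, so that the chromosomally retained
# attP/attB hybrid after excision is 47 bp.
# ---------------------------------------------------------------------------

CORE20 = "ACGATCCAGGTCGCAGTAAC"  # synthetic conserved core, GT at offset 9
CORE20_GT_OFFSET = 9

ATTP_SEQUENCE = "GGTTTGTCTGGTCAAC" + CORE20 + "CCACCGATCGGAAGA"  # 51 bp
ATTB_SEQUENCE = "GGCTTGTCGAC" + CORE20 + "GATGGCTCCAA"  # 42 bp

ATTP = AttSiteSpec("attP", ATTP_SEQUENCE, core_offset=25, minimal_length=48)
ATTB = AttSiteSpec("attB", ATTB_SEQUENCE, core_offset=20, minimal_length=42)

CORE_QUERY = ScanQuery(
    "core20", CORE20, mode="core_mismatch", threshold=2, core_offset=CORE20_GT_OFFSET
)

PRIMER_E = Primer("e", "ATATCTCCACTGACGTAAGG")
PRIMER_F = Primer("f", "ATCATCATCATAGACACACG")
PRIMER_G = Primer("g", "ATGAGAGCCCTGGTAGTCATCCG")
PRIMER_H = Primer("h", "CGGAGATCATCGATCGCTTCAGC")

ECORV = RestrictionEnzyme("EcoRV", "GATATC")
ECORI = RestrictionEnzyme("EcoRI", "GAATTC")
BAMHI = RestrictionEnzyme("BamHI", "GGATCC")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def fixture_site_specs() -> dict[str, AttSiteSpec]:
    return {"attP": ATTP, "attB": ATTB}


def fixture_placements() -> tuple[SitePlacement, SitePlacement]:
    """Placements of the fixture attP/attB within the unexcised construct."""
    return (
        SitePlacement(ATTP, "pN6_Bxb1", start=_ATTP_START, strand="+"),
        SitePlacement(ATTB, "pN6_Bxb1", start=_ATTB_START, strand="+"),
    )


# Target-construct coordinate plan (0-based half-open).  The geometry encodes
# the published diagnostic sizes: e..f spans 1230 bp across the stuffer and
# 430 bp once the 800 bp attP-stuffer-attB segment collapses to the 47 bp
# hybrid; EcoRV sites bracket probe-positive fragments of 1600 and 950 bp.
_LEN_TARGET = 4100
_ATTP_START = 230  # attP [230, 281), cut after core at 257
_ATTB_START = 1035  # attB [1035, 1077), cut after core at 1057
_STUFFER = (281, 1035)  # 754 bp
_E_SITE = (100, 120)
_F_SITE = (1310, 1330)  # reverse primer binding site (minus strand)
_PROBE = (1130, 1920)  # 790 bp gusA probe
_ECORV_SITES = (170, 320, 1920)
_ECORI_SITE = 3000
_BAMHI_SITE = 3200

_TARGET_FEATURES = [
    Feature("RB", 0, 30),
    Feature("35S", 30, 230),
    Feature("primer_e_site", *_E_SITE),
    Feature("attP", _ATTP_START, _ATTP_START + 51),
    Feature("stuffer", *_STUFFER),
    Feature("attB", _ATTB_START, _ATTB_START + 42),
    Feature("gusA", 1090, 2900),
    Feature("GUS1350_probe", *_PROBE),
    Feature("primer_f_site", *_F_SITE, "-"),
    Feature("hptII", 2950, 3950),
    Feature("LB", 4050, 4080),
]

# Recombinase-construct plan: g/h amplify 720 bp from within the integrase ORF
_LEN_RECOMB = 3000
_G_SITE = (600, 623)
_H_SITE = (1297, 1320)
_RECOMB_FEATURES = [
    Feature("RB", 0, 30),
    Feature("OXS3_promoter", 50, 550),
    Feature("Bxb1", 600, 2100),
    Feature("primer_g_site", *_G_SITE),
    Feature("primer_h_site", *_H_SITE, "-"),
    Feature("nptII", 2200, 2900),
    Feature("LB", 2960, 2990),
]

_CUT_LEFT = _ATTP_START + ATTP.core_end  # 257
_CUT_RIGHT = _ATTB_START + ATTB.core_end  # 1057
_REMOVED = _CUT_RIGHT - _CUT_LEFT  # 800


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.40) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _plant(arr: np.ndarray, pos: int, motif: str) -> None:
    arr[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _forbidden_motifs() -> list[str]:
    motifs = []
    for enz in (ECORV, ECORI, BAMHI):
        motifs += [enz.recognition, reverse_complement(enz.recognition)]
    for pr in (PRIMER_E, PRIMER_F, PRIMER_G, PRIMER_H):
        motifs += [pr.sequence, reverse_complement(pr.sequence)]
    return sorted(set(motifs))


def _scrub(
    arr: np.ndarray,
    allowed: dict[str, set[int]],
    protected: list[tuple[int, int]],
    extra_views: Optional[list] = None,
) -> None:
    """Mutate stray occurrences of forbidden motifs out of a sequence.

    ``allowed`` maps motif -> start positions that are intentional.
    ``protected`` intervals (planted literals) are never mutated.
    ``extra_views`` are (transform, back_map) pairs: the transform derives a
    secondary sequence (e.g. the excised state) from ``arr`` and ``back_map``
    converts its coordinates back, so junction-spanning artefacts in derived
    states are scrubbed at their source.
    """

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    motifs = _forbidden_motifs()
    for _ in range(200):
        dirty = False
        views = [(bytes(arr).decode(), lambda p: p)]
        for transform, back_map in extra_views or []:
            views.append((transform(bytes(arr).decode()), back_map))
        for seq, back in views:
            for motif in motifs:
                for i in find_occurrences(seq, motif):
                    # allowed positions are defined in source coordinates
                    if back(i) in allowed.get(motif, set()):
                        continue
                    for k in range(len(motif)):
                        pos = back(i + k)
                        if not is_protected(pos):
                            base = chr(arr[pos])
                            arr[pos] = ord("ACGT"[("ACGT".index(base) + 1) % 4])
                            dirty = True
                            break
                    else:
                        raise RuntimeError("cannot scrub motif inside protected region")
                    break  # rescan after each mutation
                if dirty:
                    break
            if dirty:
                break
        if not dirty:
            return
    raise RuntimeError("scrubbing did not converge")


def _excised_transform(seq: str) -> str:
    return seq[:_CUT_LEFT] + seq[_CUT_RIGHT:]


def _excised_back_map(pos: int) -> int:
    return pos if pos < _CUT_LEFT else pos + _REMOVED


@lru_cache(maxsize=None)
def _build_target_sequence() -> str:
    rng = np.random.default_rng(20120321)
    arr = _random_dna(rng, _LEN_TARGET)
    _plant(arr, _E_SITE[0], PRIMER_E.sequence)
    _plant(arr, _F_SITE[0], reverse_complement(PRIMER_F.sequence))
    _plant(arr, _ATTP_START, ATTP.sequence)
    _plant(arr, _ATTB_START, ATTB.sequence)
    for v in _ECORV_SITES:
        _plant(arr, v, ECORV.recognition)
    _plant(arr, _ECORI_SITE, ECORI.recognition)
    _plant(arr, _BAMHI_SITE, BAMHI.recognition)
    protected = [
        _E_SITE,
        _F_SITE,
        (_ATTP_START, _ATTP_START + 51),
        (_ATTB_START, _ATTB_START + 42),
        *[(v, v + 6) for v in _ECORV_SITES],
        (_ECORI_SITE, _ECORI_SITE + 6),
        (_BAMHI_SITE, _BAMHI_SITE + 6),
    ]
    allowed = {
        ECORV.recognition: set(_ECORV_SITES),
        ECORI.recognition: {_ECORI_SITE},
        BAMHI.recognition: {_BAMHI_SITE},
        PRIMER_E.sequence: {_E_SITE[0]},
        reverse_complement(PRIMER_F.sequence): {_F_SITE[0]},
    }
    _scrub(
        arr,
        allowed,
        protected,
        extra_views=[(_excised_transform, _excised_back_map)],
    )
    return bytes(arr).decode()


@lru_cache(maxsize=None)
def _build_recombinase_sequence() -> str:
    rng = np.random.default_rng(19860114)
    arr = _random_dna(rng, _LEN_RECOMB)
    _plant(arr, _G_SITE[0], PRIMER_G.sequence)
    _plant(arr, _H_SITE[0], reverse_complement(PRIMER_H.sequence))
    protected = [_G_SITE, _H_SITE]
    allowed = {
        PRIMER_G.sequence: {_G_SITE[0]},
        reverse_complement(PRIMER_H.sequence): {_H_SITE[0]},
    }
    _scrub(arr, allowed, protected)
    return bytes(arr).decode()


def _shift(f: Feature, delta: int) -> Feature:
    return Feature(f.name, f.start + delta, f.end + delta, f.strand, f.split)


def make_fixture_construct(state: str) -> AnnotatedSequence:
    """Deterministic fixture construct for one of three states.

    ``unexcised`` — the intact excision target (35S | attP | stuffer | attB |
    gusA | hptII); ``excised`` — the same locus after conservative excision,
    built independently by direct coordinate arithmetic (the retained 47 bp
    attP/attB hybrid replaces the att-flanked stuffer); ``recombinase`` — the
    integrase expression construct (OXS3 promoter | Bxb1 | nptII).
    """
    if state == "unexcised":
        return AnnotatedSequence(
            "pN6_Bxb1", _build_target_sequence(), "linear", list(_TARGET_FEATURES)
        )
    if state == "excised":
        seq = _excised_transform(_build_target_sequence())
        feats = []
        for f in _TARGET_FEATURES:
            if f.name in ("attP", "attB", "stuffer"):
                continue  # removed or replaced by the hybrid
            feats.append(f if f.end <= _CUT_LEFT else _shift(f, -_REMOVED))
        hybrid_len = ATTP.core_end + (42 - ATTB.core_end)  # 47 bp attR
        feats.append(Feature("attR", _ATTP_START, _ATTP_START + hybrid_len))
        return AnnotatedSequence("pN6_Bxb1", seq, "linear", feats)
    if state == "recombinase":
        return AnnotatedSequence(
            "pCOXS3_Bxb1", _build_recombinase_sequence(), "linear", list(_RECOMB_FEATURES)
        )
    raise ValueError(f"unknown construct state {state!r}")


# ---------------------------------------------------------------------------
# Synthetic genomes with planted att-like sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantingSpec:
    """One att-like sequence to plant into a synthetic genome."""

    query: ScanQuery
    position: int
    strand: str = "+"
    mismatches: int = 0
    include_gt_core: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.mismatches <= len(self.query):
            raise ValueError("mismatch count outside [0, query length]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.include_gt_core and self.mismatches < 1:
            raise ValueError("destroying the GT core requires >= 1 mismatch")

    @property
    def end(self) -> int:
        return self.position + len(self.query)


@dataclass(frozen=True)
class TruthSite:
    """Ground-truth record for one planted site (BED-like, 0-based)."""

    name: str
    seq_id: str
    start: int
    end: int
    strand: str
    matches: int
    identity: float
    has_gt_core: bool


def _mutate_query(
    rng: np.random.Generator, spec: PlantingSpec
) -> tuple[str, bool]:
    """Return the planted (mutated) query sequence and its GT-core status."""
    seq = list(spec.query.sequence)
    L = len(seq)
    co = spec.query.core_offset
    core_positions = set(range(co, co + 2)) if co is not None else set()
    pool = [i for i in range(L) if i not in core_positions]
    chosen: list[int] = []
    if not spec.include_gt_core:
        chosen.append(int(rng.choice(sorted(core_positions))))
    k = spec.mismatches - len(chosen)
    if k > len(pool):
        raise ValueError("more mismatches requested than mutable positions")
    chosen += [int(i) for i in rng.choice(pool, size=k, replace=False)]
    for i in chosen:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[int(rng.integers(3))]
    mutated = "".join(seq)
    has_core = (
        co is not None and mutated[co : co + 2] == "GT"
    )
    return mutated, has_core


def generate_genome(
    length: int,
    gc_fraction: float,
    plantings: list[PlantingSpec],
    seed: int,
    seq_id: str = "chr_synth",
) -> tuple[dict[str, str], list[TruthSite]]:
    """Generate an i.i.d. background genome with planted att-like sites.

    Each planting writes its query mutated at exactly the requested number of
    positions (drawn uniformly outside the GT core, or forced into the core
    when ``include_gt_core`` is false).  Returns the genome and a truth table
    recording the planted coordinates, strand, identity, and GT-core status.
    Fully reproducible under ``seed``.
    """
    spans = sorted((p.position, p.end) for p in plantings)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planting placements overlap")
    if spans and (spans[0][0] < 0 or spans[-1][1] > length):
        raise ValueError("planting outside genome bounds")
    rng = np.random.default_rng(seed)
    arr = _random_dna(rng, length, gc_fraction)
    truth = []
    for spec in plantings:
        planted, has_core = _mutate_query(rng, spec)
        if spec.strand == "-":
            _plant(arr, spec.position, reverse_complement(planted))
        else:
            _plant(arr, spec.position, planted)
        L = len(spec.query)
        truth.append(
            TruthSite(
                name=spec.query.name,
                seq_id=seq_id,
                start=spec.position,
                end=spec.end,
                strand=spec.strand,
                matches=L - spec.mismatches,
                identity=(L - spec.mismatches) / L,
                has_gt_core=has_core,
            )
        )
    return {seq_id: bytes(arr).decode()}, truth


def write_truth_bed(truth: list[TruthSite], path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(
                f"{t.seq_id}\t{t.start}\t{t.end}\t{t.name}\t"
                f"{round(t.identity * 1000)}\t{t.strand}\n"
            )


# ---------------------------------------------------------------------------
# Screening-population simulation
# ---------------------------------------------------------------------------

_DESIGN_TO_GENERATION = {
    "retransform_TR1": "TR1",
    "backcross_BC1": "BC1",
    "self_S1": "S1",
    "manual_cross_MC1": "MC1",
}

_ZYGOSITY_FREQ = {"homozygous": 1.0, "hemizygous": 0.5, "absent": 0.0}


@dataclass(frozen=True)
class CrossDesign:
    """A crossing design of the excision screen.

    ``p_germline_excision`` is the probability that an inherited target allele
    is already excised (a germline event in the parent); ``p_somatic_excision``
    the probability that a recombinase-positive, target-carrying plant shows a
    detectable de novo excision band.  Single-locus transgenes by default;
    ``n_recombinase_loci`` models independent integrase insertions.
    """

    design: str
    parent_target_zygosity: str = "hemizygous"
    parent_recombinase_zygosity: str = "hemizygous"
    n_progeny: int = 100
    p_germline_excision: float = 0.0
    p_somatic_excision: float = 0.0
    n_recombinase_loci: int = 1
    seed: int = 0
    family: str = "sim"

    def __post_init__(self) -> None:
        if self.design not in _DESIGN_TO_GENERATION:
            raise ValueError(f"unknown design {self.design!r}")
        for z in (self.parent_target_zygosity, self.parent_recombinase_zygosity):
            if z not in _ZYGOSITY_FREQ:
                raise ValueError(f"unknown zygosity {z!r}")
        for p in (self.p_germline_excision, self.p_somatic_excision):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_progeny <= 0:
            raise ValueError("n_progeny must be positive")
        if (
            self.parent_target_zygosity == "absent"
            and self.p_germline_excision > 0
        ):
            warnings.warn(
                "p_germline_excision has no effect without a target allele",
                stacklevel=2,
            )

    @property
    def generation(self) -> str:
        return _DESIGN_TO_GENERATION[self.design]


def _allele_counts(
    rng: np.random.Generator, design: str, zygosity: str, n: int
) -> np.ndarray:
    """Inherited allele count per progeny for one locus under a design."""
    q = _ZYGOSITY_FREQ[zygosity]
    if design == "retransform_TR1":
        # secondary transformants are the (selfed) offspring of the target
        # parent; a newly introduced locus is handled by the caller
        return rng.binomial(2, q, size=n)
    if design == "self_S1":
        return rng.binomial(2, q, size=n)
    # backcross/manual cross: the other parent contributes no transgene
    return rng.binomial(1, q, size=n)


def simulate_population(design: CrossDesign) -> list[PlantRecord]:
    """Simulate per-plant PCR band calls for one family under a design.

    Mendelian transmission: a hemizygous locus passes to half the gametes, a
    homozygous one to all; independent loci segregate independently.  Each
    inherited target allele is germline-excised with ``p_germline_excision``.
    The unexcised band requires >= 1 inherited unexcised allele; the excision
    band >= 1 excised allele, or a somatic event (recombinase present, target
    present, probability ``p_somatic_excision``); the recombinase band >= 1
    recombinase allele.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_progeny
    target_alleles = _allele_counts(
        rng, design.design, design.parent_target_zygosity, n
    )
    if design.design == "retransform_TR1":
        # every selected transformant carries the new recombinase T-DNA
        recomb_alleles = np.full(n, design.n_recombinase_loci)
    else:
        recomb_alleles = np.zeros(n, dtype=int)
        for _ in range(design.n_recombinase_loci):
            recomb_alleles += _allele_counts(
                rng, design.design, design.parent_recombinase_zygosity, n
            )
    excised = rng.binomial(target_alleles, design.p_germline_excision)
    unexcised = target_alleles - excised
    band_recomb = recomb_alleles >= 1
    somatic = (
        band_recomb
        & (target_alleles >= 1)
        & (rng.random(n) < design.p_somatic_excision)
    )
    band_excision = (excised >= 1) | somatic
    band_unexcised = unexcised >= 1
    return [
        PlantRecord(
            family=design.family,
            generation=design.generation,
            band_excision=bool(band_excision[i]),
            band_unexcised=bool(band_unexcised[i]),
            band_recombinase=bool(band_recomb[i]),
        )
        for i in range(n)
    ]


def estimate_excision_efficiency(
    records: list[PlantRecord], confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Estimate germline excision frequency from recombinase-free progeny.

    Among recombinase-negative, target-positive plants — where no de novo
    (somatic) event can confound the call — the fraction scored excised-only
    estimates the germline excision probability per transmitted allele.
    Returns the point estimate with a Wilson score interval.
    """
    flags = [classify(r) for r in records]
    informative = [
        f for f in flags if f.target_positive and not f.recombinase_positive
    ]
    n = len(informative)
    if n == 0:
        raise ValueError("no recombinase-negative target-positive records")
    k = sum(f.excised_only for f in informative)
    z = norm.ppf(0.5 + confidence / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return phat, (max(0.0, centre - half), min(1.0, centre + half))
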