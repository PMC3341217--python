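"""Readers/writers for the formats the toolkit exchanges.

FASTA goes through Biopython.  Annotations travel as GFF3 (1-based inclusive
on disk, converted from the internal 0-based half-open convention), scanner
hits as BED6 plus a side TSV, site specs as JSON config.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .recombination import AnnotatedSequence, AttSiteSpec, Feature

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a (multi-)FASTA into {seq_id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(seq: AnnotatedSequence, path: PathLike, source: str = "attkit") -> None:
    """Write feature annotations as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seq.seq_id} 1 {len(seq)}\n")
        for f in seq.features:
            attrs = f"Name={f.name}"
            if f.split:
                attrs += ";split=true"
            if f.end < f.start:  # wrapping feature on a circular molecule
                attrs += ";wraps_origin=true"
            fh.write(
                "\t".join(
                    (
                        seq.seq_id,
                        source,
                        "region",
                        str(f.start + 1),
                        str(f.end if f.end >= f.start else len(seq)),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


def read_gff3_features(path: PathLike) -> list[Feature]:
    """Read GFF3 rows back into internal 0-based half-open features."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                Feature(
                    name=attrs.get("Name", cols[2]),
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    split=attrs.get("split") == "true",
                )
            )
    return feats


def load_annotated(fasta: PathLike, gff3: PathLike, topology: str = "linear") -> AnnotatedSequence:
    seqs = read_fasta(fasta)
    if len(seqs) != 1:
        raise ValueError("expected exactly one sequence for an annotated construct")
    (seq_id, sequence), = seqs.items()
    return AnnotatedSequence(seq_id, sequence, topology, read_gff3_features(gff3))


def load_site_specs(path: PathLike) -> dict[str, AttSiteSpec]:
    """Load att-site specs from a JSON config.

    Accepts either a list of objects or a mapping name -> object, each object
    carrying ``name``, ``sequence``, ``core_offset`` and optionally
    ``minimal_length``.
    """
    with open(path) as fh:
        data = json.load(fh)
    entries = data.values() if isinstance(data, dict) else data
    specs = {}
    for entry in entries:
        spec = AttSiteSpec(
            name=entry["name"],
            sequence=entry["sequence"],
            core_offset=int(entry["core_offset"]),
            minimal_length=entry.get("minimal_length"),
        )
        specs[spec.name] = spec
    return specs


def write_bed(hits: Iterable, path: PathLike) -> None:
    """Write scan hits as BED6 with score = round(identity * 1000)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.seq_id,
                        str(h.start),
                        str(h.end),
                        h.query,
                        str(round(h.identity * 1000)),
                        h.strand,
                    )
                )
                + "\n"
            )


def write_hits_tsv(hits: Iterable, path: PathLike) -> None:
    cols = (
        "query\tseq_id\tstart\tend\tstrand\tmatches\tidentity\t"
        "core_mismatches\thas_gt_core\ttruncated\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hits:
            cm = "" if h.core_mismatches is None else str(h.core_mismatches)
            fh.write(
                f"{h.query}\t{h.seq_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.matches}\t{h.identity:.6f}\t{cm}\t"
                f"{int(h.has_gt_core)}\t{int(h.truncated)}\n"
            )


def write_pairs_tsv(pairs: Iterable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstartP\tstartB\torientation\tdistance\toutcome\n")
        for pr in pairs:
            fh.write(
                f"{pr.hitP.seq_id}\t{pr.hitP.start}\t{pr.hitB.start}\t"
                f"{pr.orientation}\t{pr.distance}\t{pr.predicted_outcome}\n"
            )
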