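"""Readers and writers for the standard on-disk formats.

Formats: FASTA for replicon sequences (Biopython), GFF3 CDS features with an
optional ``operon`` attribute (gffutils), and bedGraph per-base count tracks
(one file per sample per strand, 0-based half-open intervals) with a JSON
library-size sidecar, since tracks alone cannot reconstruct RPKM
denominators.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CountTrack, GenomeAnnotation, Orf  # noqa: F401  (Orf re-exported for callers)


class GFF3ParseError(ValueError):
    pass


def _prevalidate_gff3(path: Path) -> None:
    """Cheap structural check so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFF3ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GFF3ParseError(f"{path}:{lineno}: bad coordinate range {start}..{end}")


def read_annotation(gff3_path: str | Path, fasta_path: str | Path) -> GenomeAnnotation:
    """Load CDS features and replicon sequences into a GenomeAnnotation.

    GFF3 1-based inclusive coordinates are converted to the internal
    0-based half-open convention.
    """
    gff3_path, fasta_path = Path(gff3_path), Path(fasta_path)
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    _prevalidate_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    orfs = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        operon = feat.attributes.get("operon", [None])[0]
        orfs.append(
            Orf(
                id=feat.id,
                replicon=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                operon=operon,
            )
        )
    return GenomeAnnotation(sequences=sequences, orfs=orfs)


def write_annotation(
    annotation: GenomeAnnotation, gff3_path: str | Path, fasta_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in annotation.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in annotation.orfs:
            attrs = f"ID={orf.id}"
            if orf.operon is not None:
                attrs += f";operon={orf.operon}"
            fh.write(
                "\t".join(
                    [
                        orf.replicon, "orfstruct", "CDS",
                        str(orf.start + 1), str(orf.end), ".",
                        orf.strand, "0", attrs,
                    ]
                )
                + "\n"
            )


def read_bedgraph_into(
    track: CountTrack, path: str | Path, strand: str
) -> None:
    """Expand bedGraph intervals of one strand into a track in place."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            rep, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            track.add(rep, strand, start, end, value)


def read_track(
    annotation: GenomeAnnotation,
    plus_path: str | Path,
    minus_path: str | Path | None = None,
    sample_id: str = "sample",
) -> CountTrack:
    track = CountTrack.from_annotation(sample_id, annotation)
    read_bedgraph_into(track, plus_path, "+")
    if minus_path is not None:
        read_bedgraph_into(track, minus_path, "-")
    return track


def _write_bedgraph(arr_by_rep: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for rep, arr in arr_by_rep.items():
            # run-length encode identical adjacent values, dropping zero runs
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{rep}\t{s}\t{e}\t{v:g}\n")


def write_track(track: CountTrack, prefix: str | Path) -> dict[str, Path]:
    """Write one bedGraph per strand plus a library-size sidecar.

    Returns the paths written, keyed by ``plus`` / ``minus`` / ``libsize``.
    """
    prefix = Path(prefix)
    paths = {
        "plus": Path(str(prefix) + ".plus.bedgraph"),
        "minus": Path(str(prefix) + ".minus.bedgraph"),
        "libsize": Path(str(prefix) + ".libsize.json"),
    }
    for strand, key in (("+", "plus"), ("-", "minus")):
        _write_bedgraph(
            {rep: track.array(rep, strand) for rep in track.sizes}, paths[key]
        )
    with open(paths["libsize"], "w") as fh:
        json.dump(
            {"sample_id": track.sample_id, "total_assigned": track.total_assigned}, fh
        )
    return paths


def read_track_bundle(annotation: GenomeAnnotation, prefix: str | Path) -> CountTrack:
    prefix = Path(prefix)
    with open(Path(str(prefix) + ".libsize.json")) as fh:
        meta = json.load(fh)
    track = read_track(
        annotation,
        Path(str(prefix) + ".plus.bedgraph"),
        Path(str(prefix) + ".minus.bedgraph"),
        sample_id=meta["sample_id"],
    )
    return track
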