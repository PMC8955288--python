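"""Standard-format I/O: FASTA, GFF3 and the pipeline's TSV tables.

Contigs shorter than the assembly-level minimum length (200 nt by default)
are dropped at load time and the drop is counted and logged, mirroring the
contig filter applied to the source assemblies.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import is_dna
from .models import GffFeature

log = logging.getLogger("crispr_cohort")

MIN_CONTIG_LENGTH = 200


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path, min_length: int | None = None) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence dict.

    Duplicate ids and non-DNA characters (other than N) raise ParseError;
    records shorter than `min_length` are dropped with a logged count.
    """
    records: dict[str, str] = {}
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not is_dna(seq):
            raise ParseError(f"non-DNA characters in record {rec.id!r} in {path}")
        if min_length is not None and len(seq) < min_length:
            dropped += 1
            continue
        records[rec.id] = seq
    if dropped:
        log.info("dropped %d records shorter than %d nt from %s", dropped, min_length, path)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, wrap: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Parse a GFF3 file into internal features (0-based half-open)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001 - surface as a named parse error
        raise ParseError(f"malformed GFF3 {path}: {exc}") from exc
    feats = []
    for f in db.all_features(order_by=("seqid", "start")):
        attrs = {k: ",".join(v) for k, v in f.attributes.items()}
        feats.append(
            GffFeature(
                seqid=f.seqid,
                source=f.source,
                type=f.featuretype,
                start=f.start - 1,  # GFF3 is 1-based inclusive
                end=f.end,
                strand=f.strand or ".",
                attributes=attrs,
            )
        )
    return feats


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "series": str}, **kwargs)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"malformed TSV {path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_bed_regions(path: str | Path):
    """BED-like region TSV: record_id, start, end[, source] (0-based half-open)."""
    from .models import ProphageRegion

    df = pd.read_csv(path, sep="\t")
    required = {"record_id", "start", "end"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        src = getattr(row, "source", "input")
        if row.end <= row.start:
            raise ParseError(f"{path}: empty region {row.record_id}:{row.start}-{row.end}")
        out.append(ProphageRegion(str(row.record_id), int(row.start), int(row.end), str(src)))
    return out
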