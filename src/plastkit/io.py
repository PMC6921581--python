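"""Readers and writers for the standard formats the pipeline touches.

All on-disk coordinates are 1-based inclusive (GFF3/TSV convention); the
in-memory model is 0-based half-open. Every emitted table carries a header
comment naming its coordinate convention.
"""
from __future__ import annotations

import os
import tempfile

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, Plastome

COORD_COMMENT = "# coordinates: 1-based inclusive\n"


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_gff3(plastome: Plastome, path) -> None:
    """Annotation as GFF3 (1-based inclusive); exons become separate lines
    sharing the feature's ID."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.id} 1 {len(plastome.sequence)}\n")
        for f in plastome.features:
            gtype = {"CDS": "CDS", "intron": "intron", "tRNA": "tRNA",
                     "rRNA": "rRNA"}.get(f.ftype, "region")
            for a, b in f.exons:
                fh.write(
                    "\t".join(
                        [plastome.id, "plastkit", gtype, str(a + 1), str(b),
                         ".", f.strand, str(f.phase),
                         f"ID={f.name};Name={f.name}"]
                    ) + "\n"
                )


def read_gff3(path, sequence: str, genome_id: str | None = None) -> Plastome:
    """Load annotation via gffutils and attach it to a sequence."""
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            str(path), dbpath, force=True, keep_order=True,
            merge_strategy="create_unique", from_string=False,
        )
        by_id: dict[str, dict] = {}
        gid = genome_id
        for feat in db.all_features():
            gid = gid or feat.seqid
            fid = feat.attributes.get("ID", [feat.id])[0]
            rec = by_id.setdefault(
                fid, {"type": feat.featuretype, "strand": feat.strand, "exons": []}
            )
            rec["exons"].append((feat.start - 1, feat.end))
        features = [
            GeneFeature(fid, rec["type"], rec["strand"],
                        tuple(sorted(rec["exons"])))
            for fid, rec in by_id.items()
        ]
    finally:
        os.unlink(dbpath)
    return Plastome(gid or "genome", sequence, features)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bedgraph(depth, chrom: str, path) -> None:
    """Per-base depth as bedGraph (0-based half-open, the format's own
    convention)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}"\n')
        start = 0
        prev = None
        for i, d in enumerate(depth):
            if prev is None:
                prev, start = d, i
            elif d != prev:
                fh.write(f"{chrom}\t{start}\t{i}\t{prev}\n")
                prev, start = d, i
        if prev is not None:
            fh.write(f"{chrom}\t{start}\t{len(depth)}\t{prev}\n")


def write_antisense_bed(calls, chrom: str, path) -> None:
    """Antisense calls as BED6 (0-based half-open per the BED spec)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                f"{chrom}\t{c.start}\t{c.end}\tantisense_{i + 1}\t"
                f"{int(round(c.mean_depth))}\t{c.strand}\n"
            )


def write_insert_table(inserts, path) -> None:
    """MTPT insert intervals (1-based inclusive) with divergence."""
    rows = [
        {
            "plastid_start": ins.plastid_start + 1,
            "plastid_end": ins.plastid_end,
            "mito_start": ins.mito_start + 1,
            "mito_end": ins.mito_end,
            "size_nt": ins.size,
            "divergence": ins.divergence,
        }
        for ins in inserts
    ]
    write_table(pd.DataFrame(rows), path)


def read_insert_table(path) -> list[tuple[int, int]]:
    """Plastid-coordinate intervals (0-based half-open) from an insert table."""
    df = read_table(path)
    if not {"plastid_start", "plastid_end"} <= set(df.columns):
        raise ValueError("malformed insert table: need plastid_start/plastid_end")
    return [(int(r.plastid_start) - 1, int(r.plastid_end)) for r in df.itertuples()]
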