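"""Gene/transcript models and GFF3 I/O.

Internally all coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted at the read/write boundary.  A transcript span runs from the
minimum to the maximum of its exon coordinates (introns included), matching
a gene-body occupancy readout.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty transcript span for {self.transcript_id}")


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class Annotation:
    genes: list[Gene]

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def transcripts(self) -> list[Transcript]:
        return [t for g in self.genes for t in g.transcripts]


def write_gff3(annotation: Annotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tdamidkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{t.chrom}\tdamidkit\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                fh.write(
                    f"{t.chrom}\tdamidkit\texon\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id}.e1;"
                    f"Parent={t.transcript_id}\n"
                )


def read_gff3(path) -> Annotation:
    """Read gene/mRNA/exon features into an :class:`Annotation` via gffutils."""
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(Path(path)),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        genes: list[Gene] = []
        for gf in db.features_of_type("gene", order_by=("seqid", "start")):
            gene = Gene(gf.id, gf.seqid, gf.start - 1, gf.end, gf.strand or "+")
            for tf in db.children(gf, featuretype="mRNA", order_by="start"):
                exons = list(db.children(tf, featuretype="exon"))
                if exons:
                    start = min(e.start for e in exons) - 1
                    end = max(e.end for e in exons)
                else:
                    start, end = tf.start - 1, tf.end
                gene.transcripts.append(
                    Transcript(tf.id, gene.gene_id, tf.seqid, start, end,
                               tf.strand or "+")
                )
            genes.append(gene)
    return Annotation(genes)
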