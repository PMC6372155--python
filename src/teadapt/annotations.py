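"""Gene-model containers and GFF3/BED input.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read.  Feature parsing is delegated to :mod:`gffutils`; the
parent/child assembly into gene models is done here because the pipeline only
needs spans, exons, CDS and UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils.iterators
import pandas as pd

from .te_frequency import TEInsertion

Interval = tuple[int, int]


@dataclass
class Transcript:
    tx_id: str
    strand: str = "+"
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utrs: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons] or [0]
        ends = [e for _, e in self.exons] or [0]
        return min(starts), max(ends)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in transcription order."""
        exons = sorted(self.exons)
        gaps = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        gaps = [(s, e) for s, e in gaps if e > s]
        if self.strand == "-":
            gaps = gaps[::-1]
        return gaps


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    transcripts: list[Transcript] = field(default_factory=list)

    def longest_transcript(self) -> Transcript | None:
        if not self.transcripts:
            return None
        return max(self.transcripts, key=lambda t: (t.length, t.tx_id))


_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}
_TX_TYPES = {"mRNA", "transcript", "ncRNA", "tRNA", "rRNA", "snoRNA", "snRNA", "pre_miRNA"}


def read_gff3(path) -> list[GeneModel]:
    """Load gene models from a GFF3 file."""
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    tx_parent: dict[str, str] = {}
    deferred: list = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        ftype = feat.featuretype
        if ftype in ("gene", "pseudogene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            genes[gid] = GeneModel(
                gene_id=gid, chrom=feat.seqid, start=feat.start - 1, end=feat.end, strand=feat.strand
            )
        elif ftype in _TX_TYPES:
            tid = feat.attributes.get("ID", [feat.id])[0]
            parent = feat.attributes.get("Parent", [""])[0]
            transcripts[tid] = Transcript(tx_id=tid, strand=feat.strand)
            tx_parent[tid] = parent
        else:
            deferred.append(feat)
    for feat in deferred:
        parents = feat.attributes.get("Parent", [])
        iv = (feat.start - 1, feat.end)
        for parent in parents:
            tx = transcripts.get(parent)
            if tx is None:
                continue
            if feat.featuretype == "exon":
                tx.exons.append(iv)
            elif feat.featuretype == "CDS":
                tx.cds.append(iv)
            elif feat.featuretype in _UTR_TYPES:
                tx.utrs.append(iv)
    for tid, tx in transcripts.items():
        gene = genes.get(tx_parent.get(tid, ""))
        if gene is not None:
            gene.transcripts.append(tx)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def read_te_bed(path) -> list[TEInsertion]:
    """Load TE records from a BED6(+2) file.

    Columns: chrom, start, end, te_id, score, strand, then optionally
    ``family`` and ``order`` and ``canonical_length``.
    """
    tes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, te_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            family = parts[6] if len(parts) > 6 else "unknown"
            order = parts[7] if len(parts) > 7 else "unknown"
            canonical = int(parts[8]) if len(parts) > 8 else 0
            tes.append(
                TEInsertion(
                    te_id=te_id, family=family, order=order, chrom=chrom,
                    start=start, end=end, canonical_length=canonical,
                )
            )
    return tes


def write_te_bed(tes, path) -> None:
    rows = []
    for te in tes:
        rows.append(
            [te.chrom, te.start, te.end, te.te_id, 0, "+", te.family, te.order, te.canonical_length]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def gene_distance(te: TEInsertion, gene: GeneModel) -> int:
    """bp gap between a TE and a gene span on the same chromosome (0 = overlap)."""
    if te.chrom != gene.chrom:
        raise ValueError("different chromosomes")
    if te.start < gene.end and te.end > gene.start:
        return 0
    if te.end <= gene.start:
        return gene.start - te.end
    return te.start - gene.end
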