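"""SNP functional annotation against GFF3 gene models.

Each biallelic SNP receives exactly one category under a most-severe-wins
precedence across all overlapping transcripts:

``exonic`` (coding: synonymous / nonsynonymous / stop-gain / stop-loss)
> ``splicing`` (within 2 bp of an exon–intron junction, on the intron side)
> ``intronic``
> ``upstream`` / ``downstream`` (within 1 kb of the transcript start/end,
respecting strand)
> ``intergenic``.

Coding effects are determined by substituting REF and ALT into the spliced
CDS, reverse-complemented on the minus strand, and translating the affected
codon with the standard genetic code (via Biopython).  A gene whose CDS
length is not a multiple of three cannot be translated; its SNPs fall back
to ``exonic_unresolved`` and the defect is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio.Seq import Seq

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

SPLICE_WINDOW = 2  # bp into the intron counted as splicing
FLANK = 1_000  # bp of up/downstream flank

EXONIC_SYNONYMOUS = "exonic_synonymous"
EXONIC_NONSYNONYMOUS = "exonic_nonsynonymous"
EXONIC_STOPGAIN = "exonic_stopgain"
EXONIC_STOPLOSS = "exonic_stoploss"
EXONIC_UNRESOLVED = "exonic_unresolved"
SPLICING = "splicing"
INTRONIC = "intronic"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
INTERGENIC = "intergenic"

#: most severe first — used to resolve SNPs hitting several transcripts
SEVERITY = [
    EXONIC_STOPGAIN,
    EXONIC_STOPLOSS,
    EXONIC_NONSYNONYMOUS,
    EXONIC_SYNONYMOUS,
    EXONIC_UNRESOLVED,
    SPLICING,
    INTRONIC,
    UPSTREAM,
    DOWNSTREAM,
    INTERGENIC,
]
_RANK = {c: i for i, c in enumerate(SEVERITY)}

CATEGORIES = list(SEVERITY)


@dataclass
class GeneModel:
    """One transcript: sorted exons with a CDS, on a strand.

    Intervals are 1-based inclusive, as in GFF3.  The CDS intervals must be
    contained in exons; for the synthetic gene models the CDS spans every
    exon entirely.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intervals between consecutive exons."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 > e1 + 1
        ]


def genes_by_contig(genes: list[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.contig, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: (g.tx_start, g.tx_end, g.gene_id))
    return out


# ---------------------------------------------------------------------------
# coding-effect classification


def _spliced_cds(gene: GeneModel, seq: str) -> str:
    """CDS sequence 5'→3' on the coding strand."""
    parts = [seq[s - 1 : e] for s, e in gene.cds]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds.upper()


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of genomic *pos* within the spliced CDS, or None."""
    off = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            plus = off + (pos - s)
            if gene.strand == "+":
                return plus
            return gene.cds_length - 1 - plus
        off += e - s + 1
    return None


def _coding_effect(gene: GeneModel, pos: int, ref: str, alt: str, seq: str) -> str:
    if gene.cds_length % 3 != 0:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3; SNP at %s:%d unresolved",
            gene.gene_id,
            gene.cds_length,
            gene.contig,
            pos,
        )
        return EXONIC_UNRESOLVED
    off = _cds_offset(gene, pos)
    assert off is not None
    cds = _spliced_cds(gene, seq)
    ref_b, alt_b = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref_b = str(Seq(ref_b).complement())
        alt_b = str(Seq(alt_b).complement())
    codon_start = 3 * (off // 3)
    within = off % 3
    codon = list(cds[codon_start : codon_start + 3])
    ref_codon = codon.copy()
    ref_codon[within] = ref_b  # trust the VCF REF over the FASTA base
    alt_codon = codon.copy()
    alt_codon[within] = alt_b
    aa_ref = str(Seq("".join(ref_codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    if aa_ref == aa_alt:
        return EXONIC_SYNONYMOUS
    if aa_alt == "*":
        return EXONIC_STOPGAIN
    if aa_ref == "*":
        return EXONIC_STOPLOSS
    return EXONIC_NONSYNONYMOUS


def classify_variant(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    genes: dict[str, list[GeneModel]],
    sequences: dict[str, str] | None = None,
) -> tuple[str, str]:
    """Classify one SNP; returns ``(category, gene_id)`` (gene_id '' if none).

    *genes* is the output of :func:`genes_by_contig`; *sequences* maps
    contig name to its reference sequence and is required for coding-effect
    calls (without it, CDS SNPs come back ``exonic_unresolved``).
    """
    best: tuple[int, str, str] | None = None

    def consider(category: str, gene_id: str) -> None:
        nonlocal best
        cand = (_RANK[category], category, gene_id)
        if best is None or cand < best:
            best = cand

    seq = sequences.get(contig) if sequences else None
    for gene in genes.get(contig, []):
        if gene.tx_start - FLANK <= pos <= gene.tx_end + FLANK:
            cat = _classify_against_gene(gene, pos, ref, alt, seq)
            if cat is not None:
                consider(cat, gene.gene_id)
    if best is None:
        return INTERGENIC, ""
    return best[1], best[2]


def _classify_against_gene(
    gene: GeneModel, pos: int, ref: str, alt: str, seq: str | None
) -> str | None:
    for s, e in gene.cds:
        if s <= pos <= e:
            if seq is None:
                return EXONIC_UNRESOLVED
            return _coding_effect(gene, pos, ref, alt, seq)
    for s, e in gene.exons:
        if s <= pos <= e:
            return EXONIC_UNRESOLVED
    for s, e in gene.introns():
        if s <= pos <= e:
            if pos - s < SPLICE_WINDOW or e - pos < SPLICE_WINDOW:
                return SPLICING
            return INTRONIC
    if gene.tx_start - FLANK <= pos < gene.tx_start:
        return UPSTREAM if gene.strand == "+" else DOWNSTREAM
    if gene.tx_end < pos <= gene.tx_end + FLANK:
        return DOWNSTREAM if gene.strand == "+" else UPSTREAM
    return None


def annotate_matrix(
    matrix: GenotypeMatrix,
    genes: list[GeneModel],
    sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate every variant; returns a table with category and gene_id."""
    index = genes_by_contig(genes)
    rows = []
    v = matrix.variants
    for contig, pos, ref, alt in zip(v["contig"], v["pos"], v["ref"], v["alt"]):
        cat, gid = classify_variant(contig, int(pos), ref, alt, index, sequences)
        rows.append((contig, int(pos), ref, alt, cat, gid))
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "category", "gene_id"]
    )


# ---------------------------------------------------------------------------
# GFF3 I/O


def write_gff3(genes: list[GeneModel], path) -> None:
    """Emit gene/mRNA/exon/CDS features with computed phase."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.contig, g.tx_start, g.gene_id)):
        base = f"{g.contig}\tpopsweep\t"
        tail = f"\t.\t{g.strand}\t"
        lines.append(
            base + f"gene\t{g.tx_start}\t{g.tx_end}" + tail + f".\tID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            base
            + f"mRNA\t{g.tx_start}\t{g.tx_end}"
            + tail
            + f".\tID={mrna};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                base + f"exon\t{s}\t{e}" + tail + f".\tID={mrna}.exon{i};Parent={mrna}"
            )
        cds_iter = g.cds if g.strand == "+" else list(reversed(g.cds))
        consumed = 0
        phased = []
        for s, e in cds_iter:
            phase = (3 - consumed % 3) % 3
            phased.append((s, e, phase))
            consumed += e - s + 1
        for i, (s, e, phase) in enumerate(sorted(phased), 1):
            lines.append(
                base
                + f"CDS\t{s}\t{e}"
                + tail
                + f"{phase}\tID={mrna}.cds{i};Parent={mrna}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Load transcript structures from GFF3 via gffutils (in-memory db)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons += [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds += [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:  # gene without mRNA children: take direct features
            exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
            )
        )
    return genes


def category_counts(annotations: pd.DataFrame) -> pd.Series:
    """Category histogram over the annotation table (all categories listed)."""
    return annotations["category"].value_counts().reindex(CATEGORIES, fill_value=0)
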