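"""Genomic coordinate conventions, annotation parsing and strand-aware offsets.

All coordinates are 0-based half-open (BED convention). GFF3 input, which is
1-based closed, is shifted on read. A gene's 5' anchor is its ``start`` on the
plus strand and ``end - 1`` on the minus strand; offset 0 at the 5' anchor is
the first transcribed base, upstream positions are strictly negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FeatureClass = Literal["gene", "transposon", "pseudogene"]
Anchor = Literal["five_prime", "three_prime"]

#: default mapping from annotation feature types to the three model classes
DEFAULT_FEATURE_CLASS_MAP: Mapping[str, str] = {
    "gene": "gene",
    "mRNA": "gene",
    "protein_coding_gene": "gene",
    "transposable_element": "transposon",
    "transposable_element_gene": "transposon",
    "transposon": "transposon",
    "pseudogene": "pseudogene",
}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class GeneModel:
    """A strand-aware genomic feature with an exon union.

    ``start``/``end`` are 0-based half-open chromosome coordinates; ``exons``
    are non-overlapping, sorted intervals contained in ``[start, end)``.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str = "gene"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.validate()

    def validate(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(f"{self.id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.id}: empty exon ({s},{e})")
            if s < self.start or e > self.end:
                raise AnnotationError(f"{self.id}: exon ({s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.id}: exons overlap or unsorted at ({s},{e})")
            prev_end = e
        if self.feature_class not in ("gene", "transposon", "pseudogene"):
            raise AnnotationError(f"{self.id}: unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_model_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeSequence:
    """Per-chromosome nucleotide strings over {A,C,G,T,N}."""

    def __init__(self, chroms: Mapping[str, str]):
        self.chroms = {name: str(seq).upper() for name, seq in chroms.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.chroms.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def reverse_complement(self) -> "GenomeSequence":
        """Mirror image of the genome (used by strand-symmetry checks)."""
        return GenomeSequence(
            {name: str(Seq(seq).reverse_complement()) for name, seq in self.chroms.items()}
        )


def mirror_model(model: GeneModel, chrom_length: int) -> GeneModel:
    """The same feature in the reverse-complemented coordinate system."""
    exons = sorted((chrom_length - e, chrom_length - s) for s, e in model.exons)
    return GeneModel(
        id=model.id,
        chrom=model.chrom,
        start=chrom_length - model.end,
        end=chrom_length - model.start,
        strand="-" if model.strand == "+" else "+",
        feature_class=model.feature_class,
        exons=exons,
    )


def genic_position(model: GeneModel, genomic_pos: int, anchor: Anchor = "five_prime") -> int:
    """Signed offset of a genomic position relative to a gene anchor.

    Both anchors use the inward convention of ends-aligned metaplots: offset 0
    is the first (5') or last (3') transcribed base, positive offsets point
    into the gene, negative offsets point away from it. For a minus-strand
    gene the 5' anchor is ``end - 1`` and offsets increase toward lower
    genomic coordinates.
    """
    if model.strand == "+":
        t = genomic_pos - model.start
    else:
        t = (model.end - 1) - genomic_pos
    if anchor == "five_prime":
        return t
    if anchor == "three_prime":
        return (model.length - 1) - t
    raise ValueError(f"unknown anchor {anchor!r}")


def _classify(feature_type: str, attrs: Mapping[str, str], class_map: Mapping[str, str]) -> str:
    # attribute-level typing (e.g. a gene record tagged pseudogene) wins
    for key in ("feature_class", "gene_biotype", "biotype", "locus_type"):
        v = attrs.get(key)
        if v and v in class_map:
            return class_map[v]
    return class_map.get(feature_type, "gene")


def load_annotation(
    path: str | Path,
    feature_class_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read gene/TE/pseudogene models from a GFF3 or BED file.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open;
    BED input is taken as-is. ``feature_class_map`` maps annotation feature
    types (and ``feature_class``/biotype attribute values) to
    gene/transposon/pseudogene.
    """
    path = Path(path)
    class_map = dict(feature_class_map or DEFAULT_FEATURE_CLASS_MAP)
    text = path.read_text()
    if path.suffix.lower() in (".gff", ".gff3") or text.lstrip().startswith("##gff"):
        return _load_gff3(text, class_map)
    return _load_bed(text, class_map, str(path))


def _load_gff3(text: str, class_map: Mapping[str, str]) -> list[GeneModel]:
    db = gffutils.create_db(
        io.StringIO(text).getvalue(),
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    top_level = {ft for ft in db.featuretypes() if ft in class_map or ft == "gene"}
    for ft in sorted(top_level):
        for feat in db.features_of_type(ft):
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            fid = attrs.get("ID") or attrs.get("Name") or f"{feat.seqid}:{feat.start}"
            exons = sorted(
                (ex.start - 1, ex.end)
                for ex in db.children(feat, featuretype="exon")
            )
            try:
                models.append(
                    GeneModel(
                        id=fid,
                        chrom=feat.seqid,
                        start=feat.start - 1,  # GFF3 is 1-based closed
                        end=feat.end,
                        strand=feat.strand if feat.strand in "+-" else "+",
                        feature_class=_classify(ft, attrs, class_map),
                        exons=exons,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{fid}: {exc}") from exc
    return models


def _load_bed(text: str, class_map: Mapping[str, str], source: str) -> list[GeneModel]:
    models = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise AnnotationError(f"{source}:{lineno}: fewer than 3 BED columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise AnnotationError(f"{source}:{lineno}: non-integer coordinate") from exc
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
        fclass = class_map.get(parts[6], parts[6]) if len(parts) > 6 else "gene"
        if fclass not in ("gene", "transposon", "pseudogene"):
            fclass = "gene"
        try:
            models.append(
                GeneModel(id=name, chrom=chrom, start=start, end=end, strand=strand,
                          feature_class=fclass)
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{source}:{lineno}: {exc}") from exc
    return models


def write_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as 7-column BED (name in col 4, class in col 7)."""
    rows = [
        (m.chrom, m.start, m.end, m.id, 0, m.strand, m.feature_class) for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def validate_against_genome(models: Iterable[GeneModel], genome: GenomeSequence) -> None:
    for m in models:
        if m.chrom not in genome:
            raise AnnotationError(f"{m.id}: chromosome {m.chrom} not in genome")
        if m.end > genome.length(m.chrom):
            raise AnnotationError(f"{m.id}: interval exceeds chromosome length")
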