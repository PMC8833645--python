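"""Gene annotation and reference sequence access.

Parses GENCODE-style GTF into per-gene exon models (exons merged across
transcripts), builds an exact-position exon-boundary index, and extracts
reference sequence windows from an indexed FASTA.

Coordinates are 1-based inclusive throughout, matching both GTF and SAM.
Strand only affects exon ordinal numbering (ordinal 1 = first exon in
transcription order) and downstream reading-frame arithmetic; intervals and
sequences always live on the genomic forward strand.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

import gffutils
import pyfaidx

from .config import logger

BoundarySide = Literal["exon_start", "exon_end"]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """One gene's strand-aware, transcript-merged exon structure."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # sorted ascending by start, 1-based inclusive
    exon_ordinals: tuple[int, ...]  # transcription-order index per exon (1..n)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if sorted(self.exon_ordinals) != list(range(1, len(self.exons) + 1)):
            raise ValueError(f"exon_ordinals of {self.gene_id} are not a permutation of 1..n")
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"exon {start}-{end} of {self.gene_id} has end < start")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_by_ordinal(self, ordinal: int) -> tuple[int, int]:
        return self.exons[self.exon_ordinals.index(ordinal)]

    def ordinal_of_exon(self, exon_index: int) -> int:
        return self.exon_ordinals[exon_index]


class ExonBoundaryIndex:
    """Exact-position lookup of exon starts and ends.

    Maps ``(chrom, position, side)`` to the set of ``(GeneModel, ordinal)``
    pairs owning that boundary. Every exon contributes exactly two entries;
    positions not on an annotated boundary resolve to the empty set.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._entries: dict[tuple[str, int, BoundarySide], set[tuple[str, int]]] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            for i, (start, end) in enumerate(gene.exons):
                ordinal = gene.exon_ordinals[i]
                self._entries.setdefault((gene.chrom, start, "exon_start"), set()).add(
                    (gene.gene_id, ordinal)
                )
                self._entries.setdefault((gene.chrom, end, "exon_end"), set()).add(
                    (gene.gene_id, ordinal)
                )

    def lookup(self, chrom: str, pos: int, side: BoundarySide) -> frozenset[tuple[str, int]]:
        """Genes/ordinals whose exon boundary of the given side sits exactly at pos."""
        return frozenset(self._entries.get((chrom, pos, side), ()))

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def boundaries_of_gene(self, gene_id: str, side: BoundarySide) -> list[tuple[int, int]]:
        """All (position, ordinal) boundaries of one side for a gene, sorted by position."""
        gene = self.genes[gene_id]
        idx = 0 if side == "exon_start" else 1
        return sorted(
            (exon[idx], gene.exon_ordinals[i]) for i, exon in enumerate(gene.exons)
        )


def parse_gtf(gtf_path: str | Path, feature_filter: frozenset[str] = frozenset({"exon"})) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into one :class:`GeneModel` per gene.

    Exons of all transcripts are merged into the union of distinct intervals,
    so every annotated splice boundary of the gene is kept. Ordinals follow
    transcription order: genomic order on '+', reversed on '-'.

    Records with end < start are skipped with a warning; an unreadable file
    raises ``OSError``.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(f"GTF not found: {gtf_path}")
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feature in db.all_features():
        if feature.featuretype not in feature_filter:
            continue
        if feature.end < feature.start:
            logger.warning(
                "skipping malformed exon %s:%d-%d (end < start)",
                feature.seqid, feature.start, feature.end,
            )
            continue
        gene_id = feature.attributes["gene_id"][0]
        gene_name = feature.attributes.get("gene_name", [gene_id])[0]
        info = per_gene.setdefault(
            gene_id,
            {"name": gene_name, "chrom": feature.seqid, "strand": feature.strand, "exons": set()},
        )
        info["exons"].add((feature.start, feature.end))
    models = []
    for gene_id, info in per_gene.items():
        exons = tuple(sorted(info["exons"]))
        n = len(exons)
        ordinals = tuple(range(1, n + 1)) if info["strand"] == "+" else tuple(range(n, 0, -1))
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=info["name"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons,
                exon_ordinals=ordinals,
            )
        )
    return models


def build_boundary_index(genes: Iterable[GeneModel]) -> ExonBoundaryIndex:
    """Build the exact-position exon-boundary index over a set of gene models."""
    return ExonBoundaryIndex(genes)


class ReferenceSequence:
    """Thin wrapper over an indexed FASTA exposing 1-based inclusive fetches."""

    def __init__(self, fasta_path: str | Path):
        self._fasta = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r} in reference")
        if start < 1 or start > end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        if end > len(self._fasta[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} exceeds chromosome length "
                f"{len(self._fasta[chrom])}"
            )
        seq = str(self._fasta[chrom][start - 1 : end])
        assert len(seq) == end - start + 1
        return seq

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])


class InMemoryReference:
    """Reference backed by a plain ``{chrom: sequence}`` dict (same fetch API)."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {chrom: seq.upper() for chrom, seq in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r} in reference")
        if start < 1 or start > end or end > len(self._seqs[chrom]):
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        return self._seqs[chrom][start - 1 : end]

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])


def fetch_region_sequence(reference: str | Path | ReferenceSequence, chrom: str, start: int, end: int) -> str:
    """Uppercase reference bases of ``chrom:start-end`` (1-based inclusive)."""
    if not isinstance(reference, ReferenceSequence):
        reference = ReferenceSequence(reference)
    return reference.fetch(chrom, start, end)
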