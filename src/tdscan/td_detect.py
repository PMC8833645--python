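"""Two-stage detection of intragenic tandem duplications from RNA-seq alignments.

An intragenic tandem duplication (TD) repeats a block of exons head-to-tail,
so the mature transcript contains a non-canonical junction: the 3' end of the
duplicated block spliced back onto its own 5' end. Against the linear
reference a read crossing that junction aligns to one side with the remainder
soft-clipped — the same signature a back-spliced circular RNA leaves. The two
are told apart by the mate: a circRNA confines both reads of a pair to the
circularised region, whereas a genomic TD produces mates extending (partly or
completely) outside it.

Stage 1 proposes candidate regions from soft-clipped reads whose clip-adjacent
mapped coordinate sits exactly on an exon boundary and whose clipped bases
continue exactly from another exon boundary of the same gene. Stage 2 confirms
each candidate: a virtual junction sequence (last-K + first-K bases of the
region, K = min(100, region length)) is built from the reference, region reads
are re-examined against it, and verified junction reads are kept as TD
evidence only when the mate maps outside the region. Four read-pair scenarios
qualify: a forward junction read (SAM flag 99/163) at either region end with
its reverse mate past the region 3' end, or a reverse junction read (83/147)
with its forward mate before the region 5' start.

The per-sample TD-score is the number of distinct regions with TD read-pair
evidence; a score >= 2 classifies the sample as BRCA1-type HRD downstream.
"""

from __future__ import annotations

import bisect
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .annotation_io import (
    ExonBoundaryIndex,
    GeneModel,
    InMemoryReference,
    ReferenceSequence,
    build_boundary_index,
)
from .config import RunConfig, logger

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")

FORWARD_FLAGS = frozenset({99, 163})
REVERSE_FLAGS = frozenset({83, 147})


# ---------------------------------------------------------------------------
# Alignment views
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AlignedReadView:
    """Minimal view of one aligned SAM record (1-based coordinates)."""

    qname: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]  # (op, length)
    seq: str
    mate_pos: int
    isize: int

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost reference position consumed."""
        return self.pos + sum(n for op, n in self.cigar if op in _REF_CONSUMING) - 1

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & 0x1)

    def overlaps(self, start: int, end: int) -> bool:
        return self.pos <= end and self.ref_end >= start

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedReadView":
        cigar = tuple(
            ("MIDNSHP=X"[op], ln) for op, ln in (rec.cigartuples or ())
        )
        return cls(
            qname=rec.query_name,
            flag=rec.flag,
            chrom=rec.reference_name,
            pos=rec.reference_start + 1,
            mapq=rec.mapping_quality,
            cigar=cigar,
            seq=rec.query_sequence or "",
            mate_pos=(rec.next_reference_start + 1) if rec.next_reference_start >= 0 else 0,
            isize=rec.template_length,
        )


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    """SAM CIGAR string to ((op, length), ...); '*' yields an empty tuple."""
    if cigar == "*":
        return ()
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar))
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


class AlignmentStore:
    """All primary alignments of one sample, per-chromosome, position-sorted.

    Holding the sample in memory keeps region queries simple and makes the
    pipeline independent of whether the input was SAM or indexed BAM. Reads
    flagged secondary, supplementary, duplicate or unmapped are dropped at
    load time; a position regression within a chromosome (unsorted input)
    is a fatal error.
    """

    def __init__(self, reads: Iterable[AlignedReadView], known_chroms: set[str] | None = None):
        self._by_chrom: dict[str, list[AlignedReadView]] = {}
        self._starts: dict[str, list[int]] = {}
        last_pos: dict[str, int] = {}
        for read in reads:
            if known_chroms is not None and read.chrom not in known_chroms:
                logger.warning("read %s on unknown chromosome %s skipped", read.qname, read.chrom)
                continue
            if read.pos < last_pos.get(read.chrom, 0):
                raise ValueError(
                    f"alignments not coordinate-sorted: {read.chrom}:{read.pos} after "
                    f"{read.chrom}:{last_pos[read.chrom]}"
                )
            last_pos[read.chrom] = read.pos
            self._by_chrom.setdefault(read.chrom, []).append(read)
        for chrom, rs in self._by_chrom.items():
            self._starts[chrom] = [r.pos for r in rs]

    @classmethod
    def from_path(cls, path: str | Path, known_chroms: set[str] | None = None) -> "AlignmentStore":
        def gen():
            with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
                for rec in fh:
                    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                        continue
                    yield AlignedReadView.from_pysam(rec)

        return cls(gen(), known_chroms=known_chroms)

    def __iter__(self):
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def overlapping(self, chrom: str, start: int, end: int, max_read_span: int = 1000) -> list[AlignedReadView]:
        """Reads whose alignment overlaps [start, end], in position order."""
        reads = self._by_chrom.get(chrom, [])
        starts = self._starts.get(chrom, [])
        lo = bisect.bisect_left(starts, start - max_read_span)
        hi = bisect.bisect_right(starts, end)
        return [r for r in reads[lo:hi] if r.overlaps(start, end)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class JunctionRegion:
    """Candidate duplicated interval anchored on exon boundaries of one gene."""

    chrom: str
    start: int  # 1-based; an annotated exon_start (region 5' boundary)
    end: int    # 1-based; an annotated exon_end (region 3' boundary)
    gene_id: str
    first_exon_ordinal: int
    last_exon_ordinal: int
    n_junction_reads: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region start must precede end: {self.start}-{self.end}")
        if self.first_exon_ordinal > self.last_exon_ordinal:
            raise ValueError("first_exon_ordinal must be <= last_exon_ordinal")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.gene_id)


@dataclasses.dataclass(frozen=True)
class VirtualJunction:
    """Sequence a junction read traverses: region suffix-K joined to prefix-K."""

    region: JunctionRegion
    sequence: str

    @property
    def k(self) -> int:
        return len(self.sequence) // 2


@dataclasses.dataclass(frozen=True)
class TDReadPair:
    """A verified junction read whose mate maps outside the candidate region."""

    qname: str
    scenario: str  # e.g. 'FWD_MATE_PAST_3PRIME/anchor=3p'
    junction_read_pos: int
    mate_pos: int


@dataclasses.dataclass
class TDRegionCall:
    """A confirmed TD region with its supporting evidence."""

    region: JunctionRegion
    n_td_read_pairs: int
    size_bp: int
    frame_effect: str  # 'in_frame' | 'out_of_frame' | 'NA'
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = (self.region.gene_id,)


@dataclasses.dataclass
class SampleTDProfile:
    """Per-sample TD calls and the TD-score (count of distinct called regions)."""

    sample_id: str
    calls: list[TDRegionCall]

    @property
    def td_score(self) -> int:
        return len({(c.region.chrom, c.region.start, c.region.end) for c in self.calls})


# ---------------------------------------------------------------------------
# Stage 1: candidate discovery
# ---------------------------------------------------------------------------

def _passes_read_filters(read: AlignedReadView, config: RunConfig) -> bool:
    # secondary/supplementary/duplicate already removed at load
    return read.mapq == config.unique_mapq


def scan_candidate_regions(
    alignments: AlignmentStore,
    index: ExonBoundaryIndex,
    config: RunConfig,
    reference: ReferenceSequence | InMemoryReference,
) -> list[JunctionRegion]:
    """Propose candidate TD regions from soft-clipped reads.

    A read proposes the region (s, e) when one of its soft clips is at least
    ``min_clip`` bases, the clip-adjacent mapped coordinate falls exactly on
    an exon boundary (an exon_end e for a right clip, an exon_start s for a
    left clip), and the clipped bases exactly match the reference continuing
    from the complementary boundary of the same gene (from s forwards, or
    into e backwards). Candidates are deduplicated by (chrom, start, end,
    gene); no coordinate fuzz is allowed.
    """
    candidates: dict[tuple[str, int, int, str], JunctionRegion] = {}
    for read in alignments:
        if not _passes_read_filters(read, config):
            continue
        if read.right_clip >= config.min_clip:
            e = read.ref_end
            for gene_id, ord_e in index.lookup(read.chrom, e, "exon_end"):
                clip = read.seq[read.read_length - read.right_clip :]
                for s, ord_s in index.boundaries_of_gene(gene_id, "exon_start"):
                    if s >= e:
                        break
                    _propose(candidates, read.chrom, s, e, gene_id, ord_s, ord_e, clip,
                             reference, config, clip_side="right")
        if read.left_clip >= config.min_clip:
            s = read.pos
            for gene_id, ord_s in index.lookup(read.chrom, s, "exon_start"):
                clip = read.seq[: read.left_clip]
                for e, ord_e in index.boundaries_of_gene(gene_id, "exon_end"):
                    if e > s:
                        _propose(candidates, read.chrom, s, e, gene_id, ord_s, ord_e, clip,
                                 reference, config, clip_side="left")
    return sorted(candidates.values(), key=lambda r: (r.chrom, r.start, r.end, r.gene_id))


def _propose(
    candidates: dict,
    chrom: str,
    s: int,
    e: int,
    gene_id: str,
    ord_s: int,
    ord_e: int,
    clip: str,
    reference,
    config: RunConfig,
    clip_side: str,
) -> None:
    region_len = e - s + 1
    n = min(len(clip), region_len)
    if n < config.min_clip:
        return
    if clip_side == "right":
        # clip continues across the junction into the region 5' prefix
        if clip[:n] != reference.fetch(chrom, s, s + n - 1):
            return
    else:
        # left clip: bases immediately before the junction = region 3' suffix
        if clip[-n:] != reference.fetch(chrom, e - n + 1, e):
            return
    key = (chrom, s, e, gene_id)
    if key not in candidates:
        candidates[key] = JunctionRegion(
            chrom=chrom,
            start=s,
            end=e,
            gene_id=gene_id,
            first_exon_ordinal=min(ord_s, ord_e),
            last_exon_ordinal=max(ord_s, ord_e),
        )


# ---------------------------------------------------------------------------
# Stage 2: confirmation
# ---------------------------------------------------------------------------

def build_virtual_junction(
    region: JunctionRegion, reference: ReferenceSequence | InMemoryReference
) -> VirtualJunction:
    """Concatenate the region's last K and first K reference bases (K = min(100, size))."""
    k = min(100, region.size_bp)
    suffix = reference.fetch(region.chrom, region.end - k + 1, region.end)
    prefix = reference.fetch(region.chrom, region.start, region.start + k - 1)
    return VirtualJunction(region=region, sequence=suffix + prefix)


def select_region_reads(
    alignments: AlignmentStore, region: JunctionRegion, config: RunConfig
) -> list[AlignedReadView]:
    """Uniquely mapped primary reads overlapping the region, capped positionally.

    When more than ``read_cap`` reads qualify, only the first and last
    ``read_cap / 2`` by leftmost mapped position are kept — junction reads sit
    at the region termini, so the cap discards only interior coverage.
    """
    reads = [
        r
        for r in alignments.overlapping(region.chrom, region.start, region.end)
        if _passes_read_filters(r, config)
    ]
    if len(reads) > config.read_cap:
        half = config.read_cap // 2
        reads = reads[:half] + reads[-half:]
    return reads


def verify_junction_read(
    read: AlignedReadView, vj: VirtualJunction, config: RunConfig
) -> tuple[bool, str | None]:
    """Check that a read's soft-clipped bases continue exactly across the junction.

    Returns ``(verified, anchored_end)`` where ``anchored_end`` is '3p' when
    the matched portion ends at the region 3' terminus (right clip spelling
    the region prefix) and '5p' when it starts at the 5' terminus (left clip
    spelling the region suffix). Requires >= ``min_clip`` clipped bases; the
    comparison is exact, and clips longer than K are compared on their
    junction-proximal K bases only.
    """
    region, k = vj.region, vj.k
    if read.right_clip >= config.min_clip and read.ref_end == region.end:
        clip = read.seq[read.read_length - read.right_clip :]
        n = min(len(clip), k)
        if len(clip) > k:
            logger.debug("clip of %s longer than K=%d; comparing first %d bases", read.qname, k, k)
        if clip[:n] == vj.sequence[k : k + n]:
            return True, "3p"
    if read.left_clip >= config.min_clip and read.pos == region.start:
        clip = read.seq[: read.left_clip]
        n = min(len(clip), k)
        if len(clip) > k:
            logger.debug("clip of %s longer than K=%d; comparing last %d bases", read.qname, k, k)
        if clip[-n:] == vj.sequence[k - n : k]:
            return True, "5p"
    return False, None


def evaluate_mate(
    read: AlignedReadView, region: JunctionRegion, config: RunConfig, anchored: str = ""
) -> TDReadPair | None:
    """Classify a verified junction read's mate as TD evidence or not.

    TD evidence requires the mate (partly or completely) outside the region:
    a forward junction read (flag 99/163) with its reverse mate extending past
    the region 3' end, or a reverse junction read (flag 83/147) with its
    forward mate starting before the region 5' start. The mate's rightmost
    base is inferred as ``mate_pos + read_length - 1`` since its CIGAR is not
    at hand. A mate inside the region is circRNA-compatible and yields None.
    """
    if not read.is_paired or read.mate_pos <= 0:
        logger.warning("junction read %s has no mapped mate; ignored", read.qname)
        return None
    if read.flag in FORWARD_FLAGS:
        mate_end = read.mate_pos + read.read_length - 1
        if mate_end > region.end:
            return TDReadPair(
                qname=read.qname,
                scenario=f"FWD_MATE_PAST_3PRIME/anchor={anchored or '?'}",
                junction_read_pos=read.pos,
                mate_pos=read.mate_pos,
            )
    elif read.flag in REVERSE_FLAGS:
        if read.mate_pos < region.start:
            return TDReadPair(
                qname=read.qname,
                scenario=f"REV_MATE_BEFORE_5PRIME/anchor={anchored or '?'}",
                junction_read_pos=read.pos,
                mate_pos=read.mate_pos,
            )
    return None


# ---------------------------------------------------------------------------
# Frame effect
# ---------------------------------------------------------------------------

def frame_effect(region: JunctionRegion, gene: GeneModel) -> str:
    """Reading-frame consequence of duplicating the region's exons.

    The duplicated exonic length is the sum of exon lengths with transcription
    ordinal in [first_exon_ordinal, last_exon_ordinal]; a multiple of 3 keeps
    the downstream frame (``in_frame``), anything else shifts it. If the
    region is not bounded by those exons' outermost coordinates the effect is
    undefined and 'NA' is returned.
    """
    exons = [
        gene.exon_by_ordinal(o)
        for o in range(region.first_exon_ordinal, region.last_exon_ordinal + 1)
    ]
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    if lo != region.start or hi != region.end:
        return "NA"
    if any(s < region.start or e > region.end for s, e in exons):
        return "NA"
    total = sum(e - s + 1 for s, e in exons)
    return "in_frame" if total % 3 == 0 else "out_of_frame"


# ---------------------------------------------------------------------------
# End-to-end per-sample pipeline
# ---------------------------------------------------------------------------

def call_td_regions(
    sample_id: str,
    alignments: AlignmentStore | str | Path,
    genes: Sequence[GeneModel],
    reference: ReferenceSequence | InMemoryReference | str | Path,
    config: RunConfig | None = None,
) -> SampleTDProfile:
    """Run the full two-stage TD detection for one sample.

    Pipeline: discover candidate regions from soft-clipped reads, then per
    region build the virtual junction, select qualifying reads, verify
    junction reads, and keep distinct read-pairs whose mates map outside the
    region. A region is called when its distinct TD read-pair count reaches
    ``min_support``. Calls sharing identical coordinates across genes are
    collapsed to a single region (annotated with all gene ids) so the
    TD-score counts genomic regions, not gene assignments.
    """
    config = config or RunConfig()
    if not isinstance(reference, (ReferenceSequence, InMemoryReference)):
        reference = ReferenceSequence(reference)
    index = build_boundary_index(genes)
    if not isinstance(alignments, AlignmentStore):
        alignments = AlignmentStore.from_path(
            alignments, known_chroms={g.chrom for g in genes} or None
        )
    candidates = scan_candidate_regions(alignments, index, config, reference)

    per_key: dict[tuple[str, int, int], TDRegionCall] = {}
    for region in candidates:
        try:
            vj = build_virtual_junction(region, reference)
        except (ValueError, KeyError) as exc:
            logger.warning("region %s:%d-%d skipped: %s", region.chrom, region.start, region.end, exc)
            continue
        td_qnames: set[str] = set()
        n_junction = 0
        for read in select_region_reads(alignments, region, config):
            verified, anchored = verify_junction_read(read, vj, config)
            if not verified:
                continue
            n_junction += 1
            pair = evaluate_mate(read, region, config, anchored=anchored)
            if pair is not None:
                td_qnames.add(pair.qname)
        region.n_junction_reads = n_junction
        if len(td_qnames) >= config.min_support and td_qnames:
            gene = index.genes[region.gene_id]
            call = TDRegionCall(
                region=region,
                n_td_read_pairs=len(td_qnames),
                size_bp=region.size_bp,
                frame_effect=frame_effect(region, gene),
            )
            coord = (region.chrom, region.start, region.end)
            if coord in per_key:
                prev = per_key[coord]
                prev.gene_ids = tuple(sorted(set(prev.gene_ids) | {region.gene_id}))
                prev.n_td_read_pairs = max(prev.n_td_read_pairs, call.n_td_read_pairs)
            else:
                per_key[coord] = call
    calls = sorted(per_key.values(), key=lambda c: (c.region.chrom, c.region.start, c.region.end))
    return SampleTDProfile(sample_id=sample_id, calls=calls)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

CALLS_COLUMNS = [
    "sample_id", "chrom", "start", "end", "gene_id", "gene_name",
    "first_exon", "last_exon", "size_bp", "n_junction_reads",
    "n_td_read_pairs", "frame_effect",
]


def profile_to_rows(profile: SampleTDProfile, genes_by_id: dict[str, GeneModel]) -> list[dict]:
    rows = []
    for call in profile.calls:
        r = call.region
        gene_names = ",".join(
            genes_by_id[g].gene_name if g in genes_by_id else g for g in call.gene_ids
        )
        rows.append(
            {
                "sample_id": profile.sample_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "gene_id": ",".join(call.gene_ids),
                "gene_name": gene_names,
                "first_exon": r.first_exon_ordinal,
                "last_exon": r.last_exon_ordinal,
                "size_bp": call.size_bp,
                "n_junction_reads": r.n_junction_reads,
                "n_td_read_pairs": call.n_td_read_pairs,
                "frame_effect": call.frame_effect,
            }
        )
    return rows


def write_profile(profile: SampleTDProfile, genes: Sequence[GeneModel], out_dir: str | Path) -> None:
    """Write ``sample_td_calls.tsv`` and ``sample_summary.tsv`` for one sample."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes_by_id = {g.gene_id: g for g in genes}
    calls = pd.DataFrame(profile_to_rows(profile, genes_by_id), columns=CALLS_COLUMNS)
    calls.to_csv(out_dir / "sample_td_calls.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [{"sample_id": profile.sample_id, "td_score": profile.td_score}]
    )
    summary.to_csv(out_dir / "sample_summary.tsv", sep="\t", index=False)
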