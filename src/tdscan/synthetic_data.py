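"""Download-free synthetic fixtures for the TD detection pipeline.

Generates a random reference genome with multi-exon gene annotations, and SAM
alignments laid out the way a spliced aligner would report them for:

* planted intragenic tandem duplications — soft-clipped junction reads at a
  region terminus whose clipped bases continue across the duplication
  junction, with mates placed (partly or completely) outside the region;
* circRNA-configured pairs — identical junction reads but with mates confined
  to the region, which must never be called as TDs;
* canonical exonic/intronic background pairs (total-RNA style coverage).

Reads are emitted pre-"aligned" against the unmodified reference, because the
detector consumes aligner output: a junction read is literally a soft-clipped
record whose clip spells the other side of the junction. All generators are
deterministic given their seed. Junction-spanning 10-mers are checked to be
unique in the genome so clipped matches are unambiguous.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, InMemoryReference
from .config import logger

READ_QUAL_CHAR = "I"
DEFAULT_FRAGMENT_MEAN = 300
DEFAULT_FRAGMENT_SD = 50


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SimGeneSpec:
    """Layout of one simulated gene on its chromosome."""

    name: str
    strand: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    offset: int  # 0-based offset of the first exon's first base
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(f"{self.name}: need exactly n_exons - 1 introns")
        if any(v < 1 for v in self.exon_lengths + self.intron_lengths):
            raise ValueError(f"{self.name}: all exon/intron lengths must be >= 1")

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclasses.dataclass(frozen=True)
class SimTDSpec:
    """One planted TD (or circRNA decoy) on a gene, with read-pair counts."""

    gene: str
    first_exon: int  # transcription-order ordinal
    last_exon: int
    n_junction_pairs_outside: int = 0  # TD evidence: mates outside the region
    n_junction_pairs_inside: int = 0   # circRNA configuration: mates inside
    n_background_pairs: int = 0
    read_length: int = 75
    clip_length: int | None = None  # None: cycle through 15..35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.first_exon > self.last_exon:
            raise ValueError("first_exon must be <= last_exon")
        if min(self.n_junction_pairs_outside, self.n_junction_pairs_inside,
               self.n_background_pairs) < 0:
            raise ValueError("pair counts must be >= 0")


@dataclasses.dataclass(frozen=True)
class SimCohortSpec:
    """Class-conditional TD-score distributions for a simulated cohort.

    Scores are drawn per class from Poisson distributions; the defaults
    emulate the separation reported for real breast-cancer cohorts (median
    scores around 5 for BRCA1-type, 0 for BRCA2-type, 1 for HRP).
    """

    class_counts: dict = dataclasses.field(
        default_factory=lambda: {"BRCA1": 34, "BRCA2": 17, "HRP": 204}
    )
    class_means: dict = dataclasses.field(
        default_factory=lambda: {"BRCA1": 5.0, "BRCA2": 0.5, "HRP": 1.0}
    )
    seed: int = 17

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - {"BRCA1", "BRCA2", "HRP"}
        if unknown:
            raise ValueError(f"unknown class labels: {unknown}")
        if any(m < 0 for m in self.class_means.values()):
            raise ValueError("class means must be >= 0")


def pten_like_gene_spec(offset: int = 1000, chrom: str = "chrS") -> SimGeneSpec:
    """A 9-exon gene mimicking PTEN's exon geometry.

    Exons 3-5 measure 45, 44 and 239 bp and the intervening introns 5488 and
    1923 bp, so the genomic spans of exon3-5, exon4-5 and exon5 duplications
    are 7739, 2206 and 239 bp respectively, and the exon3-5 exonic sum is
    328 bp (a frame-shifting duplication).
    """
    return SimGeneSpec(
        name="PTENL",
        strand="+",
        exon_lengths=(79, 85, 45, 44, 239, 142, 67, 225, 324),
        intron_lengths=(901, 1204, 5488, 1923, 701, 803, 654, 1102),
        offset=offset,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    gtf_text: str

    @property
    def reference(self) -> InMemoryReference:
        return InMemoryReference(self.sequences)

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.gene_name == name or g.gene_id == name:
                return g
        raise KeyError(f"no simulated gene named {name!r}")

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        import pyfaidx

        pyfaidx.Faidx(str(path))  # writes the .fai sidecar
        return path

    def write_gtf(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.gtf_text)
        return path


def _gene_model_from_spec(spec: SimGeneSpec, gene_id: str) -> GeneModel:
    exons = []
    pos = spec.offset + 1  # to 1-based
    for i, elen in enumerate(spec.exon_lengths):
        exons.append((pos, pos + elen - 1))
        pos += elen
        if i < len(spec.intron_lengths):
            pos += spec.intron_lengths[i]
    n = len(exons)
    ordinals = tuple(range(1, n + 1)) if spec.strand == "+" else tuple(range(n, 0, -1))
    return GeneModel(
        gene_id=gene_id,
        gene_name=spec.name,
        chrom=spec.chrom,
        strand=spec.strand,
        exons=tuple(exons),
        exon_ordinals=ordinals,
    )


def _gtf_lines(gene: GeneModel) -> list[str]:
    attrs = (
        f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; '
        f'gene_name "{gene.gene_name}";'
    )
    span = (gene.exons[0][0], gene.exons[-1][1])
    lines = [
        "\t".join(
            [gene.chrom, "tdscan_sim", "gene", str(span[0]), str(span[1]), ".",
             gene.strand, ".", f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}";']
        ),
        "\t".join(
            [gene.chrom, "tdscan_sim", "transcript", str(span[0]), str(span[1]), ".",
             gene.strand, ".", attrs]
        ),
    ]
    for start, end in gene.exons:
        lines.append(
            "\t".join(
                [gene.chrom, "tdscan_sim", "exon", str(start), str(end), ".",
                 gene.strand, ".", attrs]
            )
        )
    return lines


def _junction_kmer_collisions(
    sequences: dict[str, str], genes: list[GeneModel], k: int = 10
) -> tuple[list[tuple[str, int, str]], set[tuple[str, int]]]:
    """Remote occurrences of junction-spanning 10-mers in the linear genome.

    A 10-mer crossing an exon-end -> exon-start junction is chimeric, so a
    hit elsewhere in the reference would make a short clipped match
    ambiguous. Occurrences overlapping the junction's own flanks are
    tautological — they arise whenever the single base adjacent to one
    boundary coincides with the base across the junction and cannot support a
    >= 10-base spurious match — and are ignored. Returns the remote hits as
    (chrom, 0-based position, kmer) plus the set of protected (chrom,
    0-based position) bases inside boundary source windows that repairs must
    not touch.
    """
    hits: list[tuple[str, int, str]] = []
    protected: set[tuple[str, int]] = set()
    for gene in genes:
        seq = sequences[gene.chrom]
        starts = sorted({s for s, _ in gene.exons})
        ends = sorted({e for _, e in gene.exons})
        for s in starts:
            protected.update((gene.chrom, p) for p in range(s - 1, s - 1 + k - 1))
        for e in ends:
            protected.update((gene.chrom, p) for p in range(e - (k - 1), e))
        for s in starts:
            for e in ends:
                if s >= e:
                    continue
                ctx = seq[max(0, e - (k - 1)) : e] + seq[s - 1 : s - 1 + (k - 1)]
                self_zones = ((e - k, e), (s - 2, s - 2 + k))  # 0-based start of a hit
                for i in range(len(ctx) - k + 1):
                    kmer = ctx[i : i + k]
                    for chrom, chrom_seq in sequences.items():
                        pos = chrom_seq.find(kmer)
                        while pos != -1:
                            is_self = chrom == gene.chrom and any(
                                lo <= pos <= hi for lo, hi in self_zones
                            )
                            if not is_self:
                                hits.append((chrom, pos, kmer))
                            pos = chrom_seq.find(kmer, pos + 1)
    return hits, protected


def make_genome_and_annotation(
    specs: Sequence[SimGeneSpec], seed: int, flank: int = 500, max_tries: int = 25
) -> SimulatedGenome:
    """Random reference + GTF for the given gene layouts, deterministic per seed.

    Base composition is uniform random; afterwards any reference occurrence
    of a 10-mer that spans a possible exon-boundary junction is removed by
    point-mutating the offending locus (bounded repair loop), so soft-clip
    matches against junctions are unambiguous. Overlapping gene layouts on
    one chromosome are an error.
    """
    by_chrom: dict[str, list[SimGeneSpec]] = {}
    for spec in specs:
        by_chrom.setdefault(spec.chrom, []).append(spec)
    for chrom, chrom_specs in by_chrom.items():
        placed = sorted((s.offset, s.offset + s.span) for s in chrom_specs)
        for (a1, b1), (a2, b2) in zip(placed, placed[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping gene layouts on {chrom}: {b1} > {a2}")

    genes = [
        _gene_model_from_spec(spec, gene_id=f"SIMG{i + 1:04d}")
        for i, spec in enumerate(specs)
    ]
    lengths = {
        chrom: max(s.offset + s.span for s in chrom_specs) + flank
        for chrom, chrom_specs in by_chrom.items()
    }
    rng = np.random.default_rng(seed)
    sequences = {
        chrom: "".join(rng.choice(list("ACGT"), size=n)) for chrom, n in lengths.items()
    }
    for attempt in range(max_tries):
        collisions, protected = _junction_kmer_collisions(sequences, genes)
        if not collisions:
            break
        logger.debug("repairing %d junction 10-mer collisions (pass %d)", len(collisions), attempt)
        for chrom, pos, kmer in collisions:
            mutable = [
                i for i in range(pos, pos + len(kmer)) if (chrom, i) not in protected
            ]
            if not mutable:
                continue
            i = mutable[len(mutable) // 2]
            seq = sequences[chrom]
            new = "ACGT"[("ACGT".index(seq[i]) + int(rng.integers(1, 4))) % 4]
            sequences[chrom] = seq[:i] + new + seq[i + 1 :]
    else:
        raise RuntimeError("could not repair junction 10-mer collisions")

    gtf_lines = ["##description: tdscan simulated annotation"]
    for gene in genes:
        gtf_lines.extend(_gtf_lines(gene))
    return SimulatedGenome(sequences=sequences, genes=genes, gtf_text="\n".join(gtf_lines) + "\n")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SamRecord:
    qname: str
    flag: int
    chrom: str
    pos: int  # 1-based
    mapq: int
    cigar: str
    pnext: int
    tlen: int
    seq: str

    def render(self) -> str:
        return "\t".join(
            [
                self.qname, str(self.flag), self.chrom, str(self.pos), str(self.mapq),
                self.cigar, "=", str(self.pnext), str(self.tlen), self.seq,
                READ_QUAL_CHAR * len(self.seq),
            ]
        )


def _region_of(gene: GeneModel, first_exon: int, last_exon: int) -> tuple[int, int]:
    exons = [gene.exon_by_ordinal(o) for o in range(first_exon, last_exon + 1)]
    return min(s for s, _ in exons), max(e for _, e in exons)


def _pair_records(
    qname: str, chrom: str,
    a: tuple[int, int, str, str], b: tuple[int, int, str, str],
) -> list[SamRecord]:
    """Two mated records from (pos, flag, cigar, seq) tuples with MPOS/ISIZE filled."""
    (pos_a, flag_a, cig_a, seq_a), (pos_b, flag_b, cig_b, seq_b) = a, b
    left = min(pos_a, pos_b)
    right = max(pos_a + len(seq_a) - 1, pos_b + len(seq_b) - 1)
    tlen = right - left + 1
    return [
        SamRecord(qname, flag_a, chrom, pos_a, 255, cig_a, pos_b,
                  tlen if pos_a <= pos_b else -tlen, seq_a),
        SamRecord(qname, flag_b, chrom, pos_b, 255, cig_b, pos_a,
                  tlen if pos_b < pos_a else -tlen, seq_b),
    ]


def simulate_td_reads(
    genome: SimulatedGenome, td: SimTDSpec, qname_prefix: str = "sim"
) -> tuple[list[SamRecord], list[dict]]:
    """Reads for one planted TD/circRNA/background specification.

    Junction reads are soft-clipped records anchored at a region terminus
    (CIGAR like ``50M25S`` at the 3' end or ``25S50M`` at the 5' end) whose
    clipped bases spell the sequence across the duplication junction. Outside
    pairs cycle through the four qualifying flag scenarios; inside pairs keep
    the mate within the region. Returns the records plus ground-truth rows
    (one per pair: qname, kind, gene, region).
    """
    gene = genome.gene(td.gene)
    ref = genome.reference
    seq = genome.sequences[gene.chrom]
    chrom_len = len(seq)
    start, end = _region_of(gene, td.first_exon, td.last_exon)
    region_len = end - start + 1
    L = td.read_length
    rng = np.random.default_rng(td.seed)

    def clip_for(i: int) -> int:
        if td.clip_length is not None:
            return td.clip_length
        # cycle 15..35, clamped into the range where both the matched portion
        # (L - clip) and the clip itself fit inside the region
        lo = max(10, L - region_len)
        hi = min(L - 1, region_len)
        if lo > hi:
            raise ValueError(
                f"region of {region_len} bp cannot host a {L}-base junction read "
                f"with >= 10 clipped bases"
            )
        return min(max(15 + (i * 7) % 21, lo), hi)

    def junction_read(anchor: str, flag: int, clip: int) -> tuple[int, int, str, str]:
        matched = L - clip
        if matched < 1 or matched > region_len or clip > region_len:
            raise ValueError(
                f"read length {L} with clip {clip} does not fit region of {region_len} bp"
            )
        if anchor == "3p":
            pos = end - matched + 1
            bases = ref.fetch(gene.chrom, pos, end) + ref.fetch(gene.chrom, start, start + clip - 1)
            return pos, flag, f"{matched}M{clip}S", bases
        pos = start
        bases = ref.fetch(gene.chrom, end - clip + 1, end) + ref.fetch(gene.chrom, start, start + matched - 1)
        return pos, flag, f"{clip}S{matched}M", bases

    def plain_read(pos: int, flag: int) -> tuple[int, int, str, str]:
        pos = max(1, min(pos, chrom_len - L + 1))
        return pos, flag, f"{L}M", ref.fetch(gene.chrom, pos, pos + L - 1)

    records: list[SamRecord] = []
    truth: list[dict] = []
    counter = 0

    def emit(kind: str, jr, mate) -> None:
        nonlocal counter
        qname = f"{qname_prefix}:{td.gene}:{td.first_exon}-{td.last_exon}:{kind}:{counter}"
        counter += 1
        records.extend(_pair_records(qname, gene.chrom, jr, mate))
        truth.append(
            {
                "qname": qname, "kind": kind, "gene": gene.gene_name,
                "gene_id": gene.gene_id, "chrom": gene.chrom,
                "region_start": start, "region_end": end,
                "first_exon": td.first_exon, "last_exon": td.last_exon,
            }
        )

    # TD evidence: mate partly or completely outside the region
    for i in range(td.n_junction_pairs_outside):
        clip = clip_for(i)
        scenario = i % 4
        if scenario == 0:   # forward junction read at 3' end, reverse mate past 3'
            jr = junction_read("3p", 99, clip)
            mate_pos = int(rng.integers(end - L + 2, min(end + 120, chrom_len - L + 1)))
            mate = plain_read(mate_pos, 147)
        elif scenario == 1:  # forward junction read at 5' end, reverse mate past 3'
            jr = junction_read("5p", 163, clip)
            mate_pos = int(rng.integers(end - L + 2, min(end + 120, chrom_len - L + 1)))
            mate = plain_read(mate_pos, 83)
        elif scenario == 2:  # reverse junction read at 5' end, forward mate before 5'
            jr = junction_read("5p", 83, clip)
            mate_pos = int(rng.integers(max(1, start - 220), start))
            mate = plain_read(min(mate_pos, start - 1), 163)
        else:               # reverse junction read at 3' end, forward mate before 5'
            jr = junction_read("3p", 147, clip)
            mate_pos = int(rng.integers(max(1, start - 220), start))
            mate = plain_read(min(mate_pos, start - 1), 99)
        emit("td_pair", jr, mate)

    # circRNA configuration: identical junction reads, mate confined to region
    for i in range(td.n_junction_pairs_inside):
        clip = clip_for(i + 3)
        if region_len >= L:
            jr = junction_read("3p" if i % 2 == 0 else "5p", 99 if i % 2 == 0 else 163, clip)
            mate_pos = int(rng.integers(start, end - L + 2))
            mate = plain_read(mate_pos, 147 if i % 2 == 0 else 83)
        else:
            # region shorter than a read: a reverse junction read with its mate
            # at/after the region start is still not TD evidence
            jr = junction_read("5p", 83, clip)
            mate = plain_read(start, 163)
        emit("circ_pair", jr, mate)

    # canonical background coverage across the gene body (exons + introns)
    gene_lo, gene_hi = gene.exons[0][0], gene.exons[-1][1]
    for _ in range(td.n_background_pairs):
        frag = int(np.clip(rng.normal(DEFAULT_FRAGMENT_MEAN, DEFAULT_FRAGMENT_SD), 2 * L, 600))
        p1 = int(rng.integers(max(1, gene_lo - 100), max(gene_lo + 1, gene_hi - frag)))
        r1 = plain_read(p1, 99)
        r2 = plain_read(p1 + frag - L, 147)
        emit("background", r1, r2)

    return records, truth


def render_sam(genome: SimulatedGenome, records: Sequence[SamRecord]) -> str:
    """Coordinate-sorted SAM text with a proper header."""
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{chrom}\tLN:{len(seq)}" for chrom, seq in genome.sequences.items()]
    order = {chrom: i for i, chrom in enumerate(genome.sequences)}
    body = [r.render() for r in sorted(records, key=lambda r: (order[r.chrom], r.pos))]
    return "\n".join(header + body) + "\n"


def simulate_sample(
    genome: SimulatedGenome,
    td_specs: Sequence[SimTDSpec],
    sample_id: str = "sim_sample",
) -> tuple[str, pd.DataFrame]:
    """SAM text plus the ground-truth table for a whole sample."""
    records: list[SamRecord] = []
    truth: list[dict] = []
    for j, td in enumerate(td_specs):
        recs, t = simulate_td_reads(genome, td, qname_prefix=f"{sample_id}:{j}")
        records.extend(recs)
        truth.extend(t)
    truth_df = pd.DataFrame(
        truth,
        columns=["qname", "kind", "gene", "gene_id", "chrom",
                 "region_start", "region_end", "first_exon", "last_exon"],
    )
    return render_sam(genome, records), truth_df


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

def simulate_cohort(spec: SimCohortSpec) -> pd.DataFrame:
    """Cohort table with class-conditional Poisson TD-scores (deterministic per seed)."""
    if any(n <= 0 for n in spec.class_counts.values()):
        raise ValueError("every class used must have at least one sample")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in ("BRCA1", "BRCA2", "HRP"):
        n = spec.class_counts.get(label, 0)
        mean = spec.class_means.get(label, 0.0)
        for i, score in enumerate(rng.poisson(mean, size=n)):
            rows.append(
                {"sample_id": f"{label}_{i:04d}", "td_score": int(score),
                 "class_label": label, "er_status": "NA"}
            )
    return pd.DataFrame(rows)


def analytic_classifier_performance(spec: SimCohortSpec, threshold: int) -> tuple[float, float]:
    """Exact sensitivity/specificity of the score cut-off under the generator.

    Sensitivity is the Poisson upper tail P(X >= threshold) at the BRCA1 mean;
    specificity is the sample-size-weighted lower tail over the negative
    classes (BRCA2, HRP).
    """
    sens = float(stats.poisson.sf(threshold - 1, spec.class_means["BRCA1"]))
    neg = [(lbl, spec.class_counts.get(lbl, 0)) for lbl in ("BRCA2", "HRP")]
    total = sum(n for _, n in neg)
    spec_ = sum(
        n * stats.poisson.cdf(threshold - 1, spec.class_means[lbl]) for lbl, n in neg
    ) / total
    return sens, float(spec_)
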