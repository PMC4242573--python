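"""Sequence and gene-model I/O, transcript selection, and codon counting.

This module turns genome FASTA + gene-model tables into in-frame coding
sequences with their introns and flanking regions, applies the
transcript-level filters used throughout the pipeline (minimum length,
one-transcript-per-gene selection, ortholog masking, splice-enhancer
trimming), and tallies codon usage.

Coordinates are 0-based, half-open (BED convention) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

# Sixfold-degenerate amino acids and their fourfold/twofold subfamilies.
_SIXFOLD_SPLIT = {
    "L": {"L4": ("CTA", "CTC", "CTG", "CTT"), "L2": ("TTA", "TTG")},
    "S": {"S4": ("TCA", "TCC", "TCG", "TCT"), "S2": ("AGC", "AGT")},
    "R": {"R4": ("CGA", "CGC", "CGG", "CGT"), "R2": ("AGA", "AGG")},
}


class CoordinateError(ValueError):
    """Annotation coordinates fall outside the named sequence."""


class FrameError(ValueError):
    """A coding sequence is not a whole number of codons."""


class AlignmentError(ValueError):
    """A codon alignment is ragged or out of frame."""


class GeneticCode:
    """The standard genetic code partitioned into synonymous families.

    A *family* is the set of codons translated to one amino acid; the
    sixfold-degenerate amino acids (Leu, Ser, Arg) may additionally be
    split into a fourfold and a twofold subfamily, the partition used for
    preferred/unpreferred codon analyses. Met and Trp form singleton
    families and are excluded from bias computation.
    """

    def __init__(self) -> None:
        fwd = dict(standard_dna_table.forward_table)
        self.codons: tuple[str, ...] = tuple(sorted(fwd))  # 61 sense codons
        self.codon_to_aa: dict[str, str] = {c: fwd[c] for c in self.codons}
        self.codon_index: dict[str, int] = {c: i for i, c in enumerate(self.codons)}

        by_aa: dict[str, list[str]] = {}
        for c in self.codons:
            by_aa.setdefault(fwd[c], []).append(c)
        # Classic partition: one family per amino acid, singletons excluded.
        self._families_classic: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cs)) for aa, cs in by_aa.items() if len(cs) > 1
        }
        # Split partition: sixfold families divided into 4-fold + 2-fold.
        split: dict[str, tuple[str, ...]] = {}
        for aa, cs in self._families_classic.items():
            if aa in _SIXFOLD_SPLIT:
                split.update(_SIXFOLD_SPLIT[aa])
            else:
                split[aa] = cs
        self._families_split = split
        self.singletons: tuple[str, ...] = tuple(
            aa for aa, cs in by_aa.items() if len(cs) == 1
        )  # Met, Trp

    def families(self, split_sixfold: bool = False) -> dict[str, tuple[str, ...]]:
        """Family name -> codon tuple, optionally splitting sixfold families."""
        return dict(self._families_split if split_sixfold else self._families_classic)

    def degeneracy(self, family: str, split_sixfold: bool = False) -> int:
        return len(self.families(split_sixfold)[family])

    def family_of(self, codon: str, split_sixfold: bool = False) -> str | None:
        """Name of the family containing ``codon`` (None for Met/Trp/stop)."""
        for name, cs in self.families(split_sixfold).items():
            if codon in cs:
                return name
        return None


#: Module-level standard code instance shared by the whole pipeline.
STANDARD_CODE = GeneticCode()


@dataclass
class TranscriptRecord:
    """One transcript in coding orientation with its genomic context."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # genome coords
    introns: list[str] = field(default_factory=list)  # coding orientation
    flank5: str = ""  # upstream of the start codon, coding orientation
    flank3: str = ""
    compartment: str | None = None  # centromeric / telomeric / interior
    chromosome_class: str | None = None  # X / autosome

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def genome_start(self) -> int:
        return min(s for s, _ in self.exons) if self.exons else 0

    def exon_cds_offsets(self) -> list[tuple[int, int]]:
        """Exon intervals in CDS coordinates (coding orientation)."""
        lengths = [e - s for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, pos = [], 0
        for ln in lengths:
            out.append((pos, pos + ln))
            pos += ln
        return out


@dataclass
class CodonCounts:
    """Per-gene counts over the 61 sense codons."""

    counts: np.ndarray  # int array aligned to STANDARD_CODE.codons
    skipped: int = 0  # ambiguous or stop codons not tallied
    gene_id: str = ""

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def count(self, codon: str) -> int:
        return int(self.counts[STANDARD_CODE.codon_index[codon]])

    def family_counts(
        self, family: str, code: GeneticCode = STANDARD_CODE, split_sixfold: bool = False
    ) -> np.ndarray:
        codons = code.families(split_sixfold)[family]
        return np.array([self.counts[code.codon_index[c]] for c in codons])

    def family_total(
        self, family: str, code: GeneticCode = STANDARD_CODE, split_sixfold: bool = False
    ) -> int:
        return int(self.family_counts(family, code, split_sixfold).sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(STANDARD_CODE.codons))

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(self.counts + other.counts, self.skipped + other.skipped)


# ---------------------------------------------------------------------------
# Gene-model loading
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {name: sequence} (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_models(path) -> pd.DataFrame:
    """Read a BED12-like gene-model table.

    Columns: chrom, start, end, name (``gene_id|transcript_id``), score,
    strand, thickStart, thickEnd, rgb, blockCount, blockSizes, blockStarts.
    """
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    return pd.read_csv(path, sep="\t", names=cols, comment="#")


def load_gene_models(
    genome: dict[str, str],
    annotation: pd.DataFrame,
    flank_size: int = 2000,
) -> list[TranscriptRecord]:
    """Extract in-frame transcripts, introns, and flanks from a genome.

    Minus-strand transcripts are reverse-complemented into coding
    orientation; intron order follows coding orientation as well.

    Raises :class:`CoordinateError` for out-of-range exons and
    :class:`FrameError` when a CDS is not a whole number of codons.
    """
    records = []
    for row in annotation.itertuples(index=False):
        name = str(row.name)
        gene_id, _, transcript_id = name.partition("|")
        transcript_id = transcript_id or name
        chrom_seq = genome.get(row.chrom)
        if chrom_seq is None:
            raise CoordinateError(f"{transcript_id}: unknown sequence {row.chrom!r}")
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(row.start + s, row.start + s + sz) for s, sz in zip(starts, sizes)]
        for s, e in exons:
            if s < 0 or e > len(chrom_seq) or s >= e:
                raise CoordinateError(
                    f"{transcript_id}: exon {s}-{e} outside {row.chrom} "
                    f"(length {len(chrom_seq)})"
                )
        cds = "".join(chrom_seq[s:e] for s, e in exons)
        introns = [chrom_seq[e1:s2] for (_, e1), (s2, _) in zip(exons, exons[1:])]
        up = chrom_seq[max(0, row.start - flank_size): row.start]
        down = chrom_seq[row.end: row.end + flank_size]
        if row.strand == "-":
            cds = reverse_complement(cds)
            introns = [reverse_complement(i) for i in introns[::-1]]
            up, down = reverse_complement(down), reverse_complement(up)
        if len(cds) % 3:
            raise FrameError(f"{transcript_id}: CDS length {len(cds)} not divisible by 3")
        records.append(
            TranscriptRecord(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=str(row.chrom),
                strand=str(row.strand),
                cds=cds,
                exons=exons,
                introns=introns,
                flank5=up,
                flank3=down,
                chromosome_class="X" if str(row.chrom).endswith("X") else "autosome",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Transcript-level filters
# ---------------------------------------------------------------------------

def select_transcript(
    transcripts: list[TranscriptRecord],
    policy: str = "random",
    seed: int | None = None,
) -> TranscriptRecord:
    """Pick one transcript of a gene: random (seeded), shortest, or longest.

    Shortest/longest ties are broken by lexicographic transcript id.
    """
    if not transcripts:
        raise ValueError("no transcripts to select from")
    if policy == "random":
        rng = np.random.default_rng(seed)
        return transcripts[int(rng.integers(len(transcripts)))]
    if policy in ("shortest", "longest"):
        # min/max are stable, so sorting by id first breaks ties lexicographically
        ordered = sorted(transcripts, key=lambda t: t.transcript_id)
        pick = min if policy == "shortest" else max
        return pick(ordered, key=lambda t: len(t.cds))
    raise ValueError(f"unknown policy {policy!r}")


def filter_min_codons(record: TranscriptRecord, min_codons: int = 100) -> bool:
    """Keep a transcript iff its CDS has at least ``min_codons`` codons."""
    return record.n_codons >= min_codons


# ---------------------------------------------------------------------------
# Ortholog alignment masking
# ---------------------------------------------------------------------------

def mask_ortholog_codons(alignment: dict[str, str]) -> dict[str, str]:
    """Mask an in-frame multi-species codon alignment.

    Removes (a) every codon column containing a gap or ambiguity in any
    species, and (b) every column at or 3' of the earliest stop codon
    observed in any species on the aligned codon grid. Idempotent.
    """
    seqs = list(alignment.values())
    if not seqs:
        return {}
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise AlignmentError("ragged alignment")
    if length % 3:
        raise AlignmentError(f"alignment length {length} not divisible by 3")
    n_cod = length // 3
    cols = [[s[3 * i: 3 * i + 3].upper() for s in seqs] for i in range(n_cod)]
    stop_at = next(
        (i for i, col in enumerate(cols) if any(c in STOP_CODONS for c in col)),
        n_cod,
    )
    keep = [
        i
        for i, col in enumerate(cols[:stop_at])
        if all(set(c) <= set(BASES) for c in col)
    ]
    return {
        name: "".join(seq[3 * i: 3 * i + 3] for i in keep)
        for name, seq in alignment.items()
    }


# ---------------------------------------------------------------------------
# Exon splice enhancer trimming
# ---------------------------------------------------------------------------

def trim_ese(record: TranscriptRecord, trim: int = 15) -> str:
    """Remove putative exon-splice-enhancer sequence from each exon end.

    From each end of every coding exon, 15 bases plus 0-2 extra are removed
    so that each removed block begins/ends on a codon boundary of the
    transcript frame; the surviving sequence is therefore in frame. Exons
    too short to survive both trims are dropped entirely.
    """
    pieces = []
    for s, e in record.exon_cds_offsets():
        lead = trim + (-(s + trim)) % 3  # extend to the next codon boundary
        tail = trim + (e - trim) % 3  # extend back to the previous boundary
        if e - s <= lead + tail:
            continue
        pieces.append(record.cds[s + lead: e - tail])
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------

def count_codons(cds: str, code: GeneticCode = STANDARD_CODE, gene_id: str = "") -> CodonCounts:
    """Tally the 61 sense codons of an in-frame CDS.

    Ambiguous codons and stop codons are skipped (counted in ``skipped``),
    so sense counts + skipped always equal the codon length of the input.
    """
    counts = np.zeros(len(code.codons), dtype=np.int64)
    skipped = 0
    cds = cds.upper()
    for i in range(0, len(cds) - len(cds) % 3, 3):
        idx = code.codon_index.get(cds[i: i + 3])
        if idx is None:
            skipped += 1
        else:
            counts[idx] += 1
    if skipped:
        logger.debug("count_codons(%s): skipped %d non-sense codons", gene_id, skipped)
    return CodonCounts(counts=counts, skipped=skipped, gene_id=gene_id)


# ---------------------------------------------------------------------------
# Chromosomal compartments
# ---------------------------------------------------------------------------

def read_compartment_table(path) -> pd.DataFrame:
    """TSV with columns chrom, cen_start, cen_end, chrom_length."""
    return pd.read_csv(path, sep="\t", comment="#")


def classify_compartment(
    record: TranscriptRecord,
    table: pd.DataFrame,
    window_mb: float = 10.0,
) -> str | None:
    """Label a gene centromeric, telomeric, or interior.

    A gene is centromeric when its start lies within ``window_mb`` of the
    centromere boundary, telomeric when within the window of either
    chromosome end; genes matching both are called centromeric (logged).
    The window is configurable (5, 10, or 20 Mb are the usual choices).
    """
    rows = table[table["chrom"] == record.chrom]
    if rows.empty:
        logger.warning("classify_compartment: unknown chromosome %s", record.chrom)
        return None
    row = rows.iloc[0]
    w = window_mb * 1e6
    pos = record.genome_start
    d_cen = max(0, max(row.cen_start - pos, pos - row.cen_end))
    d_tel = min(pos, row.chrom_length - pos)
    cen, tel = d_cen <= w, d_tel <= w
    if cen and tel:
        logger.info(
            "%s within %g Mb of both centromere and telomere; labelled centromeric",
            record.transcript_id, window_mb,
        )
    label = "centromeric" if cen else ("telomeric" if tel else "interior")
    record.compartment = label
    return label
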