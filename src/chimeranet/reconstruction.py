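"""Chimeric coding-sequence reconstruction and translation.

A gene fusion joins the 5' part of one transcript to the 3' part of another,
possibly with a short templated insertion across the junction.  Given
strand-aware transcript models (ordered exons plus the spliced nucleotide
sequence) and genomic breakpoint coordinates, this module rebuilds the
chimeric coding sequence, translates it from the first ATG with the standard
genetic code, and enumerates all coding-isoform combinations of the two
partner genes.

Coordinate conventions: genomic coordinates are 1-based inclusive (the GTF
dialect); transcript-relative offsets are 0-based half-open.  For a fusion
descriptor, ``off5`` is the number of 5' nucleotides retained and ``off3`` is
the index of the first retained 3' nucleotide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .exceptions import (
    NoInitiationCodonError,
    OffsetOutOfRangeError,
    PositionNotExonicError,
)

logger = logging.getLogger(__name__)

STOP_SYMBOL = "*"

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class ExonRecord:
    """One exon, in genomic coordinates (1-based, inclusive on both ends)."""

    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TranscriptModel:
    """One isoform: ordered exons (5'->3' in transcript orientation) plus its spliced sequence."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[ExonRecord]
    spliced_seq: str
    coding: bool = True

    def __post_init__(self) -> None:
        total = sum(len(e) for e in self.exons)
        if self.spliced_seq and total != len(self.spliced_seq):
            raise ValueError(
                f"{self.transcript_id}: exon lengths sum to {total} but spliced "
                f"sequence has {len(self.spliced_seq)} nt"
            )
        coords = [e.start for e in self.exons]
        if self.strand == "+":
            if coords != sorted(coords):
                raise ValueError(f"{self.transcript_id}: plus-strand exons not in ascending order")
        else:
            if coords != sorted(coords, reverse=True):
                raise ValueError(f"{self.transcript_id}: minus-strand exons not in descending order")

    def __len__(self) -> int:
        return len(self.spliced_seq)


@dataclass(frozen=True)
class Breakpoint:
    """A genomic fusion junction coordinate on one side of the event."""

    chrom: str
    genomic_pos: int
    side: str = "5p"  # {"5p", "3p"}


@dataclass
class FusionDescriptor:
    """A fully-resolved fusion: the two isoforms, retained offsets and any insertion.

    ``off5`` nucleotides of ``t5`` are retained, then ``insert_seq``, then
    ``t3.spliced_seq[off3:]``.
    """

    t5: TranscriptModel
    t3: TranscriptModel
    off5: int
    off3: int
    insert_seq: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.off5 <= len(self.t5.spliced_seq):
            raise OffsetOutOfRangeError(
                f"off5={self.off5} outside [0, {len(self.t5.spliced_seq)}] for {self.t5.transcript_id}"
            )
        if not 0 <= self.off3 <= len(self.t3.spliced_seq):
            raise OffsetOutOfRangeError(
                f"off3={self.off3} outside [0, {len(self.t3.spliced_seq)}] for {self.t3.transcript_id}"
            )
        bad = set(self.insert_seq) - _NUCLEOTIDES
        if bad:
            raise ValueError(f"insert_seq contains non-ACGT symbols: {sorted(bad)}")


@dataclass
class FusionProtein:
    """Translated fusion product over the 20 amino acids plus the stop symbol."""

    fusion_id: str
    gene5: str
    gene3: str
    aa_seq: str
    source: FusionDescriptor | None = field(default=None, repr=False)

    @property
    def terminated(self) -> bool:
        return self.aa_seq.endswith(STOP_SYMBOL)


def genomic_to_transcript_offset(tm: TranscriptModel, pos: int) -> int:
    """Map a genomic position to its 0-based offset along the spliced transcript.

    The offset counts transcript nucleotides strictly 5' of ``pos`` in
    transcript orientation, so the returned value indexes the base at ``pos``.

    Raises
    ------
    PositionNotExonicError
        If ``pos`` is intronic or outside the transcript's exons.
    """
    cum = 0
    for exon in tm.exons:
        if exon.contains(pos):
            if tm.strand == "+":
                return cum + (pos - exon.start)
            return cum + (exon.end - pos)
        cum += len(exon)
    raise PositionNotExonicError(
        f"position {pos} is not exonic in transcript {tm.transcript_id}"
    )


def transcript_offset_to_genomic(tm: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_transcript_offset` for offsets within the transcript."""
    if not 0 <= offset < len(tm.spliced_seq):
        raise OffsetOutOfRangeError(
            f"offset {offset} outside [0, {len(tm.spliced_seq)}) for {tm.transcript_id}"
        )
    cum = 0
    for exon in tm.exons:
        if offset < cum + len(exon):
            within = offset - cum
            if tm.strand == "+":
                return exon.start + within
            return exon.end - within
        cum += len(exon)
    raise AssertionError("unreachable: offset validated above")


def build_chimeric_cds(fd: FusionDescriptor) -> str:
    """Concatenate the retained 5' prefix, the insertion and the retained 3' suffix."""
    return fd.t5.spliced_seq[: fd.off5] + fd.insert_seq + fd.t3.spliced_seq[fd.off3 :]


def translate_to_protein(nt: str) -> str:
    """Translate from the first ATG with the standard genetic code.

    Translation proceeds codon-by-codon from the first ATG and halts at the
    first stop codon, which is appended as the stop symbol ``*``.  If no stop
    codon occurs before the end of the sequence the open translation is
    returned unterminated, with a warning: the downstream encoder pads either
    way.

    Raises
    ------
    NoInitiationCodonError
        If the sequence contains no ATG.
    """
    start = nt.find("ATG")
    if start < 0:
        raise NoInitiationCodonError("no ATG initiation codon found")
    frame = nt[start:]
    frame = frame[: len(frame) - len(frame) % 3]
    aa = str(Seq(frame).translate(table="Standard"))
    stop = aa.find(STOP_SYMBOL)
    if stop < 0:
        warnings.warn("no stop codon found; returning unterminated translation")
        return aa
    return aa[: stop + 1]


def descriptor_from_breakpoints(
    t5: TranscriptModel,
    t3: TranscriptModel,
    bp5: Breakpoint,
    bp3: Breakpoint,
    insert_seq: str = "",
    include_breakpoint_base_5p: bool = True,
) -> FusionDescriptor:
    """Resolve genomic breakpoints against the two isoforms into a descriptor.

    By convention the 5' breakpoint base is the last retained nucleotide of the
    5' partner and the 3' breakpoint base is the first retained nucleotide of
    the 3' partner; ``include_breakpoint_base_5p=False`` excludes the 5'
    breakpoint base instead (source catalogues differ on this point).
    """
    off5 = genomic_to_transcript_offset(t5, bp5.genomic_pos)
    if include_breakpoint_base_5p:
        off5 += 1
    off3 = genomic_to_transcript_offset(t3, bp3.genomic_pos)
    return FusionDescriptor(t5=t5, t3=t3, off5=off5, off3=off3, insert_seq=insert_seq)


def enumerate_isoform_fusions(
    gene5_isoforms: list[TranscriptModel],
    gene3_isoforms: list[TranscriptModel],
    bp5: Breakpoint,
    bp3: Breakpoint,
    insert_seq: str = "",
) -> list[FusionDescriptor]:
    """Cross all coding isoform pairs of the two genes against the breakpoints.

    Non-coding isoforms are discarded; isoforms for which a breakpoint is not
    exonic are skipped with a log message.  An empty result is valid and
    reported as a warning.
    """
    if not gene5_isoforms or not gene3_isoforms:
        raise ValueError("isoform lists must be non-empty")
    out: list[FusionDescriptor] = []
    for t5 in gene5_isoforms:
        if not t5.coding:
            continue
        for t3 in gene3_isoforms:
            if not t3.coding:
                continue
            try:
                out.append(descriptor_from_breakpoints(t5, t3, bp5, bp3, insert_seq))
            except PositionNotExonicError as exc:
                logger.info("skipping isoform pair (%s, %s): %s", t5.transcript_id, t3.transcript_id, exc)
    if not out:
        warnings.warn("no coding isoform pair is compatible with the breakpoints")
    return out


def reconstruct_proteins(
    fusion_id: str, descriptors: list[FusionDescriptor]
) -> list[FusionProtein]:
    """Translate every descriptor and deduplicate identical protein products.

    Different isoform pairs of one event frequently yield byte-identical
    proteins; only the first descriptor per distinct sequence is kept.
    Descriptors whose chimera lacks an initiation codon are skipped.
    """
    seen: dict[str, FusionProtein] = {}
    for i, fd in enumerate(descriptors):
        try:
            aa = translate_to_protein(build_chimeric_cds(fd))
        except NoInitiationCodonError:
            logger.info("descriptor %d of %s has no initiation codon; skipped", i, fusion_id)
            continue
        if aa not in seen:
            suffix = "" if not seen else f".{len(seen)}"
            seen[aa] = FusionProtein(
                fusion_id=f"{fusion_id}{suffix}",
                gene5=fd.t5.gene_id,
                gene3=fd.t3.gene_id,
                aa_seq=aa,
                source=fd,
            )
    return list(seen.values())
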