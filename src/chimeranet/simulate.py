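"""Desk-scale synthetic data with the structure the pipeline assumes.

Two generators are provided.  ``generate_toy_genome`` emits a miniature
annotated genome — multi-exon coding transcripts on both strands with their
contig sequences — in the same FASTA/GTF formats the reconstruction stage
consumes, so coordinate arithmetic can be verified exhaustively.

``generate_motif_dataset`` emits labelled fusion proteins in which the
oncogenic class carries a planted local sequence motif at a random position
with configurable probability, over a shared background composition and an
identical length distribution for both classes.  Gene partners are drawn
within small blocks of the gene pool, so genes recur across fusions and the
gene co-occurrence graph has non-trivial — but bounded — connected
components; this exercises the leakage-control machinery while keeping
group-disjoint splits feasible, as in real catalogues where most partner
genes participate in only a handful of fusions.
The planted motif emulates the local, position-independent discriminative
patterns a convolutional classifier is built to find; real fusion data differ
in having homology structure, domain grammar and non-uniform residue usage,
none of which are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledFusion
from .encoding import AMINO_ACIDS
from .reconstruction import ExonRecord, TranscriptModel

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [c for c in _CODONS if c not in _STOP_CODONS and c != "ATG"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticToyGenome:
    """A handful of coding genes, one contig each, both strands represented."""

    contigs: dict[str, str]
    transcripts: list[TranscriptModel]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n{self.contigs[name]}\n")

    def to_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for tm in self.transcripts:
                for exon in sorted(tm.exons, key=lambda e: e.start):
                    attrs = f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}";'
                    fh.write(
                        f"{exon.chrom}\tchimeranet_sim\texon\t{exon.start}\t{exon.end}"
                        f"\t.\t{tm.strand}\t.\t{attrs}\n"
                    )


def generate_toy_genome(n_genes: int = 4, seed: int = 0) -> SyntheticToyGenome:
    """Simulate coding genes with 2-5 exons each; odd-indexed genes are minus-strand.

    Every transcript starts with ATG, ends with a stop codon and has no
    in-frame internal stop, so it always translates cleanly.  Deterministic
    per seed.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2 so both strands are represented")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    for i in range(n_genes):
        gene_id = f"GEN{i + 1:04d}"
        tid = f"{gene_id}.t1"
        contig = f"ctg{i + 1}"
        strand = "-" if i % 2 else "+"
        n_codons = int(rng.integers(40, 161))
        cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2)) + str(rng.choice(_STOP_CODONS))
        n_exons = int(rng.integers(2, 6))
        cuts = np.sort(rng.choice(np.arange(10, len(cds) - 10), size=n_exons - 1, replace=False))
        chunks = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]

        flank5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 51))))
        layout, coords, pos = [flank5], [], len(flank5) + 1
        for j, chunk in enumerate(chunks):
            coords.append((pos, pos + len(chunk) - 1))
            layout.append(chunk)
            pos += len(chunk)
            if j < len(chunks) - 1:
                intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 101))))
                layout.append(intron)
                pos += len(intron)
        layout.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 51)))))
        layout_seq = "".join(layout)
        length = len(layout_seq)

        if strand == "+":
            contig_seq = layout_seq
            exons = [ExonRecord(contig, s, e, "+", tid) for s, e in coords]
        else:
            contig_seq = _revcomp(layout_seq)
            exons = [
                ExonRecord(contig, length - e + 1, length - s + 1, "-", tid) for s, e in coords
            ]
        contigs[contig] = contig_seq
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                strand=strand,
                exons=exons,
                spliced_seq=cds,
                coding=True,
            )
        )
    return SyntheticToyGenome(contigs=contigs, transcripts=transcripts)


def make_fusion_table(genome: SyntheticToyGenome, n_fusions: int = 6, seed: int = 0):
    """Draw random exonic breakpoint pairs from a toy genome as a fusion table.

    Returns a DataFrame in the pipeline's breakpoint-TSV schema; occasional
    rows carry a short templated insertion across the junction.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    tms = genome.transcripts
    for i in range(n_fusions):
        t5, t3 = (tms[j] for j in rng.choice(len(tms), size=2, replace=False))
        e5 = t5.exons[int(rng.integers(len(t5.exons)))]
        e3 = t3.exons[int(rng.integers(len(t3.exons)))]
        insert = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 3)) * 3))
        rows.append(
            {
                "fusion_id": f"FUS{i + 1:03d}",
                "gene5": t5.gene_id,
                "transcript5": t5.transcript_id,
                "chrom5": e5.chrom,
                "pos5": int(rng.integers(e5.start, e5.end + 1)),
                "gene3": t3.gene_id,
                "transcript3": t3.transcript_id,
                "chrom3": e3.chrom,
                "pos3": int(rng.integers(e3.start, e3.end + 1)),
                "insert_seq": insert,
                "label": "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SyntheticSpec:
    """Conditions for the planted-motif fusion-protein generator.

    Lengths follow a log-normal (median ≈ 400 residues, a typical scale for
    reconstructed fusion products) truncated to [50, 5000]; both classes draw
    from the same distribution.  With probability ``motif_prob`` an Onco
    sequence becomes a motif carrier: it receives at least one copy of a
    contiguous k-mer motif (k in 5-12), with the copy count drawn as
    Poisson(length x ``motif_density``), each copy overwritten at a uniform
    random position.  The repeated-motif array mimics the distributed,
    domain-like signal (repeat arrays, zinc-finger stretches) that separates
    functional classes of real proteins; an isolated single occurrence is
    deliberately not the default, since a needle-in-a-haystack signal is not
    recoverable by a flatten-plus-dense convolutional architecture at this
    sample size.  The background is uniform over the 20 amino acids unless
    explicit frequencies are given.
    """

    n_per_class: int = 300
    length_meanlog: float = 6.0
    length_sdlog: float = 0.6
    min_length: int = 50
    max_length: int = 5000
    motifs: tuple[str, ...] = ("HWKDECYR",)
    motif_prob: float = 0.9
    motif_density: float = 0.05  # expected motif copies per residue in carriers
    background_freqs: dict[str, float] | None = None
    n_genes: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must lie in [0, 1]")
        if self.motif_density <= 0.0:
            raise ValueError("motif_density must be positive")
        for m in self.motifs:
            if not 5 <= len(m) <= 12:
                raise ValueError(f"motif length must be 5-12, got {len(m)} for {m!r}")
            if len(m) > self.min_length:
                raise ValueError("motif longer than the minimum sequence length")
            if set(m) - set(AMINO_ACIDS):
                raise ValueError(f"motif {m!r} contains non-amino-acid symbols")


def _sample_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    for _ in range(1000):
        l = int(round(rng.lognormal(spec.length_meanlog, spec.length_sdlog)))
        if spec.min_length <= l <= spec.max_length:
            return l
    return int(np.clip(l, spec.min_length, spec.max_length))


def generate_motif_dataset(spec: SyntheticSpec) -> list[LabeledFusion]:
    """Draw ``n_per_class`` labelled fusion proteins per class.

    Gene partners are sampled within blocks of ~4 genes, so genes recur
    across fusions while connected components stay small; gene pairs never
    straddle the two classes.  Roughly 30% of fusions are flagged recurrent.
    Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    if spec.background_freqs is None:
        probs = np.full(len(aas), 1.0 / len(aas))
    else:
        probs = np.array([spec.background_freqs.get(a, 0.0) for a in aas])
        probs = probs / probs.sum()
    genes = [f"GEN{i + 1:04d}" for i in range(spec.n_genes)]
    block_size = 4
    blocks = [genes[i : i + block_size] for i in range(0, spec.n_genes, block_size)]
    blocks = [b for b in blocks if len(b) >= 2]

    used_pairs: dict[tuple[str, str], str] = {}
    out: list[LabeledFusion] = []
    idx = 0
    for label in ("Onco", "NotOnco"):
        for _ in range(spec.n_per_class):
            for _try in range(1000):
                block = blocks[int(rng.integers(len(blocks)))]
                g5, g3 = rng.choice(block, size=2, replace=False)
                if used_pairs.get((g5, g3), label) == label:
                    break
            used_pairs[(g5, g3)] = label
            length = _sample_length(spec, rng)
            seq = rng.choice(aas, size=length, p=probs)
            if label == "Onco" and rng.random() < spec.motif_prob:
                motif = spec.motifs[int(rng.integers(len(spec.motifs)))]
                n_copies = max(1, int(rng.poisson(length * spec.motif_density)))
                for _ in range(n_copies):
                    pos = int(rng.integers(0, length - len(motif) + 1))
                    seq[pos : pos + len(motif)] = list(motif)
            idx += 1
            out.append(
                LabeledFusion(
                    fusion_id=f"SYN{idx:05d}",
                    gene5=str(g5),
                    gene3=str(g3),
                    aa_seq="".join(seq) + "*",
                    label=label,
                    recurrent=bool(rng.random() < 0.3),
                )
            )
    return out
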