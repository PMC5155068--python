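"""Methyltransferase recognition-site scanning and inter-site gap statistics.

Finds all occurrences of a (possibly degenerate) IUPAC motif on both strands
of a genome, reports the coordinate of the *modified* base (the Dam/EcoK
adenine, the second Dcm cytosine) in forward 1-based coordinates, and computes
the spacing between consecutive duplex occurrences — relevant to MutH strand
discrimination, which fails in hypomethylated regions longer than ~1 kb.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Built-in motif definitions: name -> (IUPAC pattern, 0-based offset of the
#: modified base within the pattern).  EcoK's two printed recognition
#: sequences (AAC-N6-GTGC and GCAC-N6-GTT) are reverse complements of one
#: another, so a double-strand scan of either finds both.
BUILTIN_MOTIFS: dict[str, tuple[str, int]] = {
    "Dam_GATC": ("GATC", 1),
    "Dcm_CCWGG": ("CCWGG", 1),
    "EcoK": ("AACNNNNNNGTGC", 1),
}


@dataclass(frozen=True)
class GenomeSequence:
    """A DNA sequence with an identifier and topology flag."""

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("genome sequence must be non-empty")
        seq = self.residues.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in genome: {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class MotifSite:
    """A modified-base position: 1-based forward coordinate plus strand."""

    genome_id: str
    position: int
    strand: str
    motif_name: str = ""
    matched_text: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.position < 1:
            raise ValueError("position is 1-based; must be >= 1")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.strand)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    parts = []
    for ch in pattern.upper():
        try:
            opts = IUPAC_CODES[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {pattern!r}") from None
        # N in the genome matches only an explicit N in the motif.
        parts.append(ch if len(opts) == 1 else "[" + opts + "]")
    # Lookahead so overlapping occurrences are all found.
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    genome: GenomeSequence,
    motif: str,
    modified_offset: int,
    motif_name: str | None = None,
) -> list[MotifSite]:
    """Scan both strands for ``motif``; report modified-base coordinates.

    Reverse-strand matches are located by scanning the reverse complement of
    the motif on the forward sequence and reflecting the offset.  Circular
    genomes are scanned with a ``len(motif) - 1`` wrap-around extension so
    origin-spanning matches are included.  Results are sorted by
    (position, strand).
    """
    L = len(motif)
    if L < 1:
        raise ValueError("motif must have length >= 1")
    if not (0 <= modified_offset < L):
        raise ValueError("modified_offset must lie within the motif")
    name = motif_name if motif_name is not None else motif

    seq = genome.residues
    n = len(seq)
    search_seq = seq + seq[: L - 1] if genome.circular and L > 1 else seq

    sites: list[MotifSite] = []
    for pat, strand in ((motif, "+"), (reverse_complement(motif), "-")):
        rx = _iupac_regex(pat)
        for m in rx.finditer(search_seq):
            start = m.start()
            if start >= n:  # wrap-extension duplicate
                continue
            if strand == "+":
                pos0 = start + modified_offset
            else:
                pos0 = start + (L - 1 - modified_offset)
            sites.append(
                MotifSite(
                    genome_id=genome.id,
                    position=pos0 % n + 1,
                    strand=strand,
                    motif_name=name,
                    matched_text=m.group(1),
                )
            )
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def collapse_to_duplex(sites: Sequence[MotifSite]) -> list[int]:
    """Collapse stranded sites to unique duplex positions (sorted).

    For palindromic motifs each duplex occurrence carries one site per
    strand; gap statistics count the occurrence once, anchored at the
    forward-strand modified-base coordinate.
    """
    plus = sorted({s.position for s in sites if s.strand == "+"})
    if plus:
        return plus
    return sorted({s.position for s in sites})


def gap_lengths(sites: Sequence[MotifSite], genome: GenomeSequence) -> list[int]:
    """Distances between consecutive duplex occurrences.

    Linear genomes yield ``n - 1`` gaps; circular genomes add the wrap-around
    gap for ``n`` total.
    """
    positions = collapse_to_duplex(sites)
    if not positions:
        raise ValueError("cannot compute gaps for an empty site list")
    gaps = [b - a for a, b in zip(positions, positions[1:])]
    if genome.circular:
        gaps.append(len(genome) - positions[-1] + positions[0])
    return gaps


def count_long_gaps(gaps: Iterable[int], threshold: int) -> int:
    """Number of gaps strictly greater than ``threshold`` bp."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return sum(1 for g in gaps if g > threshold)


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [GenomeSequence(id=r.id, residues=str(r.seq), circular=circular) for r in records]


def write_sites_bed(sites: Sequence[MotifSite], path: str | Path) -> None:
    """Write sites as BED6 (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.genome_id}\t{s.position - 1}\t{s.position}\t"
                f"{s.motif_name or '.'}\t.\t{s.strand}\n"
            )


def read_sites_bed(path: str | Path) -> list[MotifSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            sites.append(
                MotifSite(genome_id=chrom, position=int(start) + 1, strand=strand, motif_name=name)
            )
    return sites
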