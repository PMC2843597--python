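"""Pairwise whole-genome alignments: loading, coordinate projection, and
column-level divergence statistics.

A :class:`PairwiseGenomeAlignment` is an ordered set of two-row alignment
blocks forming a one-to-one orthology map between two genomes.  All
coordinates are 0-based, half-open, and on the forward strand; MAF's
start/size and reverse-strand conventions are converted on read.  Blocks
must not overlap within a genome — overlapping blocks would make orthology
ambiguous and are rejected at construction time, mirroring the upstream
practice of discarding regions with duplicated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import AlignIO
from intervaltree import IntervalTree

GAP = ord("-")

__all__ = [
    "AlignmentBlock",
    "PairwiseGenomeAlignment",
    "ColumnStats",
    "NoAlignmentError",
    "read_maf",
    "write_maf",
]


class NoAlignmentError(ValueError):
    """Raised when an interval has no aligned columns at all."""


@dataclass(frozen=True)
class ColumnStats:
    """Per-interval alignment divergence summary.

    Attributes
    ----------
    identity_fraction : float
        Fraction of match/mismatch columns (both rows ungapped) whose bases
        agree, case-insensitively.  In [0, 1].
    indel_frequency : float
        Gap-opening events (maximal gap runs in either row) per aligned
        column spanned by the interval.
    n_columns : int
        Number of alignment columns spanned.
    """

    identity_fraction: float
    indel_frequency: float
    n_columns: int


class AlignmentBlock:
    """One gapped two-row alignment block.

    Parameters
    ----------
    genomes : (str, str)
        Labels of the two genomes, in row order.
    chroms, starts, strands, texts : dict
        Per-genome chromosome name, forward-strand 0-based start, strand
        (+1/-1), and aligned row text (bases plus ``-`` gaps).  Rows must
        have equal length and each row's ungapped length defines its span.
    """

    def __init__(self, genomes, chroms, starts, strands, texts):
        self.genomes = tuple(genomes)
        if len(self.genomes) != 2 or len(set(self.genomes)) != 2:
            raise ValueError("a block needs exactly two distinct genomes")
        self.chroms = dict(chroms)
        self.starts = dict(starts)
        self.strands = {g: strands.get(g, 1) for g in self.genomes}
        self.texts = {g: str(texts[g]) for g in self.genomes}
        lengths = {len(t) for t in self.texts.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        (self.n_columns,) = lengths
        self._arr = {
            g: np.frombuffer(self.texts[g].encode("ascii"), dtype=np.uint8)
            for g in self.genomes
        }
        self._positions = {}
        for g in self.genomes:
            arr = self._arr[g]
            nongap = arr != GAP
            size = int(nongap.sum())
            if size == 0:
                raise ValueError(f"block row for {g} is all gaps")
            idx = np.cumsum(nongap) - 1
            if self.strands[g] >= 0:
                pos = self.starts[g] + idx
            else:
                # forward coordinates descend along reverse-strand rows
                pos = self.starts[g] + size - 1 - idx
            pos = np.where(nongap, pos, -1)
            self._positions[g] = pos.astype(np.int64)
            self._sizes = getattr(self, "_sizes", {})
            self._sizes[g] = size

    def span(self, genome: str) -> tuple[int, int]:
        """Forward-strand half-open interval covered in `genome`."""
        return self.starts[genome], self.starts[genome] + self._sizes[genome]

    def positions(self, genome: str) -> np.ndarray:
        """Per-column forward position in `genome`; -1 at gap columns."""
        return self._positions[genome]

    def row_bytes(self, genome: str) -> np.ndarray:
        return self._arr[genome]

    def other(self, genome: str) -> str:
        a, b = self.genomes
        if genome == a:
            return b
        if genome == b:
            return a
        raise ValueError(f"unknown genome {genome!r}")


class PairwiseGenomeAlignment:
    """Block-structured coordinate map between two genomes.

    Maintains, per genome and chromosome, an interval index from positions
    to blocks.  Blocks overlapping within a genome raise ``ValueError``.
    """

    def __init__(self, blocks: Sequence[AlignmentBlock]):
        blocks = list(blocks)
        if not blocks:
            raise ValueError("alignment has no blocks")
        self.genomes = blocks[0].genomes
        gset = set(self.genomes)
        for b in blocks:
            if set(b.genomes) != gset:
                raise ValueError("inconsistent genome labels across blocks")
        self.blocks = blocks
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for b in blocks:
            for g in self.genomes:
                key = (g, b.chroms[g])
                tree = self._trees.setdefault(key, IntervalTree())
                s, e = b.span(g)
                if tree.overlap(s, e):
                    raise ValueError(
                        f"overlapping blocks in {g} {b.chroms[g]}:{s}-{e}"
                    )
                tree.addi(s, e, b)

    def other(self, genome: str) -> str:
        a, b = self.genomes
        if genome == a:
            return b
        if genome == b:
            return a
        raise ValueError(f"unknown genome {genome!r}")

    def chromosomes(self, genome: str) -> list[str]:
        self.other(genome)  # validates the label
        return sorted({c for (g, c) in self._trees if g == genome})

    def _check(self, genome: str, chrom: str) -> None:
        self.other(genome)
        if (genome, chrom) not in self._trees:
            raise ValueError(f"unknown chromosome {chrom!r} in genome {genome!r}")

    def blocks_overlapping(self, genome, chrom, start, end):
        self._check(genome, chrom)
        ivs = sorted(self._trees[(genome, chrom)].overlap(start, end))
        return [iv.data for iv in ivs]

    def project_interval(self, genome, chrom, start, end):
        """Map a half-open interval onto the other genome.

        Returns ``(intervals, coverage)`` where `intervals` is a sorted
        list of non-overlapping ``(chrom, start, end)`` tuples in the other
        genome, and `coverage` is the fraction of the query's bases sitting
        in columns aligned to a base (not a gap) of the other genome.
        """
        if not (0 <= start < end):
            raise ValueError("require 0 <= start < end")
        other = self.other(genome)
        self._check(genome, chrom)
        aligned_cols = 0
        pieces: list[tuple[str, int, int]] = []
        for b in self.blocks_overlapping(genome, chrom, start, end):
            src = b.positions(genome)
            tgt = b.positions(other)
            sel = (src >= start) & (src < end)
            hit = sel & (tgt >= 0)
            aligned_cols += int(hit.sum())
            tpos = np.sort(tgt[hit])
            if tpos.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(tpos) != 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [tpos.size - 1]))
            tchrom = b.chroms[other]
            for i, j in zip(starts, ends):
                pieces.append((tchrom, int(tpos[i]), int(tpos[j]) + 1))
        pieces.sort()
        merged: list[tuple[str, int, int]] = []
        for c, s, e in pieces:
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                merged[-1] = (c, merged[-1][1], max(e, merged[-1][2]))
            else:
                merged.append((c, s, e))
        return merged, aligned_cols / (end - start)

    def column_stats(self, genome, chrom, start, end) -> ColumnStats:
        """Identity and gap-opening statistics over the columns spanning an
        interval.

        The span in each block runs from the first to the last column whose
        `genome` position falls in ``[start, end)``, so gap columns strictly
        inside the interval are included.  Identity is computed over
        match/mismatch columns only; ``indel_frequency`` counts maximal gap
        runs (events), not gap columns.
        """
        other = self.other(genome)
        self._check(genome, chrom)
        matches = 0
        matchcols = 0
        openings = 0
        span_cols = 0
        for b in self.blocks_overlapping(genome, chrom, start, end):
            src = b.positions(genome)
            sel = np.flatnonzero((src >= start) & (src < end))
            if sel.size == 0:
                continue
            lo, hi = int(sel[0]), int(sel[-1]) + 1
            a = b.row_bytes(genome)[lo:hi]
            c = b.row_bytes(other)[lo:hi]
            span_cols += hi - lo
            both = (a != GAP) & (c != GAP)
            matchcols += int(both.sum())
            # case-insensitive base comparison (softmask carries no meaning here)
            au = np.where((a >= 97) & (a <= 122), a - 32, a)
            cu = np.where((c >= 97) & (c <= 122), c - 32, c)
            matches += int((both & (au == cu)).sum())
            for row in (a, c):
                gap = row == GAP
                if gap.any():
                    openings += int(gap[0]) + int(
                        (gap[1:] & ~gap[:-1]).sum()
                    )
        if span_cols == 0:
            raise NoAlignmentError(
                f"{genome} {chrom}:{start}-{end} has no aligned columns"
            )
        identity = matches / matchcols if matchcols else float("nan")
        return ColumnStats(identity, openings / span_cols, span_cols)


def _split_src(name: str) -> tuple[str, str]:
    if "." not in name:
        raise ValueError(f"MAF src {name!r} is not of the form genome.chrom")
    g, c = name.split(".", 1)
    return g, c


def read_maf(path) -> PairwiseGenomeAlignment:
    """Load a two-species MAF file.

    Every block must contain exactly two ``s`` rows.  Reverse-strand rows
    are normalized to forward coordinates at load time.  Overlapping blocks
    within a genome raise ``ValueError``.
    """
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        if len(msa) != 2:
            raise ValueError(
                f"expected exactly 2 rows per MAF block, got {len(msa)}"
            )
        chroms, starts, strands, texts = {}, {}, {}, {}
        genomes = []
        for rec in msa:
            g, c = _split_src(rec.id)
            if g in chroms:
                raise ValueError(f"duplicate genome {g!r} within a block")
            genomes.append(g)
            ann = rec.annotations
            start, size = int(ann["start"]), int(ann["size"])
            strand = int(ann["strand"])
            if strand < 0:
                start = int(ann["srcSize"]) - start - size
            chroms[g], starts[g], strands[g] = c, start, strand
            texts[g] = str(rec.seq)
        blocks.append(AlignmentBlock(genomes, chroms, starts, strands, texts))
    return PairwiseGenomeAlignment(blocks)


def write_maf(aln: PairwiseGenomeAlignment, path, header_comment: str | None = None):
    """Write an alignment as MAF (forward-strand rows only)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\n")
        src_sizes: dict[tuple[str, str], int] = {}
        for b in aln.blocks:
            for g in aln.genomes:
                key = (g, b.chroms[g])
                src_sizes[key] = max(src_sizes.get(key, 0), b.span(g)[1])
        for b in aln.blocks:
            fh.write("a\n")
            for g in b.genomes:
                s, e = b.span(g)
                fh.write(
                    "s {src} {start} {size} + {srcsize} {text}\n".format(
                        src=f"{g}.{b.chroms[g]}",
                        start=s,
                        size=e - s,
                        srcsize=src_sizes[(g, b.chroms[g])],
                        text=b.texts[g],
                    )
                )
            fh.write("\n")
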