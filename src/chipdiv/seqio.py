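"""Small genome-sequence IO helpers (case-preserving FASTA)."""

from __future__ import annotations

from Bio import SeqIO

__all__ = ["read_fasta", "chrom_lengths"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {chromosome: sequence}, preserving case
    (lowercase marks softmasked sequence)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def chrom_lengths(seqs: dict[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in seqs.items()}
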