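"""Toy circular genomes and marker-bearing reads with a replication gradient.

Actively replicating bacterial chromosomes are over-represented near the
replication origin: with a log2 peak-to-trough ratio rho, steady-state
coverage follows ``coverage(x) ∝ 2^(rho * (1 - 2 d(x)))`` where d(x) in
[0, 0.5] is the circular distance from the origin as a fraction of genome
length.  The generator plants an origin marker (a dnaA-like
replication-initiator coding sequence) at the origin and a 28-bp dif-like
site at the terminus, samples read start positions from the coverage law,
and applies substitution errors — everything the origin:terminus growth
estimator needs, with rho as the known ground truth.

The marker sequences shipped here are synthetic stand-ins (fixed arbitrary
sequences, not database entries); real scans accept any protein/motif FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SYNTHETIC_DNAA_PEPTIDE",
    "SYNTHETIC_DIF_MOTIF",
    "GenomeModel",
    "simulate_marker_reads",
    "write_fasta",
    "write_fastq",
]

# Synthetic 120-residue replication-initiator-like peptide (arbitrary fixed
# sequence over the 20-letter alphabet; NOT a RefSeq dnaA entry).
SYNTHETIC_DNAA_PEPTIDE = (
    "MSLWQKCLEHIRDNVPAQSYKTWFAGIEPLSVQDNTLRIYAPNEFARDWLESHYSDLITE"
    "TLRKVAGQPVKLEFIVSPRAGNGERPAQMDWNKHTYGSNVLNPKYTFDTFVIGKGNQMAH"
)

# Synthetic 28-bp chromosome-dimer-resolution-like site (NOT a curated dif).
SYNTHETIC_DIF_MOTIF = "AGTACGCATAATGTATATTATGTTAAAT"

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTC", "P": "CCG", "S": "TCT", "T": "ACC", "W": "TGG",
    "Y": "TAC", "V": "GTT",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode_peptide(peptide: str) -> str:
    return "".join(_CODON[a] for a in peptide)


@dataclass
class GenomeModel:
    """A circular toy genome with origin/terminus markers and a per-sample
    replication gradient rho (log2 origin:terminus coverage ratio)."""

    length: int = 20_000
    origin_position: int = 0
    terminus_position: int | None = None  # default: antipodal
    dnaa_peptide: str = SYNTHETIC_DNAA_PEPTIDE
    dif_site: str = SYNTHETIC_DIF_MOTIF
    rho: float = 0.0
    seed: int = 0
    sequence: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.terminus_position is None:
            self.terminus_position = (self.origin_position + self.length // 2) % self.length
        if len(self.dif_site) != 28:
            raise ValueError("dif site must be 28 bp")
        if not self.sequence:
            rng = np.random.default_rng(self.seed)
            seq = rng.choice(list("ACGT"), size=self.length)
            cds = _encode_peptide(self.dnaa_peptide)
            for offset, char in enumerate(cds):
                seq[(self.origin_position + offset) % self.length] = char
            for offset, char in enumerate(self.dif_site):
                seq[(self.terminus_position + offset) % self.length] = char
            self.sequence = "".join(seq)

    def coverage_weights(self) -> np.ndarray:
        """Un-normalized coverage at every position: 2^(rho * (1 - 2 d))."""
        pos = np.arange(self.length)
        raw = np.abs(pos - self.origin_position)
        d = np.minimum(raw, self.length - raw) / self.length  # in [0, 0.5]
        return 2.0 ** (self.rho * (1.0 - 2.0 * d))


def simulate_marker_reads(
    genome: GenomeModel,
    n_reads: int = 20_000,
    read_length: int = 150,
    error_rate: float = 0.005,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Sample reads from the genome's circular coverage law.

    Read start positions are drawn proportional to the coverage weights;
    reads wrap around the circle; substitutions are applied uniformly at
    ``error_rate`` per base.  Returns (read id, sequence) pairs.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if read_length >= genome.length:
        raise ValueError("read length must be shorter than the genome")
    rng = np.random.default_rng(seed)
    w = genome.coverage_weights()
    starts = rng.choice(genome.length, size=n_reads, p=w / w.sum())
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    doubled = np.concatenate([seq, seq])  # wraparound without modular indexing
    reads = []
    for i, s in enumerate(starts):
        read = doubled[s : s + read_length].copy()
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            if len(errs):
                # substitute with one of the three other bases
                lut = np.zeros(256, dtype=np.uint8)
                lut[_BASES] = np.arange(4)
                idx = lut[read[errs]]
                read[errs] = _BASES[(idx + rng.integers(1, 4, size=len(errs))) % 4]
        reads.append((f"read_{i + 1}", read.tobytes().decode()))
    return reads


def write_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(reads: list[tuple[str, str]], path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")
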