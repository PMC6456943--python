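"""Quaternary K-mer encoding and slot-indexed indicator vectors.

A K-mer over {A, C, G, T} is read as a base-4 integer (A=0, C=1, G=2, T=3,
first base most significant).  To keep ciphertext spaces small, K-mers are
split into ``B = ceil(K / L)`` blocks of ``L`` bases each and every block is
encoded separately.  The ``b``-th blocks of up to ``N`` user K-mers are packed
into one binary indicator vector ``v_b`` of length ``slots``::

    v_b[i] = 1  iff  i = value(K-mer n, block b) * N + n   for some n < N

which is injective because ``n < N``.  Matching a panel block value ``V`` then
amounts to rotating ``v_b`` by ``N * V``: slot ``n`` of the rotated vector is
1 exactly when user K-mer ``n`` agrees with the panel K-mer on block ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import EncodingError

__all__ = [
    "BlockSpec",
    "EncodedVectors",
    "to_quaternary_int",
    "split_blocks",
    "block_values",
    "choose_slots",
    "build_indicator_vectors",
    "kmerize_reads",
    "revcomp",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

# byte -> code lookup; 255 marks anything outside {A,C,G,T}
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in _CODE.items():
    _LUT[ord(_b)] = _v

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def seq_codes(seq: str) -> np.ndarray:
    """Sequence -> uint8 code array; 255 for ambiguous bases."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def to_quaternary_int(kmer: str) -> int:
    """Base-4 value of a K-mer, first base most significant.

    >>> to_quaternary_int("GACT")
    135
    """
    codes = seq_codes(kmer)
    if codes.size == 0 or np.any(codes == 255):
        raise EncodingError(f"K-mer contains non-ACGT symbols: {kmer!r}")
    val = 0
    for c in codes:
        val = val * 4 + int(c)
    return val


def split_blocks(kmer: str, L: int) -> list[str]:
    """Split into ``ceil(K/L)`` blocks of size ``L``; the last block is
    right-padded with 'A' (value 0), matching the panel-side padding."""
    if L < 1:
        raise ValueError("block size L must be >= 1")
    B = -(-len(kmer) // L)
    padded = kmer + "A" * (B * L - len(kmer))
    return [padded[b * L : (b + 1) * L] for b in range(B)]


def block_values(kmer: str, L: int) -> tuple[int, ...]:
    """Base-4 value of every block of the K-mer."""
    return tuple(to_quaternary_int(b) for b in split_blocks(kmer, L))


def choose_slots(L: int, N: int, max_slots: int | None = None) -> int:
    """Smallest power of two that fits every index ``value*N + n < 4^L * N``."""
    if L < 1 or N < 1:
        raise ValueError("L and N must be >= 1")
    need = 4**L * N
    slots = 1 << (need - 1).bit_length()
    if max_slots is not None and slots > max_slots:
        raise ValueError(
            f"{slots} slots needed for L={L}, N={N} exceed backend capacity "
            f"{max_slots}; split the batch or lower L"
        )
    return slots


@dataclass(frozen=True)
class BlockSpec:
    """Geometry of the block encoding: K-mer length ``K``, block size ``L``,
    block count ``B``, batch size ``N`` and indicator-vector length ``slots``."""

    K: int
    L: int
    N: int
    B: int
    slots: int

    @classmethod
    def design(cls, K: int, L: int, N: int, max_slots: int | None = None) -> "BlockSpec":
        B = -(-K // L)
        return cls(K=K, L=L, N=N, B=B, slots=choose_slots(L, N, max_slots))

    def to_dict(self) -> dict:
        return {"K": self.K, "L": self.L, "N": self.N, "B": self.B, "slots": self.slots}

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSpec":
        return cls(**{k: int(d[k]) for k in ("K", "L", "N", "B", "slots")})


@dataclass
class EncodedVectors:
    """The ``B`` indicator vectors for one batch of user K-mers."""

    vectors: np.ndarray  # (B, slots) int64 over {0, 1}
    spec: BlockSpec
    kmer_order: tuple[str, ...]  # K-mer assigned to each n index

    def decode_block_values(self) -> list[tuple[int, ...]]:
        """Recover every K-mer's block values from the set bits (inverse map)."""
        N = self.spec.N
        out = [[None] * self.spec.B for _ in self.kmer_order]
        for b in range(self.spec.B):
            for i in np.flatnonzero(self.vectors[b]):
                n = int(i) % N
                if n < len(self.kmer_order):
                    out[n][b] = int(i) // N
        return [tuple(row) for row in out]


def _batch_block_values(kmers: Sequence[str], spec: BlockSpec) -> np.ndarray:
    """(n_kmers, B) block values, vectorised."""
    if not kmers:
        return np.zeros((0, spec.B), dtype=np.int64)
    bad = {len(k) for k in kmers} - {spec.K}
    if bad:
        raise EncodingError(f"expected {spec.K}-mers, got length(s) {sorted(bad)}")
    codes = np.stack([seq_codes(k) for k in kmers]).astype(np.int64)
    if np.any(codes == 255):
        raise EncodingError("user K-mers must not contain ambiguous bases")
    pad = spec.B * spec.L - spec.K
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((len(kmers), pad), dtype=np.int64)], axis=1
        )
    weights = 4 ** np.arange(spec.L - 1, -1, -1, dtype=np.int64)
    return codes.reshape(len(kmers), spec.B, spec.L) @ weights


def build_indicator_vectors(user_kmers: Sequence[str], spec: BlockSpec) -> EncodedVectors:
    """Pack up to ``N`` user K-mers into the ``B`` indicator vectors.

    With fewer than ``N`` K-mers the unused ``n`` slots stay all-zero, so they
    can never contribute to a match count.
    """
    if len(user_kmers) > spec.N:
        raise ValueError(f"batch holds at most N={spec.N} K-mers, got {len(user_kmers)}")
    vals = _batch_block_values(user_kmers, spec)  # (nk, B)
    vectors = np.zeros((spec.B, spec.slots), dtype=np.int64)
    n_idx = np.arange(len(user_kmers))
    for b in range(spec.B):
        vectors[b, vals[:, b] * spec.N + n_idx] = 1
    return EncodedVectors(vectors=vectors, spec=spec, kmer_order=tuple(user_kmers))


def kmerize_reads(
    reads: Iterable[str], K: int, include_reverse_complement: bool = True
) -> list[str]:
    """All stride-1 windows of length ``K`` from each read (and, by default,
    from its reverse complement).  Windows containing 'N' are dropped;
    duplicates are retained so that match counts reflect coverage."""
    out: list[str] = []
    for read in reads:
        seqs = (read, revcomp(read)) if include_reverse_complement else (read,)
        for seq in seqs:
            if len(seq) < K:
                continue
            codes = seq_codes(seq)
            bad = codes == 255
            if bad.any():
                # positions whose window would contain an ambiguous base
                kernel = np.convolve(bad.astype(np.int64), np.ones(K, dtype=np.int64))
                valid = kernel[K - 1 : len(seq)] == 0
            else:
                valid = np.ones(len(seq) - K + 1, dtype=bool)
            out.extend(seq[i : i + K] for i in np.flatnonzero(valid))
    return out
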