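"""Panel preprocessing and panel-specific K-mer length design.

A *panel* is a set of disease-associated SNP residues, each carried on its
flanking sequence.  Before the encrypted equality test can work, the panel
must satisfy two distinctness conditions at the chosen K-mer length ``K``:

(A) every pair of SNP-covering K-mers from *different* loci is separated by a
    Hamming distance greater than the Point Deviation Tolerance (PDT), and
(B) every background K-mer (a panel window covering no SNP, on either strand)
    is farther than PDT from every SNP-covering K-mer.

PDT generalises plain uniqueness (PDT = 0) to a safety margin: as long as a
patient K-mer deviates from the panel sequence in at most PDT positions, it
can never be mistaken for a different residue's K-mer.  The ref/alt pair at
one locus differs at exactly one position by construction; those same-locus
pairs are exempt from the conditions because telling them apart is the
assay's purpose, not a collision.

Residues whose flanking sequences overlap are merged into one entity when the
overlap is clean and short enough to be trusted (between ``full_overlap_cutoff``
and ``max_overlap`` base pairs, mismatch-free); any other overlap keeps one
randomly chosen survivor and discards the other residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import PanelDesignError
from .kmer_codec import revcomp, seq_codes

__all__ = [
    "SNPResidue",
    "PanelEntity",
    "Panel",
    "KmerRecord",
    "KmerSets",
    "KDesignResult",
    "hamming",
    "preprocess_panel",
    "kmerize_panel",
    "check_pdt_conditions",
    "find_min_k",
]

_NUCS = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SNPResidue:
    """One disease-associated SNP with its flanking sequence.

    ``pos`` is the 0-based genomic position of the variant base; ``flank5``
    and ``flank3`` are the upstream/downstream flanks (650 bp per side in the
    reference simulation design).
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    flank5: str
    flank3: str

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if a not in _NUCS:
                raise ValueError(f"{self.id}: allele {a!r} is not a nucleotide")
        for fl in (self.flank5, self.flank3):
            if set(fl) - _NUCS:
                raise ValueError(f"{self.id}: flanks must contain only ACGT")

    @property
    def start(self) -> int:
        """Genomic start of the flanked sequence."""
        return self.pos - len(self.flank5)

    @property
    def end(self) -> int:
        """Genomic end (inclusive) of the flanked sequence."""
        return self.pos + len(self.flank3)

    def sequence(self, allele: str | None = None) -> str:
        base = allele or self.ref_allele
        return self.flank5 + base + self.flank3


@dataclass(frozen=True)
class PanelEntity:
    """A contiguous panel sequence carrying one or more merged residues."""

    entity_id: str
    residues: tuple[SNPResidue, ...]
    sequence: str  # with reference alleles at every residue offset
    residue_offsets: tuple[int, ...]

    def __post_init__(self):
        offs = self.residue_offsets
        if any(o2 <= o1 for o1, o2 in zip(offs, offs[1:])):
            raise ValueError("residue offsets must be strictly increasing")
        if offs and (offs[0] < 0 or offs[-1] >= len(self.sequence)):
            raise ValueError("residue offset outside entity sequence")

    def allele_sequence(self, residue_index: int, allele: str) -> str:
        """Entity sequence with one residue switched to the given allele."""
        off = self.residue_offsets[residue_index]
        return self.sequence[:off] + allele + self.sequence[off + 1 :]


@dataclass
class Panel:
    """Surviving entities plus the log of discarded residues."""

    entities: list[PanelEntity]
    discarded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def N(self) -> int:
        """Number of surviving residues."""
        return sum(len(e.residues) for e in self.entities)

    def all_residues(self) -> list[SNPResidue]:
        return [r for e in self.entities for r in e.residues]


@dataclass(frozen=True)
class KmerRecord:
    """A panel K-mer labeled by origin."""

    seq: str
    entity_id: str
    residue_id: str | None
    allele: str  # 'ref' | 'alt' | 'background'
    offset: int  # 0-based start within the entity sequence (forward strand)
    strand: str = "+"


@dataclass
class KmerSets:
    """Panel K-mers split into SNP-covering set A and background set B."""

    K: int
    set_A: list[KmerRecord]
    set_B: list[KmerRecord]


@dataclass
class KDesignResult:
    """Outcome of the minimum-K search."""

    K: int
    PDT: int
    violations_at_K_minus_1: list[tuple[KmerRecord, KmerRecord, int]]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _overlap_len(prev_end: int, nxt: SNPResidue) -> int:
    """Genomic overlap (bp) between a running entity ending at ``prev_end``
    (inclusive) and the flanked sequence of the next residue."""
    return prev_end - nxt.start + 1


def preprocess_panel(
    residues: Iterable[SNPResidue],
    full_overlap_cutoff: int = 100,
    max_overlap: int = 150,
    seed: int = 0,
) -> Panel:
    """Merge cleanly overlapping residues; discard one of every other
    overlapping pair.

    Residues are processed in (chrom, pos) order.  A pair overlapping by
    ``v`` bp is merged into a single extended entity when
    ``full_overlap_cutoff <= v <= max_overlap`` and the overlapping substrings
    agree base-for-base.  Overlaps with a mismatch, or longer than
    ``max_overlap`` (beyond the read length, so unresolvable by short reads),
    keep one seeded-random survivor.  Every removal is logged in
    ``Panel.discarded``; residue count is conserved.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(residues, key=lambda r: (r.chrom, r.pos, r.id))
    entities: list[PanelEntity] = []
    discarded: list[tuple[str, str]] = []

    # runs of merged residues under construction, per chromosome sweep
    run: list[SNPResidue] = []
    run_seq = ""
    run_start = 0
    run_chrom = None

    def close_run():
        nonlocal run, run_seq
        if run:
            eid = "+".join(r.id for r in run)
            offsets = tuple(r.pos - run_start for r in run)
            entities.append(
                PanelEntity(
                    entity_id=eid,
                    residues=tuple(run),
                    sequence=run_seq,
                    residue_offsets=offsets,
                )
            )
        run, run_seq = [], ""

    for res in ordered:
        if not run or res.chrom != run_chrom:
            close_run()
            run, run_seq, run_start, run_chrom = [res], res.sequence(), res.start, res.chrom
            continue
        run_end = run_start + len(run_seq) - 1
        v = _overlap_len(run_end, res)
        if v <= 0:
            close_run()
            run, run_seq, run_start = [res], res.sequence(), res.start
            continue
        new_seq = res.sequence()
        clean = v <= len(run_seq) and v <= len(new_seq) and run_seq[-v:] == new_seq[:v]
        if clean and full_overlap_cutoff <= v <= max_overlap:
            run.append(res)
            run_seq = run_seq + new_seq[v:]
            continue
        # unmergeable overlap: keep one of (last residue in run, new residue)
        reason = (
            f"overlap {v} bp > {max_overlap} bp"
            if clean and v > max_overlap
            else f"overlap {v} bp with mismatch"
            if not clean
            else f"overlap {v} bp below merge cutoff {full_overlap_cutoff} bp"
        )
        last = run[-1]
        if rng.integers(2) == 0:  # keep the earlier residue
            discarded.append((res.id, reason))
        else:
            discarded.append((last.id, reason))
            if len(run) == 1:
                run, run_seq, run_start = [res], res.sequence(), res.start
            else:
                # drop the tail residue from the run, then restart with res
                run = run[:-1]
                tail_end = run[-1].end
                run_seq = run_seq[: tail_end - run_start + 1]
                close_run()
                run, run_seq, run_start = [res], res.sequence(), res.start
    close_run()
    return Panel(entities=entities, discarded=discarded)


# ---------------------------------------------------------------------------
# K-merization
# ---------------------------------------------------------------------------


def kmerize_panel(panel: Panel, K: int) -> KmerSets:
    """Slide a stride-1 window of length ``K`` over every entity sequence.

    Windows covering a residue offset go to set A, once per allele, labeled
    (residue, allele).  Set B holds every other window: the non-covering
    forward windows plus all reverse-complement windows of each allele
    version (patient reads come from both strands, so reverse-strand
    sequence must also keep its distance from set A).  B is deduplicated by
    string.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    set_A: list[KmerRecord] = []
    seen_b: dict[str, KmerRecord] = {}
    for ent in panel.entities:
        L = len(ent.sequence)
        if K > L:
            raise PanelDesignError(
                f"K={K} exceeds entity {ent.entity_id!r} length {L}"
            )
        for i, res in enumerate(ent.residues):
            off = ent.residue_offsets[i]
            if off < K - 1 or off + K > L:
                raise PanelDesignError(
                    f"residue {res.id!r} sits closer than K={K} to the edge of "
                    f"entity {ent.entity_id!r}; extend the flanks"
                )
            for allele_name, base in (("ref", res.ref_allele), ("alt", res.alt_allele)):
                seq_a = ent.allele_sequence(i, base)
                for start in range(off - K + 1, off + 1):
                    set_A.append(
                        KmerRecord(
                            seq=seq_a[start : start + K],
                            entity_id=ent.entity_id,
                            residue_id=res.id,
                            allele=allele_name,
                            offset=start,
                        )
                    )
                # reverse strand of this allele version -> background
                rc = revcomp(seq_a)
                for start in range(L - K + 1):
                    s = rc[start : start + K]
                    seen_b.setdefault(
                        s,
                        KmerRecord(
                            seq=s,
                            entity_id=ent.entity_id,
                            residue_id=None,
                            allele="background",
                            offset=L - K - start,
                            strand="-",
                        ),
                    )
        covered = set()
        for off in ent.residue_offsets:
            covered.update(range(off - K + 1, off + 1))
        for start in range(L - K + 1):
            if start in covered:
                continue
            s = ent.sequence[start : start + K]
            seen_b.setdefault(
                s,
                KmerRecord(
                    seq=s,
                    entity_id=ent.entity_id,
                    residue_id=None,
                    allele="background",
                    offset=start,
                ),
            )
    # strings equal to an A member stay in B on purpose: such collisions are
    # exactly what condition (ii) must flag
    return KmerSets(K=K, set_A=set_A, set_B=list(seen_b.values()))


# ---------------------------------------------------------------------------
# PDT conditions
# ---------------------------------------------------------------------------


def _codes_matrix(records: Sequence[KmerRecord], K: int) -> np.ndarray:
    if not records:
        return np.zeros((0, K), dtype=np.uint8)
    return np.stack([seq_codes(r.seq) for r in records])


def check_pdt_conditions(
    kmer_sets: KmerSets,
    PDT: int,
    max_violations: int = 10,
) -> tuple[bool, list[tuple[KmerRecord, KmerRecord, int]]]:
    """Check the two distinctness conditions at tolerance ``PDT``.

    (i) every cross-locus pair within set A has Hamming distance > PDT;
    (ii) every (A, B) pair has Hamming distance > PDT.  Pairs at the same
    locus (identical entity and offset, differing allele) are exempt.
    Returns ``(passed, violations)`` with at most ``max_violations`` offending
    pairs collected.
    """
    if PDT < 0:
        raise ValueError("PDT must be >= 0")
    A, B = kmer_sets.set_A, kmer_sets.set_B
    K = kmer_sets.K
    viol: list[tuple[KmerRecord, KmerRecord, int]] = []
    a_mat = _codes_matrix(A, K).astype(np.int16)
    keys = [(r.entity_id, r.offset) for r in A]

    # condition (i): pairwise within A, chunked
    chunk = max(1, 2_000_000 // max(1, len(A) * K))
    for lo in range(0, len(A), chunk):
        hi = min(lo + chunk, len(A))
        d = (a_mat[lo:hi, None, :] != a_mat[None, :, :]).sum(axis=2)
        for ii, jj in zip(*np.nonzero(d <= PDT)):
            i, j = lo + int(ii), int(jj)
            if j <= i or keys[i] == keys[j]:
                continue
            viol.append((A[i], A[j], int(d[ii, jj])))
            if len(viol) >= max_violations:
                return False, viol

    # condition (ii): A against B, chunked over B
    if B:
        b_mat = _codes_matrix(B, K).astype(np.int16)
        chunk = max(1, 4_000_000 // max(1, len(A) * K))
        for lo in range(0, len(B), chunk):
            hi = min(lo + chunk, len(B))
            d = (a_mat[:, None, :] != b_mat[None, lo:hi, :]).sum(axis=2)
            for ii, jj in zip(*np.nonzero(d <= PDT)):
                viol.append((A[int(ii)], B[lo + int(jj)], int(d[ii, jj])))
                if len(viol) >= max_violations:
                    return False, viol
    return len(viol) == 0, viol


def find_min_k(
    panel: Panel,
    PDT: int,
    k_floor: int | None = None,
    k_cap: int = 48,
) -> KDesignResult:
    """Smallest ``K`` in ``[k_floor, k_cap]`` satisfying the PDT conditions.

    ``k_floor`` defaults to ``PDT + 1``: a Hamming distance can never exceed
    the K-mer length, so no shorter K-mer can clear the tolerance.  Raises
    :class:`PanelDesignError` naming a blocking pair when no K passes —
    the signal that the panel itself needs redesign.
    """
    k_floor = PDT + 1 if k_floor is None else k_floor
    if k_cap < k_floor:
        raise ValueError("k_cap must be >= k_floor")
    prev_viol: list = []
    for K in range(k_floor, k_cap + 1):
        sets = kmerize_panel(panel, K)
        ok, viol = check_pdt_conditions(sets, PDT)
        if ok:
            return KDesignResult(K=K, PDT=PDT, violations_at_K_minus_1=prev_viol)
        prev_viol = viol
    a, b, d = prev_viol[0]
    raise PanelDesignError(
        f"no K <= {k_cap} satisfies PDT={PDT}: e.g. {a.residue_id or a.entity_id}"
        f"@{a.offset} vs {b.residue_id or b.entity_id}@{b.offset} at distance {d}"
    )
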