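"""Synthetic panels, planted genotypes and paired short reads.

The generator reproduces a targeted-sequencing simulation design: each SNP
residue carries 650 bp of flanking sequence per side (1300 bp total), paired
151 bp reads are drawn at an average depth of 10 with zero sequencing error,
and each residue has a 50% chance of carrying the alternative allele.
Flanking sequence is i.i.d. uniform over {A,C,G,T}; real genomes contain
repeats that uniform sequence does not emulate, so minimum-K values here are
a lower envelope of what repetitive references would require.

Controlled *point deviations* — single-base differences from the panel's
expected sequence — can be injected into reads to stress the Point Deviation
Tolerance machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .kmer_codec import revcomp
from .panel_design import Panel, PanelEntity, SNPResidue

__all__ = [
    "SimConfig",
    "TruthTable",
    "ReadPair",
    "simulate_panel",
    "simulate_reads",
    "inject_deviations",
    "random_dna",
    "all_read_sequences",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

OverlapKind = Literal["merge", "mismatch", "long"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the simulation.

    Defaults mirror the reference setup: 650 bp flanks per side, paired
    151 bp reads, depth 10, 50% per-residue substitution chance, no
    sequencing error and no extra deviations.
    """

    n_residues: int = 10
    flank_len: int = 650
    read_len: int = 151
    paired: bool = True
    depth: float = 10.0
    substitution_prob: float = 0.5
    deviation_rate: float = 0.0
    insert_len: int = 500
    seed: int = 0
    chrom: str = "chrS"
    spacing: int = 100_000
    overlap_cases: tuple[OverlapKind, ...] = ()

    def __post_init__(self):
        for name in ("substitution_prob", "deviation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class TruthTable:
    """Planted genotype per residue plus any injected deviation positions."""

    genotypes: dict[str, str] = field(default_factory=dict)  # residue id -> ref|alt
    deviations: dict[str, list[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class ReadPair:
    """A simulated read pair; ``seq2`` is empty in single-end mode."""

    name: str
    entity_id: str
    start: int  # 0-based start of the fragment within the entity sequence
    seq1: str
    seq2: str


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(3)]


_OVERLAP_BP = {"merge": 120, "mismatch": 120, "long": 200}


def simulate_panel(config: SimConfig) -> tuple[list[SNPResidue], TruthTable]:
    """Draw the panel: residues with uniform-random flanks, planted genotypes.

    ``config.overlap_cases`` appends residue *pairs* that share genomic
    sequence so every preprocessing branch can be exercised: ``"merge"``
    (clean 120 bp overlap), ``"mismatch"`` (120 bp overlap with one
    mismatching base) and ``"long"`` (clean 200 bp overlap, beyond the read
    length).  Those extra residues come after the ``n_residues`` independent
    ones.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng([config.seed, 0xA])
    fl = config.flank_len
    residues: list[SNPResidue] = []
    truth = TruthTable()

    def add_residue(rid: str, pos: int, flank5: str, flank3: str) -> SNPResidue:
        ref = random_dna(rng, 1)
        alt = _alt_base(rng, ref)
        res = SNPResidue(
            id=rid, chrom=config.chrom, pos=pos,
            ref_allele=ref, alt_allele=alt, flank5=flank5, flank3=flank3,
        )
        residues.append(res)
        truth.genotypes[rid] = "alt" if rng.random() < config.substitution_prob else "ref"
        return res

    for i in range(config.n_residues):
        pos = (i + 1) * config.spacing
        add_residue(f"snp{i:03d}", pos, random_dna(rng, fl), random_dna(rng, fl))

    base = (config.n_residues + 2) * config.spacing
    for ci, kind in enumerate(config.overlap_cases):
        v = _OVERLAP_BP[kind]
        dist = 2 * fl + 1 - v  # genomic distance between the two variant bases
        seg = random_dna(rng, dist + 2 * fl + 1)
        pos_a = base + (ci + 1) * config.spacing
        ref_a = seg[fl]
        ref_b = seg[fl + dist]
        seg_b = seg
        if kind == "mismatch":
            # corrupt one base of the second residue's copy inside the overlap
            # region, which spans segment indices [dist, 2*fl]
            mis_at = dist + v // 2
            seg_b = seg[:mis_at] + _alt_base(rng, seg[mis_at]) + seg[mis_at + 1 :]
        for tag, pos, refbase, source, centre in (
            ("a", pos_a, ref_a, seg, fl),
            ("b", pos_a + dist, ref_b, seg_b, fl + dist),
        ):
            rid = f"ovl{ci}{tag}_{kind}"
            res = SNPResidue(
                id=rid, chrom=config.chrom, pos=pos,
                ref_allele=source[centre],
                alt_allele=_alt_base(rng, source[centre]),
                flank5=source[centre - fl : centre],
                flank3=source[centre + 1 : centre + fl + 1],
            )
            residues.append(res)
            truth.genotypes[rid] = (
                "alt" if rng.random() < config.substitution_prob else "ref"
            )
    return residues, truth


def _entity_haplotype(ent: PanelEntity, truth: TruthTable) -> str:
    seq = ent.sequence
    for i, res in enumerate(ent.residues):
        if truth.genotypes.get(res.id) == "alt":
            off = ent.residue_offsets[i]
            seq = seq[:off] + res.alt_allele + seq[off + 1 :]
    return seq


def simulate_reads(
    panel: Panel, truth: TruthTable, config: SimConfig
) -> list[ReadPair]:
    """Paired reads from each entity's allele-resolved sequence.

    Fragments start uniformly within the entity; the mate is the reverse
    complement of the fragment end; no sequencing errors are introduced.  The
    pair count per entity is calibrated so each residue is covered ``depth``
    times in expectation (the throughput is derived from the per-residue
    coverage geometry, not from raw bases, since flanks near the entity edges
    are irrelevant to calling).  When the fragment length would leave the
    residues in the unsequenced middle of every fragment — possible only for
    short entities — the insert shrinks to twice the read length so the mates
    abut.  ``deviation_rate`` > 0 additionally substitutes bases of the
    finished reads at that per-base rate (recorded in ``truth.deviations``
    under the entity id).
    """
    rng = np.random.default_rng([config.seed, 0xB])
    pairs: list[ReadPair] = []
    for ent in panel.entities:
        hap = _entity_haplotype(ent, truth)
        length = len(hap)
        rl = min(config.read_len, length)
        insert = min(config.insert_len, length) if config.paired else rl
        insert = max(insert, rl)

        def reads_per_start(ins: int) -> float:
            """Mean number of reads of one fragment covering a residue."""
            span = length - ins + 1
            if not ent.residue_offsets:
                return 2.0 if config.paired else 1.0
            tot = 0
            for off in ent.residue_offsets:
                s1 = range(max(0, off - rl + 1), min(span - 1, off) + 1)
                tot += len(s1)
                if config.paired:
                    lo = max(0, off - ins + 1)
                    hi = min(span - 1, off - ins + rl)
                    tot += max(0, hi - lo + 1)
            return tot / (span * len(ent.residue_offsets))

        cov_per_pair = reads_per_start(insert)
        if config.paired and cov_per_pair == 0:
            insert = min(2 * rl, length)
            cov_per_pair = reads_per_start(insert)
        n_pairs = int(round(config.depth / cov_per_pair)) if cov_per_pair else 0
        starts = rng.integers(0, length - insert + 1, n_pairs)
        for i, s in enumerate(sorted(starts.tolist())):
            seq1 = hap[s : s + rl]
            seq2 = revcomp(hap[s + insert - rl : s + insert]) if config.paired else ""
            pairs.append(
                ReadPair(
                    name=f"{ent.entity_id}|{i}",
                    entity_id=ent.entity_id,
                    start=s,
                    seq1=seq1,
                    seq2=seq2,
                )
            )
    if config.deviation_rate > 0:
        mutated = []
        for rp in pairs:
            s1, pos1 = _mutate_at_rate(rp.seq1, config.deviation_rate, rng)
            s2, pos2 = _mutate_at_rate(rp.seq2, config.deviation_rate, rng)
            if pos1 or pos2:
                truth.deviations.setdefault(rp.entity_id, []).extend(
                    [rp.start + p for p in pos1]
                )
            mutated.append(replace(rp, seq1=s1, seq2=s2))
        pairs = mutated
    return pairs


def _mutate_at_rate(seq: str, rate: float, rng: np.random.Generator):
    if not seq:
        return seq, []
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    out = list(seq)
    for h in hits:
        out[h] = _alt_base(rng, out[h])
    return "".join(out), [int(h) for h in hits]


def inject_deviations(
    seq: str,
    count: int,
    protected_pos: int | None,
    min_distance: int,
    rng: np.random.Generator,
    window: int | None = None,
) -> tuple[str, list[int]]:
    """Substitute ``count`` bases of ``seq`` at recorded positions.

    Positions keep at least ``min_distance`` bp away from ``protected_pos``
    (the SNP base itself, so the planted allele survives).  When ``window``
    is given, all deviations land within one ``window``-length span on the
    same side of the protected position — the regime in which a single K-mer
    accumulates all ``count`` deviations.  ``count == 0`` returns the input
    unchanged.
    """
    if count == 0:
        return seq, []
    candidates = np.arange(len(seq))
    if protected_pos is not None:
        candidates = candidates[np.abs(candidates - protected_pos) >= min_distance]
    if window is not None and protected_pos is not None:
        right = candidates[candidates > protected_pos]
        left = candidates[candidates < protected_pos]
        side = right if len(right) >= len(left) else left
        anchor = side[0] if side is right else side[-1]
        candidates = side[np.abs(side - anchor) < window]
    if len(candidates) < count:
        raise ValueError("not enough positions satisfy the distance constraints")
    chosen = sorted(rng.choice(candidates, size=count, replace=False).tolist())
    out = list(seq)
    for c in chosen:
        out[c] = _alt_base(rng, out[c])
    return "".join(out), [int(c) for c in chosen]


def all_read_sequences(pairs: Iterable[ReadPair]) -> list[str]:
    """Flatten read pairs into the list of sequences the patient K-merizes."""
    out: list[str] = []
    for rp in pairs:
        out.append(rp.seq1)
        if rp.seq2:
            out.append(rp.seq2)
    return out
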