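"""The 4-step homomorphic equality test between patient and panel K-mers.

The patient encrypts the indicator vectors of up to ``N`` K-mers per batch
(one ciphertext per block) and sends them, with public evaluation material,
to the hospital.  The hospital holds the panel K-mers in the clear, grouped
by (residue, allele), and for each group runs:

Step 1   rotate ciphertext ``c_b`` by ``N * Kref[b]`` — slot ``n`` of the
         result is 1 iff user K-mer ``n`` agrees with the panel K-mer on
         block ``b``;
Step 2   component-wise product over the ``B`` rotated ciphertexts — slot
         ``n`` is 1 iff the full K-mers agree;
Step 3   sum over the group's panel K-mers — slot ``n`` counts the panel
         K-mers equal to user K-mer ``n`` (0 or 1 when the panel design
         guarantees no duplicated subsequences);
Step 4   rotate-and-add so slot 0 accumulates ``sum_n d[n]`` — the number of
         patient K-mers matching the group.

The result is one encrypted count per (residue, allele); only the patient
can decrypt.  Counts from successive batches are summed homomorphically.
Rotations by identical amounts are computed once per batch and shared across
panel K-mers and groups, which leaves the block products as the dominant
cost — as in any slot-batched equality test, proportional to the panel K-mer
count times ``B``.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import KmerlockError
from .kmer_codec import BlockSpec, block_values, build_indicator_vectors
from .panel_design import KmerSets, Panel

__all__ = [
    "ProtocolPlan",
    "MatchResult",
    "build_plan",
    "step1_rotate",
    "step2_block_product",
    "step3_sum",
    "step4_aggregate",
    "encrypt_user_kmers",
    "match_panel",
    "run_protocol",
    "decrypt_counts",
    "decrypt_report",
    "plaintext_match_counts",
]

log = logging.getLogger(__name__)

GroupKey = tuple[str, str]  # (residue id, 'ref'|'alt')


@dataclass
class ProtocolPlan:
    """Hospital-side execution plan: block geometry plus panel codes."""

    spec: BlockSpec
    groups: "OrderedDict[GroupKey, list[tuple[int, ...]]]"
    group_seqs: dict[GroupKey, list[str]]

    def rotation_amounts(self, step4: str = "literal") -> set[int]:
        amounts = {
            self.spec.N * v
            for codes in self.groups.values()
            for code in codes
            for v in code
        }
        if step4 == "literal":
            amounts |= set(range(1, self.spec.N))
        else:
            sh = 1
            while sh < self.spec.slots:
                amounts.add(sh)
                sh *= 2
        amounts.discard(0)
        if any(a >= self.spec.slots for a in amounts):
            raise KmerlockError("rotation amount exceeds slot count")
        return amounts


def build_plan(kmer_sets: KmerSets, L: int, N: int, max_slots: int | None = None) -> ProtocolPlan:
    """Group set-A panel K-mers by (residue, allele) and encode their blocks."""
    spec = BlockSpec.design(kmer_sets.K, L, N, max_slots)
    groups: OrderedDict[GroupKey, list[tuple[int, ...]]] = OrderedDict()
    seqs: dict[GroupKey, list[str]] = {}
    for rec in kmer_sets.set_A:
        key = (rec.residue_id, rec.allele)
        groups.setdefault(key, []).append(block_values(rec.seq, L))
        seqs.setdefault(key, []).append(rec.seq)
    return ProtocolPlan(spec=spec, groups=groups, group_seqs=seqs)


@dataclass
class MatchResult:
    """Encrypted per-(residue, allele) match counts."""

    counts: "OrderedDict[GroupKey, object]"  # group -> count ciphertext
    spec: BlockSpec
    n_batches: int
    n_user_kmers: int = 0


# ---------------------------------------------------------------------------
# the four steps
# ---------------------------------------------------------------------------


def step1_rotate(c_b, kref_b: int, spec: BlockSpec, backend):
    """Rotate block-``b`` ciphertext by ``N * Kref[b]``."""
    return backend.rotate(c_b, spec.N * int(kref_b))


def step2_block_product(rotated: Sequence, backend):
    """Component-wise product across blocks (logical AND of agreements)."""
    if not rotated:
        raise ValueError("need at least one block")
    acc = rotated[0]
    for ct in rotated[1:]:
        acc = backend.mult(acc, ct)
    return acc


def step3_sum(d_ms: Sequence, backend, slots: int):
    """Sum the per-panel-K-mer indicators of one group."""
    if not d_ms:
        return backend.enc(np.zeros(slots, dtype=np.int64))
    acc = d_ms[0]
    for ct in d_ms[1:]:
        acc = backend.add(acc, ct)
    return acc


def step4_aggregate(d, N: int, backend, method: str = "literal"):
    """Fold slots 0..N-1 of ``d`` into slot 0.

    ``literal`` follows the defining sum of N rotations; ``masked`` zeroes
    the slots beyond N and then uses log2(slots) rotate-and-add doublings —
    the same slot-0 value with far fewer rotations, at the cost of one
    plaintext multiplication.
    """
    if method == "literal":
        acc = d
        for n in range(1, N):
            acc = backend.add(acc, backend.rotate(d, n))
        return acc
    if method == "masked":
        slots = d.slot_count
        mask = np.zeros(slots, dtype=np.int64)
        mask[:N] = 1
        acc = backend.mult_plain(d, mask)
        sh = 1
        while sh < slots:
            acc = backend.add(acc, backend.rotate(acc, sh))
            sh *= 2
        return acc
    raise ValueError(f"unknown step-4 method {method!r}")


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


def encrypt_user_kmers(user_kmers: Sequence[str], spec: BlockSpec, backend):
    """Patient side: indicator vectors per batch of N K-mers, encrypted.

    Returns a list of batches; each batch is the list of ``B`` block
    ciphertexts.
    """
    batches = []
    for lo in range(0, max(len(user_kmers), 1), spec.N):
        chunk = user_kmers[lo : lo + spec.N]
        enc_vecs = build_indicator_vectors(chunk, spec)
        batches.append([backend.enc(enc_vecs.vectors[b]) for b in range(spec.B)])
    return batches


def match_panel(
    encrypted_batches: Sequence[Sequence],
    plan: ProtocolPlan,
    backend,
    step4: str = "literal",
) -> MatchResult:
    """Hospital side: run Steps 1-4 per (residue, allele) group.

    Step-1 rotations depend only on ``(block, panel block value)``, so each
    distinct rotation is evaluated once per batch and shared.  Per-batch
    group counts are summed homomorphically across batches.
    """
    spec = plan.spec
    if backend.p <= spec.N:
        raise KmerlockError(
            f"plaintext modulus {backend.p} must exceed the batch size {spec.N} "
            "so counts cannot wrap"
        )
    totals: OrderedDict[GroupKey, object] = OrderedDict()
    for bi, cts in enumerate(encrypted_batches):
        if len(cts) != spec.B:
            raise KmerlockError(f"batch {bi}: expected {spec.B} block ciphertexts")
        rot_cache: dict[tuple[int, int], object] = {}

        def rotated(b: int, val: int):
            key = (b, val)
            if key not in rot_cache:
                rot_cache[key] = step1_rotate(cts[b], val, spec, backend)
            return rot_cache[key]

        for gkey, codes in plan.groups.items():
            d_ms = [
                step2_block_product([rotated(b, v) for b, v in enumerate(code)], backend)
                for code in codes
            ]
            d = step3_sum(d_ms, backend, spec.slots)
            c_res = step4_aggregate(d, spec.N, backend, method=step4)
            totals[gkey] = (
                c_res if gkey not in totals else backend.add(totals[gkey], c_res)
            )
        log.info("matched batch %d/%d", bi + 1, len(encrypted_batches))
    return MatchResult(counts=totals, spec=spec, n_batches=len(encrypted_batches))


def run_protocol(
    user_kmers: Sequence[str],
    plan: ProtocolPlan,
    backend,
    step4: str = "literal",
) -> MatchResult:
    """Encrypt, match and return encrypted counts in one call."""
    if plan.spec.slots > backend.max_slots():
        raise KmerlockError(
            f"{plan.spec.slots} slots exceed the backend capacity "
            f"{backend.max_slots()}; lower the batch size N or block size L"
        )
    backend.ensure_rotation_keys(plan.rotation_amounts(step4))
    batches = encrypt_user_kmers(user_kmers, plan.spec, backend)
    result = match_panel(batches, plan, backend, step4=step4)
    result.n_user_kmers = len(user_kmers)
    return result


def decrypt_counts(result: MatchResult, backend) -> "OrderedDict[GroupKey, int]":
    """Patient side: decrypt slot 0 of every group's count ciphertext."""
    return OrderedDict(
        (gkey, int(backend.dec(ct)[0])) for gkey, ct in result.counts.items()
    )


def decrypt_report(counts: "OrderedDict[GroupKey, int]", panel: Panel) -> pd.DataFrame:
    """Per-residue call table from decrypted counts.

    call = 'het' when both alleles scored, 'ref'/'alt' when one did, and
    'no-coverage' when neither did — the detectable false-negative state in
    which the residue should be re-assayed rather than reported absent.
    """
    rows = []
    for ent in panel.entities:
        for res in ent.residues:
            ref_c = counts.get((res.id, "ref"), 0)
            alt_c = counts.get((res.id, "alt"), 0)
            if ref_c > 0 and alt_c > 0:
                call = "het"
            elif alt_c > 0:
                call = "alt"
            elif ref_c > 0:
                call = "ref"
            else:
                call = "no-coverage"
            rows.append(
                {
                    "residue_id": res.id,
                    "ref_count": ref_c,
                    "alt_count": alt_c,
                    "call": call,
                }
            )
    return pd.DataFrame(rows)


def plaintext_match_counts(
    user_kmers: Iterable[str], plan_or_sets
) -> "OrderedDict[GroupKey, int]":
    """Independent oracle: exact string matching of user vs panel K-mers.

    Counts, for every (residue, allele) group, the user K-mers equal to any
    of the group's panel K-mer strings (with multiplicity on both sides).
    Shares no code with the encrypted path beyond the panel K-mer strings.
    """
    if isinstance(plan_or_sets, ProtocolPlan):
        group_seqs = plan_or_sets.group_seqs
    else:  # KmerSets
        group_seqs = {}
        for rec in plan_or_sets.set_A:
            group_seqs.setdefault((rec.residue_id, rec.allele), []).append(rec.seq)
    from collections import Counter

    user_counter = Counter(user_kmers)
    out: OrderedDict[GroupKey, int] = OrderedDict()
    for gkey, seqs in group_seqs.items():
        out[gkey] = sum(user_counter.get(s, 0) for s in seqs)
    return out
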