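from collections import OrderedDict

import numpy as np
import pytest

from kmerlock.equality_protocol import (
    build_plan,
    decrypt_counts,
    decrypt_report,
    plaintext_match_counts,
    run_protocol,
    step1_rotate,
    step2_block_product,
    step3_sum,
    step4_aggregate,
)
from kmerlock.errors import KmerlockError
from kmerlock.kmer_codec import BlockSpec, block_values, build_indicator_vectors, kmerize_reads
from kmerlock.panel_design import find_min_k, kmerize_panel
from kmerlock.rlwe_backend import PlainBackend
from kmerlock.synthetic_data import (
    SimConfig,
    all_read_sequences,
    inject_deviations,
    simulate_panel,
    simulate_reads,
)

from conftest import make_panel


def enc_batch(kmers, spec, backend):
    ev = build_indicator_vectors(kmers, spec)
    return [backend.enc(ev.vectors[b]) for b in range(spec.B)]


class TestSteps:
    """Step-level semantics, verified under the exact plaintext backend."""

    def test_step1_marks_agreeing_slots(self, plain_backend):
        spec = BlockSpec.design(K=4, L=2, N=4)
        kmers = ["CATC", "CAGG", "TTTT"]
        cts = enc_batch(kmers, spec, plain_backend)
        ref_blocks = block_values("CATC", 2)
        got = plain_backend.dec(step1_rotate(cts[0], ref_blocks[0], spec, plain_backend))
        # block 0 ("CA") agrees for k-mers 0 and 1, not 2
        assert got[:3].tolist() == [1, 1, 0]

    def test_step1_zero_reference_block_is_identity(self, plain_backend):
        spec = BlockSpec.design(K=2, L=2, N=2)
        cts = enc_batch(["AA", "GT"], spec, plain_backend)
        same = plain_backend.dec(step1_rotate(cts[0], 0, spec, plain_backend))
        assert np.array_equal(same, plain_backend.dec(cts[0]))

    def test_step2_single_block_is_identity_and_disagreement_zeroes(self, plain_backend):
        spec = BlockSpec.design(K=4, L=2, N=2)
        kmers = ["CATC", "CAGG"]
        cts = enc_batch(kmers, spec, plain_backend)
        rot = [
            step1_rotate(cts[b], v, spec, plain_backend)
            for b, v in enumerate(block_values("CATC", 2))
        ]
        only = plain_backend.dec(step2_block_product(rot[:1], plain_backend))
        assert only[:2].tolist() == [1, 1]  # both share block "CA"
        both = plain_backend.dec(step2_block_product(rot, plain_backend))
        assert both[:2].tolist() == [1, 0]  # second disagrees on block 1

    def test_step2_equals_and_oracle_on_random_data(self, plain_backend):
        rng = np.random.default_rng(0)
        spec = BlockSpec.design(K=6, L=2, N=8)
        kmers = ["".join("ACGT"[c] for c in rng.integers(0, 4, 6)) for _ in range(8)]
        ref = "".join("ACGT"[c] for c in rng.integers(0, 4, 6))
        cts = enc_batch(kmers, spec, plain_backend)
        rot = [
            step1_rotate(cts[b], v, spec, plain_backend)
            for b, v in enumerate(block_values(ref, 2))
        ]
        d = plain_backend.dec(step2_block_product(rot, plain_backend))
        for n, k in enumerate(kmers):
            assert d[n] == int(k == ref)

    def test_step3_empty_group_and_duplicate_panel_kmer(self, plain_backend):
        spec = BlockSpec.design(K=2, L=2, N=2)
        zero = step3_sum([], plain_backend, spec.slots)
        assert not plain_backend.dec(zero).any()
        cts = enc_batch(["GT"], spec, plain_backend)
        rot = [step1_rotate(cts[0], block_values("GT", 2)[0], spec, plain_backend)]
        d_m = step2_block_product(rot, plain_backend)
        # the same panel K-mer listed twice: slot value 2, the failure mode
        # excluded by the panel-design uniqueness assumption
        d = plain_backend.dec(step3_sum([d_m, d_m], plain_backend, spec.slots))
        assert d[0] == 2

    @pytest.mark.parametrize("method", ["literal", "masked"])
    def test_step4_folds_first_n_slots_into_slot0(self, plain_backend, method):
        rng = np.random.default_rng(1)
        spec = BlockSpec.design(K=4, L=2, N=8)
        vec = rng.integers(0, 2, spec.slots)
        ct = plain_backend.enc(vec)
        out = plain_backend.dec(step4_aggregate(ct, spec.N, plain_backend, method))
        assert out[0] == vec[: spec.N].sum()

    def test_step4_all_zero_and_three_ones(self, plain_backend):
        vec = np.zeros(64, dtype=np.int64)
        ct = plain_backend.enc(vec)
        assert plain_backend.dec(step4_aggregate(ct, 16, plain_backend))[0] == 0
        vec[[1, 5, 9]] = 1
        ct = plain_backend.enc(vec)
        assert plain_backend.dec(step4_aggregate(ct, 16, plain_backend))[0] == 3


class TestFullProtocol:
    def test_counts_equal_string_oracle_on_small_panel(self, small_sim, plain_backend):
        cfg, panel, truth, pairs = small_sim
        res = find_min_k(panel, PDT=0)
        sets = kmerize_panel(panel, res.K)
        user = kmerize_reads(all_read_sequences(pairs), res.K)
        plan = build_plan(sets, L=2, N=512)
        mr = run_protocol(user, plan, plain_backend, step4="masked")
        counts = decrypt_counts(mr, plain_backend)
        assert counts == plaintext_match_counts(user, plan)
        report = decrypt_report(counts, panel)
        calls = dict(zip(report.residue_id, report.call))
        assert calls == truth.genotypes

    def test_zero_deviation_completeness_and_soundness(self, small_sim, plain_backend):
        """Without deviations: every covered residue scores on its planted
        allele and never on the other allele (no FN, no cross-allele FP)."""
        cfg, panel, truth, pairs = small_sim
        res = find_min_k(panel, PDT=0)
        sets = kmerize_panel(panel, res.K)
        user = kmerize_reads(all_read_sequences(pairs), res.K)
        counts = plaintext_match_counts(user, build_plan(sets, L=2, N=64))
        for ent in panel.entities:
            for r in ent.residues:
                planted = truth.genotypes[r.id]
                other = "alt" if planted == "ref" else "ref"
                assert counts[(r.id, planted)] >= 1
                assert counts[(r.id, other)] == 0

    def test_batching_is_transparent(self, plain_backend):
        """Counts must not depend on how user K-mers split into batches."""
        panel = make_panel(n=2, flank=120, seed=50)
        res = find_min_k(panel, PDT=0)
        sets = kmerize_panel(panel, res.K)
        user = [r.seq for r in sets.set_A][:20]
        by_batch = {}
        for N in (4, 7, 64):
            plan = build_plan(sets, L=2, N=N)
            mr = run_protocol(user, plan, plain_backend)
            by_batch[N] = decrypt_counts(mr, plain_backend)
        assert by_batch[4] == by_batch[7] == by_batch[64]
        assert by_batch[4] == plaintext_match_counts(user, plan)

    def test_batch_size_must_stay_below_plaintext_modulus(self, small_sim):
        _, panel, _, _ = small_sim
        sets = kmerize_panel(panel, 10)
        plan = build_plan(sets, L=2, N=64)
        tiny_p = PlainBackend(p=17)
        with pytest.raises(KmerlockError, match="modulus"):
            run_protocol([r.seq for r in sets.set_A[:3]], plan, tiny_p)

    def test_rlwe_and_plaintext_backends_agree_end_to_end(self, tiny_rlwe, plain_backend):
        """Identical per-SNP counts from both backends and the string oracle."""
        cfg = SimConfig(n_residues=2, flank_len=60, depth=4, insert_len=100,
                        read_len=50, seed=31)
        residues, truth = simulate_panel(cfg)
        from kmerlock.panel_design import preprocess_panel

        panel = preprocess_panel(residues)
        res = find_min_k(panel, PDT=0)
        assert res.K <= 12  # B <= 6 blocks: within the tiny ring's depth
        sets = kmerize_panel(panel, res.K)
        pairs = simulate_reads(panel, truth, cfg)
        user = kmerize_reads(all_read_sequences(pairs), res.K)[:48]
        plan = build_plan(sets, L=2, N=tiny_rlwe.max_slots() // 16)
        oracle = plaintext_match_counts(user, plan)
        counts_p = decrypt_counts(run_protocol(user, plan, plain_backend), plain_backend)
        counts_r = decrypt_counts(run_protocol(user, plan, tiny_rlwe), tiny_rlwe)
        assert counts_p == oracle
        assert counts_r == oracle


class TestReport:
    def test_call_rules(self, small_sim):
        _, panel, _, _ = small_sim
        rids = [r.id for e in panel.entities for r in e.residues]
        counts = OrderedDict()
        counts[(rids[0], "ref")], counts[(rids[0], "alt")] = 5, 5
        counts[(rids[1], "ref")], counts[(rids[1], "alt")] = 0, 0
        counts[(rids[2], "ref")], counts[(rids[2], "alt")] = 3, 0
        counts[(rids[3], "ref")], counts[(rids[3], "alt")] = 0, 7
        report = decrypt_report(counts, panel).set_index("residue_id")
        assert report.loc[rids[0], "call"] == "het"
        assert report.loc[rids[1], "call"] == "no-coverage"
        assert report.loc[rids[2], "call"] == "ref"
        assert report.loc[rids[3], "call"] == "alt"


class TestDeviationGeometry:
    def test_single_deviation_leaves_min_d_matching_kmers(self, plain_backend):
        """A deviation d bases from the residue breaks all but min(d, ...) of
        a read's residue-covering K-mers — verified against the string oracle."""
        cfg = SimConfig(n_residues=1, flank_len=200, depth=6, insert_len=300, seed=13)
        residues, truth = simulate_panel(cfg)
        from kmerlock.panel_design import preprocess_panel

        panel = preprocess_panel(residues)
        res_k = find_min_k(panel, PDT=1)
        K = res_k.K
        sets = kmerize_panel(panel, K)
        pairs = simulate_reads(panel, truth, cfg)
        ent = panel.entities[0]
        off = ent.residue_offsets[0]
        rid = ent.residues[0].id
        planted = truth.genotypes[rid]
        rng = np.random.default_rng(5)
        checked = 0
        for d in (1, 3, 7, K - 1):
            for rp in pairs:
                pos_in_read = off - rp.start
                # need room for the deviation and full K-mer coverage each side
                if not (K - 1 <= pos_in_read - 0 and pos_in_read + d + K <= len(rp.seq1)):
                    continue
                mutated = list(rp.seq1)
                mutated[pos_in_read + d] = "A" if mutated[pos_in_read + d] != "A" else "C"
                mutated = "".join(mutated)
                user = kmerize_reads([mutated], K, include_reverse_complement=False)
                counts = plaintext_match_counts(user, build_plan(sets, L=2, N=512))
                assert counts[(rid, planted)] == min(d, K)
                checked += 1
                break
        assert checked >= 3
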