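"""End-to-end encrypted genotyping of a small synthetic patient.

Simulates a 3-residue panel and patient reads with planted genotypes, designs
K, then runs the whole exchange: the patient encrypts K-mer indicator
vectors under an RLWE key; the hospital — holding only public material and
its plaintext panel — executes the 4-step homomorphic equality test; the
patient decrypts per-SNP counts.  The decrypted calls are checked against
the planted truth and against an exact plaintext execution of the same
protocol.
"""

from kmerlock import (
    PlainBackend,
    RlweBackend,
    SimConfig,
    all_read_sequences,
    build_plan,
    decrypt_counts,
    decrypt_report,
    find_min_k,
    kmerize_panel,
    kmerize_reads,
    preprocess_panel,
    run_protocol,
    simulate_panel,
    simulate_reads,
    toy_params,
)

cfg = SimConfig(n_residues=3, flank_len=60, depth=4, read_len=50, insert_len=100, seed=31)
residues, truth = simulate_panel(cfg)
panel = preprocess_panel(residues)
K = find_min_k(panel, PDT=0).K
sets = kmerize_panel(panel, K)
pairs = simulate_reads(panel, truth, cfg)
all_kmers = kmerize_reads(all_read_sequences(pairs), K)
# query a subset that still covers every residue — full read sets run the
# same way, just across more batches (see the plaintext backend for scale)
user = []
for ent in panel.entities:
    off = ent.residue_offsets[0]
    rp = next(p for p in pairs if p.entity_id == ent.entity_id
              and p.start + K - 1 <= off < p.start + len(p.seq1))
    pos = off - rp.start
    starts = [min(max(0, pos - K + 1 + j), len(rp.seq1) - K) for j in (0, K // 2)]
    user += [rp.seq1[s : s + K] for s in starts]
user += all_kmers[:10]
print(f"panel: {panel.N} residues, K={K}; patient queries {len(user)} of "
      f"{len(all_kmers)} read K-mers")

plan = build_plan(sets, L=2, N=8)  # 4^2 * 8 = 128 slots fills the tiny ring
rlwe = RlweBackend(toy_params(n=256, b_max=plan.spec.B), seed=5)
result = run_protocol(user, plan, rlwe)
counts = decrypt_counts(result, rlwe)

plain = PlainBackend(p=rlwe.p)
counts_plain = decrypt_counts(run_protocol(user, plan, plain), plain)
assert counts == counts_plain, "encrypted and plaintext executions must agree"

report = decrypt_report(counts, panel)
print(report.to_string(index=False))
print("planted:", truth.genotypes)
budget = min(ct.noise_budget for ct in result.counts.values())
print(f"remaining noise budget: {budget:.0f} bits "
      f"(counts decrypt exactly while this stays positive)")
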