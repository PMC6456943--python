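"""Design the panel-specific K-mer length for a synthetic SNP panel.

Builds a 10-residue panel with 650 bp flanks (plus one cleanly overlapping
residue pair to show the merge step), then searches for the smallest K whose
SNP-covering K-mers stay mutually distinguishable at each Point Deviation
Tolerance (PDT).  Larger PDT buys robustness against unannotated variation at
the price of a longer K, hence more homomorphic work per query.
"""

from kmerlock import SimConfig, find_min_k, preprocess_panel, simulate_panel

cfg = SimConfig(n_residues=10, seed=7, overlap_cases=("merge",))
residues, _ = simulate_panel(cfg)
panel = preprocess_panel(residues)

print(f"{len(residues)} input residues -> {len(panel.entities)} entities "
      f"({panel.N} surviving residues, {len(panel.discarded)} discarded)")
for ent in panel.entities:
    if len(ent.residues) > 1:
        print(f"  merged entity {ent.entity_id}: {len(ent.sequence)} bp, "
              f"residues at offsets {ent.residue_offsets}")

print("\nPDT  min K   (distance every SNP K-mer keeps from all others > PDT)")
for pdt in range(4):
    result = find_min_k(panel, PDT=pdt)
    print(f"{pdt:>3}  {result.K:>5}")
print("\nA PDT of p means: up to p point deviations per K-mer can never "
      "redirect a match to a different residue.")
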