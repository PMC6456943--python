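# Methods

This note records the model, the parameter choices, the numerical decisions
and the limits of what the tests demonstrate.

## Panel preprocessing

Residues are swept in (chrom, pos) order. Genomic coordinates decide whether
two flanked residues overlap; the overlapping substrings are then compared
base-for-base. A pair is merged into one extended entity when the overlap is
mismatch-free and lies in `[full_overlap_cutoff, max_overlap]` =
[100, 150] bp by default — long enough that a chance overlap of unrelated
flanks is essentially impossible (probability `1 − (1 − 2·4⁻¹⁰⁰)²`,
`overlap_chance()`), short enough to be spanned by one 151 bp read. Any
other genomic overlap (mismatching, longer than a read, or shorter than the
cutoff) keeps one seeded-random survivor and logs the discard; residue count
is always conserved. Chains of overlaps merge left-to-right in sweep order,
which makes multi-residue entities deterministic.

## K-mer design and the PDT conditions

Set *A* holds the K windows covering each residue, once per allele, labeled
(residue, allele); other residues in a merged entity stay at reference
within those windows (merged residues are ≥ 1150 bp apart, so no window can
cover two). Set *B* holds every other window: forward windows covering no
residue, plus **all reverse-complement windows of every allele version**.
The reverse strand is included because patient K-mers are taken from both
read orientations; a reverse-strand window colliding with a set-A K-mer is a
real false-positive channel that forward-only conditions would miss (at
K ≈ 13 on a 10-residue panel the chance of such a collision is of order
10⁻¹ per panel — rare but not ignorable across many panels).

The conditions at tolerance PDT: all cross-locus pairs within *A*, and all
(*A*, *B*) pairs, must have Hamming distance > PDT. The ref/alt pair at one
locus differs by exactly 1 by construction and distinguishing it is the
assay's purpose, so pairs with identical (entity, offset) are exempt — the
source description leaves this case open, and without the exemption no panel
could pass at PDT ≥ 1. `find_min_k` searches K upward from `PDT + 1` (a
Hamming distance never exceeds the string length, so smaller K cannot pass);
uniform-random flanks put the answer near 11–17 for 4–10 residues at
PDT 0–2, lower than repetitive real genomes would give (see Limitations).

## The cryptosystem

BGV-style RLWE over `R = Z[X]/(Xⁿ + 1)`, `n` a power of two:

* **Plaintext space.** `p` prime with `p ≡ 1 (mod 2n)` (default 65537), so
  `X^n + 1` splits into linear factors mod `p` and a polynomial is an exact
  vector of `n` integer slots. Messages here are 0/1 indicators and small
  counts, so exact integer batching (rather than approximate complex
  embeddings) loses nothing and makes every test bit-exact.
* **Slot layout.** The protocol vector of length `slots` (a power of two
  dividing `n/2`) is repeated along the orbit of 5 in `(Z/2n)*` and mirrored
  on the conjugate orbit. The automorphism `X → X^(5^r)` then cyclically
  shifts the vector by `r`, for any `r < slots`.
* **Keys.** Ternary secret; `pk = (b, a)` with `b = −a·s + p·e`;
  encryption adds `p`-scaled noise so decryption is `[⟨c, sk⟩]_q mod p`.
* **Key switching** (relinearisation and rotation) decomposes along the RNS
  primes: digit k of `c₁` is `[c₁·(q/q_k)⁻¹]_{q_k}`, paired with key
  material `(−a_k·s + p·e_k + (q/q_k)·s_src, a_k)`. All arithmetic stays in
  `int64`; polynomial products use negacyclic NTTs vectorised across the
  prime stack, and ciphertexts live in the NTT domain so rotation is a
  permutation of evaluation points.
* **Modulus sizing.** No modulus switching. The deepest protocol circuit is
  the block product: B sequential multiplications of rotated fresh
  ciphertexts, each carrying key-switch noise ≈ `p·D·n·2²⁸·6σ`. `toy_params`
  sizes the prime count from `B·ν_ks + (B−1)·log₂n + log₂p + 30` bits, so a
  preset always supports its declared depth with margin; the tracked
  noise-budget estimate errors out *before* silent corruption.
* **Security.** None claimed. n = 256–2048 with a 300–600-bit modulus is far
  outside any secure regime; the presets exist to make the protocol
  executable and exactly checkable at desk scale.

## The protocol

Steps 1–4 run once per (residue, allele) group so the output is a per-SNP
readout rather than one aggregate count. Step-1 rotations depend only on
(block index, panel block value), so each distinct rotation is computed once
per batch and shared across groups — the dominant cost is then the block
products, proportional to |panel K-mers| × B. Step 4 is implemented two
ways: `literal` (the defining sum of N rotations, used for small N) and
`masked` (zero the slots ≥ N with one plaintext multiplication, then
log₂(slots) rotate-and-add doublings); both put Σₙ d[n] in slot 0 and both
are tested. Patient batches of N K-mers are processed independently and
counts summed homomorphically; batch size must stay below `p` so counts
cannot wrap (validated at run time). Block size defaults to L = 2: it keeps
the indicator vectors at `16·N` slots and the block count at ⌈K/2⌉, a good
trade for the K ≈ 11–17 this generator produces.

## Synthetic data

The generator emulates a targeted-sequencing study: residues with 650 bp
i.i.d. uniform flanks per side, paired 151 bp error-free reads, depth 10,
50% per-residue substitution chance. Substituted residues are planted
homozygous (all reads carry alt), which is the contract the report's
`ref`/`alt` calls are tested against; `het` calls arise when both alleles
score and are exercised with constructed counts. Fragment throughput per
entity is calibrated so *each residue* is covered `depth` times in
expectation under the actual fragment-start geometry (for a 1301 bp entity
with 500 bp inserts that is ~27 pairs); when an entity is too short for the
insert to let either mate reach the residue, the insert shrinks to twice
the read length. Optional overlap cases ("merge", "mismatch", "long")
append residue pairs sharing a genomic segment so every preprocessing branch
is exercised. Point deviations can be injected at recorded positions with a
protected radius around the SNP and an optional single-window constraint.

What passing tests on this generator do *not* show: uniform-random sequence
has no repeats, so the minimum-K values here are a lower envelope —
repetitive genomes force both larger K and more discarded residues.
Sequencing error, indels and structural variation are deliberately absent
(the reference design disables them), and germline variation enters only
through the PDT margin.

## Problem sizes used in the checks

The automated checks run, on one CPU: homomorphic-operation equivalence over
201 randomized trials at n = 256; the full encrypted protocol on the
10-residue / 650 bp-flank panel with a 32-K-mer covering patient subset at
n = 1024 (the full 2×10⁵-K-mer read set runs under the plaintext backend,
which is the same code path with exact arithmetic); genotype recovery at the
full simulation design; and 20–50 deviation trials on 4-residue panels with
300 bp flanks. These sizes were chosen so the whole suite completes in
minutes while still covering every code path at the study's parameters where
it matters (flank length, read geometry, depth, substitution rate).

## Known limitations

* The scheme reveals K and the number of panel groups to the patient, and
  match counts are revealed to the patient by design; hiding them is out of
  scope.
* Counts assume no duplicated K-mers within a group (guaranteed by the
  design conditions); a deliberately duplicated panel K-mer yields counts
  of 2 per match, exercised in tests as the assumption's failure mode.
* The risk model treats mutation pairs as independent and uniform across
  panels — the same approximation the catalog statistics embody.
* One reference-table cell (N = 90) does not follow from the risk formula
  under either stated rounding convention; the computed value (0.077%) is
  reported as-is.
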