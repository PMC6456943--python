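# kmerlock

Secure SNP panel genotyping on homomorphically encrypted K-mers.

## The problem

A hospital curates a *SNP panel*: clinically actionable single-nucleotide
variants, each carried on its flanking sequence. A patient holds raw targeted
sequencing reads. Both sides have something to protect — the patient's genome
is innate and irrevocable once leaked; the panel is the hospital's asset. In
the usual workflow one of the two must be revealed. `kmerlock` implements a
scheme in which neither is: the patient's reads are chunked into K-mers and
encrypted under the patient's own key; the hospital evaluates an equality
test between the encrypted patient K-mers and its plaintext panel K-mers
*under the encryption*, and returns encrypted per-SNP match counts that only
the patient can decrypt.

## The scheme

**Panel design.** Panel sequences are K-merized into the SNP-covering set *A*
(both alleles of every residue) and the background set *B* (all remaining
windows, both strands). The panel-specific K is the smallest value for which

- every cross-locus pair within *A* has Hamming distance > PDT, and
- every (*A*, *B*) pair has Hamming distance > PDT,

where the *Point Deviation Tolerance* PDT ≥ 0 generalises uniqueness: as
long as a patient K-mer deviates from the panel sequence in at most PDT
positions (somatic mutation, individual variation, sequencing error), it can
never be attributed to the wrong residue. Overlapping residues are merged
when their flanks agree over a 100–150 bp overlap, otherwise one survivor is
kept.

**Encoding.** A K-mer maps to a base-4 integer (A,C,G,T → 0..3; e.g.
`GACT` → 2013₄ = 135) and is split into B = ⌈K/L⌉ blocks of L bases. The
b-th blocks of N patient K-mers become one binary indicator vector

    v_b[i] = 1  iff  i = K⁽ⁿ⁾[b]·N + n,   n < N,

encrypted as a single ciphertext via slot batching.

**Equality test** (per (residue, allele) group of panel K-mers): rotate
`c_b` by `N·Kref[b]` (step 1), multiply the B rotated ciphertexts slot-wise
(step 2), sum over the group's K-mers (step 3), and fold the first N slots
into slot 0 (step 4). Slot 0 then encrypts the number of patient K-mers
exactly matching that allele at that residue. Decrypting all groups yields a
call per residue: `ref`, `alt`, `het`, or `no-coverage` (a detectable
false-negative state).

**Cryptosystem.** A BGV-flavoured RLWE scheme on Z[X]/(Xⁿ+1): plaintext
modulus p ≡ 1 (mod 2n) splits the ring into exact integer slots; rotation is
the Galois automorphism X → X^(5^r) plus key switching; multiplication uses
relinearisation with RNS digit decomposition. A plaintext reference backend
implements the identical operation contract with exact modular arithmetic
and serves both as correctness oracle and as the fast mode for full read
sets. Shipped parameter presets are sized for correctness at desk scale,
**not** for cryptographic security.

**Risk model.** A second mutation within the same K-mer window masks a
residue. From catalog statistics (116,607 somatic mutations, 1,308 of the
C(116607,2) = 6,798,537,921 pairs within 32 bp), the chance a panel of N
residues contains a masking pair is P = 1 − (1 − 1308/6798537921)^C(N,2) —
below 0.1% even at N = 100.

## Worked example

```
$ python examples/encrypted_genotyping.py
panel: 3 residues, K=10; patient queries 16 of 1968 read K-mers
residue_id  ref_count  alt_count call
    snp000          0          2  alt
    snp001          0          2  alt
    snp002          2          0  ref
planted: {'snp000': 'alt', 'snp001': 'alt', 'snp002': 'ref'}
remaining noise budget: 51 bits (counts decrypt exactly while this stays positive)
```

Each count is the number of patient K-mers that exactly matched that
residue-allele's panel K-mers under encryption; a positive count for one
allele and zero for the other calls the genotype, and the encrypted and
plaintext executions agree bit-for-bit. The other scripts in `examples/`
demonstrate panel K design (`design_panel_k.py`), the risk table
(`false_negative_risk.py`) and deviation stress tests
(`deviation_stress.py`).

The same pipeline is available as a CLI:

```
kmerlock simulate --out-dir sim --n-residues 10 --seed 1
kmerlock design   --panel sim/panel.tsv --flanks sim/flanks.fasta --pdt 0 --out design.json
kmerlock encrypt  --reads sim/reads_1.fastq --reads sim/reads_2.fastq \
                  --design design.json --backend rlwe --preset toy \
                  --keys-out keys.json --public-out public.json --out cts.json
kmerlock match    --ciphertexts cts.json --public public.json \
                  --panel sim/panel.tsv --flanks sim/flanks.fasta --out results.json
kmerlock decrypt  --results results.json --keys keys.json --out report.tsv
kmerlock risk     --n 10 --n 100
```

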