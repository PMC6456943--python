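"""File formats: panel TSV, flank FASTA, FASTQ reads, key / ciphertext JSON.

Panel TSV columns: ``id  chrom  pos  ref  alt`` (0-based positions).  Flanks
travel in a FASTA whose records are keyed by residue id and hold the full
flanked sequence; the 0-based offset of the variant base inside the record is
carried in the description as ``offset=<int>``.

Key and ciphertext envelopes are JSON with a params fingerprint so that
mismatched material fails loudly instead of decrypting garbage.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import KmerlockError, ParameterMismatch
from .kmer_codec import BlockSpec
from .panel_design import SNPResidue
from .rlwe_backend import (
    Ciphertext,
    KeySwitchKey,
    PlainBackend,
    PlainCiphertext,
    PublicKey,
    RingParams,
    RlweBackend,
    SecretKey,
)
from .synthetic_data import ReadPair, TruthTable

__all__ = [
    "write_panel_tsv",
    "read_panel_tsv",
    "write_flanks_fasta",
    "load_panel_inputs",
    "write_fastq",
    "read_fastq_sequences",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_keys",
    "load_backend",
    "write_ciphertext_bundle",
    "read_ciphertext_bundle",
    "write_match_results",
    "read_match_results",
]


# ---------------------------------------------------------------------------
# panel / reads / truth
# ---------------------------------------------------------------------------


def write_panel_tsv(residues: Sequence[SNPResidue], path) -> None:
    pd.DataFrame(
        [
            {"id": r.id, "chrom": r.chrom, "pos": r.pos,
             "ref": r.ref_allele, "alt": r.alt_allele}
            for r in residues
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    missing = {"id", "chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise KmerlockError(f"panel TSV lacks columns: {sorted(missing)}")
    return df


def write_flanks_fasta(residues: Sequence[SNPResidue], path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence()),
            id=r.id,
            description=f"offset={len(r.flank5)}",
        )
        for r in residues
    ]
    SeqIO.write(records, path, "fasta")


def load_panel_inputs(panel_tsv, flanks_fasta) -> list[SNPResidue]:
    """Combine the panel TSV with the flank FASTA into residue objects."""
    df = read_panel_tsv(panel_tsv)
    seqs: dict[str, tuple[str, int]] = {}
    for rec in SeqIO.parse(str(flanks_fasta), "fasta"):
        fields = dict(
            kv.split("=") for kv in rec.description.split() if "=" in kv
        )
        if "offset" not in fields:
            raise KmerlockError(f"flank record {rec.id!r} lacks offset=<int>")
        seqs[rec.id] = (str(rec.seq).upper(), int(fields["offset"]))
    residues = []
    for row in df.itertuples(index=False):
        if row.id not in seqs:
            raise KmerlockError(f"no flank sequence for residue {row.id!r}")
        seq, off = seqs[row.id]
        if seq[off] != row.ref:
            raise KmerlockError(
                f"residue {row.id!r}: flank base {seq[off]!r} at offset {off} "
                f"does not match ref allele {row.ref!r}"
            )
        residues.append(
            SNPResidue(
                id=row.id, chrom=row.chrom, pos=int(row.pos),
                ref_allele=row.ref, alt_allele=row.alt,
                flank5=seq[:off], flank3=seq[off + 1 :],
            )
        )
    return residues


def write_fastq(pairs: Sequence[ReadPair], path1, path2=None) -> None:
    """Paired FASTQ (constant high quality — the simulation has no error model)."""

    def dump(path, mate):
        with open(path, "w") as fh:
            for rp in pairs:
                seq = rp.seq1 if mate == 1 else rp.seq2
                if not seq:
                    continue
                fh.write(f"@{rp.name}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")

    dump(path1, 1)
    if path2 is not None:
        dump(path2, 2)


def read_fastq_sequences(*paths) -> list[str]:
    seqs: list[str] = []
    for path in paths:
        seqs.extend(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq"))
    return seqs


def write_truth_tsv(truth: TruthTable, path) -> None:
    pd.DataFrame(
        [{"residue_id": rid, "genotype": g} for rid, g in truth.genotypes.items()]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"residue_id": str})
    return TruthTable(genotypes=dict(zip(df.residue_id, df.genotype)))


# ---------------------------------------------------------------------------
# key material
# ---------------------------------------------------------------------------


def _arr(a: np.ndarray) -> list:
    return a.tolist()


def _ksk_dict(k: KeySwitchKey) -> dict:
    return {"b": _arr(k.b_hat), "a": _arr(k.a_hat)}


def _ksk_from(params: RingParams, d: dict) -> KeySwitchKey:
    return KeySwitchKey(
        params,
        np.array(d["b"], dtype=np.int64),
        np.array(d["a"], dtype=np.int64),
    )


def write_keys(backend, path, include_secret: bool) -> None:
    """JSON envelope with params and key material.

    ``include_secret=False`` writes the hospital-side bundle (public,
    evaluation and rotation keys only).
    """
    if isinstance(backend, PlainBackend):
        env = {"format": "kmerlock-keys", "backend": "plaintext", "p": backend.p}
    else:
        env = {
            "format": "kmerlock-keys",
            "backend": "rlwe",
            "params": backend.params.to_dict(),
            "fingerprint": backend.params.fingerprint,
            "public": {"b": _arr(backend.pk.b_hat), "a": _arr(backend.pk.a_hat)},
            "evk": _ksk_dict(backend.evk),
            "rot": {str(r): _ksk_dict(k) for r, k in backend.rot_keys.items()},
        }
        if include_secret:
            env["secret"] = {"s": _arr(backend.sk.s)}
    with open(path, "w") as fh:
        json.dump(env, fh)


def load_backend(path, seed: int = 0):
    """Rebuild a backend from a key envelope (with or without the secret)."""
    with open(path) as fh:
        env = json.load(fh)
    if env.get("format") != "kmerlock-keys":
        raise KmerlockError(f"{path}: not a key envelope")
    if env["backend"] == "plaintext":
        return PlainBackend(p=int(env["p"]))
    params = RingParams.from_dict(env["params"])
    backend = RlweBackend.__new__(RlweBackend)
    backend.params = params
    backend.p = params.p
    backend.rng = np.random.default_rng(seed)
    from .rlwe_backend import _SlotCodec  # local import to avoid cycle noise

    backend.codec = _SlotCodec(params)
    backend.pk = PublicKey(
        params,
        np.array(env["public"]["b"], dtype=np.int64),
        np.array(env["public"]["a"], dtype=np.int64),
    )
    backend.evk = _ksk_from(params, env["evk"])
    backend.rot_keys = {int(r): _ksk_from(params, d) for r, d in env["rot"].items()}
    if "secret" in env:
        backend.sk = SecretKey(params, np.array(env["secret"]["s"], dtype=np.int64))
    else:
        backend.sk = None
    return backend


# ---------------------------------------------------------------------------
# ciphertexts
# ---------------------------------------------------------------------------


def _ct_dict(ct) -> dict:
    if isinstance(ct, PlainCiphertext):
        return {"vec": _arr(ct.vec)}
    return {
        "c0": _arr(ct.c0),
        "c1": _arr(ct.c1),
        "slots": ct.slot_count,
        "noise": ct.noise_log,
    }


def _ct_from(backend, d: dict):
    if "vec" in d:
        return PlainCiphertext(np.array(d["vec"], dtype=np.int64), backend.p)
    return Ciphertext(
        backend.params,
        np.array(d["c0"], dtype=np.int64),
        np.array(d["c1"], dtype=np.int64),
        int(d["slots"]),
        float(d["noise"]),
    )


def _fingerprint(backend) -> str:
    if isinstance(backend, PlainBackend):
        return f"plaintext-p{backend.p}"
    return backend.params.fingerprint


def _check_fp(env: dict, backend) -> None:
    if env.get("fingerprint") != _fingerprint(backend):
        raise ParameterMismatch(
            "ciphertext bundle and key material carry different parameter "
            f"fingerprints ({env.get('fingerprint')} vs {_fingerprint(backend)})"
        )


def write_ciphertext_bundle(batches, spec: BlockSpec, backend, path, n_user_kmers: int) -> None:
    env = {
        "format": "kmerlock-ciphertexts",
        "backend": getattr(backend, "name", "plaintext"),
        "fingerprint": _fingerprint(backend),
        "spec": spec.to_dict(),
        "n_user_kmers": n_user_kmers,
        "batches": [[_ct_dict(ct) for ct in batch] for batch in batches],
    }
    with open(path, "w") as fh:
        json.dump(env, fh)


def read_ciphertext_bundle(path, backend) -> tuple[list, BlockSpec, int]:
    with open(path) as fh:
        env = json.load(fh)
    if env.get("format") != "kmerlock-ciphertexts":
        raise KmerlockError(f"{path}: not a ciphertext bundle")
    _check_fp(env, backend)
    spec = BlockSpec.from_dict(env["spec"])
    batches = [[_ct_from(backend, d) for d in batch] for batch in env["batches"]]
    return batches, spec, int(env["n_user_kmers"])


def write_match_results(result, backend, path) -> None:
    env = {
        "format": "kmerlock-results",
        "backend": getattr(backend, "name", "plaintext"),
        "fingerprint": _fingerprint(backend),
        "spec": result.spec.to_dict(),
        "n_batches": result.n_batches,
        "groups": [
            {"residue": rid, "allele": allele, "ct": _ct_dict(ct)}
            for (rid, allele), ct in result.counts.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(env, fh)


def read_match_results(path, backend):
    from collections import OrderedDict

    from .equality_protocol import MatchResult

    with open(path) as fh:
        env = json.load(fh)
    if env.get("format") != "kmerlock-results":
        raise KmerlockError(f"{path}: not a results envelope")
    _check_fp(env, backend)
    counts = OrderedDict(
        ((g["residue"], g["allele"]), _ct_from(backend, g["ct"]))
        for g in env["groups"]
    )
    return MatchResult(
        counts=counts,
        spec=BlockSpec.from_dict(env["spec"]),
        n_batches=int(env["n_batches"]),
    )
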