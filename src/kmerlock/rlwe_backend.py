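"""RLWE homomorphic vector machine with exact integer slot batching.

The scheme is a BGV-flavoured ring-LWE cryptosystem on the power-of-two
cyclotomic ring ``R = Z[X]/(X^n + 1)``:

* messages are vectors over ``Z_p`` packed into plaintext slots through the
  CRT isomorphism ``Z_p[X]/(X^n+1) ≅ Z_p^n`` (``p`` prime, ``p ≡ 1 mod 2n``,
  so ``X^n + 1`` splits completely);
* a ciphertext is a pair ``(c0, c1)`` over ``R_q`` with
  ``c0 + c1·s = m + p·e (mod q)`` — decryption reduces centred mod ``q`` and
  then mod ``p``;
* addition and multiplication act slot-wise; slot rotation is the Galois
  automorphism ``X -> X^(5^r)`` followed by key switching back to ``s``.

Slot layout: the message vector of length ``slots`` (a power of two dividing
``n/2``) is repeated along the orbit of ``5`` in ``(Z/2n)*`` and mirrored on
the conjugate orbit, so the automorphism realises an exact cyclic shift of the
vector.  All arithmetic over ``q`` uses a residue number system of word-sized
NTT primes; key switching decomposes along those primes, which keeps every
intermediate inside ``int64``.

The moduli here are sized for correctness at desk scale, NOT for cryptographic
security; see :func:`toy_params`.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from ._ntt import NttPlan, find_ntt_primes, get_plan, is_prime
from .errors import (
    KmerlockError,
    MissingRotationKey,
    NoiseBudgetExhausted,
    ParameterMismatch,
)

__all__ = [
    "RingParams",
    "toy_params",
    "SecretKey",
    "PublicKey",
    "KeySwitchKey",
    "Ciphertext",
    "sk_gen",
    "pk_gen",
    "rot_key_gen",
    "enc",
    "dec",
    "add",
    "mult",
    "mult_plain",
    "rotate",
    "RlweBackend",
    "PlainBackend",
    "PlainCiphertext",
]

_PRIME_BITS = 28


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingParams:
    """Ring, modulus and noise parameters for the scheme.

    Attributes
    ----------
    n : ring degree (power of two); the cyclotomic index is ``M = 2n``.
    p : plaintext modulus, prime with ``p ≡ 1 (mod 2n)``.
    q_primes : word-sized NTT primes whose product is the ciphertext modulus.
    sigma : standard deviation of the discrete-Gaussian error distribution.
    """

    n: int
    p: int
    q_primes: tuple[int, ...]
    sigma: float = 3.2

    def __post_init__(self):
        if self.n & (self.n - 1) or self.n < 8:
            raise ValueError("n must be a power of two >= 8")
        if not is_prime(self.p) or (self.p - 1) % (2 * self.n):
            raise ValueError("p must be prime with p ≡ 1 (mod 2n)")
        for qi in self.q_primes:
            if (qi - 1) % (2 * self.n):
                raise ValueError("every q prime must be ≡ 1 (mod 2n)")
        # digit-product accumulations must stay inside int64
        if len(self.q_primes) * max(self.q_primes) ** 2 >= 2**63:
            raise ValueError("too many / too large q primes for int64 accumulation")

    @property
    def M(self) -> int:
        return 2 * self.n

    @property
    def q(self) -> int:
        return math.prod(self.q_primes)

    @property
    def slots_capacity(self) -> int:
        return self.n // 2

    @property
    def q_log2(self) -> float:
        return sum(math.log2(qi) for qi in self.q_primes)

    @property
    def fresh_noise_log(self) -> float:
        # || m + p(v e + e0 + e1 s) ||_inf with ternary v, s
        return math.log2(self.p * (1 + 6 * self.sigma * (2 * self.n + 2)))

    @property
    def ks_noise_log(self) -> float:
        # || p * sum_k d_k e_k ||_inf, digits bounded by the largest prime
        bound = (
            self.p * len(self.q_primes) * self.n * max(self.q_primes) * 6 * self.sigma
        )
        return math.log2(bound)

    @cached_property
    def fingerprint(self) -> str:
        blob = json.dumps(
            {"n": self.n, "p": self.p, "q_primes": list(self.q_primes), "sigma": self.sigma},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def plan(self) -> NttPlan:
        return get_plan(self.q_primes, self.n)

    def plain_plan(self) -> NttPlan:
        return get_plan((self.p,), self.n)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p": self.p,
            "q_primes": list(self.q_primes),
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RingParams":
        return cls(int(d["n"]), int(d["p"]), tuple(int(x) for x in d["q_primes"]), float(d["sigma"]))


def _default_p(n: int) -> int:
    # 65537 ≡ 1 (mod 2n) for every n ≤ 32768
    if n <= 32768:
        return 65537
    cand = 2 * n + 1
    while not is_prime(cand):
        cand += 2 * n
    return cand


def toy_params(n: int = 1024, b_max: int = 8, p: int | None = None, sigma: float = 3.2) -> RingParams:
    """Desk-scale parameters supporting ``b_max`` sequential multiplications.

    The modulus is sized from the worst-case noise of a product chain of
    ``b_max`` rotated fresh ciphertexts (the protocol's block product) plus
    additive slack for the aggregation steps.  These parameter sets are for
    functional testing only — the lattice dimension is far too small for any
    security claim.
    """
    p = p or _default_p(n)
    n_primes = 4
    for _ in range(4):
        nu_ks = math.log2(p * n_primes * n * 2**_PRIME_BITS * 6 * sigma)
        req = b_max * nu_ks + (b_max - 1) * math.log2(n) + math.log2(p) + 30
        n_primes = max(2, math.ceil(req / (_PRIME_BITS - 0.2)))
    return RingParams(n=n, p=p, q_primes=find_ntt_primes(n_primes, 2 * n), sigma=sigma)


# ---------------------------------------------------------------------------
# slot codec
# ---------------------------------------------------------------------------


class _SlotCodec:
    """CRT slot packing on the orbit of 5 in (Z/2n)*."""

    def __init__(self, params: RingParams):
        self.params = params
        n, M = params.n, params.M
        half = n // 2
        exps = np.empty(half, dtype=np.int64)
        e = 1
        for j in range(half):
            exps[j] = e
            e = e * 5 % M
        self.idx_orbit = (exps - 1) // 2  # eval index of psi^(5^j)
        self.idx_conj = (M - exps - 1) // 2  # eval index of psi^(-5^j)
        self.plan = params.plain_plan()

    def encode(self, vec: np.ndarray) -> np.ndarray:
        """Length-``s`` vector over Z_p -> polynomial coefficients mod p."""
        p, half = self.params.p, self.params.n // 2
        s = len(vec)
        if s == 0 or half % s:
            raise ValueError(f"slot count {s} must divide {half}")
        w = np.tile(np.asarray(vec, dtype=np.int64) % p, half // s)
        evals = np.zeros((1, self.params.n), dtype=np.int64)
        evals[0, self.idx_orbit] = w
        evals[0, self.idx_conj] = w
        return self.plan.inv(evals)[0]

    def decode(self, poly: np.ndarray, s: int) -> np.ndarray:
        evals = self.plan.fwd(poly.reshape(1, -1))[0]
        return evals[self.idx_orbit][:s].copy()


# ---------------------------------------------------------------------------
# keys and ciphertexts
# ---------------------------------------------------------------------------


@dataclass
class SecretKey:
    """sk = (1, s) with ``s`` sampled from the error distribution (ternary)."""

    params: RingParams
    s: np.ndarray  # (n,) int64, small coefficients


@dataclass
class PublicKey:
    """pk = (b, a) with ``b = -a·s + p·e``; stored in the NTT domain."""

    params: RingParams
    b_hat: np.ndarray  # (P, n)
    a_hat: np.ndarray  # (P, n)


@dataclass
class KeySwitchKey:
    """Material converting a ciphertext under ``s_src`` to one under ``s``.

    Digit ``k`` holds ``(b_k, a_k)`` with ``b_k = -a_k·s + p·e_k + (q/q_k)·s_src``;
    decomposition is along the RNS primes, so ``D = len(q_primes)``.
    """

    params: RingParams
    b_hat: np.ndarray  # (P, D, n)
    a_hat: np.ndarray  # (P, D, n)


@dataclass
class Ciphertext:
    """Pair of ring elements in NTT-domain RNS plus a noise estimate.

    Components are kept in the evaluation domain so that addition and
    multiplication are pointwise and rotation is a permutation of evaluation
    points; key switching transforms back and forth internally.
    """

    params: RingParams
    c0: np.ndarray  # (P, n) int64, NTT domain
    c1: np.ndarray  # (P, n) int64, NTT domain
    slot_count: int
    noise_log: float

    @property
    def noise_budget(self) -> float:
        """Bits of headroom before decryption fails (estimate)."""
        return self.params.q_log2 - 1.0 - self.noise_log


def _check_same_params(*objs) -> RingParams:
    fps = {o.params.fingerprint for o in objs}
    if len(fps) != 1:
        raise ParameterMismatch("objects were created under different ring parameters")
    return objs[0].params


# ---------------------------------------------------------------------------
# sampling and RNS helpers
# ---------------------------------------------------------------------------


def _sample_err(params: RingParams, rng: np.random.Generator) -> np.ndarray:
    e = np.rint(rng.normal(0.0, params.sigma, params.n)).astype(np.int64)
    bound = int(math.ceil(6 * params.sigma))
    return np.clip(e, -bound, bound)


def _sample_ternary(params: RingParams, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(-1, 2, params.n).astype(np.int64)


def _to_rns(params: RingParams, coeffs: np.ndarray) -> np.ndarray:
    """Small-coefficient polynomial -> (P, n) residues."""
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    return coeffs.astype(np.int64)[None, :] % p_col


def _digits(params: RingParams, poly_rns: np.ndarray) -> np.ndarray:
    """RNS decomposition digits, broadcast across the prime stack -> (P, D, n)."""
    primes = params.q_primes
    P = len(primes)
    q = params.q
    small = np.empty((P, params.n), dtype=np.int64)
    for k, qk in enumerate(primes):
        inv_k = pow((q // qk) % qk, -1, qk)
        small[k] = poly_rns[k] * inv_k % qk
    p_col = np.array(primes, dtype=np.int64).reshape(P, 1, 1)
    return small[None, :, :] % p_col


def _crt_reconstruct(params: RingParams, poly_rns: np.ndarray) -> np.ndarray:
    """(P, n) residues -> centred big-integer coefficients (object array)."""
    q = params.q
    acc = np.zeros(params.n, dtype=object)
    for k, qk in enumerate(params.q_primes):
        lift = (q // qk) * pow((q // qk) % qk, -1, qk) % q
        acc = acc + poly_rns[k].astype(object) * lift
    acc %= q
    return np.where(acc > q // 2, acc - q, acc)


def _automorphism(params: RingParams, arr: np.ndarray, t: int) -> np.ndarray:
    """Apply ``X -> X^t`` to coefficient-domain RNS arrays (last axis = n)."""
    n = params.n
    i = np.arange(n)
    tgt = i * t % (2 * n)
    sign = np.where(tgt < n, 1, -1).astype(np.int64)
    out = np.empty_like(arr)
    out[..., tgt % n] = arr * sign
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(
        (-1,) + (1,) * (arr.ndim - 1)
    )
    return out % p_col


def _automorphism_eval_perm(params: RingParams, t: int) -> np.ndarray:
    """Permutation realising ``X -> X^t`` directly on NTT evaluation points.

    Evaluation index ``k`` holds the value at ``psi^(2k+1)``; under the
    automorphism the value at exponent ``e`` moves to exponent ``e·t^{-1}``,
    i.e. ``out[k] = in[((2k+1)·t mod 2n - 1) / 2]``.
    """
    M = params.M
    k = np.arange(params.n)
    src = ((2 * k + 1) * t % M - 1) // 2
    return src


def _logadd(a: float, b: float) -> float:
    hi, lo = max(a, b), min(a, b)
    return hi + math.log2(1 + 2 ** (lo - hi))


# ---------------------------------------------------------------------------
# key generation
# ---------------------------------------------------------------------------


def sk_gen(params: RingParams, rng: np.random.Generator) -> SecretKey:
    """Sample the secret ring element from the (ternary) key distribution."""
    return SecretKey(params, _sample_ternary(params, rng))


def _make_ksk(
    params: RingParams,
    sk: SecretKey,
    s_src_rns: np.ndarray,
    rng: np.random.Generator,
) -> KeySwitchKey:
    plan = params.plan()
    primes = params.q_primes
    P = len(primes)
    n = params.n
    q = params.q
    p_col3 = np.array(primes, dtype=np.int64).reshape(P, 1, 1)
    a = rng.integers(0, 2**62, (P, P, n)).astype(np.int64) % p_col3
    a_hat = plan.fwd(a)
    s_hat = plan.fwd(_to_rns(params, sk.s))  # (P, n)
    neg_as = plan.inv((-(a_hat * s_hat[:, None, :] % p_col3)) % p_col3)
    b = neg_as
    for k in range(P):
        e_k = _sample_err(params, rng)
        t_k = (q // primes[k]) % q
        # b_k = -a_k s + p e_k + (q/q_k) * s_src
        for j, qj in enumerate(primes):
            term = (
                params.p * e_k % qj
                + (t_k % qj) * s_src_rns[j] % qj
            )
            b[j, k] = (b[j, k] + term) % qj
    return KeySwitchKey(params, plan.fwd(b), a_hat)


def pk_gen(
    params: RingParams, sk: SecretKey, rng: np.random.Generator
) -> tuple[PublicKey, KeySwitchKey]:
    """Public key ``(b, a)`` with ``b = -a·s + p·e`` and the evaluation key.

    The evaluation key is key-switch material for ``s²`` used to relinearise
    degree-2 ciphertexts after multiplication.
    """
    plan = params.plan()
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    a = rng.integers(0, 2**62, (len(params.q_primes), params.n)).astype(np.int64) % p_col
    a_hat = plan.fwd(a)
    s_rns = _to_rns(params, sk.s)
    s_hat = plan.fwd(s_rns)
    e = _to_rns(params, _sample_err(params, rng) * params.p)
    b_hat = plan.fwd((plan.inv((-(a_hat * s_hat % p_col)) % p_col) + e) % p_col)
    pk = PublicKey(params, b_hat, a_hat)
    s2_rns = plan.inv(s_hat * s_hat % p_col)
    evk = _make_ksk(params, sk, s2_rns, rng)
    return pk, evk


def rot_key_gen(
    params: RingParams, sk: SecretKey, r: int, rng: np.random.Generator
) -> KeySwitchKey:
    """Key-switch material for slot rotation by ``r`` (automorphism X->X^(5^r))."""
    t = pow(5, r, params.M)
    s_src = _automorphism(params, _to_rns(params, sk.s), t)
    return _make_ksk(params, sk, s_src, rng)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def enc(
    params: RingParams,
    pk: PublicKey,
    m: np.ndarray,
    rng: np.random.Generator,
    codec: _SlotCodec | None = None,
) -> Ciphertext:
    """Encrypt a slot vector (values in ``[0, p)``) under the public key."""
    m = np.asarray(m, dtype=np.int64)
    if np.any((m < 0) | (m >= params.p)):
        raise KmerlockError("slot values must lie in [0, p)")
    codec = codec or _SlotCodec(params)
    plan = params.plan()
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    m_poly = codec.encode(m)
    v_hat = plan.fwd(_to_rns(params, _sample_ternary(params, rng)))
    e0 = _sample_err(params, rng) * params.p
    e1 = _sample_err(params, rng) * params.p
    c0 = (v_hat * pk.b_hat + plan.fwd(_to_rns(params, m_poly + e0))) % p_col
    c1 = (v_hat * pk.a_hat + plan.fwd(_to_rns(params, e1))) % p_col
    return Ciphertext(params, c0, c1, len(m), params.fresh_noise_log)


def dec(sk: SecretKey, ct: Ciphertext, codec: _SlotCodec | None = None) -> np.ndarray:
    """Decrypt: ``[<c, sk>]_q`` centred, reduced mod ``p``, slot-decoded."""
    params = _check_same_params(sk, ct)
    if ct.noise_budget <= 0:
        raise NoiseBudgetExhausted(
            f"estimated noise ({ct.noise_log:.0f} bits) exceeds q/2"
        )
    codec = codec or _SlotCodec(params)
    plan = params.plan()
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    s_hat = plan.fwd(_to_rns(params, sk.s))
    phase = plan.inv((ct.c0 + ct.c1 * s_hat) % p_col)
    coeffs = _crt_reconstruct(params, phase) % params.p
    return codec.decode(coeffs.astype(np.int64), ct.slot_count)


def add(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    params = _check_same_params(ct1, ct2)
    if ct1.slot_count != ct2.slot_count:
        raise KmerlockError("slot count mismatch")
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    return Ciphertext(
        params,
        (ct1.c0 + ct2.c0) % p_col,
        (ct1.c1 + ct2.c1) % p_col,
        ct1.slot_count,
        _logadd(ct1.noise_log, ct2.noise_log),
    )


def _key_switch(
    params: RingParams,
    c1_eval: np.ndarray,
    ksk: KeySwitchKey,
) -> tuple[np.ndarray, np.ndarray]:
    """NTT-domain component under ``s_src`` -> ciphertext pair under ``s``."""
    plan = params.plan()
    P = len(params.q_primes)
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(P, 1)
    p_col3 = p_col.reshape(P, 1, 1)
    d_hat = plan.fwd(_digits(params, plan.inv(c1_eval)))  # (P, D, n)
    acc0 = (d_hat * ksk.b_hat % p_col3).sum(axis=1) % p_col
    acc1 = (d_hat * ksk.a_hat % p_col3).sum(axis=1) % p_col
    return acc0, acc1


def mult(ct1: Ciphertext, ct2: Ciphertext, evk: KeySwitchKey) -> Ciphertext:
    """Slot-wise product via tensoring and relinearisation with ``evk``."""
    params = _check_same_params(ct1, ct2, evk)
    if ct1.slot_count != ct2.slot_count:
        raise KmerlockError("slot count mismatch")
    noise = ct1.noise_log + ct2.noise_log + math.log2(params.n)
    noise = _logadd(noise, params.ks_noise_log)
    if noise >= params.q_log2 - 1.0:
        raise NoiseBudgetExhausted(
            f"multiplication would reach {noise:.0f} noise bits "
            f"(q has {params.q_log2:.0f}); use parameters with a larger depth"
        )
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    d0 = ct1.c0 * ct2.c0 % p_col
    d1 = (ct1.c0 * ct2.c1 % p_col + ct1.c1 * ct2.c0) % p_col
    d2 = ct1.c1 * ct2.c1 % p_col
    k0, k1 = _key_switch(params, d2, evk)
    return Ciphertext(
        params, (d0 + k0) % p_col, (d1 + k1) % p_col, ct1.slot_count, noise
    )


def mult_plain(
    ct: Ciphertext, vec: np.ndarray, codec: _SlotCodec | None = None
) -> Ciphertext:
    """Slot-wise product with an unencrypted vector (no relinearisation)."""
    params = ct.params
    codec = codec or _SlotCodec(params)
    plan = params.plan()
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    m_hat = plan.fwd(_to_rns(params, codec.encode(np.asarray(vec))))
    noise = ct.noise_log + math.log2(params.n * params.p / 2)
    return Ciphertext(
        params,
        ct.c0 * m_hat % p_col,
        ct.c1 * m_hat % p_col,
        ct.slot_count,
        noise,
    )


def rotate(ct: Ciphertext, r: int, rot_keys: dict[int, KeySwitchKey]) -> Ciphertext:
    """Cyclic slot rotation: slot ``i`` of the result holds slot ``i+r``."""
    params = ct.params
    r = int(r) % ct.slot_count
    if r == 0:
        return Ciphertext(params, ct.c0.copy(), ct.c1.copy(), ct.slot_count, ct.noise_log)
    if r not in rot_keys:
        raise MissingRotationKey(f"no key-switch material for rotation amount {r}")
    _check_same_params(ct, rot_keys[r])
    p_col = np.array(params.q_primes, dtype=np.int64).reshape(-1, 1)
    src = _automorphism_eval_perm(params, pow(5, r, params.M))
    a0 = ct.c0[:, src]
    a1 = ct.c1[:, src]
    k0, k1 = _key_switch(params, a1, rot_keys[r])
    noise = _logadd(ct.noise_log, params.ks_noise_log)
    return Ciphertext(params, (a0 + k0) % p_col, k1, ct.slot_count, noise)


# ---------------------------------------------------------------------------
# backend objects (the interface the protocol layer consumes)
# ---------------------------------------------------------------------------


class RlweBackend:
    """Keyed RLWE backend: keygen at construction, rotation keys on demand."""

    name = "rlwe"

    def __init__(self, params: RingParams, seed: int):
        self.params = params
        self.p = params.p
        self.rng = np.random.default_rng(seed)
        self.codec = _SlotCodec(params)
        self.sk = sk_gen(params, self.rng)
        self.pk, self.evk = pk_gen(params, self.sk, self.rng)
        self.rot_keys: dict[int, KeySwitchKey] = {}

    def ensure_rotation_keys(self, amounts) -> None:
        for r in sorted(set(int(a) for a in amounts)):
            r %= self.params.slots_capacity
            if r and r not in self.rot_keys:
                self.rot_keys[r] = rot_key_gen(self.params, self.sk, r, self.rng)

    # -- operation contract -------------------------------------------
    def enc(self, vec) -> Ciphertext:
        return enc(self.params, self.pk, vec, self.rng, self.codec)

    def dec(self, ct: Ciphertext) -> np.ndarray:
        return dec(self.sk, ct, self.codec)

    def add(self, ct1, ct2) -> Ciphertext:
        return add(ct1, ct2)

    def mult(self, ct1, ct2) -> Ciphertext:
        return mult(ct1, ct2, self.evk)

    def mult_plain(self, ct, vec) -> Ciphertext:
        return mult_plain(ct, vec, self.codec)

    def rotate(self, ct, r: int) -> Ciphertext:
        return rotate(ct, r, self.rot_keys)

    def max_slots(self) -> int:
        return self.params.slots_capacity


@dataclass
class PlainCiphertext:
    """Stand-in ciphertext of the reference backend: the vector itself."""

    vec: np.ndarray
    p: int

    @property
    def slot_count(self) -> int:
        return len(self.vec)


class PlainBackend:
    """Reference backend: identical operation contract, exact arithmetic mod p.

    Used both as the correctness oracle for the RLWE backend and as the fast
    execution mode for large read sets.
    """

    name = "plaintext"

    def __init__(self, p: int = 65537, seed: int | None = None):
        if p ** 2 >= 2**62:
            raise ValueError("p too large for int64 slot products")
        self.p = p

    def ensure_rotation_keys(self, amounts) -> None:  # no-op, kept for parity
        return None

    def enc(self, vec) -> PlainCiphertext:
        v = np.asarray(vec, dtype=np.int64) % self.p
        return PlainCiphertext(v.copy(), self.p)

    def dec(self, ct: PlainCiphertext) -> np.ndarray:
        return ct.vec.copy()

    def add(self, c1: PlainCiphertext, c2: PlainCiphertext) -> PlainCiphertext:
        return PlainCiphertext((c1.vec + c2.vec) % self.p, self.p)

    def mult(self, c1: PlainCiphertext, c2: PlainCiphertext) -> PlainCiphertext:
        return PlainCiphertext(c1.vec * c2.vec % self.p, self.p)

    def mult_plain(self, ct: PlainCiphertext, vec) -> PlainCiphertext:
        return PlainCiphertext(ct.vec * (np.asarray(vec, dtype=np.int64) % self.p) % self.p, self.p)

    def rotate(self, ct: PlainCiphertext, r: int) -> PlainCiphertext:
        return PlainCiphertext(np.roll(ct.vec, -int(r)), self.p)

    def max_slots(self) -> int:
        return 1 << 30
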