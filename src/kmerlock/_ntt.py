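"""Negacyclic number-theoretic transforms over stacks of word-sized primes.

Everything here works on integer arrays of shape ``(P, ..., n)`` where ``P``
indexes a tuple of NTT-friendly primes (each ``≡ 1 mod 2n``) and ``n`` is the
ring degree of ``Z[X]/(X^n + 1)``.  The forward transform evaluates a
polynomial at the primitive ``2n``-th roots of unity ``psi^(2k+1)`` in natural
order ``k = 0..n-1``, which is the ordering the slot-encoding layer relies on.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "NttPlan",
    "find_ntt_primes",
    "is_prime",
    "root_of_unity",
]


def is_prime(x: int) -> bool:
    """Deterministic Miller-Rabin for word-sized integers."""
    if x < 2:
        return False
    for sp in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37):
        if x % sp == 0:
            return x == sp
    d, r = x - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    # deterministic witness set for x < 3.3e24
    for a in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37):
        y = pow(a, d, x)
        if y in (1, x - 1):
            continue
        for _ in range(r - 1):
            y = y * y % x
            if y == x - 1:
                break
        else:
            return False
    return True


def find_ntt_primes(count: int, modulus: int, bits: int = 28) -> tuple[int, ...]:
    """Largest ``count`` primes below ``2**bits`` that are ``≡ 1 (mod modulus)``."""
    primes = []
    # candidates are 1 + k*modulus, scanned downward
    k = (2**bits - 2) // modulus
    while len(primes) < count and k > 0:
        cand = k * modulus + 1
        if is_prime(cand):
            primes.append(cand)
        k -= 1
    if len(primes) < count:
        raise ValueError(
            f"could not find {count} NTT primes ≡ 1 mod {modulus} below 2^{bits}"
        )
    return tuple(primes)


def root_of_unity(order: int, prime: int) -> int:
    """An element of exact multiplicative order ``order`` modulo ``prime``."""
    if (prime - 1) % order:
        raise ValueError(f"{order} does not divide {prime}-1")
    for x in range(2, prime):
        g = pow(x, (prime - 1) // order, prime)
        if pow(g, order // 2, prime) != 1:
            return g
    raise ValueError("no root of unity found")  # pragma: no cover


def _bit_reverse(n: int) -> np.ndarray:
    bits = n.bit_length() - 1
    idx = np.arange(n)
    rev = np.zeros(n, dtype=np.int64)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev


class NttPlan:
    """Precomputed tables for batched negacyclic NTTs over a prime stack."""

    def __init__(self, primes: tuple[int, ...], n: int):
        if n & (n - 1):
            raise ValueError("ring degree must be a power of two")
        self.primes = tuple(int(p) for p in primes)
        self.n = n
        P = len(self.primes)
        self.p_col = np.array(self.primes, dtype=np.int64).reshape(P, 1)
        self._brev = _bit_reverse(n)

        psi = np.array([root_of_unity(2 * n, p) for p in self.primes], dtype=object)
        self._psi_pows = np.empty((P, n), dtype=np.int64)
        self._ipsi_pows = np.empty((P, n), dtype=np.int64)
        self._n_inv = np.empty((P, 1), dtype=np.int64)
        for j, p in enumerate(self.primes):
            ps = int(psi[j])
            ips = pow(ps, -1, p)
            acc_f, acc_i = 1, 1
            for i in range(n):
                self._psi_pows[j, i] = acc_f
                self._ipsi_pows[j, i] = acc_i
                acc_f = acc_f * ps % p
                acc_i = acc_i * ips % p
            self._n_inv[j, 0] = pow(n, -1, p)

        # per-stage twiddles for the cyclic DFT on omega = psi^2
        self._fwd_tw: list[np.ndarray] = []
        self._inv_tw: list[np.ndarray] = []
        half = 1
        while half < n:
            tw_f = np.empty((P, half), dtype=np.int64)
            tw_i = np.empty((P, half), dtype=np.int64)
            for j, p in enumerate(self.primes):
                w = pow(int(psi[j]), 2 * (n // (2 * half)), p)
                wi = pow(w, -1, p)
                af, ai = 1, 1
                for i in range(half):
                    tw_f[j, i] = af
                    tw_i[j, i] = ai
                    af = af * w % p
                    ai = ai * wi % p
            self._fwd_tw.append(tw_f)
            self._inv_tw.append(tw_i)
            half *= 2

    # -- shape helpers -------------------------------------------------
    def _expand(self, table: np.ndarray, ndim: int) -> np.ndarray:
        """Reshape a (P, k) table so it broadcasts against (P, ..., n) data."""
        P, k = table.shape
        return table.reshape((P,) + (1,) * (ndim - 2) + (k,))

    def _dft(self, a: np.ndarray, tables: list[np.ndarray]) -> np.ndarray:
        n = self.n
        shape = a.shape
        a = a[..., self._brev]
        half, s = 1, 0
        while half < n:
            blk = a.reshape(shape[:-1] + (n // (2 * half), 2, half))
            even = blk[..., 0, :]
            tw = self._expand(tables[s], even.ndim)
            odd = blk[..., 1, :] * tw % self._expand(self.p_col, even.ndim)
            p_bc = self._expand(self.p_col, even.ndim)
            a = np.concatenate([(even + odd) % p_bc, (even - odd) % p_bc], axis=-1)
            a = a.reshape(shape)
            half *= 2
            s += 1
        return a

    # -- public API ----------------------------------------------------
    def fwd(self, a: np.ndarray) -> np.ndarray:
        """Coefficients -> evaluations at psi^(2k+1), natural k order."""
        p_bc = self._expand(self.p_col, a.ndim)
        a = a % p_bc
        a = a * self._expand(self._psi_pows, a.ndim) % p_bc
        return self._dft(a, self._fwd_tw)

    def inv(self, a: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`fwd`."""
        p_bc = self._expand(self.p_col, a.ndim)
        a = self._dft(a % p_bc, self._inv_tw)
        a = a * self._expand(self._n_inv, a.ndim) % p_bc
        return a * self._expand(self._ipsi_pows, a.ndim) % p_bc

    def negacyclic_mul(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Product of polynomials modulo ``X^n + 1`` (per prime row)."""
        return self.inv(self.fwd(a) * self.fwd(b) % self._expand(self.p_col, a.ndim))


@lru_cache(maxsize=32)
def get_plan(primes: tuple[int, ...], n: int) -> NttPlan:
    return NttPlan(primes, n)
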