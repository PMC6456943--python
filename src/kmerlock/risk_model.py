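"""False-negative risk of the panel scheme from mutation proximity statistics.

The equality test needs a perfect match over K bases around a panel SNP, so a
second, unannotated mutation landing within the same K-mer window can mask a
residue entirely.  Given a catalog of known somatic mutations, the chance that
a random mutation pair falls within ``window`` bp of each other is estimated
as ``r = close_pairs / total_pairs``; a panel of ``N`` residues then has

    P = 1 - (1 - r)^C(N,2)

probability of containing at least one such masking pair.  The reference
catalog in the source study contributes 116,607 somatic mutations with 1,308
pairs closer than 32 bp out of C(116607, 2) = 6,798,537,921 possible pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MutationCatalog",
    "RiskEstimate",
    "pair_count",
    "count_close_pairs",
    "fn_risk",
    "overlap_chance",
    "risk_table",
    "percent_2sf",
]


@dataclass
class MutationCatalog:
    """Sorted, deduplicated mutation positions per chromosome."""

    positions: dict[str, np.ndarray]

    @classmethod
    def from_records(cls, records) -> "MutationCatalog":
        """Build from an iterable of ``(chrom, pos)`` pairs."""
        by_chrom: dict[str, set[int]] = {}
        for chrom, pos in records:
            by_chrom.setdefault(str(chrom), set()).add(int(pos))
        return cls(
            {c: np.array(sorted(s), dtype=np.int64) for c, s in sorted(by_chrom.items())}
        )

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"], comment="#")
        return cls.from_records(df.itertuples(index=False))

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.positions.values())


@dataclass
class RiskEstimate:
    """Probability that a panel of N residues contains a masking mutation pair."""

    N: int
    window: int
    close_pairs: int
    total_pairs: int
    P: float

    @property
    def percent(self) -> float:
        return 100.0 * self.P


def pair_count(n: int) -> int:
    """Number of unordered pairs among ``n`` items: n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) // 2


def count_close_pairs(catalog: MutationCatalog, window: int = 32) -> int:
    """Unordered same-chromosome pairs with ``|pos_i - pos_j| <= window``.

    Linear scan over the sorted positions per chromosome (two-pointer via
    searchsorted); the boundary is inclusive.
    """
    total = 0
    for pos in catalog.positions.values():
        hi = np.searchsorted(pos, pos + window, side="right")
        total += int((hi - np.arange(1, len(pos) + 1)).sum())
    return total


def fn_risk(close_pairs: int, total_pairs: int, N: int, window: int = 32) -> RiskEstimate:
    """Evaluate ``P = 1 - (1 - close/total)^C(N,2)`` (log-space for stability)."""
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    if not 0 <= close_pairs <= total_pairs:
        raise ValueError("close_pairs must lie in [0, total_pairs]")
    if N < 0:
        raise ValueError("N must be >= 0")
    c = pair_count(N)
    ratio = close_pairs / total_pairs
    P = -math.expm1(c * math.log1p(-ratio)) if ratio < 1 else float(c > 0)
    return RiskEstimate(N=N, window=window, close_pairs=close_pairs,
                        total_pairs=total_pairs, P=P)


def overlap_chance(overlap_len: int) -> float:
    """Chance that two unrelated uniform-random flanks share a mismatch-free
    overlap of ``overlap_len`` bp in either of the two orientations:
    ``1 - (1 - 2·4^(-v))^2``."""
    if overlap_len < 1:
        raise ValueError("overlap_len must be >= 1")
    return -math.expm1(2.0 * math.log1p(-2.0 * 4.0 ** (-overlap_len)))


def risk_table(
    close_pairs: int,
    total_pairs: int,
    panel_sizes,
    window: int = 32,
) -> pd.DataFrame:
    """Risk estimates for a range of panel sizes, as a tidy table."""
    rows = []
    for N in panel_sizes:
        est = fn_risk(close_pairs, total_pairs, int(N), window)
        rows.append(
            {
                "N": est.N,
                "pairs": pair_count(est.N),
                "P": est.P,
                "P_percent": est.percent,
                "P_percent_2sf": percent_2sf(est.P),
            }
        )
    return pd.DataFrame(rows)


def percent_2sf(p: float) -> float:
    """Probability -> percent rounded half-up to 2 significant figures."""
    x = 100.0 * p
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - 1)
    return math.floor(x / scale + 0.5) * scale
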