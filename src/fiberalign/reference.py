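"""Reference locus maps: the 5'->3' ordered genomic positions of imaged loci."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReferenceMap"]


@dataclass(frozen=True)
class ReferenceMap:
    """Ordered genomic coordinates (bp) of the imaged loci of one chromosome.

    Locus orders are 1-based and run 5' to 3'.  ``interval(t, u)`` yields the
    genomic separation L in bp between two orders, the quantity the Gaussian
    chain converts into an expected spatial variance.
    """

    chromosome: str
    positions_bp: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_bp, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("a reference map needs at least two ordered loci")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("locus coordinates must be strictly increasing 5'->3'")
        object.__setattr__(self, "positions_bp", pos)

    @property
    def n_loci(self) -> int:
        return int(self.positions_bp.size)

    def interval(self, t: int, u: int) -> float:
        """Genomic distance in bp between locus orders ``t`` and ``u`` (1-based)."""
        if not (1 <= t <= self.n_loci and 1 <= u <= self.n_loci):
            raise IndexError("locus order out of range")
        return float(abs(self.positions_bp[u - 1] - self.positions_bp[t - 1]))

    def intervals(self) -> np.ndarray:
        """Adjacent-locus genomic intervals, length ``n_loci - 1``."""
        return np.diff(self.positions_bp)

    def scrambled(self, rng: np.random.Generator) -> "ReferenceMap":
        """Return a map whose adjacent-interval sequence is randomly permuted.

        The interval multiset (and hence total span) is preserved, but the
        observed spatial distances of a chain generated under the original
        map no longer abide by the permuted genomic separations -- the null
        construction behind the karyotype acceptance threshold.
        """
        iv = rng.permutation(self.intervals())
        pos = self.positions_bp[0] + np.concatenate([[0.0], np.cumsum(iv)])
        return ReferenceMap(self.chromosome, pos)
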