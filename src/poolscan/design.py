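"""Experimental design: sequenced lines, selection regimes, pool sizes.

The reference design is two unselected control lines (C1, C2) and four
selection lines (S1..S4), each sequenced as a single pool.  The design
object owns the pair bookkeeping that the rest of the pipeline relies on:
which unordered line pairs cross the regime boundary ("between", the
selection-vs-control comparisons carrying the signal) and which stay
inside one regime ("within", the drift noise floor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

CONTROL = "control"
SELECTION = "selection"

_VALID_REGIMES = frozenset({CONTROL, SELECTION})


@dataclass(frozen=True)
class PoolDesign:
    """Line labels, their regimes, and the number of chromosomes per pool.

    Parameters
    ----------
    line_ids : tuple of str
        Ordered pool labels, matching sync column order.
    regimes : tuple of str
        Per line, ``"control"`` or ``"selection"``.
    pool_sizes : tuple of int
        Per line, number of chromosomes sampled into the pool.
    """

    line_ids: tuple[str, ...]
    regimes: tuple[str, ...]
    pool_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.line_ids) != len(set(self.line_ids)):
            raise ValueError("duplicate line ids")
        if len(self.regimes) != len(self.line_ids):
            raise ValueError("regimes must match line_ids in length")
        if len(self.pool_sizes) != len(self.line_ids):
            raise ValueError("pool_sizes must match line_ids in length")
        bad = set(self.regimes) - _VALID_REGIMES
        if bad:
            raise ValueError(f"unknown regimes: {sorted(bad)}")
        if any(n <= 0 for n in self.pool_sizes):
            raise ValueError("pool sizes must be positive")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def all_pairs(self) -> list[tuple[int, int]]:
        """All C(L, 2) unordered line-index pairs, lexicographic."""
        return list(itertools.combinations(range(self.n_lines), 2))

    def between_pairs(self) -> list[tuple[int, int]]:
        """Pairs crossing the regime boundary (control vs selection)."""
        return [
            (i, j)
            for i, j in self.all_pairs()
            if self.regimes[i] != self.regimes[j]
        ]

    def within_pairs(self) -> list[tuple[int, int]]:
        """Same-regime pairs (control-control and selection-selection)."""
        return [
            (i, j)
            for i, j in self.all_pairs()
            if self.regimes[i] == self.regimes[j]
        ]

    def pair_label(self, pair: tuple[int, int]) -> str:
        i, j = pair
        return f"{self.line_ids[i]}:{self.line_ids[j]}"

    def index_of(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise KeyError(f"unknown line id {line_id!r}") from None


def default_design(pool_size: int = 200) -> PoolDesign:
    """The canonical 2-control x 4-selection design (C1, C2, S1..S4)."""
    return PoolDesign(
        line_ids=("C1", "C2", "S1", "S2", "S3", "S4"),
        regimes=(CONTROL, CONTROL, SELECTION, SELECTION, SELECTION, SELECTION),
        pool_sizes=(pool_size,) * 6,
    )
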