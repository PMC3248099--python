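"""Wright's inbreeding coefficient from a pedigree table.

F of an individual equals the kinship between its parents; kinship is
computed by the tabular (recursive) method, which agrees with Wright's
path-counting formula on any acyclic pedigree and is robust to complex,
looped ancestries.  Unknown parents are treated as unique unrelated
founders.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Mapping

__all__ = ["Pedigree", "read_pedigree", "kinship", "inbreeding_coefficient"]

UNKNOWN = ("", "0", ".", "NA", None)


class Pedigree:
    """individual -> (sire, dam); ``None`` marks an unknown parent."""

    def __init__(self, parents: Mapping[str, tuple[str | None, str | None]]) -> None:
        self.parents: dict[str, tuple[str | None, str | None]] = {
            ind: (
                None if s in UNKNOWN else s,
                None if d in UNKNOWN else d,
            )
            for ind, (s, d) in parents.items()
        }
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(ind: str, stack: list[str]) -> None:
            if state.get(ind) == 1:
                return
            if state.get(ind) == 0:
                raise ValueError(f"cyclic pedigree at {ind!r}: {' -> '.join(stack)}")
            state[ind] = 0
            for p in self.parents.get(ind, (None, None)):
                if p is not None:
                    visit(p, stack + [p])
            state[ind] = 1

        for ind in self.parents:
            visit(ind, [ind])

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        return self.parents.get(ind, (None, None))

    def __contains__(self, ind: str) -> bool:
        return ind in self.parents

    def __len__(self) -> int:
        return len(self.parents)


def read_pedigree(path: str | Path) -> Pedigree:
    """Pedigree TSV: id, sire, dam; '0' or empty marks an unknown parent."""
    parents: dict[str, tuple[str | None, str | None]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("id\t"):
            continue
        fields = (line.split("\t") + ["", ""])[:3]
        parents[fields[0]] = (fields[1], fields[2])
    return Pedigree(parents)


def kinship(ped: Pedigree, a: str | None, b: str | None) -> float:
    """Coefficient of kinship: probability that one allele sampled from each
    of ``a`` and ``b`` is identical by descent."""

    @lru_cache(maxsize=None)
    def phi(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        if x == y:
            sx, dx = ped.parents_of(x)
            return 0.5 * (1.0 + phi(sx, dx))
        # recurse on the individual appearing later in a topological order;
        # depth works because the pedigree is acyclic
        if _depth(x) < _depth(y):
            x, y = y, x
        sx, dx = ped.parents_of(x)
        return 0.5 * (phi(sx, y) + phi(dx, y))

    @lru_cache(maxsize=None)
    def _depth(ind: str) -> int:
        s, d = ped.parents_of(ind)
        return 1 + max(
            _depth(s) if s is not None else 0,
            _depth(d) if d is not None else 0,
        )

    return phi(a, b)


def inbreeding_coefficient(ped: Pedigree, individual: str) -> float:
    """Wright's F: the kinship between the individual's parents.  Founders
    (both parents unknown) have F = 0."""
    if individual not in ped:
        raise KeyError(f"{individual!r} not in pedigree")
    sire, dam = ped.parents_of(individual)
    return kinship(ped, sire, dam)
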