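"""Half-diallel mating designs.

A half diallel crosses ``p`` parents in all unordered pairs without
reciprocals.  With selfs (the parents themselves) included the design has
``p(p+1)/2`` genotype entries — the layout required by Griffing's Method 2,
which analyses parents and one set of F1 hybrids together.  Entries are laid
out in a randomized complete block design (RCBD): every entry appears exactly
once in each of ``b`` blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DiallelDesign:
    """A half-diallel crossing design with an RCBD field layout.

    Parameters
    ----------
    parent_ids
        Unique labels for the ``p`` parents. Order fixes the index used by
        every downstream matrix (GCA vectors, SCA and distance matrices).
    blocks
        Number of complete blocks ``b`` (replications). Must be at least 2,
        otherwise the ANOVA error stratum has no degrees of freedom.
    include_selfs
        Whether parents themselves are entries (required for Method 2).
    """

    parent_ids: tuple[str, ...]
    blocks: int = 3
    include_selfs: bool = True

    def __init__(self, parent_ids, blocks: int = 3, include_selfs: bool = True):
        parent_ids = tuple(str(x) for x in parent_ids)
        if len(set(parent_ids)) != len(parent_ids):
            raise ValueError("parent_ids must be unique")
        if len(parent_ids) < 2:
            raise ValueError("a diallel needs at least 2 parents")
        if blocks < 2:
            raise ValueError(
                "blocks must be >= 2: with a single block the RCBD "
                "error stratum is undefined"
            )
        object.__setattr__(self, "parent_ids", parent_ids)
        object.__setattr__(self, "blocks", int(blocks))
        object.__setattr__(self, "include_selfs", bool(include_selfs))

    @property
    def p(self) -> int:
        return len(self.parent_ids)

    @property
    def n_hybrids(self) -> int:
        p = self.p
        return p * (p - 1) // 2

    @property
    def n_entries(self) -> int:
        return self.n_hybrids + (self.p if self.include_selfs else 0)

    @property
    def entries(self) -> list[tuple[str, str]]:
        """Genotype entries as (parent_a, parent_b) with a <= b in design order.

        Selfs appear as (x, x). Each entry occurs once per block in the RCBD.
        """
        ids = self.parent_ids
        out: list[tuple[str, str]] = []
        for i in range(self.p):
            start = i if self.include_selfs else i + 1
            for j in range(start, self.p):
                out.append((ids[i], ids[j]))
        return out

    @property
    def hybrid_entries(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.entries if a != b]

    def index_of(self, parent: str) -> int:
        return self.parent_ids.index(parent)
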