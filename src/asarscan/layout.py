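"""Genome layout: chromosome names, lengths, and the X-control designation.

The pipeline is reference-agnostic; a :class:`GenomeLayout` carries the
ordered chromosome list with lengths and marks which chromosome plays the
"X control" role (skewed/clonal X inactivation serving as the internal
positive control for epigenetic AEI and ASRT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name -> length map with an optional X designation.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp, in genome order.
    x_chromosome
        Name of the chromosome used as the X-inactivation internal control,
        or ``None`` when no such control exists in the dataset.
    """

    chromosomes: Mapping[str, int]
    x_chromosome: str | None = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        object.__setattr__(self, "chromosomes", dict(self.chromosomes))
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.x_chromosome is not None and self.x_chromosome not in self.chromosomes:
            raise ValueError(f"x_chromosome {self.x_chromosome!r} not in layout")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c != self.x_chromosome]

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)
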