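"""The 22-category nucleated-cell taxonomy used for marrow differentials.

Sixteen categories enter the differential cell count; six (apoptotic cell,
atypical lymphocyte, immature lymphocyte, prolymphocyte, smudge cell and
the catch-all "others") are recognised by the classifier but excluded from
the count denominator, mirroring standard manual counting practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources


@dataclass(frozen=True)
class CellTaxonomy:
    """Ordered class names with a per-class countable flag."""

    names: tuple[str, ...]
    countable: tuple[bool, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.countable):
            raise ValueError("names and countable flags differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate class names")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def countable_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.countable) if c)

    @property
    def excluded_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.countable) if not c)

    def is_countable(self, name: str) -> bool:
        return self.countable[self._index[name]]


def load_default_taxonomy() -> CellTaxonomy:
    """Load the packaged 22-class marrow taxonomy (16 countable)."""
    text = resources.files("marrowdcc.data").joinpath("cell_taxonomy.tsv").read_text()
    names: list[str] = []
    flags: list[bool] = []
    for line in text.strip().splitlines()[1:]:
        name, flag = line.split("\t")
        names.append(name)
        flags.append(flag.strip() == "1")
    tax = CellTaxonomy(tuple(names), tuple(flags))
    if len(tax) != 22 or len(tax.countable_names) != 16:
        raise RuntimeError("packaged taxonomy must list 22 classes, 16 countable")
    return tax


DEFAULT_TAXONOMY = load_default_taxonomy()
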