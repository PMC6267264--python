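"""Region-of-interest label sets.

A :class:`RoiSet` is an ordered, unique list of ROI labels. Its order is the
canonical row/column order of every matrix in the pipeline — connectomes,
RDMs, and beta tables are always stored and compared in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True)
class RoiSet:
    """Ordered set of ROI labels defining canonical matrix order.

    Parameters
    ----------
    labels
        Ordered unique region labels. The default constructor
        :meth:`default` produces 43 generic labels ``ROI01..ROI43``,
        matching the lateral associative-cortex parcellation size this
        pipeline was designed around; anatomical names may be substituted.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("RoiSet needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @classmethod
    def default(cls, n: int = 43) -> "RoiSet":
        width = max(2, len(str(n)))
        return cls(tuple(f"ROI{i:0{width}d}" for i in range(1, n + 1)))

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "RoiSet":
        return cls(tuple(labels))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, RoiSet):
            return self.labels == other.labels
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.labels)
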