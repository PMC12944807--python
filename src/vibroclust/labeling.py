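"""Assignment of items (compounds) to clusters or categories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = ["Labeling", "LabelAlignmentError"]


class LabelAlignmentError(ValueError):
    """Two labelings do not cover the same set of item ids."""


@dataclass(frozen=True)
class Labeling:
    """Maps each item id to one label.

    Labels may be integer cluster indices or categorical descriptors
    (e.g. odor words); every id carries exactly one label.
    """

    ids: tuple
    values: tuple

    def __post_init__(self):
        ids = tuple(self.ids)
        values = tuple(self.values)
        if len(ids) != len(values):
            raise ValueError("ids and values must be equally long")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in labeling")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_dict(cls, mapping: Mapping[Hashable, Hashable]) -> "Labeling":
        items = list(mapping.items())
        return cls(tuple(k for k, _ in items), tuple(v for _, v in items))

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, item_id):
        return self.to_dict()[item_id]

    def to_dict(self) -> dict:
        return dict(zip(self.ids, self.values))

    @property
    def n_labels(self) -> int:
        return len(set(self.values))

    def codes(self, order: Sequence | None = None) -> np.ndarray:
        """Integer codes 0..k-1 in first-appearance order, aligned to ``order``.

        With ``order=None`` the labeling's own id order is used.
        """
        mapping = self.to_dict()
        if order is None:
            order = self.ids
        missing = [i for i in order if i not in mapping]
        if missing:
            raise LabelAlignmentError(f"ids missing from labeling: {missing!r}")
        seen: dict = {}
        codes = np.empty(len(order), dtype=int)
        for pos, item_id in enumerate(order):
            lab = mapping[item_id]
            if lab not in seen:
                seen[lab] = len(seen)
            codes[pos] = seen[lab]
        return codes

    def relabel_contiguous(self) -> "Labeling":
        """Replace labels by integer codes 0..k-1 in first-appearance order."""
        return Labeling(self.ids, tuple(int(c) for c in self.codes()))


def aligned_codes(a: Labeling, b: Labeling) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of two labelings over the same id set, in a's id order."""
    if set(a.ids) != set(b.ids):
        only_a = sorted(set(a.ids) - set(b.ids), key=str)
        only_b = sorted(set(b.ids) - set(a.ids), key=str)
        raise LabelAlignmentError(
            f"labelings cover different ids (only in first: {only_a!r}; "
            f"only in second: {only_b!r})"
        )
    return a.codes(), b.codes(order=a.ids)
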