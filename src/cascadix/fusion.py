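"""Stage 3: concatenation fusion of sample-aligned feature sets.

Fusion is a pure column-wise concatenation — no re-weighting, no
re-scaling (standardisation happens per training fold inside the
classifier stage).  ``enumerate_fusions`` generates every subset of the
requested sizes, which for four backbones and sizes {2, 3, 4} yields the
canonical 6 + 4 + 1 = 11 combinations.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .datatypes import AlignmentError, FusionSet, InvalidSpecificationError

__all__ = ["concat", "enumerate_fusions"]


def concat(components: Sequence) -> FusionSet:
    """Concatenate feature sets column-wise in the given component order.

    Every component must carry an identical label vector in identical row
    order; anything else is a sample-alignment bug, not a broadcasting
    opportunity.
    """
    if len(components) == 0:
        raise InvalidSpecificationError("need at least one component")
    ref = components[0]
    for c in components[1:]:
        if c.values.shape[0] != ref.values.shape[0] or not np.array_equal(
            c.labels, ref.labels
        ):
            raise AlignmentError(
                f"components {ref.name!r} and {c.name!r} are not sample-aligned"
            )
    values = np.hstack([c.values for c in components])
    name = "+".join(c.name for c in components)
    return FusionSet(list(components), values, ref.labels.copy(), name)


def enumerate_fusions(components: Sequence, sizes: set[int]) -> list[FusionSet]:
    """All size-k concatenations for each k in ``sizes``.

    Subsets are emitted smallest size first, lexicographically by
    component name within a size, so run reports are deterministic.
    """
    m = len(components)
    if any(k < 1 or k > m for k in sizes):
        raise InvalidSpecificationError(f"sizes must lie in 1..{m}")
    ordered = sorted(components, key=lambda c: c.name)
    out: list[FusionSet] = []
    for k in sorted(sizes):
        for combo in combinations(ordered, k):
            out.append(concat(list(combo)))
    return out
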