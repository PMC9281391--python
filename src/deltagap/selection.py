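"""Farthest point sampling of structures under the SOAP dissimilarity metric.

Greedy rule: starting from a seed structure (or from a preselected set, as
when test structures are chosen maximally far from an existing training
set), repeatedly add the pool structure whose minimum distance to the
already-selected set is largest.  Ties break toward the lowest pool index,
making the selection fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .soap import EnvironmentDescriptor, descriptor_matrix, structure_dissimilarity

__all__ = ["SelectionResult", "fps_select"]


@dataclass
class SelectionResult:
    """Ordered FPS picks.

    ``distances[k]`` is the recorded min-distance of ``chosen[k]`` to the set
    that was already selected (or preselected) when it was picked; for a
    seeded run the seed itself has no such distance and ``distances`` starts
    at the second pick.  Each entry is exactly recomputable from the metric.
    """

    chosen: list[int] = field(default_factory=list)
    distances: list[float] = field(default_factory=list)


def _as_matrix(item) -> np.ndarray:
    if isinstance(item, np.ndarray):
        return np.atleast_2d(item)
    return descriptor_matrix(item)


def fps_select(
    pool: Sequence,
    n_select: int,
    seed_index: int = 0,
    preselected: Sequence | None = None,
    zeta: int = 4,
    metric: Callable | None = None,
) -> SelectionResult:
    """Greedy farthest-point sampling over a pool of environment sets.

    Parameters
    ----------
    pool : sequence of descriptor sets (lists of EnvironmentDescriptor or
        2-D arrays of stacked descriptor vectors, one row per environment).
    n_select : number of structures to choose (1 <= n_select <= len(pool)).
    seed_index : pool index to start from when no preselected set is given.
    preselected : optional descriptor sets already in the training set; when
        given, selection starts by maximizing distance to this set and the
        seed index is ignored.
    zeta : kernel exponent of the default metric.
    metric : optional override ``metric(a, b) -> float``; defaults to the
        symmetric Hausdorff :func:`structure_dissimilarity`.
    """
    npool = len(pool)
    if not 1 <= n_select <= npool:
        raise ValueError("n_select must satisfy 1 <= n_select <= pool size")
    if metric is None:
        mats = [_as_matrix(p) for p in pool]
        pre = [_as_matrix(p) for p in (preselected or [])]

        def metric(a, b):  # noqa: F811 - deliberate default binding
            return structure_dissimilarity(a, b, zeta)

    else:
        mats = list(pool)
        pre = list(preselected or [])

    def dists_to(item) -> np.ndarray:
        return np.array([metric(item, m) for m in mats])

    mind = np.full(npool, np.inf)
    result = SelectionResult()

    if pre:
        for item in pre:
            mind = np.minimum(mind, dists_to(item))
        first = int(np.argmax(mind))
        result.chosen.append(first)
        result.distances.append(float(mind[first]))
    else:
        if not 0 <= seed_index < npool:
            raise ValueError("seed_index out of range")
        result.chosen.append(int(seed_index))
    mind = np.minimum(mind, dists_to(mats[result.chosen[-1]]))

    while len(result.chosen) < n_select:
        cand = mind.copy()
        cand[result.chosen] = -np.inf
        nxt = int(np.argmax(cand))
        result.chosen.append(nxt)
        result.distances.append(float(cand[nxt]))
        mind = np.minimum(mind, dists_to(mats[nxt]))

    return result
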