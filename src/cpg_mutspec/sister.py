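"""Shared-SNV detection across sister clones and reference-swap concordance."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import SNVCall

__all__ = ["SharedSNVResult", "shared_snvs", "reference_swap_concordance"]

Key = tuple[str, int, str, str]


@dataclass
class SharedSNVResult:
    """Pairwise shared-SNV counts and per-variant clone subsets.

    Two shared-fraction conventions are reported because the definition is
    ambiguous in common usage: ``shared_fraction_unique`` counts each shared
    variant once over all distinct variants; ``shared_fraction_instances``
    counts every per-clone occurrence of a shared variant over all calls.
    """

    clone_names: list[str]
    totals: dict[str, int]
    matrix: np.ndarray
    shared_variants: dict[Key, tuple[str, ...]]
    shared_fraction_unique: float
    shared_fraction_instances: float

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.clone_names,
                            columns=self.clone_names)

    def pair_count(self, a: str, b: str) -> int:
        i, j = self.clone_names.index(a), self.clone_names.index(b)
        return int(self.matrix[i, j])


def _as_mapping(call_sets) -> dict[str, Sequence[SNVCall]]:
    if isinstance(call_sets, Mapping):
        return dict(call_sets)
    return {f"clone{i + 1}": calls for i, calls in enumerate(call_sets)}


def shared_snvs(call_sets: Union[Mapping[str, Sequence[SNVCall]],
                                 Sequence[Sequence[SNVCall]]]) -> SharedSNVResult:
    """Find variants present in two or more clones' call sets.

    Variants match on (contig, pos, ref, alt). Call sets must come from a
    run with the sister-exclusion filter off, otherwise shared variants
    have already been removed upstream. A duplicated key within one clone
    is an upstream bug and raises.
    """
    sets = _as_mapping(call_sets)
    names = list(sets)
    keys_per_clone: dict[str, set[Key]] = {}
    for name, calls in sets.items():
        keys = [c.key for c in calls]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate variant key(s) in clone {name!r}: "
                             f"{dupes[:3]}")
        keys_per_clone[name] = set(keys)

    carriers: dict[Key, list[str]] = {}
    for name in names:
        for k in keys_per_clone[name]:
            carriers.setdefault(k, []).append(name)
    shared = {k: tuple(sorted(v, key=names.index))
              for k, v in carriers.items() if len(v) >= 2}

    n = len(names)
    matrix = np.zeros((n, n), dtype=np.int64)
    for k, who in shared.items():
        for a in who:
            for b in who:
                if a != b:
                    matrix[names.index(a), names.index(b)] += 1
    # symmetric with zero diagonal by construction
    totals = {name: len(keys_per_clone[name]) for name in names}
    n_distinct = len(carriers)
    n_calls = sum(totals.values())
    n_shared_instances = sum(len(who) for who in shared.values())
    return SharedSNVResult(
        clone_names=names,
        totals=totals,
        matrix=matrix,
        shared_variants=shared,
        shared_fraction_unique=(len(shared) / n_distinct if n_distinct else 0.0),
        shared_fraction_instances=(n_shared_instances / n_calls if n_calls else 0.0),
    )


def reference_swap_concordance(set_a: Iterable, set_b: Iterable,
                               mode: str = "jaccard") -> float:
    """Concordance (%) between two call sets for the same clone.

    Inputs may be :class:`SNVCall` sequences or raw key sets. ``jaccard``
    (default) is |A∩B| / |A∪B|; ``asymmetric`` is |A∩B| / |A|. Two empty
    sets are undefined and return NaN with a warning.
    """
    a = {c.key if isinstance(c, SNVCall) else tuple(c) for c in set_a}
    b = {c.key if isinstance(c, SNVCall) else tuple(c) for c in set_b}
    if mode == "jaccard":
        denom = len(a | b)
    elif mode == "asymmetric":
        denom = len(a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        warnings.warn("concordance undefined for empty call sets")
        return math.nan
    return 100.0 * len(a & b) / denom
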