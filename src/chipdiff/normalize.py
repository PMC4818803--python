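"""Depth normalization by random subselection of the deeper tag collection.

The two ChIP libraries are sequenced to different depths; before the
two-condition comparison the larger collection is randomly subsampled
(without replacement) down to the size of the smaller one, so per-region tag
counts are directly comparable.  The ChIP-versus-its-input comparison inside
the peak caller instead scales the input expectation by the depth ratio, so
no input tags are discarded.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from chipdiff.genomic import TagCollection

__all__ = ["subsample_tags", "normalize_pair"]


def subsample_tags(tags: TagCollection, target_n: int, seed: int) -> TagCollection:
    """Uniform subsample (without replacement) to exactly ``target_n`` tags.

    The result is a sub-multiset of the input; per-chromosome position order
    is preserved.  Deterministic given ``seed``.
    """
    total = tags.total_tags
    if target_n > total:
        raise ValueError(f"target_n {target_n} exceeds total tags {total}")
    if target_n < 0:
        raise ValueError("target_n must be non-negative")
    if target_n == total:
        return TagCollection(
            {c: tags.positions(c) for c in tags.chromosomes()},
            {c: tags.strands(c) for c in tags.chromosomes()},
        )
    rng = np.random.default_rng(seed)
    keep = np.zeros(total, dtype=bool)
    keep[rng.choice(total, size=target_n, replace=False)] = True

    positions: Dict[str, np.ndarray] = {}
    strands: Dict[str, np.ndarray] = {}
    offset = 0
    for chrom in tags.chromosomes():
        n = tags.count(chrom)
        mask = keep[offset : offset + n]
        offset += n
        if mask.any():
            positions[chrom] = tags.positions(chrom)[mask]
            strands[chrom] = tags.strands(chrom)[mask]
    return TagCollection(positions, strands)


def normalize_pair(
    a: TagCollection, b: TagCollection, seed: int
) -> Tuple[TagCollection, TagCollection, float]:
    """Subsample the deeper of two collections to the shallower's total.

    Returns the (possibly subsampled) pair in the original order plus the
    original deeper/shallower depth ratio for logging.
    """
    na, nb = a.total_tags, b.total_tags
    if na == 0 or nb == 0:
        raise ValueError("cannot normalize an empty tag collection")
    if na == nb:
        return a, b, 1.0
    if na > nb:
        return subsample_tags(a, nb, seed), b, na / nb
    return a, subsample_tags(b, na, seed), nb / na
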