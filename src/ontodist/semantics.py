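"""Inter-concept Wu-Palmer distances and semantic augmentation vectors.

Two semantic resources are derived from the ontology:

* a symmetric n x n Wu-Palmer distance lookup table over all non-root
  concepts, ``dist(a, b) = 1 - 2*depth(LCS) / (depth(a) + depth(b))``;
* per-concept augmentation vectors assigning weight ``1/(1 + n)`` to the
  n-th ancestor of a concept (n = 0 for the concept itself, n = 1 for its
  parent, ...), up to but excluding the root. Descendants are not weighted.

Both resources index concepts lexicographically by id; the root concept is
excluded from the vector space (it would contribute a constant component
shared by every patient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import Ontology, OntologyError

__all__ = [
    "ConceptIndex",
    "ConceptDistanceTable",
    "AugmentationTable",
    "wu_palmer_distance",
    "build_distance_table",
    "augmentation_vector",
    "build_augmentation_table",
]

#: above this concept count the distance table is computed lazily per entry
DENSE_LIMIT = 2000


@dataclass(frozen=True)
class ConceptIndex:
    """Bijection between non-root concept ids and 0-based matrix positions."""

    ids: tuple[str, ...]
    position_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "position_of", {c: i for i, c in enumerate(self.ids)})
        if len(self.position_of) != len(self.ids):
            raise ValueError("duplicate ids in concept index")

    @classmethod
    def from_ontology(cls, ontology: Ontology) -> "ConceptIndex":
        return cls(tuple(ontology.non_root_concepts()))

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, concept: str) -> int:
        try:
            return self.position_of[concept]
        except KeyError:
            raise KeyError(f"concept {concept!r} not in index") from None


def wu_palmer_distance(ontology: Ontology, a: str, b: str) -> float:
    """Wu-Palmer distance between two non-root concepts, in [0, 1].

    Zero iff ``a == b`` (in a mono-hierarchy two distinct concepts cannot
    both equal their lowest common subsumer); 1 when only the root is shared.
    """
    for c in (a, b):
        if c not in ontology:
            raise OntologyError(f"unknown concept id {c!r}")
        if c == ontology.root:
            raise OntologyError("Wu-Palmer distance is undefined for the root")
    lcs = ontology.lcs(a, b)
    return 1.0 - 2.0 * ontology.depth_of(lcs) / (
        ontology.depth_of(a) + ontology.depth_of(b))


class ConceptDistanceTable:
    """n x n Wu-Palmer lookup over an ontology's non-root concepts.

    Materialized dense for n <= DENSE_LIMIT, computed lazily (with row
    caching) above that; the lookup contract is identical either way.
    """

    def __init__(self, ontology: Ontology, dense: bool | None = None) -> None:
        self.ontology = ontology
        self.index = ConceptIndex.from_ontology(ontology)
        n = len(self.index)
        self._dense = dense if dense is not None else n <= DENSE_LIMIT
        self._values: np.ndarray | None = None
        self._row_cache: dict[int, np.ndarray] = {}
        if self._dense:
            self._values = self._compute_block(range(n))

    def _compute_block(self, rows) -> np.ndarray:
        # depth(LCS) for every pair via ancestor-set sweeps per row concept
        rows = list(rows)
        ids = self.index.ids
        o = self.ontology
        depths = np.array([o.depth_of(c) for c in ids], dtype=float)
        out = np.empty((len(rows), len(ids)))
        for r, i in enumerate(rows):
            anc = {c: d for d, c in enumerate(reversed(o.ancestors(ids[i])))}
            # anc maps ancestor -> its depth (root has depth 0)
            lcs_depth = np.empty(len(ids))
            for j, cj in enumerate(ids):
                best = 0
                c = cj
                while c not in anc:
                    c = o.parent_of(c)
                best = anc[c]
                lcs_depth[j] = best
            out[r] = 1.0 - 2.0 * lcs_depth / (depths[i] + depths)
        return out

    @property
    def values(self) -> np.ndarray:
        if self._values is None:
            self._values = self._compute_block(range(len(self.index)))
        return self._values

    def distance(self, a: str, b: str) -> float:
        i, j = self.index[a], self.index[b]
        return float(self._row(i)[j])

    def _row(self, i: int) -> np.ndarray:
        if self._values is not None:
            return self._values[i]
        if i not in self._row_cache:
            self._row_cache[i] = self._compute_block([i])[0]
        return self._row_cache[i]

    def submatrix(self, ids_a, ids_b) -> np.ndarray:
        """Distances between two concept id sequences (|A| x |B|)."""
        cols = [self.index[b] for b in ids_b]
        return np.array([self._row(self.index[a])[cols] for a in ids_a])

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.values, index=self.index.ids,
                             columns=self.index.ids)
        frame.to_csv(path, float_format="%.12g")

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        """Read a previously exported table as a labelled DataFrame."""
        return pd.read_csv(path, index_col=0)


def build_distance_table(ontology: Ontology,
                         dense: bool | None = None) -> ConceptDistanceTable:
    """Build the n x n Wu-Palmer lookup table for an ontology."""
    return ConceptDistanceTable(ontology, dense=dense)


def augmentation_vector(ontology: Ontology, concept: str,
                        index: ConceptIndex | None = None) -> dict[int, float]:
    """Sparse ancestor-weight vector for one concept.

    Weight ``1/(1 + n)`` at the position of the n-th ancestor, for every
    ancestor up to but excluding the root: the concept itself gets 1, its
    parent 1/2, its grandparent 1/3, and so on. Descendants get no weight.
    """
    if concept == ontology.root:
        raise OntologyError("the root has no augmentation vector")
    if index is None:
        index = ConceptIndex.from_ontology(ontology)
    chain = ontology.ancestors(concept)[:-1]  # drop the root
    return {index[c]: 1.0 / (1 + n) for n, c in enumerate(chain)}


@dataclass(frozen=True)
class AugmentationTable:
    """Per-concept sparse augmentation vectors over a shared concept index."""

    index: ConceptIndex
    vector_of: dict[str, dict[int, float]]

    def __getitem__(self, concept: str) -> dict[int, float]:
        try:
            return self.vector_of[concept]
        except KeyError:
            raise KeyError(
                f"concept {concept!r} not in augmentation table") from None


def build_augmentation_table(ontology: Ontology) -> AugmentationTable:
    """Augmentation vectors for every non-root concept of the ontology."""
    index = ConceptIndex.from_ontology(ontology)
    vectors = {c: augmentation_vector(ontology, c, index)
               for c in index.ids}
    return AugmentationTable(index=index, vector_of=vectors)
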