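"""Mono-hierarchical finding ontology: parsing, validation and queries.

The ontology is a rooted tree of clinical finding concepts (e.g. UMLS CUIs):
every non-root concept has exactly one parent and every parent chain
terminates at the single root. The root is a structural node ("neurological
finding"), not itself a finding; downstream code that treats concepts as
findings excludes it.

The on-disk format is a UTF-8 TSV with header ``concept_id\\tlabel\\tparent_id``,
one row per concept and exactly one row with an empty ``parent_id`` (the
root). Depths are always recomputed from the parent links, never read.
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = ["Ontology", "OntologyError", "load_ontology"]

ONTOLOGY_COLUMNS = ("concept_id", "label", "parent_id")


class OntologyError(ValueError):
    """Raised when an ontology file or structure violates the mono-hierarchy."""


class Ontology:
    """A validated rooted mono-hierarchy of concepts.

    Parameters
    ----------
    parent_of
        Mapping from each non-root concept id to its single parent id.
    labels
        Optional mapping from concept id to a display label; missing labels
        default to the id itself.

    Depth convention: ``depth(root) = 0`` and ``depth(c) = depth(parent) + 1``,
    so two depth-1 concepts whose only shared ancestor is the root are
    maximally distant under the Wu-Palmer measure.
    """

    def __init__(self, parent_of: Mapping[str, str],
                 labels: Mapping[str, str] | None = None) -> None:
        self._parent = dict(parent_of)
        self._validate_ids()
        self.root = self._find_root()
        self._depth = self._compute_depths()
        all_ids = [self.root, *self._parent]
        labels = dict(labels or {})
        self._label = {c: labels.get(c, c) for c in all_ids}

    # -- construction / validation ------------------------------------------

    def _validate_ids(self) -> None:
        for child, parent in self._parent.items():
            for ident in (child, parent):
                if not ident or any(ch.isspace() for ch in ident):
                    raise OntologyError(
                        f"invalid concept id {ident!r} (empty or whitespace)")
            if child == parent:
                raise OntologyError(f"concept {child!r} is its own parent")

    def _find_root(self) -> str:
        children = set(self._parent)
        parents = set(self._parent.values())
        roots = parents - children
        if not roots:
            raise OntologyError("no root found (every concept has a parent)")
        if len(roots) > 1:
            raise OntologyError(
                "multiple roots: " + ", ".join(sorted(roots)))
        return roots.pop()

    def _compute_depths(self) -> dict[str, int]:
        depth = {self.root: 0}
        for concept in self._parent:
            chain = []
            c = concept
            while c not in depth:
                chain.append(c)
                c = self._parent[c]
                if c in chain:
                    raise OntologyError(f"cycle detected at concept {c!r}")
            d = depth[c]
            for node in reversed(chain):
                d += 1
                depth[node] = d
        return depth

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Ontology":
        """Build an ontology from a ``concept_id/label/parent_id`` frame."""
        missing = set(ONTOLOGY_COLUMNS) - set(frame.columns)
        if missing:
            raise OntologyError(f"missing columns: {sorted(missing)}")
        if frame.empty:
            raise OntologyError("empty ontology file")
        ids = frame["concept_id"].astype(str)
        dup = ids[ids.duplicated()]
        if not dup.empty:
            row = dup.index[0]
            raise OntologyError(
                f"duplicate concept id {dup.iloc[0]!r} at row {row + 2}")
        parent_col = frame["parent_id"].fillna("").astype(str)
        root_rows = frame.index[parent_col == ""]
        if len(root_rows) == 0:
            raise OntologyError("no root row (empty parent_id) found")
        if len(root_rows) > 1:
            raise OntologyError(
                "multiple roots at rows "
                + ", ".join(str(r + 2) for r in root_rows))
        known = set(ids)
        parent_of: dict[str, str] = {}
        labels: dict[str, str] = {}
        for row, (cid, label, pid) in enumerate(
                zip(ids, frame["label"].astype(str), parent_col)):
            labels[cid] = label
            if pid == "":
                continue
            if pid not in known:
                raise OntologyError(
                    f"unknown parent id {pid!r} at row {row + 2}")
            parent_of[cid] = pid
        return cls(parent_of, labels)

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.root, self._label[self.root], "")]
        rows += [(c, self._label[c], p) for c, p in sorted(self._parent.items())]
        return pd.DataFrame(rows, columns=list(ONTOLOGY_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    # -- queries -------------------------------------------------------------

    def __contains__(self, concept: str) -> bool:
        return concept == self.root or concept in self._parent

    def __len__(self) -> int:
        return 1 + len(self._parent)

    def __iter__(self) -> Iterator[str]:
        return iter(self.concepts())

    def concepts(self) -> list[str]:
        """All concept ids including the root, in lexicographic order."""
        return sorted([self.root, *self._parent])

    def non_root_concepts(self) -> list[str]:
        """All finding concepts (root excluded), in lexicographic order."""
        return sorted(self._parent)

    def leaves(self) -> list[str]:
        parents = set(self._parent.values())
        return sorted(c for c in self._parent if c not in parents)

    def parent_of(self, concept: str) -> str:
        self._require(concept)
        if concept == self.root:
            raise OntologyError("the root has no parent")
        return self._parent[concept]

    def label_of(self, concept: str) -> str:
        self._require(concept)
        return self._label[concept]

    def depth_of(self, concept: str) -> int:
        self._require(concept)
        return self._depth[concept]

    def ancestors(self, concept: str) -> list[str]:
        """Ancestor chain starting at ``concept`` (position 0), ending at root."""
        self._require(concept)
        chain = [concept]
        while chain[-1] != self.root:
            chain.append(self._parent[chain[-1]])
        return chain

    def lcs(self, a: str, b: str) -> str:
        """Lowest common subsumer: the deepest concept on both ancestor chains."""
        self._require(a)
        self._require(b)
        seen = set(self.ancestors(a))
        for c in self.ancestors(b):
            if c in seen:
                return c
        return self.root  # unreachable: root is on every chain

    def _require(self, concept: str) -> None:
        if concept not in self:
            raise OntologyError(f"unknown concept id {concept!r}")


def load_ontology(path) -> Ontology:
    """Load and validate an ontology from its TSV file.

    Depths are computed from the parent links; any depth-like column in the
    file is ignored.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise OntologyError(f"empty ontology file: {path}") from None
    return Ontology.from_frame(frame)
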