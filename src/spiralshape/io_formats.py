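"""File formats and core containers.

Three plain-text formats cover everything the analysis touches:

* landmark curves in TPS records (``LM3=k`` header followed by ``k`` lines of
  three decimals, optional ``ID=`` / ``IMAGE=`` lines),
* rooted, time-calibrated trees in Newick with branch lengths,
* species-level trait tables in CSV.

The containers defined here (:class:`LandmarkConfiguration`,
:class:`Phylogeny`, :class:`TraitTable`) are the currency passed between all
downstream modules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "Phylogeny",
    "TraitTable",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_newick",
    "write_newick",
    "read_traits",
]


class TPSParseError(ValueError):
    """Raised when a TPS file does not follow the LM3 dialect."""


# ---------------------------------------------------------------------------
# Landmark configurations
# ---------------------------------------------------------------------------

@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D landmark curve, base (round window) -> apex.

    ``points`` holds both fixed landmarks and semi-landmarks in curve order;
    ``fixed_index_set`` / ``semi_index_set`` partition ``range(k)``. The
    optional ``source_curve`` is the dense, ordered polyline the
    semi-landmarks were sampled from; sliding operates along it.
    """

    specimen_id: str
    species_id: str
    side: str  # "left" | "right"
    points: np.ndarray  # (k, 3)
    fixed_index_set: frozenset[int] = field(default_factory=frozenset)
    semi_index_set: frozenset[int] = field(default_factory=frozenset)
    source_curve: np.ndarray | None = None  # (n, 3) dense polyline

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be a (k, 3) array")
        k = self.points.shape[0]
        if k < 3:
            raise ValueError(f"need at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite landmark coordinate")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not self.fixed_index_set and not self.semi_index_set:
            # untyped record (e.g. fresh from a TPS file): first/last fixed
            self.fixed_index_set = frozenset({0, k - 1})
            self.semi_index_set = frozenset(range(1, k - 1))
        fixed, semi = self.fixed_index_set, self.semi_index_set
        if fixed & semi:
            raise ValueError("fixed and semi index sets overlap")
        if (fixed | semi) != set(range(k)):
            raise ValueError("fixed and semi index sets must cover 0..k-1")
        if 0 not in fixed or (k - 1) not in fixed:
            raise ValueError("first and last landmarks must be fixed")
        if self.source_curve is not None:
            self.source_curve = np.asarray(self.source_curve, dtype=float)
            if self.source_curve.ndim != 2 or self.source_curve.shape[1] != 3:
                raise ValueError("source_curve must be an (n, 3) array")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, points=np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree with branch lengths, stored as flat parent/length arrays.

    Node 0 is the root; nodes are numbered in preorder, so every parent index
    is smaller than its child's. Tips carry unique labels. Branch lengths are
    in time units; the tree need not be ultrametric (fossil tips may end
    before the present).
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n_nodes = len(self.parent)
        if not (len(self.length) == len(self.labels) == n_nodes):
            raise ValueError("parent, length and labels must have equal size")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the single root")
        if np.any(self.parent[1:] >= np.arange(1, n_nodes)):
            raise ValueError("nodes must be in preorder (parent before child)")
        if np.any(self.length[1:] < 0) or not np.all(np.isfinite(self.length[1:])):
            raise ValueError("branch lengths must be finite and nonnegative")
        self.length[0] = 0.0
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        for i in range(1, n_nodes):
            self.children[self.parent[i]].append(i)
        self.tip_indices = np.array(
            [i for i in range(n_nodes) if not self.children[i]], dtype=int
        )
        self.tip_labels = [self.labels[i] for i in self.tip_indices]
        if any(lab is None for lab in self.tip_labels):
            raise ValueError("every tip must carry a label")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = {x for x in self.tip_labels if self.tip_labels.count(x) > 1}
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_count(self) -> int:
        return len(self.tip_indices)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.length[i]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[self.tip_indices]

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.max(d) - np.min(d) <= rtol * max(np.max(d), 1e-300))

    def postorder(self) -> np.ndarray:
        return np.arange(self.n_nodes - 1, -1, -1)

    def subtree_nodes(self, node: int) -> list[int]:
        """All nodes in the clade rooted at ``node`` (including it)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def tips_below(self, node: int) -> np.ndarray:
        """Boolean mask over tip order for tips descending from ``node``."""
        sub = set(self.subtree_nodes(node))
        return np.array([i in sub for i in self.tip_indices])

    def with_lengths(self, length: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(length, float), list(self.labels))

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        parent: list[int] = []
        length: list[float] = []
        labels: list[str | None] = []
        index: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            idx = len(parent)
            index[id(node)] = idx
            if node.parent_node is None:
                parent.append(-1)
                length.append(0.0)
            else:
                parent.append(index[id(node.parent_node)])
                if node.edge.length is None:
                    raise ValueError(
                        "missing branch length (trees without lengths are rejected)"
                    )
                if node.edge.length < 0:
                    raise ValueError(f"negative branch length {node.edge.length}")
                length.append(float(node.edge.length))
            lab = None
            if node.taxon is not None:
                lab = node.taxon.label
            elif node.label:
                lab = node.label
            labels.append(lab)
        return cls(parent, length, labels)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                core = _quote_label(self.labels[i])
            else:
                core = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    core += _quote_label(self.labels[i])
            if i == 0:
                return core
            return f"{core}:{self.length[i]:.17g}"

        return render(0) + ";"


def _quote_label(label: str | None) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species-level scalar traits, one row per species.

    Typical columns: ``body_mass`` (grams), ``cochlear_length`` (mm),
    ``n_turns`` (revolutions), ``centroid_size``, PC scores.
    """

    data: pd.DataFrame  # indexed by species_id

    def __post_init__(self) -> None:
        if self.data.index.name != "species_id":
            raise ValueError("TraitTable index must be species_id")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate species_id: {dupes}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated column names")
        if "body_mass" in self.data.columns:
            mass = self.data["body_mass"].dropna()
            if (mass <= 0).any():
                bad = mass.index[mass <= 0].tolist()
                raise ValueError(f"non-positive body_mass for {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def mismatches(self, tree: Phylogeny) -> tuple[list[str], list[str]]:
        """Species present only in the table / only in the tree."""
        table = set(self.species)
        tips = set(tree.tip_labels)
        return sorted(table - tips), sorted(tips - table)

    def aligned_to(self, labels: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in labels if s not in self.data.index]
        if missing:
            raise KeyError(f"species missing from trait table: {missing}")
        return self.data.loc[list(labels)]


# ---------------------------------------------------------------------------
# TPS reading / writing
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS file of 3D landmark records.

    Dialect: each record starts with ``LM3=k``, followed by ``k`` lines of
    three whitespace-separated decimals; ``ID=`` (specimen id) and ``IMAGE=``
    lines are honoured, comment lines (starting with ``#``) ignored.
    Species/side metadata are not part of TPS; records come back with
    ``species_id`` equal to the specimen id and ``side='right'`` unless a
    sidecar table overrides them downstream.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise TPSParseError(f"{path}:{i + 1}: expected 'LM3=' header, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}:{i + 1}: malformed LM3 header {line!r}") from exc
        if k <= 0:
            raise TPSParseError(f"{path}: record {record_idx} has LM3={k} (empty record)")
        i += 1
        pts = np.empty((k, 3))
        for j in range(k):
            if i >= len(lines):
                raise TPSParseError(f"{path}: record {record_idx} truncated")
            parts = lines[i].split()
            if len(parts) != 3:
                raise TPSParseError(
                    f"{path}:{i + 1}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                pts[j] = [float(x) for x in parts]
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}:{i + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from exc
            i += 1
        specimen_id = f"record_{record_idx}"
        while i < len(lines):
            meta = lines[i].strip()
            if meta.upper().startswith("ID="):
                specimen_id = meta.split("=", 1)[1].strip()
                i += 1
            elif meta.upper().startswith("IMAGE="):
                i += 1
            elif not meta:
                i += 1
            else:
                break
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                species_id=specimen_id,
                side="right",
                points=pts,
            )
        )
        record_idx += 1
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as consecutive LM3 records (order preserved)."""
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty sequence of configurations")
    buf = io.StringIO()
    for cfg in configs:
        buf.write(f"LM3={cfg.k}\n")
        for p in cfg.points:
            buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        buf.write(f"ID={cfg.specimen_id}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Newick / traits
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree; branch lengths are required on every edge."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return Phylogeny.from_dendropy(tree)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_traits(path: str | Path, tree: Phylogeny | None = None) -> TraitTable:
    """Read a species trait CSV (must contain a ``species_id`` column).

    When a tree is supplied, species present in only one of the two inputs
    are reported via the returned table's ``mismatches``; downstream stages
    use the intersection.
    """
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise ValueError(f"{path}: no species_id column")
    table = TraitTable(df.set_index("species_id"))
    if tree is not None:
        table.mismatches(tree)  # validates on read
    return table
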