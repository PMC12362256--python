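"""Core domain types and tab-delimited readers/writers.

The central object is the sample-by-feature count matrix Z (n samples, m
leaf-level features such as ASVs or OTUs), accompanied by a taxonomy tree
whose leaves map one-to-one onto the features, an optional phylogenetic tree
with branch lengths for UniFrac distances, and an outcome specification
(continuous, binary, categorical, or right-censored survival) with optional
covariates.

All file formats are plain UTF-8 tab-separated text; lines starting with
'#' are ignored. Trees are Newick.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from skbio import TreeNode

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = dict(zip(RANK_PREFIXES, RANKS))
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Sample x feature matrix of nonnegative integer counts (the matrix Z)."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.feature_ids)} features)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id: {dup!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise ValueError(f"duplicate feature id: {dup!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"feature {self.feature_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def proportions(self) -> np.ndarray:
        """Per-sample relative abundances; errors on zero-total samples."""
        totals = self.counts.sum(axis=1)
        if np.any(totals == 0):
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValueError(f"sample {bad!r} has zero total count")
        return self.counts / totals[:, None]

    def feature_index(self, feature_ids: Iterable[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([lookup[f] for f in feature_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"feature {exc.args[0]!r} not in count table") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in sample_ids]
        return CountTable(list(sample_ids), list(self.feature_ids), self.counts[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# TaxonomyTree
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyNode:
    """One node of a taxonomy tree. Anonymous placeholders have name ''."""

    name: str
    rank: str  # one of RANKS, "root", or "leaf"
    parent: "TaxonomyNode | None" = None
    children: list["TaxonomyNode"] = field(default_factory=list)
    feature_id: str | None = None  # set for leaves only

    def is_leaf(self) -> bool:
        return self.rank == "leaf"

    def leaf_features(self) -> list[str]:
        """Feature ids of all leaves at or below this node, in tree order."""
        if self.is_leaf():
            return [self.feature_id]  # type: ignore[list-item]
        out: list[str] = []
        stack = list(reversed(self.children))
        while stack:
            node = stack.pop()
            if node.is_leaf():
                out.append(node.feature_id)  # type: ignore[arg-type]
            else:
                stack.extend(reversed(node.children))
        return out

    def path(self) -> str:
        parts = []
        node: TaxonomyNode | None = self
        while node is not None and node.rank != "root":
            label = node.name if node.name else "<unnamed>"
            parts.append(f"{node.rank}:{label}")
            node = node.parent
        return "/".join(reversed(parts))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonomyNode({self.rank}:{self.name or '<unnamed>'})"


class TaxonomyTree:
    """Rooted taxonomy built by prefix-merging rank-prefixed lineage strings.

    Leaves are in bijection with count-table feature ids; internal nodes
    carry a rank from kingdom down to species. Empty rank segments in a
    lineage (e.g. ``g__``) produce anonymous placeholder nodes so every leaf
    sits at the bottom of a full rank ladder.
    """

    def __init__(self, root: TaxonomyNode, leaf_map: dict[str, TaxonomyNode]):
        self.root = root
        self.leaf_map = leaf_map
        self._name_index: dict[str, list[TaxonomyNode]] = {}
        self._build_index()

    def _build_index(self) -> None:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.name and not node.is_leaf():
                self._name_index.setdefault(node.name, []).append(node)
            stack.extend(node.children)
        for fid, leaf in self.leaf_map.items():
            self._name_index.setdefault(fid, []).append(leaf)

    @classmethod
    def from_lineages(cls, lineages: Mapping[str, str]) -> "TaxonomyTree":
        """Build the tree from {feature_id: 'k__..; p__..; ...'} assignments."""
        root = TaxonomyNode("", "root")
        leaf_map: dict[str, TaxonomyNode] = {}
        for fid, lineage in lineages.items():
            fid = str(fid)
            if fid in leaf_map:
                raise ValueError(f"feature {fid!r} assigned more than one lineage")
            node = root
            last_rank = -1
            for seg in str(lineage).split(";"):
                seg = seg.strip()
                if not seg:
                    continue
                prefix, name = seg[:3], seg[3:].strip()
                if prefix not in _PREFIX_TO_RANK:
                    raise ValueError(
                        f"feature {fid!r}: unrecognized rank prefix in segment {seg!r}"
                    )
                rank = _PREFIX_TO_RANK[prefix]
                if _RANK_INDEX[rank] <= last_rank:
                    raise ValueError(
                        f"feature {fid!r}: rank {rank!r} out of canonical order in {lineage!r}"
                    )
                last_rank = _RANK_INDEX[rank]
                child = next(
                    (c for c in node.children if c.rank == rank and c.name == name),
                    None,
                )
                if child is None:
                    child = TaxonomyNode(name, rank, parent=node)
                    node.children.append(child)
                node = child
            leaf = TaxonomyNode(fid, "leaf", parent=node, feature_id=fid)
            node.children.append(leaf)
            leaf_map[fid] = leaf
        return cls(root, leaf_map)

    def find(self, taxon: str) -> TaxonomyNode:
        """Resolve a taxon to a unique node.

        Accepts a bare name (``'Ruminococcaceae'``), a Greengenes-prefixed
        name (``'f__Ruminococcaceae'``), or a rank-qualified name
        (``'family:Ruminococcaceae'``) to disambiguate homonyms. ``'root'``
        returns the root.
        """
        query = taxon.strip()
        if query in ("root", ""):
            return self.root
        rank: str | None = None
        if ":" in query:
            rank, query = query.split(":", 1)
            rank = rank.strip().lower()
            if rank not in _RANK_INDEX and rank != "leaf":
                raise KeyError(f"unknown rank qualifier {rank!r} in {taxon!r}")
        elif query[:3] in _PREFIX_TO_RANK:
            rank = _PREFIX_TO_RANK[query[:3]]
            query = query[3:]
        hits = self._name_index.get(query, [])
        if rank is not None:
            hits = [h for h in hits if h.rank == rank]
        if not hits:
            import difflib

            near = difflib.get_close_matches(query, list(self._name_index), n=3)
            hint = f"; near matches: {', '.join(near)}" if near else ""
            raise KeyError(f"taxon {taxon!r} not found{hint}")
        if len(hits) > 1:
            paths = ", ".join(h.path() for h in hits)
            raise KeyError(
                f"taxon {taxon!r} is ambiguous ({len(hits)} nodes: {paths}); "
                "qualify it as 'rank:name'"
            )
        return hits[0]

    def leaves(self, taxon: "str | TaxonomyNode" = "root") -> list[str]:
        """Feature ids descending from (or equal to) the given taxon."""
        node = taxon if isinstance(taxon, TaxonomyNode) else self.find(taxon)
        return node.leaf_features()

    def nodes_at_rank(self, rank: str) -> list[TaxonomyNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.rank == rank:
                out.append(node)
            stack.extend(node.children)
        return sorted(out, key=lambda n: n.name)

    @property
    def feature_ids(self) -> list[str]:
        return self.root.leaf_features()


# ---------------------------------------------------------------------------
# PhylogeneticTree
# ---------------------------------------------------------------------------


class PhylogeneticTree:
    """Rooted phylogeny with branch lengths, backed by a skbio TreeNode.

    Exposes a leaf-by-branch incidence matrix used to compute UniFrac
    distances as dense linear algebra; the matrix is cached per feature
    ordering because the conditional test recomputes distances many times
    on the same tree.
    """

    def __init__(self, tree: TreeNode):
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(f"invalid branch length {node.length!r} on {node.name!r}")
        names = [lf.name for lf in tree.tips()]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate leaf label: {_first_duplicate(names)!r}")
        self.tree = tree
        self.leaf_names = names
        self._branch_cache: dict[tuple[str, ...], tuple[sparse.csr_matrix, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_newick(cls, source: str) -> "PhylogeneticTree":
        """Parse a Newick string. Unrooted (trifurcating) input keeps its
        basal polytomy as the root; no midpoint re-rooting is applied."""
        tree = TreeNode.read(StringIO(source))
        return cls(tree)

    def branch_matrix(
        self, feature_ids: Sequence[str]
    ) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        """Incidence of features on branches.

        Returns ``(M, lengths, present)`` where ``M[i, b] = 1`` if feature
        ``i`` descends through branch ``b`` (the edge above each non-root
        node), ``lengths[b]`` is that branch's length, and ``present[i]``
        flags features found as tree leaves.
        """
        key = tuple(feature_ids)
        cached = self._branch_cache.get(key)
        if cached is not None:
            return cached
        lookup = {f: i for i, f in enumerate(feature_ids)}
        rows: list[int] = []
        cols: list[int] = []
        lengths: list[float] = []
        present = np.zeros(len(feature_ids), dtype=bool)
        # postorder: collect the feature indices under each node once
        under: dict[int, list[int]] = {}
        branch_no = 0
        for node in self.tree.postorder(include_self=True):
            if node.is_tip():
                i = lookup.get(node.name)
                mine = [] if i is None else [i]
                if i is not None:
                    present[i] = True
            else:
                mine = []
                for child in node.children:
                    mine.extend(under.pop(id(child)))
            under[id(node)] = mine
            if node.parent is not None:  # every non-root node defines a branch
                rows.extend(mine)
                cols.extend([branch_no] * len(mine))
                lengths.append(float(node.length))
                branch_no += 1
        m = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(feature_ids), branch_no),
        )
        out = (m, np.asarray(lengths), present)
        self._branch_cache[key] = out
        return out

    def to_newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# OutcomeSpec
# ---------------------------------------------------------------------------


@dataclass
class OutcomeSpec:
    """Per-sample outcome X plus optional covariates U.

    ``kind`` is one of ``continuous``, ``binary``, ``categorical``,
    ``survival``. For survival, ``values`` holds strictly positive follow-up
    times and ``event`` the 0/1 event indicator.
    """

    kind: str
    values: np.ndarray
    event: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical", "survival"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.kind == "categorical":
            self.values = np.asarray(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
        n = len(self.values)
        if self.kind == "survival":
            if self.event is None:
                raise ValueError("survival outcome requires an event indicator")
            self.event = np.asarray(self.event, dtype=int)
            if len(self.event) != n:
                raise ValueError("event indicator length mismatch")
            if not set(np.unique(self.event)) <= {0, 1}:
                raise ValueError("event indicator must be 0/1")
            if np.any(self.values <= 0):
                raise ValueError("survival times must be strictly positive")
        if self.kind == "binary":
            if not set(np.unique(self.values)) <= {0.0, 1.0}:
                raise ValueError("binary outcome must be coded 0/1")
        if self.kind == "categorical":
            levels, counts = np.unique(self.values, return_counts=True)
            if len(levels) < 2:
                raise ValueError("categorical outcome needs at least 2 levels")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate table length mismatch")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_count_table(
    path: str | Path, orientation: str = "samples_as_rows"
) -> CountTable:
    """Read a tab-separated count table with one header row and a label column."""
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = df.index[int(parsed.isna().argmax())]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        arr = parsed.to_numpy()
        if np.any(arr != np.floor(arr)):
            row = df.index[int(np.argmax(arr != np.floor(arr)))]
            raise ValueError(f"non-integer cell at row {row!r}, column {col!r}")
        if np.any(arr < 0):
            row = df.index[int(np.argmax(arr < 0))]
            raise ValueError(f"negative cell at row {row!r}, column {col!r}")
        values[:, j] = arr.astype(np.int64)
    if orientation == "features_as_rows":
        return CountTable(list(df.columns), list(df.index), values.T)
    return CountTable(list(df.index), list(df.columns), values)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read feature -> lineage assignments (two tab-separated columns)."""
    df = _read_tsv(path, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"taxonomy file {path} needs two columns (feature, lineage)")
    lineages: dict[str, str] = {}
    for fid, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if fid in lineages and lineages[fid] != lineage:
            raise ValueError(f"feature {fid!r} assigned two different lineages")
        lineages[fid] = lineage
    return TaxonomyTree.from_lineages(lineages)


def write_taxonomy(tax: TaxonomyTree, path: str | Path) -> None:
    rows = []
    for fid in tax.feature_ids:
        leaf = tax.leaf_map[fid]
        parts = []
        node = leaf.parent
        while node is not None and node.rank != "root":
            prefix = RANK_PREFIXES[_RANK_INDEX[node.rank]]
            parts.append(f"{prefix}{node.name}")
            node = node.parent
        rows.append((fid, "; ".join(reversed(parts))))
    pd.DataFrame(rows, columns=["feature_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_newick(path: str | Path) -> PhylogeneticTree:
    text = Path(path).read_text()
    return PhylogeneticTree.from_newick(text)


def read_metadata(
    path: str | Path,
    outcome_column: str,
    outcome_kind: str,
    covariate_columns: Sequence[str] = (),
    event_column: str | None = None,
    sample_ids: Sequence[str] | None = None,
) -> OutcomeSpec:
    """Read sample metadata and assemble an OutcomeSpec.

    If ``sample_ids`` (typically a CountTable's sample order) is given, the
    result is aligned to that order over the id intersection; samples on
    either side only are dropped with a logged warning.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    if outcome_column not in df.columns:
        raise ValueError(f"outcome column {outcome_column!r} not in {path}")
    if outcome_kind == "survival" and event_column is None:
        raise ValueError("survival outcome requires event_column")
    for col in list(covariate_columns) + ([event_column] if event_column else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in {path}")

    ids = list(df.index)
    if sample_ids is not None:
        wanted = [str(s) for s in sample_ids]
        meta_only = sorted(set(ids) - set(wanted))
        counts_only = sorted(set(wanted) - set(ids))
        if meta_only:
            logger.warning("dropping %d metadata-only samples: %s", len(meta_only), meta_only)
        if counts_only:
            logger.warning("dropping %d count-only samples: %s", len(counts_only), counts_only)
        ids = [s for s in wanted if s in set(df.index)]
        df = df.loc[ids]

    raw = df[outcome_column]
    if outcome_kind == "binary" and not set(pd.unique(raw)) <= {0, 1}:
        levels = sorted(map(str, pd.unique(raw.astype(str))))
        if len(levels) != 2:
            raise ValueError(
                f"binary outcome column {outcome_column!r} has {len(levels)} levels"
            )
        coding = {levels[0]: 0, levels[1]: 1}
        logger.info("binary outcome coding: %s", coding)
        values = raw.astype(str).map(coding).to_numpy()
    elif outcome_kind == "categorical":
        values = raw.astype(str).to_numpy()
    else:
        values = pd.to_numeric(raw).to_numpy()

    event = None
    if outcome_kind == "survival":
        event = pd.to_numeric(df[event_column]).to_numpy()
    covariates = df[list(covariate_columns)].copy() if covariate_columns else None
    return OutcomeSpec(
        kind=outcome_kind,
        values=values,
        event=event,
        covariates=covariates,
        sample_ids=ids,
    )


RESULT_COLUMNS = (
    "taxon",
    "rank",
    "n_leaves",
    "r2_original",
    "r2_perm_mean",
    "p_value",
    "B",
    "seed",
)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-taxon results table as TSV (see RESULT_COLUMNS)."""
    if len(results) == 0:
        raise ValueError("results table is empty")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    cols = [c for c in results.columns]
    results.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)
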