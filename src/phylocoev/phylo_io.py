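"""Trees and tabular inputs: the shared coordinate conventions.

All downstream modules consume the three containers defined here:

* :class:`Phylogeny` — a rooted tree with named tips and non-negative
  branch lengths in time units (TimeTree-style: millions of years; only
  the product rate x length matters, so the unit is a labeling
  convention).
* :class:`TraitMatrix` — species x genes binary presence/absence with an
  explicit missing state.
* :class:`BranchLengthTable` — per-gene branch lengths on a fixed
  species topology plus a genome-wide reference length per branch.

Newick parsing and writing are delegated to :mod:`dendropy`; the
wrapper adds validation (non-negative lengths, unique tips), stable ids
for unlabeled internal nodes, and a 12-significant-digit round trip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TraitMatrix",
    "BranchLengthTable",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_branch_length_table",
    "write_branch_length_table",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


@dataclass
class Phylogeny:
    """Rooted phylogeny backed by a :class:`dendropy.Tree`.

    Tips carry unique labels; internal nodes without a label receive a
    stable generated id (``_nd0``, ``_nd1``, ... in preorder).  Branch
    lengths are non-negative reals in time units; a length on the root
    (stem) edge is retained through round trips and pruning but ignored
    by the likelihood machinery, which conditions on the root state at
    the crown.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self._validate()
        self._assign_internal_ids()

    # -- structure ---------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def postorder_nodes(self):
        return self.tree.postorder_node_iter()

    def max_tip_depth(self) -> float:
        """Maximum root-to-tip path length, excluding any stem edge."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return max(leaf.root_distance for leaf in self.tree.leaf_node_iter())

    def mean_branch_length(self) -> float:
        """Mean length over non-root edges; used to condition rate scales."""
        lengths = [
            nd.edge.length
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None and nd.edge.length is not None
        ]
        return float(np.mean(lengths)) if lengths else 1.0

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {nd.edge.length} on edge to "
                    f"{nd.taxon.label if nd.taxon else 'internal node'}"
                )

    def _assign_internal_ids(self) -> None:
        i = 0
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if nd.label is None:
                nd.label = f"_nd{i}"
            i += 1

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Raises
    ------
    NewickParseError
        On malformed input; the message names the offending position
        where dendropy reports one.
    TreeValidationError
        On negative branch lengths or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialize with 12 significant digits so round trips are lossless."""
    s = phy.tree.as_string(
        schema="newick",
        real_value_format_specifier=".12g",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=True,
    )
    return s.strip()


def prune_to_taxa(phy: Phylogeny, taxa) -> Phylogeny:
    """Restrict the tree to ``taxa``, preserving path lengths.

    Suppressed degree-2 nodes have their branch lengths summed, so every
    patristic distance among retained tips — and the root-to-tip path,
    counting any stem edge accumulated at the root — is unchanged.
    """
    taxa = set(taxa)
    known = set(phy.tip_labels)
    missing = sorted(taxa - known)
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    t = phy.tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(taxa))
    return Phylogeny(t)


# ---------------------------------------------------------------------------
# Trait matrices
# ---------------------------------------------------------------------------

PRESENT = 1.0
ABSENT = 0.0
# missing is np.nan inside the values frame


@dataclass
class TraitMatrix:
    """Species x genes presence/absence; 1.0 present, 0.0 absent, NaN missing."""

    values: pd.DataFrame  # index: species, columns: genes, float64

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicate species labels: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = sorted(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicate gene labels: {dupes}")
        bad = ~(self.values.isin([0.0, 1.0]) | self.values.isna())
        if bad.any().any():
            r, c = np.argwhere(bad.values)[0]
            raise ValueError(
                f"non-binary trait value {self.values.iat[r, c]!r} at "
                f"species={self.values.index[r]!r} gene={self.values.columns[c]!r}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def states_for(self, gene: str) -> dict[str, float | None]:
        """Per-species state for one gene; missing entries map to ``None``."""
        col = self.values[gene]
        return {sp: (None if pd.isna(v) else float(v)) for sp, v in col.items()}

    def tallies(self) -> pd.DataFrame:
        """Per-gene counts of present / absent / missing species."""
        return pd.DataFrame(
            {
                "present": (self.values == 1.0).sum(),
                "absent": (self.values == 0.0).sum(),
                "missing": self.values.isna().sum(),
            }
        )


def read_trait_matrix(
    source,
    sep: str = "\t",
    present_token: str = "1",
    absent_token: str = "0",
    missing_token: str = "?",
) -> TraitMatrix:
    """Read a delimited presence/absence table.

    Layout: header row of gene names, first column species labels, cells
    in ``{present_token, absent_token, missing_token}`` (defaults
    ``1/0/?``).  The missing token marks an unobserved state, not an
    absence.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    mapping = {present_token: 1.0, absent_token: 0.0, missing_token: np.nan}
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, gene in enumerate(df.columns):
        for i, sp in enumerate(df.index):
            tok = df.iat[i, j].strip()
            if tok not in mapping:
                raise ValueError(
                    f"unrecognized trait token {tok!r} at species={sp!r} gene={gene!r}"
                )
            out.iat[i, j] = mapping[tok]
    out.index.name = df.index.name
    return TraitMatrix(out)


def write_trait_matrix(tm: TraitMatrix, path, sep: str = "\t") -> None:
    df = tm.values.copy()
    out = df.map(lambda v: "?" if pd.isna(v) else str(int(v)))
    out.index.name = df.index.name or "species"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Branch-length tables (ERC input)
# ---------------------------------------------------------------------------


@dataclass
class BranchLengthTable:
    """Per-gene branch lengths over a shared branch index.

    ``reference`` holds the genome-wide expected length of each branch
    (all > 0); ``gene_lengths`` is branches x genes with NaN where a
    gene lacks data on a branch.
    """

    branch_ids: list[str]
    reference: np.ndarray  # shape (n_branches,)
    gene_lengths: pd.DataFrame  # index: branch_ids, columns: genes

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (len(self.branch_ids),):
            raise ValueError("reference length vector does not match branch ids")
        if not np.all(self.reference > 0):
            bad = [self.branch_ids[i] for i in np.where(self.reference <= 0)[0]]
            raise ValueError(f"non-positive reference lengths on branches: {bad}")
        vals = self.gene_lengths.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative gene branch lengths present")
        if list(self.gene_lengths.index) != list(self.branch_ids):
            raise ValueError("gene_lengths index must equal branch_ids")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_lengths.columns)


def read_branch_length_table(
    source, sep: str = "\t", reference_column: str = "reference"
) -> BranchLengthTable:
    """Read a TSV of branch lengths: one row per branch id, a reference
    column, and one column per gene (empty cells = missing)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, index_col=0)
    if reference_column not in df.columns:
        raise ValueError(f"missing reference column {reference_column!r}")
    ref = df[reference_column].to_numpy(dtype=float)
    genes = df.drop(columns=[reference_column]).astype(float)
    return BranchLengthTable(
        branch_ids=[str(b) for b in df.index],
        reference=ref,
        gene_lengths=genes.set_axis([str(b) for b in df.index], axis=0),
    )


def write_branch_length_table(
    table: BranchLengthTable, path, sep: str = "\t", reference_column: str = "reference"
) -> None:
    df = table.gene_lengths.copy()
    df.insert(0, reference_column, table.reference)
    df.index.name = "branch"
    df.to_csv(path, sep=sep)
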