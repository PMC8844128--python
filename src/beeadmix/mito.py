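"""Mitotype classification: K2P distances, neighbor joining, bootstrap.

Mitochondria are maternally inherited without recombination, so a single
gene tree relates every sequence.  Queries from admixed populations are
classified into the four *Apis mellifera* matrilineal clades (A, M, C, O) by
building a Kimura 2-parameter / neighbor-joining phylogeny together with
labeled reference mitogenomes, midpoint-rooting it, and reading off the
smallest clade that joins each query with references.

Columns containing a gap or ambiguous base in ANY sequence are removed
before distance computation ("complete deletion", the MEGA convention), so
all pairwise distances are computed on the same set of columns.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MitoAlignment",
    "K2PSaturationError",
    "k2p_from_proportions",
    "k2p_distance",
    "k2p_distance_matrix",
    "nj_tree",
    "midpoint_root",
    "bootstrap_support",
    "assign_clades",
    "mitotype_table",
    "tree_distance_matrix",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# transition partner (A<->G purines, C<->T pyrimidines)
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


class K2PSaturationError(ValueError):
    """Sequences too diverged for a finite Kimura 2-parameter distance."""


@dataclass
class MitoAlignment:
    """Pre-aligned mitochondrial sequences with reference/query roles.

    ``reference_clades`` maps reference sequence names to their clade
    (A/M/C/O); every other name is a query.  ``true_query_clades`` holds the
    generating clade of simulated queries (ground truth for benchmarking)
    and is empty for real data.
    """

    names: list[str]
    sequences: list[str]
    reference_clades: dict[str, str] = field(default_factory=dict)
    true_query_clades: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        if len(self.sequences) >= 2:
            lengths = {len(s) for s in self.sequences}
            if len(lengths) != 1:
                raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")

    @property
    def query_names(self) -> list[str]:
        return [n for n in self.names if n not in self.reference_clades]

    def encoded(self) -> np.ndarray:
        """(S, L) uint8 matrix; 255 marks gaps/ambiguity codes."""
        lut = np.full(256, 255, dtype=np.uint8)
        for b, c in _BASE_CODE.items():
            lut[ord(b)] = c
            lut[ord(b.lower())] = c
        arr = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        return lut[arr].reshape(len(self.sequences), -1)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=n, description="")
            for n, s in zip(self.names, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(
        cls, path, reference_clades: Mapping[str, str] | None = None
    ) -> "MitoAlignment":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(names=names, sequences=seqs, reference_clades=dict(reference_clades or {}))


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

def complete_deletion(encoded: np.ndarray) -> np.ndarray:
    """Indices of columns without gaps/ambiguity in any sequence."""
    return np.flatnonzero((encoded < 4).all(axis=0))


def k2p_from_proportions(p_transition: float, q_transversion: float) -> float:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    a = 1.0 - 2.0 * p_transition - q_transversion
    b = 1.0 - 2.0 * q_transversion
    if a <= 0 or b <= 0:
        raise K2PSaturationError(
            f"saturated: P={p_transition:.4g}, Q={q_transversion:.4g}"
        )
    return -0.5 * np.log(a) - 0.25 * np.log(b)


def _pair_counts(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise (transitions, transversions, columns) over an encoded block."""
    s, length = enc.shape
    onehot = np.stack([(enc == b) for b in range(4)]).astype(float)  # (4, S, L)
    flat = onehot.reshape(4 * s, length)
    pair = (flat @ flat.T).reshape(4, s, 4, s).transpose(0, 2, 1, 3)  # (4, 4, S, S)
    match = pair[0, 0] + pair[1, 1] + pair[2, 2] + pair[3, 3]
    ts = pair[0, 2] + pair[2, 0] + pair[1, 3] + pair[3, 1]
    tv = length - match - ts
    return ts, tv, np.full((s, s), float(length))


def k2p_distance_matrix(aln: MitoAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(distance matrix, retained column indices) under complete deletion."""
    enc = aln.encoded()
    cols = complete_deletion(enc)
    if cols.size == 0:
        raise K2PSaturationError("no columns survive complete deletion")
    ts, tv, length = _pair_counts(enc[:, cols])
    p = ts / length
    q = tv / length
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    bad = (a <= 0) | (b <= 0)
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise K2PSaturationError(
            f"saturated pair ({aln.names[i]}, {aln.names[j]})"
        )
    d = -0.5 * np.log(np.where(a > 0, a, 1.0)) - 0.25 * np.log(np.where(b > 0, b, 1.0))
    np.fill_diagonal(d, 0.0)
    return d, cols


def k2p_distance(seq1: str, seq2: str, deletion: str = "complete") -> float:
    """K2P distance between two sequences (gapped columns removed)."""
    if deletion != "complete":
        raise ValueError("only complete deletion is supported")
    aln = MitoAlignment(names=["s1", "s2"], sequences=[seq1, seq2])
    d, _ = k2p_distance_matrix(aln)
    return float(d[0, 1])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distances: np.ndarray, labels: Iterable[str]) -> Tree:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    The Q-criterion (n-2)d_ij - r_i - r_j is minimized each step, ties broken
    by the smallest (row, column) index pair.  Negative branch lengths are
    clamped to zero with a warning.  Returns an unrooted tree represented
    with a trifurcating (or smaller) root.
    """
    d = np.array(distances, dtype=float)
    labels = list(labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    nodes = [Clade(name=lab) for lab in labels]
    if n == 1:
        return Tree(root=nodes[0], rooted=False)
    if n == 2:
        for node in nodes:
            node.branch_length = d[0, 1] / 2.0
        return Tree(root=Clade(clades=nodes), rooted=False)

    n_clamped = 0
    active = list(range(n))
    dm = d.copy()
    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qc = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qc, np.inf)
        qc[np.tril_indices(m)] = np.inf  # keep i < j; argmin scans row-major
        i, j = np.unravel_index(np.argmin(qc), qc.shape)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            n_clamped += 1
        li, lj = max(li, 0.0), max(lj, 0.0)
        ai, aj = active[i], active[j]
        nodes[ai].branch_length = li
        nodes[aj].branch_length = lj
        parent = Clade(clades=[nodes[ai], nodes[aj]])
        new_row = 0.5 * (dm[ai, active] + dm[aj, active] - dij)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, active] = new_row
        dm[active, -1] = new_row
        dm[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    for idx, length in zip((a, b, c), (la, lb, lc)):
        if length < 0:
            n_clamped += 1
        nodes[idx].branch_length = max(length, 0.0)
    root = Clade(clades=[nodes[a], nodes[b], nodes[c]])
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative NJ branch length(s) to 0")
    return Tree(root=root, rooted=False)


def midpoint_root(tree: Tree) -> Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-leaf path."""
    rooted = copy.deepcopy(tree)
    if rooted.count_terminals() > 2:
        rooted.root_at_midpoint()
    rooted.rooted = True
    return rooted


def tree_distance_matrix(tree: Tree, labels: Iterable[str]) -> np.ndarray:
    """Patristic (path-length) distances between the named leaves."""
    labels = list(labels)
    leaves = {t.name: t for t in tree.get_terminals()}
    paths = {}
    for name in labels:
        path = tree.get_path(leaves[name])
        paths[name] = [tree.root] + path
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[labels[i]], paths[labels[j]]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k] is pj[k]:
                k += 1
            dist = sum(c.branch_length or 0.0 for c in pi[k:]) + sum(
                c.branch_length or 0.0 for c in pj[k:]
            )
            out[i, j] = out[j, i] = dist
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: Tree, all_leaves: frozenset) -> dict[frozenset, Clade]:
    """Canonical internal bipartitions (smaller-or-lexicographic side) -> clade."""
    out: dict[frozenset, Clade] = {}
    n = len(all_leaves)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if len(side) < 2 or len(side) > n - 2:
            continue
        other = all_leaves - side
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out[key] = clade
    return out


def bootstrap_support(
    aln: MitoAlignment, n_reps: int = 2000, seed: int = 0
) -> tuple[Tree, dict]:
    """Felsenstein bootstrap supports on the full-data K2P/NJ tree.

    Alignment columns retained after complete deletion are resampled with
    replacement; each replicate tree votes for the internal bipartitions of
    the full-data tree.  Replicates hitting K2P saturation are dropped and
    the support denominator adjusted.  Supports are percentages stored as
    clade ``confidence`` values on the returned (unrooted) tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = aln.encoded()
    cols = complete_deletion(enc)
    kept = enc[:, cols]
    dist, _ = k2p_distance_matrix(aln)
    tree = nj_tree(dist, aln.names)
    all_leaves = frozenset(aln.names)
    biparts = _bipartitions(tree, all_leaves)
    counts = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    n_dropped = 0
    length = kept.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        ts, tv, ncol = _pair_counts(kept[:, idx])
        p, q = ts / ncol, tv / ncol
        a = 1.0 - 2.0 * p - q
        b = 1.0 - 2.0 * q
        bad = (a <= 0) | (b <= 0)
        np.fill_diagonal(bad, False)
        if bad.any():
            n_dropped += 1
            continue
        d = -0.5 * np.log(a) - 0.25 * np.log(b)
        np.fill_diagonal(d, 0.0)
        rep = nj_tree(d, aln.names)
        rep_biparts = _bipartitions(rep, all_leaves)
        for key in counts:
            if key in rep_biparts:
                counts[key] += 1
    n_valid = n_reps - n_dropped
    if n_valid == 0:
        raise K2PSaturationError("all bootstrap replicates saturated")
    for key, clade in biparts.items():
        clade.confidence = 100.0 * counts[key] / n_valid
    return tree, {"n_reps": n_reps, "n_dropped": n_dropped, "n_valid": n_valid}


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------

def clade_bipartition_supports(
    tree: Tree, aln: MitoAlignment, clades: Iterable[str] = ("A", "M", "C", "O")
) -> dict[str, float | None]:
    """Bootstrap support of the bipartition separating each clade's
    sequences (references plus true-clade queries) from the rest.

    Returns None for a clade whose bipartition is absent from the tree.
    """
    all_leaves = frozenset(aln.names)
    biparts = _bipartitions(tree, all_leaves)
    out: dict[str, float | None] = {}
    for clade in clades:
        members = frozenset(
            [n for n, c in aln.reference_clades.items() if c == clade]
            + [n for n, c in aln.true_query_clades.items() if c == clade]
        )
        if not members:
            continue
        key = min(members, all_leaves - members, key=lambda s: (len(s), sorted(s)))
        out[clade] = biparts[key].confidence if key in biparts else None
    return out


def assign_clades(
    tree: Tree,
    aln: MitoAlignment,
    reference_clades: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assign each query to a mitotype clade.

    Primary rule: in the midpoint-rooted tree, the query's clade is that of
    the references inside the smallest enclosing clade that contains at least
    one reference, provided those references all share one clade.  If that
    clade mixes reference labels, fall back to the minimum mean K2P distance.
    The method used is recorded per query.
    """
    refs = dict(reference_clades or aln.reference_clades)
    if not refs:
        raise ValueError("no reference sequences with clade labels")
    rooted = tree if tree.rooted else midpoint_root(tree)
    parents: dict[int, Clade] = {}
    for clade in rooted.find_clades(order="level"):
        for child in clade.clades:
            parents[id(child)] = clade
    leaves = {t.name: t for t in rooted.get_terminals()}
    dist, _ = k2p_distance_matrix(aln)
    name_idx = {n: i for i, n in enumerate(aln.names)}
    clades_order = sorted(set(refs.values()))
    ref_idx = {
        c: [name_idx[n] for n, cl in refs.items() if cl == c] for c in clades_order
    }

    rows = []
    for query in aln.query_names:
        qi = name_idx[query]
        mean_d = {c: float(np.mean(dist[qi, idx])) for c, idx in ref_idx.items()}
        node = leaves[query]
        assigned, method = None, "distance"
        while id(node) in parents:
            node = parents[id(node)]
            inside = {refs[t.name] for t in node.get_terminals() if t.name in refs}
            if inside:
                if len(inside) == 1:
                    assigned, method = inside.pop(), "tree"
                break
        if assigned is None:
            assigned = min(mean_d, key=lambda c: (mean_d[c], c))
        row = {"query": query, "clade": assigned, "method": method}
        row.update({f"dist_{c}": mean_d[c] for c in clades_order})
        rows.append(row)
    return pd.DataFrame(rows)


def mitotype_table(
    assignments: pd.DataFrame,
    populations: Mapping[str, str],
    clades: Iterable[str] = ("A", "M", "C", "O"),
) -> pd.DataFrame:
    """Clade-by-population count table from per-query assignments."""
    df = assignments.copy()
    df["population"] = df["query"].map(dict(populations))
    table = (
        df.groupby(["clade", "population"]).size().unstack(fill_value=0)
    )
    table = table.reindex(list(clades), fill_value=0)
    table.index.name = "clade"
    return table


def write_newick(tree: Tree, path) -> None:
    Phylo.write(tree, str(path), "newick")
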