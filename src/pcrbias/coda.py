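"""Compositional-data machinery: closure, phylogenetic ILR bases, count filters.

An n-part composition carries only relative information; the isometric
log-ratio (ILR) transform maps it to n-1 unconstrained real coordinates
("balances") defined by a sequential binary partition, here taken from a
rooted binary phylogeny of the templates.  Each internal node i of the tree
contributes one balance contrasting its left against its right subclade::

    b_i = k_i * [ mean(log x_right) - mean(log x_left) ]

with k_i = sqrt(n_i- * n_i+ / (n_i- + n_i+)), which makes the rows of the
contrast matrix orthonormal and zero-sum.  The zero row sums are what cancel
the unknown per-library scale factor of sequencing counts.

Also implemented here are the count-table preprocessing steps applied before
modelling: prevalence filtering, rarefaction (sampling without replacement to
a common depth) and Bayesian-multiplicative zero replacement.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


class CodaError(ValueError):
    """Invalid compositional input (non-positive or non-finite parts)."""


class TreeStructureError(ValueError):
    """Tree is not strictly binary / rooted, or leaf names are inconsistent."""


class EmptyResultError(ValueError):
    """A filter removed every template."""


class InsufficientDepthError(ValueError):
    """A sample has fewer reads than the requested rarefaction depth."""


def closure(x: np.ndarray) -> np.ndarray:
    """Rescale strictly positive parts to sum to 1 (compositional closure).

    Accepts a vector or a matrix whose last axis holds the parts.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise CodaError("closure requires finite components")
    if np.any(x <= 0):
        raise CodaError("closure requires strictly positive components")
    return x / x.sum(axis=-1, keepdims=True)


def _check_binary(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        if len(node.children) != 2:
            raise TreeStructureError(
                f"internal node {node.name or '<unnamed>'} has "
                f"{len(node.children)} children; a strictly binary rooted "
                "tree is required (multifurcations are not resolved silently)"
            )


def sign_matrix_from_tree(
    tree: TreeNode | str, leaf_order: Sequence[str] | None = None
) -> np.ndarray:
    """Build the (n-1) x n sign matrix of a rooted binary tree.

    Row i corresponds to internal node i (preorder from the root); entry j is
    -1 if leaf j descends from the node's first ("left") child, +1 if from the
    second ("right") child, and 0 if leaf j does not descend from the node.

    Parameters
    ----------
    tree
        Rooted, strictly binary tree with uniquely named leaves, or a Newick
        string.
    leaf_order
        Column order of the matrix.  Defaults to the tree's tip order.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(_io.StringIO(tree))
    _check_binary(tree)
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise TreeStructureError("every leaf must be named")
    if len(set(names)) != len(names):
        raise TreeStructureError("duplicate leaf names in tree")
    if leaf_order is None:
        leaf_order = names
    elif set(leaf_order) != set(names):
        missing = set(leaf_order) ^ set(names)
        raise TreeStructureError(
            f"leaf_order does not match tree tips; differing names: {sorted(missing)}"
        )
    col = {name: j for j, name in enumerate(leaf_order)}
    n = len(leaf_order)
    if n < 2:
        raise TreeStructureError("tree must have at least two leaves")
    rows = []
    for node in tree.preorder(include_self=True):
        if node.is_tip():
            continue
        row = np.zeros(n, dtype=int)
        left, right = node.children
        for tip in ([left] if left.is_tip() else left.tips()):
            row[col[tip.name]] = -1
        for tip in ([right] if right.is_tip() else right.tips()):
            row[col[tip.name]] = +1
        rows.append(row)
    return np.array(rows, dtype=float)


def contrast_from_sign(phi: np.ndarray) -> np.ndarray:
    """Scale a sign matrix into the orthonormal ILR contrast matrix.

    Negative entries become -k_i / n_i-, positive entries +k_i / n_i+, with
    k_i = sqrt(n_i- n_i+ / (n_i- + n_i+)); zeros are preserved.  Rows of the
    result are zero-sum and orthonormal.
    """
    phi = np.asarray(phi, dtype=float)
    n_minus = (phi < 0).sum(axis=1).astype(float)
    n_plus = (phi > 0).sum(axis=1).astype(float)
    if np.any(n_minus == 0) or np.any(n_plus == 0):
        bad = np.where((n_minus == 0) | (n_plus == 0))[0]
        raise TreeStructureError(f"sign-matrix rows {bad.tolist()} lack one sign")
    k = np.sqrt(n_minus * n_plus / (n_minus + n_plus))
    psi = np.where(
        phi < 0,
        -(k / n_minus)[:, None],
        np.where(phi > 0, (k / n_plus)[:, None], 0.0),
    )
    return psi


@dataclass(frozen=True)
class ContrastBasis:
    """A phylogenetic ILR basis: tree, leaf order and derived Phi / Psi.

    Attributes
    ----------
    tree
        The rooted binary tree the basis derives from.
    leaf_order
        Template identifiers fixing the column order of both matrices.
    sign_matrix
        (n-1) x n matrix over {-1, 0, +1}.
    contrast_matrix
        (n-1) x n orthonormal, zero-row-sum matrix Psi.
    """

    tree: TreeNode = field(repr=False)
    leaf_order: tuple[str, ...]
    sign_matrix: np.ndarray = field(repr=False)
    contrast_matrix: np.ndarray = field(repr=False)

    @classmethod
    def from_tree(
        cls, tree: TreeNode | str, leaf_order: Sequence[str] | None = None
    ) -> "ContrastBasis":
        if isinstance(tree, str):
            tree = TreeNode.read(_io.StringIO(tree))
        phi = sign_matrix_from_tree(tree, leaf_order)
        psi = contrast_from_sign(phi)
        if leaf_order is None:
            leaf_order = [tip.name for tip in tree.tips()]
        return cls(tree=tree, leaf_order=tuple(leaf_order), sign_matrix=phi,
                   contrast_matrix=psi)

    @classmethod
    def from_newick(
        cls, path: str | Path, leaf_order: Sequence[str] | None = None
    ) -> "ContrastBasis":
        tree = TreeNode.read(str(path))
        return cls.from_tree(tree, leaf_order)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    @property
    def n_balances(self) -> int:
        return self.n_leaves - 1

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


def ilr(x: np.ndarray, basis: ContrastBasis) -> np.ndarray:
    """Isometric log-ratio transform: b = log(x) Psi^T.

    ``x`` may be a single composition (length n) or a matrix of row
    compositions (..., n).  The result is invariant to positive rescaling of
    each row, so raw positive counts need not be closed first.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.n_leaves:
        raise CodaError(
            f"expected {basis.n_leaves} parts, got {x.shape[-1]}"
        )
    if np.any(x == 0):
        raise CodaError(
            "zero components cannot be log-transformed; run zero_replace first"
        )
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise CodaError("ilr requires finite, strictly positive parts")
    return np.log(x) @ basis.contrast_matrix.T


def ilr_inverse(b: np.ndarray, basis: ContrastBasis) -> np.ndarray:
    """Map balances back to the simplex: x = closure(exp(b Psi))."""
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise CodaError("balances must be finite")
    if b.shape[-1] != basis.n_balances:
        raise CodaError(
            f"expected {basis.n_balances} balances, got {b.shape[-1]}"
        )
    return closure(np.exp(b @ basis.contrast_matrix))


@dataclass
class CountExperiment:
    """Amplicon counts (templates x samples) with per-sample cycle/replicate.

    Attributes
    ----------
    counts
        Non-negative integer matrix, one row per template, one column per
        sample (library).
    cycles
        Per-sample PCR cycle number t (>= 1).
    replicates
        Per-sample replicate label j.
    template_ids, sample_ids
        Unique row / column identifiers; ``template_ids`` must match the
        ``leaf_order`` of the basis used downstream.
    """

    counts: np.ndarray
    cycles: np.ndarray
    replicates: np.ndarray
    template_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D templates x samples matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.replicates = np.asarray(self.replicates)
        self.template_ids = tuple(str(t) for t in self.template_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        n_t, n_s = self.counts.shape
        if len(self.template_ids) != n_t or len(self.sample_ids) != n_s:
            raise ValueError("id lengths do not match the count matrix")
        if len(set(self.template_ids)) != n_t:
            raise ValueError("template_ids must be unique")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("sample_ids must be unique")
        if len(self.cycles) != n_s or len(self.replicates) != n_s:
            raise ValueError("cycles/replicates must have one entry per sample")
        if np.any(self.cycles < 1):
            raise ValueError("cycle numbers must be >= 1")
        totals = self.counts.sum(axis=0)
        if np.any(totals == 0):
            empty = [self.sample_ids[i] for i in np.where(totals == 0)[0]]
            raise ValueError(f"samples with zero total counts: {empty}")

    @property
    def n_templates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.template_ids), columns=list(self.sample_ids)
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "cycle": self.cycles,
                "replicate": self.replicates,
            }
        )


def prevalence_filter(
    exp: CountExperiment, min_count: int = 10, min_fraction: float = 0.5
) -> CountExperiment:
    """Drop templates not observed more than ``min_count`` times in at least
    ``min_fraction`` of the libraries.

    A template is kept iff the number of samples in which its count is
    strictly greater than ``min_count`` is at least ``min_fraction`` times the
    number of samples.  The sample set is unchanged.
    """
    prevalent = (exp.counts > min_count).sum(axis=1)
    keep = prevalent >= min_fraction * exp.n_samples
    if not keep.any():
        raise EmptyResultError(
            f"prevalence filter (>{min_count} in >= {min_fraction:.0%} of "
            f"{exp.n_samples} libraries) removed every template"
        )
    return CountExperiment(
        counts=exp.counts[keep],
        cycles=exp.cycles,
        replicates=exp.replicates,
        template_ids=tuple(np.array(exp.template_ids)[keep]),
        sample_ids=exp.sample_ids,
    )


def rarefy(exp: CountExperiment, depth: int, seed: int | None = None) -> CountExperiment:
    """Subsample each library without replacement to exactly ``depth`` reads.

    Per-sample draws are multivariate hypergeometric, so the expected rarefied
    count of template i is depth * c_i / total.  Reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    totals = exp.counts.sum(axis=0)
    short = np.where(totals < depth)[0]
    if short.size:
        names = [exp.sample_ids[i] for i in short]
        raise InsufficientDepthError(
            f"samples below rarefaction depth {depth}: {names}"
        )
    out = np.empty_like(exp.counts)
    for s in range(exp.n_samples):
        out[:, s] = rng.multivariate_hypergeometric(exp.counts[:, s], depth)
    return CountExperiment(
        counts=out,
        cycles=exp.cycles,
        replicates=exp.replicates,
        template_ids=exp.template_ids,
        sample_ids=exp.sample_ids,
    )


def zero_replace(
    exp: CountExperiment, prior_strength: float | None = None
) -> np.ndarray:
    """Bayesian-multiplicative zero replacement with a Dirichlet prior.

    Zeros in a sample with total N are imputed by the pseudo-counts
    N * s_i / (N + S) under a symmetric Dirichlet prior with per-component
    strength s_i, where S sums the prior strength of the sample's zero
    components; the non-zero entries are multiplicatively shrunk so each
    sample total is preserved.  The default prior strength is s_i = 1/n.

    Returns a strictly positive real matrix of the same shape; samples
    without zeros pass through unchanged.
    """
    n = exp.n_templates
    s_i = (1.0 / n) if prior_strength is None else float(prior_strength)
    if s_i <= 0:
        raise ValueError("prior strength must be positive")
    counts = exp.counts.astype(float)
    out = counts.copy()
    for s in range(exp.n_samples):
        col = counts[:, s]
        zeros = col == 0
        if not zeros.any():
            continue
        total = col.sum()
        imputed = total * s_i / (total + s_i * zeros.sum())
        replaced_mass = imputed * zeros.sum()
        if replaced_mass >= total:
            raise ValueError(
                f"sample {exp.sample_ids[s]}: imputed mass exceeds the total; "
                "lower the prior strength"
            )
        out[zeros, s] = imputed
        out[~zeros, s] = col[~zeros] * (1.0 - replaced_mass / total)
    return out
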