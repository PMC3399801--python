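"""Blomberg's K phylogenetic signal for species-mean traits.

K compares the observed ratio of trait variance to phylogenetically
corrected variance (via generalized least squares with the Brownian-motion
covariance C of the tree) against the ratio expected under Brownian
evolution.  K = 1 matches Brownian expectation, K < 1 means relatives
resemble each other less than expected.

Trees are handled through dendropy; branch lengths are in Myr (any unit —
K is invariant to rescaling).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = ["parse_newick", "write_newick", "tip_labels", "bm_covariance",
           "blomberg_k", "k_randomization_p", "KResult", "KResults",
           "PhylogeneticSignal", "default_tree", "DEFAULT_DIVERGENCES_MYR"]

#: divergence dates (Myr) used to assemble the default 8-taxon tree
DEFAULT_DIVERGENCES_MYR = {
    "platyrrhine_catarrhine": 35.0,
    "catarrhine": 25.0,          # cercopithecoid vs hominoid
    "cercopithecine_colobine": 14.0,
    "macaca_papio": 10.0,
    "hominid_hylobatid": 18.0,
    "pongo": 14.0,
    "homo_pan": 6.0,
}


def default_tree(dates: dict | None = None) -> dendropy.Tree:
    """The 8-genus anthropoid tree with divergence-date branch lengths.

    ``dates`` overrides entries of :data:`DEFAULT_DIVERGENCES_MYR`.
    """
    d = dict(DEFAULT_DIVERGENCES_MYR)
    if dates:
        unknown = set(dates) - set(d)
        if unknown:
            raise ValueError(f"unknown divergence keys: {sorted(unknown)}")
        d.update(dates)
    root, cat, cc, mp = (d["platyrrhine_catarrhine"], d["catarrhine"],
                         d["cercopithecine_colobine"], d["macaca_papio"])
    hh, po, hp = d["hominid_hylobatid"], d["pongo"], d["homo_pan"]
    newick = (
        f"(((((Homo:{hp},Pan:{hp}):{po - hp},Pongo:{po}):{hh - po},"
        f"Symphalangus:{hh}):{cat - hh},"
        f"((Macaca:{mp},Papio:{mp}):{cc - mp},Trachypithecus:{cc}):{cat - cc}"
        f"):{root - cat},Alouatta:{root}):0;"
    )
    return parse_newick(newick)


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring branch lengths and unique tips."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree is missing branch lengths")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    return buf.getvalue().strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance: C_ij = root-to-MRCA shared path length."""
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] if parent is not None else 0.0) + edge
    # tip set below each node
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label}
        else:
            below[node] = set().union(*(below[c] for c in node.child_nodes()))
        if (node.edge.length or 0.0) == 0.0 and node.is_leaf():
            warnings.warn(f"zero-length terminal branch at {node.taxon.label}")
    n = len(labels)
    C = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for node in tree.preorder_node_iter():
        tips = below[node]
        d = depth[node]
        for a in tips:
            for b in tips:
                if a != b:
                    C[idx[a], idx[b]] = max(C[idx[a], idx[b]], d)
    for lf in leaves:
        C[idx[lf.taxon.label], idx[lf.taxon.label]] = depth[lf]
    return pd.DataFrame(C, index=labels, columns=labels)


@dataclass
class KResult:
    """K with its ingredients: observed and Brownian-expected MSE0/MSE ratios."""

    K: float
    mse0: float
    mse: float
    observed_ratio: float
    expected_ratio: float
    n_tips: int


def _k_ingredients(C: np.ndarray, x: np.ndarray):
    n = len(x)
    ones = np.ones(n)
    Cinv_x = np.linalg.solve(C, x)
    Cinv_1 = np.linalg.solve(C, ones)
    denom = ones @ Cinv_1
    a_hat = (ones @ Cinv_x) / denom
    d = x - a_hat
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ np.linalg.solve(C, d)) / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    return a_hat, mse0, mse, float(expected)


def blomberg_k(tree: dendropy.Tree, trait: pd.Series | dict) -> KResult:
    """Blomberg's K for one species-mean trait.

    The trait index must match the tree's tip labels.  The GLS mean under
    Brownian motion is ā = (1ᵀC⁻¹x)/(1ᵀC⁻¹1); K is the observed MSE0/MSE
    ratio divided by its Brownian expectation [tr(C) − n/(1ᵀC⁻¹1)]/(n − 1).
    """
    trait = pd.Series(trait).astype(float)
    labels = tip_labels(tree)
    if set(trait.index) != set(labels):
        raise ValueError("trait index must equal the tree tip set")
    if len(labels) < 3:
        raise ValueError("K requires at least 3 tips")
    x = trait.loc[labels].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined (MSE = 0)")
    C = bm_covariance(tree).to_numpy()
    try:
        _, mse0, mse, expected = _k_ingredients(C, x)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular BM covariance: {exc}") from exc
    observed = mse0 / mse
    return KResult(K=observed / expected, mse0=mse0, mse=mse,
                   observed_ratio=observed, expected_ratio=expected,
                   n_tips=len(labels))


def k_randomization_p(tree: dendropy.Tree, trait: pd.Series | dict,
                      n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value: fraction of tip permutations with MSE ≤ observed.

    One-tailed with +1 smoothing.  (Reliable only for ~20+ tips; provided
    for completeness.)
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    trait = pd.Series(trait).astype(float)
    labels = tip_labels(tree)
    x = trait.loc[labels].to_numpy()
    C = bm_covariance(tree).to_numpy()
    _, _, mse_obs, _ = _k_ingredients(C, x)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, mse_p, _ = _k_ingredients(C, rng.permutation(x))
        if mse_p <= mse_obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass
class KResults:
    """Per-trait K table (rows = traits, columns = KResult fields)."""

    table: pd.DataFrame

    def summary(self) -> str:
        lines = ["Phylogenetic signal (Blomberg's K)", "-" * 36,
                 f"{'variable':<20}{'K':>8}"]
        for var, row in self.table.iterrows():
            lines.append(f"{var:<20}{row['K']:>8.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table[["K"]].to_csv(path, index_label="variable")


class PhylogeneticSignal:
    """Model object: species-mean traits on a tree; ``fit`` computes K per trait."""

    def __init__(self, tree: dendropy.Tree, traits: pd.DataFrame):
        self.tree = tree
        self.traits = traits.astype(float)
        if set(self.traits.index) != set(tip_labels(tree)):
            raise ValueError("trait rows must equal the tree tip set")

    @classmethod
    def from_species_means(cls, tree, specimen_table: pd.DataFrame,
                           species_col: str, trait_cols: list[str]):
        means = specimen_table.groupby(species_col)[trait_cols].mean()
        return cls(tree, means)

    def fit(self) -> KResults:
        rows = {}
        for var in self.traits.columns:
            r = blomberg_k(self.tree, self.traits[var])
            rows[var] = {"K": r.K, "mse0": r.mse0, "mse": r.mse,
                         "observed_ratio": r.observed_ratio,
                         "expected_ratio": r.expected_ratio,
                         "n_tips": r.n_tips}
        return KResults(pd.DataFrame(rows).T)
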