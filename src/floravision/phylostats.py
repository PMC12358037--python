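"""Simulation-based phylogenetic ANOVA (phylANOVA) and Brownian machinery.

The omnibus test compares an observed one-way ANOVA F statistic with the
distribution of F statistics obtained by simulating trait evolution under
Brownian motion (BM) on the phylogeny, with group labels held fixed on the
tips.  The BM rate is estimated once from the observed traits by maximum
likelihood under the tree's covariance structure.  P-values use the add-one
estimator p = (1 + #{F_sim >= F_obs}) / (n_sim + 1), which is never zero and
never below 1 / (n_sim + 1).

Post hoc pairwise comparisons use pooled-variance t statistics (Welch by
flag), each referenced to its own simulated null distribution drawn from the
same BM simulations as the omnibus test, then Holm-adjusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "PhylAnovaResult",
    "read_trait_table",
    "fit_bm_rate",
    "simulate_bm",
    "anova_f",
    "pairwise_t",
    "phylanova",
    "holm_adjust",
]


class PhyloTree:
    """A rooted tree with branch lengths, backed by dendropy.

    Tip labels must be unique; branch lengths must be non-negative (a missing
    root edge is treated as zero).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in tree")
        self._labels = labels

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse Newick from a file path or a literal Newick string."""
        try:
            if str(source).lstrip().startswith("("):
                tree = dendropy.Tree.get(data=str(source), schema="newick")
            else:
                tree = dendropy.Tree.get(path=str(source), schema="newick")
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid Newick input: {exc}") from exc
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def write_newick(self, path) -> None:
        self._tree.write(path=str(path), schema="newick", suppress_rooting=True)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def vcv(self, labels: list[str] | None = None) -> np.ndarray:
        """Phylogenetic covariance matrix: shared root-to-MRCA path lengths."""
        order = labels if labels is not None else self._labels
        missing = set(order) - set(self._labels)
        if missing:
            raise ValueError(f"labels absent from tree: {sorted(missing)}")
        idx = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))

        # post-order sweep: tip pairs first coalescing at a node share its depth
        depth: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            depth[id(node)] = (
                0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
            )
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                node._fv_tips = [idx[lab]] if lab in idx else []
                if lab in idx:
                    C[idx[lab], idx[lab]] = depth[id(node)]
                continue
            children = node.child_nodes()
            tipsets = [c._fv_tips for c in children]
            for a, b in itertools.combinations(range(len(children)), 2):
                for i in tipsets[a]:
                    for j in tipsets[b]:
                        C[i, j] = C[j, i] = depth[id(node)]
            node._fv_tips = [t for ts in tipsets for t in ts]
        return C

    def prune_to(self, labels: list[str]) -> "PhyloTree":
        """Subtree containing only the given tips (branch lengths retained)."""
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        return PhyloTree(sub)


@dataclass
class PhylAnovaResult:
    """Outcome of a phylogenetic ANOVA."""

    f_observed: float
    p_phylo: float
    n_sim: int
    seed: int | None
    sigma2: float
    posthoc: pd.DataFrame | None


def read_trait_table(path) -> pd.DataFrame:
    """Read a delimited trait table with columns ``label, value, group``."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"label", "value", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    return df


def _validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    t = traits[["label", "value", "group"]].copy()
    if t["label"].duplicated().any():
        dups = t.loc[t["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate trait labels: {dups}")
    if t["group"].nunique() < 2:
        raise ValueError("phylANOVA needs at least two groups")
    sizes = t.groupby("group").size()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(
            f"groups with fewer than 2 observations: {sorted(small.index)}"
        )
    return t


def _match(tree: PhyloTree, traits: pd.DataFrame) -> pd.DataFrame:
    tips = set(tree.tip_labels)
    labs = set(traits["label"])
    if tips != labs:
        offenders = sorted(tips ^ labs)
        raise ValueError(
            f"tree tips and trait labels do not match; offenders: {offenders}"
        )
    return traits.set_index("label").loc[tree.tip_labels].reset_index()


def fit_bm_rate(tree: PhyloTree, traits: pd.DataFrame) -> float:
    """Maximum-likelihood Brownian rate sigma^2 under the tree covariance.

    GLS estimate: mu = (1'C^-1 x)/(1'C^-1 1); sigma^2 = r'C^-1 r / n with
    r = x - mu.  Doubling all branch lengths halves the estimate.
    """
    t = traits[["label", "value"]].copy()
    if t["label"].duplicated().any():
        raise ValueError("duplicate trait labels")
    t = _match(tree, t.assign(group="_"))
    x = t["value"].to_numpy(dtype=float)
    C = tree.vcv()
    if np.max(np.diag(C)) <= 0:
        raise ValueError("degenerate zero-depth tree")
    Cinv_x = np.linalg.solve(C, x)
    ones = np.ones(len(x))
    Cinv_1 = np.linalg.solve(C, ones)
    mu = float(ones @ Cinv_x) / float(ones @ Cinv_1)
    r = x - mu
    return float(r @ np.linalg.solve(C, r)) / len(x)


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    seed: int | np.random.Generator | None = None,
    n_datasets: int = 1,
    root_value: float = 0.0,
) -> np.ndarray:
    """Simulate BM tip traits: multivariate normal with covariance sigma^2 C.

    Returns an array of shape ``(n_datasets, n_tips)`` (or 1-D when
    ``n_datasets == 1``), tips ordered as ``tree.tip_labels``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(tree)
    C = tree.vcv()
    if sigma2 == 0:
        out = np.full((n_datasets, n), root_value)
    else:
        try:
            L = np.sqrt(sigma2) * np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            # semi-definite C (e.g. zero-length pendant edges): tiny ridge
            L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(n))
        z = rng.standard_normal((n_datasets, n))
        out = root_value + z @ L.T
    return out[0] if n_datasets == 1 else out


def _group_indices(groups: pd.Series) -> tuple[list[str], list[np.ndarray]]:
    names = list(dict.fromkeys(groups))
    return names, [np.flatnonzero((groups == g).to_numpy()) for g in names]


def _f_stats(X: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    """Vectorised one-way F over rows of X (each row one dataset)."""
    X = np.atleast_2d(X)
    n = X.shape[1]
    k = len(idx)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for ii in idx:
        sub = X[:, ii]
        m = sub.mean(axis=1)
        ssb += len(ii) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    # zero within-group variance: +inf when group means differ, else 0
    f = np.where(msw == 0, np.where(msb > 0, np.inf, 0.0), f)
    return f


def anova_f(traits: pd.DataFrame) -> float:
    """Classical one-way ANOVA F statistic for a ``label, value, group`` table.

    With zero within-group variance and unequal means the statistic is
    reported as ``inf`` (sentinel for a degenerate, perfectly separated
    table).
    """
    t = _validate_traits(traits)
    _, idx = _group_indices(t["group"])
    if len(t) - len(idx) < 1:
        raise ValueError("residual degrees of freedom < 1")
    return float(_f_stats(t["value"].to_numpy(dtype=float), idx)[0])


def pairwise_t(
    x_a: np.ndarray, x_b: np.ndarray, welch: bool = False
) -> np.ndarray:
    """Two-sample t statistics, vectorised over rows (datasets)."""
    x_a, x_b = np.atleast_2d(x_a), np.atleast_2d(x_b)
    na, nb = x_a.shape[1], x_b.shape[1]
    ma, mb = x_a.mean(axis=1), x_b.mean(axis=1)
    va = x_a.var(axis=1, ddof=1)
    vb = x_b.var(axis=1, ddof=1)
    if welch:
        se = np.sqrt(va / na + vb / nb)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    return np.where(se == 0, np.where(ma == mb, 0.0, np.inf * np.sign(ma - mb)), t)


def holm_adjust(p: "list[float] | np.ndarray") -> np.ndarray:
    """Holm step-down multiple-testing adjustment.

    Adjusted values are monotone non-decreasing in the sorted order of the
    raw P-values, never below them, and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def phylanova(
    tree: PhyloTree,
    traits: pd.DataFrame,
    n_sim: int = 10000,
    seed: int | None = None,
    posthoc: bool = True,
    welch: bool = False,
) -> PhylAnovaResult:
    """Phylogenetic ANOVA by Brownian simulation.

    The BM rate is estimated once from the observed traits; ``n_sim``
    datasets are simulated on the tree with group labels fixed, and the
    omnibus P-value is the add-one exceedance proportion of simulated F
    statistics.  Post hoc pairwise t tests share the same simulated draws and
    are Holm-adjusted.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    t = _match(tree, _validate_traits(traits))
    x = t["value"].to_numpy(dtype=float)
    names, idx = _group_indices(t["group"])
    f_obs = float(_f_stats(x, idx)[0])

    sigma2 = fit_bm_rate(tree, traits)
    rng = np.random.default_rng(seed)
    sims = np.atleast_2d(simulate_bm(tree, sigma2, seed=rng, n_datasets=n_sim))
    f_sim = _f_stats(sims, idx)
    p_phylo = (1.0 + np.sum(f_sim >= f_obs)) / (n_sim + 1.0)

    posthoc_df = None
    if posthoc and len(names) >= 2:
        rows = []
        for a, b in itertools.combinations(range(len(names)), 2):
            t_obs = float(pairwise_t(x[idx[a]], x[idx[b]], welch=welch)[0])
            t_sim = pairwise_t(sims[:, idx[a]], sims[:, idx[b]], welch=welch)
            p_raw = (1.0 + np.sum(np.abs(t_sim) >= abs(t_obs))) / (n_sim + 1.0)
            rows.append(
                {"group_a": names[a], "group_b": names[b], "t": t_obs, "p_raw": p_raw}
            )
        posthoc_df = pd.DataFrame(rows)
        posthoc_df["p_holm"] = holm_adjust(posthoc_df["p_raw"].to_numpy())

    return PhylAnovaResult(f_obs, float(p_phylo), n_sim, seed, sigma2, posthoc_df)
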