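"""First-principles phylogenetic comparative statistics.

Closely related species are not independent samples: under Brownian-motion
(BM) trait evolution on a rooted tree, the trait covariance between two
tips is proportional to the depth of their most recent common ancestor.
This module builds that variance–covariance matrix C from a tree, measures
phylogenetic signal via Pagel's lambda (a multiplier on the off-diagonal
entries, estimated by maximum likelihood), and runs phylogenetic
generalized least squares (PGLS) ANOVA/MANOVA between groups with
significance assessed by residual randomization (RRPP): the data are
whitened by C^{-1/2}, an ordinary linear model is fitted, and the null
distribution of the F ratio is built by permuting the reduced-model
(intercept-only) whitened residuals.

Tree I/O uses Newick via dendropy; all statistics are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize


class NewickParseError(ValueError):
    """Malformed Newick input."""


# --------------------------------------------------------------------------
# Tree handling
# --------------------------------------------------------------------------


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickParseError("duplicate tip labels in tree")
    tree.is_rooted = True
    return tree


def read_newick_file(path) -> dendropy.Tree:
    from pathlib import Path

    return read_newick(Path(path).read_text())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in leaf-iteration order (the row order of the VCV)."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune(tree: dendropy.Tree, keep: set[str] | list[str]) -> dendropy.Tree:
    """Prune a tree to a tip subset, collapsing unifurcations.

    Path lengths among the kept tips are conserved: branch lengths of
    suppressed degree-2 nodes are summed. Unknown labels raise an error
    naming them.
    """
    keep = set(keep)
    have = set(tip_labels(tree))
    missing = sorted(keep - have)
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    # retain_taxa suppresses unifurcations by default, but the root can be
    # left with a single child whose edge must be absorbed.
    pruned.suppress_unifurcations()
    pruned.is_rooted = True
    return pruned


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion variance–covariance matrix of a rooted tree.

    C[i, i] is the root-to-tip distance of tip i; C[i, j] the depth of the
    most recent common ancestor of tips i and j. Symmetric positive
    semi-definite for non-negative branch lengths.
    """
    if not tree.is_rooted:
        raise ValueError("phylo_vcv requires a rooted tree")
    labels = tip_labels(tree)
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    # Depth-first fill: each internal node contributes its depth as the
    # covariance of every cross-child tip pair beneath it.
    def visit(node, depth: float) -> list[int]:
        if node.is_leaf():
            k = index[node.taxon.label]
            C[k, k] = depth
            return [k]
        below: list[int] = []
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length")
            tips_child = visit(child, depth + length)
            for i in below:
                for j in tips_child:
                    C[i, j] = C[j, i] = depth
            below.extend(tips_child)
        return below

    # A root (stem) edge — e.g. left by pruning to one side of the original
    # root — counts toward every depth, conserving root-to-tip distances.
    visit(tree.seed_node, tree.seed_node.edge.length or 0.0)
    return pd.DataFrame(C, index=labels, columns=labels)


def lambda_transform(C: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Pagel's lambda rescaling: off-diagonals times lambda, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    A = C.to_numpy(dtype=float)
    out = lam * A + (1.0 - lam) * np.diag(np.diag(A))
    return pd.DataFrame(out, index=C.index, columns=C.columns)


# --------------------------------------------------------------------------
# Pagel's lambda by maximum likelihood
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaResult:
    """ML estimate of Pagel's lambda with its profile log-likelihood."""

    lambda_hat: float
    loglik: float
    mu_hat: float
    sigma2_hat: float
    profile: pd.DataFrame = field(repr=False)
    unidentifiable: bool = False


def _profiled_loglik(y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of N(mu*1, sigma2*C) over mu, sigma2 (ML)."""
    n = y.size
    L = np.linalg.cholesky(C)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(n)
    # GLS via triangular solves: z = L^{-1} y, w = L^{-1} 1
    z = np.linalg.solve(L, y)
    w = np.linalg.solve(L, ones)
    mu = float(w @ z) / float(w @ w)
    r = z - mu * w
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        raise FloatingPointError("degenerate (constant) trait: sigma2 = 0")
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


def pagel_lambda_ml(
    y: pd.Series | np.ndarray,
    tree: dendropy.Tree | pd.DataFrame,
    grid_step: float = 0.01,
) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda for one continuous trait.

    ``y`` may be a Series indexed by species (matched to the tree tips) or
    a plain vector already in tip order. The mean and rate are profiled
    analytically by GLS at each lambda; lambda is optimized on [0, 1] by a
    coarse grid followed by bounded local refinement. A flat profile (a
    star tree, or fewer than 4 tips of signal) is flagged unidentifiable.
    """
    C = tree if isinstance(tree, pd.DataFrame) else phylo_vcv(tree)
    if isinstance(y, pd.Series):
        missing = sorted(set(C.index) - set(y.index))
        if missing:
            raise ValueError(f"trait missing for tips: {missing}")
        y = y.loc[C.index].to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.size != len(C):
            raise ValueError("trait vector length does not match tree tips")
    if y.size < 4:
        raise ValueError("need >= 4 species to estimate lambda")
    if np.ptp(y) == 0:
        raise FloatingPointError("constant trait: lambda is undefined")

    A = C.to_numpy(dtype=float)

    def nll(lam: float) -> float:
        Cl = lam * A + (1.0 - lam) * np.diag(np.diag(A))
        return -_profiled_loglik(y, Cl)[0]

    grid = np.arange(0.0, 1.0 + 1e-9, grid_step)
    grid_ll = np.array([-nll(l) for l in grid])
    best = int(np.argmax(grid_ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        lam_hat = float(res.x)
        if nll(grid[best]) < res.fun:  # guard against refinement losses
            lam_hat = float(grid[best])
    else:
        lam_hat = float(grid[best])

    Cl = lam_hat * A + (1.0 - lam_hat) * np.diag(np.diag(A))
    ll, mu, sigma2 = _profiled_loglik(y, Cl)
    flat = bool(np.ptp(grid_ll) < 1e-8 * max(1.0, abs(grid_ll).max()))
    profile = pd.DataFrame({"lambda": grid, "loglik": grid_ll})
    return LambdaResult(
        lambda_hat=lam_hat,
        loglik=ll,
        mu_hat=mu,
        sigma2_hat=sigma2,
        profile=profile,
        unidentifiable=flat,
    )


# --------------------------------------------------------------------------
# PGLS ANOVA / MANOVA with residual randomization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloTestResult:
    """F-type statistic and permutation p of a PGLS group test."""

    statistic: float
    p: float | None
    n_perm: int
    seed: int | None
    df_model: int
    df_resid: int
    n_traits: int


def whitening_matrix(C: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root P with P C P = I (so P'P = C^{-1})."""
    C = np.asarray(C, dtype=float)
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    if w.min() <= rtol * w.max():
        raise np.linalg.LinAlgError(
            f"covariance matrix is singular (min eigenvalue {w.min():.3g})"
        )
    return (V / np.sqrt(w)) @ V.T


def _group_design(groups: np.ndarray) -> np.ndarray:
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError(f"need >= 2 groups, got {labels}")
    cols = [(groups == lab).astype(float) for lab in labels[1:]]
    return np.column_stack([np.ones(groups.size)] + cols)


def _sse_factors(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis Q of X (SSE(Y) = ||Y||^2 - ||Q'Y||^2)."""
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-12 * max(1.0, np.abs(R).max())
    return Q[:, keep]


def pgls_manova_rrpp(
    Y: pd.DataFrame | np.ndarray,
    groups,
    tree: dendropy.Tree | pd.DataFrame | None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloTestResult:
    """PGLS MANOVA between groups with an RRPP permutation p value.

    The data are whitened by the symmetric inverse square root of C (pass
    ``tree=None`` for C = I, which reduces the test to an ordinary
    one-way (M)ANOVA). The statistic is the trace-form SS ratio

        F = (sum_t SS_model,t / df_model) / (sum_t SS_resid,t / df_resid),

    equal to the classical F for a single trait. The null distribution is
    built by permuting the rows of the reduced-model (intercept-only)
    whitened residual matrix; p = (1 + #{F* >= F}) / (n_perm + 1). With
    ``n_perm=0`` only the statistic is returned (p is None).
    """
    if isinstance(Y, pd.DataFrame):
        index = Y.index
        Ymat = Y.to_numpy(dtype=float)
    else:
        Ymat = np.asarray(Y, dtype=float)
        index = None
        if Ymat.ndim == 1:
            Ymat = Ymat[:, None]
    groups = np.asarray(groups)
    n, t = Ymat.shape
    if groups.size != n:
        raise ValueError("groups length does not match data rows")
    if np.isnan(Ymat).any():
        raise ValueError("missing values in tested traits")

    if tree is None:
        P = np.eye(n)
    else:
        C = tree if isinstance(tree, pd.DataFrame) else phylo_vcv(tree)
        if index is not None:
            missing = sorted(set(C.index) - set(index))
            if missing:
                raise ValueError(f"traits missing for tips: {missing}")
            order = list(C.index)
            pos = {lab: k for k, lab in enumerate(index)}
            sel = [pos[lab] for lab in order]
            Ymat = Ymat[sel]
            groups = groups[sel]
        if len(C) != n:
            raise ValueError("covariance size does not match data rows")
        P = whitening_matrix(C.to_numpy())

    Z = P @ Ymat
    Xf = P @ _group_design(groups)
    Xr = P @ np.ones((n, 1))
    Qf = _sse_factors(Xf)
    Qr = _sse_factors(Xr)
    df_model = Qf.shape[1] - Qr.shape[1]
    df_resid = n - Qf.shape[1]
    if df_model < 1 or df_resid < 1:
        raise ValueError("degenerate design: not enough observations")

    def trace_F(Zmat: np.ndarray) -> float:
        total = float(np.sum(Zmat * Zmat))
        sse_full = total - float(np.sum((Qf.T @ Zmat) ** 2))
        sse_red = total - float(np.sum((Qr.T @ Zmat) ** 2))
        ss_model = sse_red - sse_full
        return (ss_model / df_model) / (sse_full / df_resid)

    F_obs = trace_F(Z)
    if n_perm == 0:
        return PhyloTestResult(F_obs, None, 0, seed, df_model, df_resid, t)

    fitted_red = Qr @ (Qr.T @ Z)
    resid_red = Z - fitted_red
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if trace_F(fitted_red + resid_red[perm]) >= F_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PhyloTestResult(F_obs, p, n_perm, seed, df_model, df_resid, t)


def pgls_anova_rrpp(
    y,
    groups,
    tree: dendropy.Tree | pd.DataFrame | None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloTestResult:
    """Single-trait PGLS ANOVA with RRPP (see :func:`pgls_manova_rrpp`)."""
    if isinstance(y, pd.Series):
        y = y.to_frame()
    return pgls_manova_rrpp(y, groups, tree, n_perm=n_perm, seed=seed)
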