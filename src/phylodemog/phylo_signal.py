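"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

The central object is the phylogenetic covariance matrix C, whose entry
C[i, j] is the branch length shared between the root-to-tip paths of tips i
and j. Under Brownian-motion (BM) trait evolution with rate sigma^2, tip
values are multivariate normal with covariance sigma^2 * C, so C encodes the
"expected resemblance" between relatives against which signal is measured.

Blomberg's K compares the observed ratio of trait variance (around the GLS
phylogenetic mean) to its GLS-weighted counterpart, against the value this
ratio takes in expectation under BM:

    a_hat = (1' C^-1 1)^-1 1' C^-1 x                 (phylogenetic mean)
    MSE0  = (x - a_hat)' (x - a_hat) / (n - 1)
    MSE   = (x - a_hat)' C^-1 (x - a_hat) / (n - 1)
    K     = (MSE0 / MSE) / ( [tr C - n / (1' C^-1 1)] / (n - 1) )

K = 1 under BM, K -> 0 when trait values are independent of the phylogeny,
K > 1 when relatives are even more similar than BM predicts.

Intrageneric (within-tip) variation enters as measurement error: the trait
covariance becomes sigma^2 * C + diag(se^2), sigma^2 is estimated by ML, and
K is evaluated on the working matrix C + diag(se^2)/sigma^2.

Pagel's lambda rescales the off-diagonal of C by a factor lambda in
[0, lambda_max] and is estimated by ML; lambda = 1 recovers BM, lambda = 0 a
star phylogeny (no covariance).

Significance for K follows a tip-randomization scheme: trait values (with
their standard errors, permuted jointly) are shuffled across tips, and the
observed K is compared with the 2.5-97.5 percentile band of the permuted
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = [
    "PhyloCovariance",
    "SignalResult",
    "phylo_vcv",
    "blomberg_K",
    "blomberg_K_batch",
    "blomberg_K_with_se",
    "permutation_test",
    "pagel_lambda",
]


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloCovariance:
    """Tip-labelled phylogenetic variance-covariance matrix.

    ``matrix[i, j]`` is the shared root-to-tip path length of ``labels[i]``
    and ``labels[j]``, in the branch-length units of the source tree.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix must be square and match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("tip labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, labels) -> "PhyloCovariance":
        """Restrict C to ``labels`` (in the given order).

        Dropping tips does not change shared path lengths among the kept
        tips, so this is equivalent to pruning the tree first.
        """
        idx = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in idx]
        if missing:
            raise KeyError(f"labels not in covariance: {missing[:5]}")
        sel = np.array([idx[lab] for lab in labels])
        return PhyloCovariance(tuple(labels), self.matrix[np.ix_(sel, sel)])


def phylo_vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Build the phylogenetic covariance matrix C from a rooted tree.

    Tip order is the tree's leaf-traversal order (deterministic). Requires a
    root with at least two children and strictly positive branch lengths on
    every non-root edge.
    """
    root = tree.seed_node
    if len(root.child_nodes()) < 2:
        raise ValueError("tree must be rooted with >= 2 children at the root")

    depth: dict = {root: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        el = nd.edge.length
        if el is None or el <= 0:
            raise ValueError(
                f"branch length missing or non-positive on edge above "
                f"{nd.taxon.label if nd.taxon else 'an internal node'}"
            )
        depth[nd] = depth[nd.parent_node] + el

    leaves = list(tree.leaf_node_iter())
    labels = []
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise ValueError("every tip must carry a label")
        labels.append(lf.taxon.label)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")

    pos = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for lf in leaves:
        C[pos[lf], pos[lf]] = depth[lf]

    # tips in different child subtrees of a node share exactly depth(node)
    tipsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tipsets[nd] = [pos[nd]]
            continue
        kids = [tipsets.pop(ch) for ch in nd.child_nodes()]
        d = depth[nd]
        if d > 0:
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.array(kids[a])
                    ib = np.array(kids[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
        merged = [i for k in kids for i in k]
        tipsets[nd] = merged

    return PhyloCovariance(tuple(labels), C)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class SignalResult:
    """Outcome of a phylogenetic-signal computation."""

    statistic_name: str  # "K" or "lambda"
    estimate: float
    sigma2: float  # BM rate, trait-units^2 per branch-length unit
    se_used: bool
    n_tips: int
    perm_count: int = 0
    perm_quantiles: tuple[float, float] | None = None  # (2.5%, 97.5%)
    significant: bool | None = None
    log_likelihood: float | None = None
    lrt_pvalue: float | None = None  # lambda only: LRT vs lambda = 0
    seed: int | None = None
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


def _as_xc(x, C: PhyloCovariance, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Coerce trait input to an array aligned with C's tip order."""
    if hasattr(x, "index") and not isinstance(x, np.ndarray):  # pandas Series
        x = x.reindex(list(C.labels))
        if x.isna().any():
            raise ValueError("trait values missing for some tips")
        return x.to_numpy(dtype=float), C.matrix
    x = np.asarray(x, dtype=float)
    if labels is not None:
        sub = C.subset(list(labels))
        return x, sub.matrix
    if x.shape[0] != C.n:
        raise ValueError("trait vector length does not match tip count")
    return x, C.matrix


def _k_from_matrix(X: np.ndarray, C: np.ndarray, fac=None) -> np.ndarray:
    """K for each column of X (n x m) on covariance C; vectorized core."""
    n = C.shape[0]
    if fac is None:
        fac = cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve(fac, ones)
    s11 = ones @ Ci1
    CiX = cho_solve(fac, X)
    num1 = ones @ CiX  # 1' C^-1 X, shape (m,)
    a = num1 / s11
    R = X - a
    mse0 = np.sum(R * R, axis=0) / (n - 1)
    quad = np.sum(X * CiX, axis=0) - 2 * a * num1 + a * a * s11
    mse = quad / (n - 1)
    expected = (np.trace(C) - n / s11) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_K(x, C: PhyloCovariance, labels=None) -> SignalResult:
    """Blomberg's K of trait vector ``x`` on covariance ``C``.

    ``x`` may be a pandas Series indexed by tip label or a plain array in
    C's tip order. Raises on a constant trait (the statistic is undefined).
    """
    xv, Cm = _as_xc(x, C, labels)
    n = Cm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips for a meaningful K")
    if np.ptp(xv) == 0:
        raise ValueError("degenerate trait: constant across tips")
    try:
        fac = cho_factor(Cm, lower=True)
    except LinAlgError as err:
        raise ValueError("singular phylogenetic covariance") from err
    k = float(_k_from_matrix(xv[:, None], Cm, fac)[0])
    # ML sigma^2 under BM for reference
    ones = np.ones(n)
    Ci1 = cho_solve(fac, ones)
    s11 = ones @ Ci1
    Cix = cho_solve(fac, xv)
    a = (ones @ Cix) / s11
    quad = xv @ Cix - 2 * a * (ones @ Cix) + a * a * s11
    return SignalResult(
        statistic_name="K",
        estimate=k,
        sigma2=float(quad / n),
        se_used=False,
        n_tips=n,
    )


def blomberg_K_batch(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """K for every column of ``X`` on a fixed covariance (shared factorization)."""
    return _k_from_matrix(np.asarray(X, dtype=float), C)


# ---------------------------------------------------------------------------
# measurement-error-aware K
# ---------------------------------------------------------------------------


def _mvn_profile_ll(x: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """GLS mean, residual quadratic form and log-likelihood for N(a*1, V)."""
    n = x.shape[0]
    fac = cho_factor(V, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve(fac, ones)
    s11 = ones @ Ci1
    Cix = cho_solve(fac, x)
    a = (ones @ Cix) / s11
    quad = x @ Cix - 2 * a * (ones @ Cix) + a * a * s11
    logdet = 2.0 * np.sum(np.log(np.diag(fac[0])))
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return a, quad, ll


def _fit_sigma2_with_se(
    x: np.ndarray, Cm: np.ndarray, se2: np.ndarray, sigma2_init: float, xatol: float = 1e-6
) -> tuple[float, float]:
    """ML estimate of the BM rate under covariance sigma2*C + diag(se2).

    Profiles the likelihood over ln(sigma2) with a bounded scalar search.
    Returns (sigma2_hat, log_likelihood).
    """
    lo, hi = np.log(sigma2_init) - 18.0, np.log(sigma2_init) + 12.0

    def nll(t: float) -> float:
        V = np.exp(t) * Cm + np.diag(se2)
        return -_mvn_profile_ll(x, V)[2]

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"sigma^2 optimization failed: {res.message}")
    t_hat = float(res.x)
    if t_hat - lo < 1.0:
        raise RuntimeError(
            "signal indistinguishable from noise: ML sigma^2 collapsed to the "
            "search floor given the supplied standard errors"
        )
    return float(np.exp(t_hat)), float(-res.fun)


def blomberg_K_with_se(
    x, se, C: PhyloCovariance, labels=None, sigma2_init: float | None = None, xatol: float = 1e-6
) -> SignalResult:
    """Blomberg's K accounting for per-tip standard errors.

    Estimates sigma^2 by ML under covariance sigma^2*C + diag(se^2), then
    evaluates the K formulas on the working matrix C + diag(se^2)/sigma^2.
    With all-zero ``se`` this reduces exactly to :func:`blomberg_K`.
    """
    xv, Cm = _as_xc(x, C, labels)
    if hasattr(se, "reindex") and not isinstance(se, np.ndarray):
        se = se.reindex(list(C.labels) if labels is None else list(labels)).to_numpy(dtype=float)
    sev = np.asarray(se, dtype=float)
    if sev.shape != xv.shape:
        raise ValueError("se vector must match trait vector")
    if np.any(sev < 0) or not np.all(np.isfinite(sev)):
        raise ValueError("standard errors must be finite and >= 0")
    if np.ptp(xv) == 0:
        raise ValueError("degenerate trait: constant across tips")
    if np.all(sev == 0):
        out = blomberg_K(xv, PhyloCovariance(tuple(f"t{i}" for i in range(len(xv))), Cm))
        out.se_used = True
        return out

    n = Cm.shape[0]
    if sigma2_init is None:
        # plain BM ML rate as a starting point
        _, quad, _ = _mvn_profile_ll(xv, Cm)
        sigma2_init = max(quad / n, 1e-12)
    sigma2_hat, ll = _fit_sigma2_with_se(xv, Cm, sev**2, sigma2_init, xatol=xatol)
    Cstar = Cm + np.diag(sev**2) / sigma2_hat
    k = float(_k_from_matrix(xv[:, None], Cstar)[0])
    return SignalResult(
        statistic_name="K",
        estimate=k,
        sigma2=sigma2_hat,
        se_used=True,
        n_tips=n,
        log_likelihood=ll,
        notes={"sigma2_method": "ML"},
    )


# ---------------------------------------------------------------------------
# tip-randomization significance
# ---------------------------------------------------------------------------


def permutation_test(
    x,
    se,
    C: PhyloCovariance,
    n_perm: int = 1000,
    seed: int | None = None,
    labels=None,
) -> SignalResult:
    """Tip-randomization test for Blomberg's K.

    Shuffles trait values (jointly with their standard errors, when given)
    across tips ``n_perm`` times and flags the observed K as significant when
    it falls outside the 2.5-97.5 percentile band of the permuted values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    xv, Cm = _as_xc(x, C, labels)
    if np.ptp(xv) == 0:
        raise ValueError("degenerate trait: constant across tips")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    rng = np.random.default_rng(seed)
    n = Cm.shape[0]

    if se is None:
        obs = blomberg_K(xv, PhyloCovariance(tuple(f"t{i}" for i in range(n)), Cm))
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)  # n_perm independent shuffles
        Xp = xv[perm_idx].T  # (n, n_perm)
        kperm = _k_from_matrix(Xp, Cm)
    else:
        sev = np.asarray(
            se.reindex(list(C.labels)).to_numpy(dtype=float)
            if hasattr(se, "reindex") and not isinstance(se, np.ndarray)
            else se,
            dtype=float,
        )
        obs = blomberg_K_with_se(xv, sev, PhyloCovariance(tuple(f"t{i}" for i in range(n)), Cm))
        s2_init = obs.sigma2
        kperm = np.full(n_perm, np.nan)
        for b in range(n_perm):
            p = rng.permutation(n)
            try:
                r = blomberg_K_with_se(
                    xv[p], sev[p],
                    PhyloCovariance(tuple(f"t{i}" for i in range(n)), Cm),
                    sigma2_init=s2_init, xatol=1e-5,
                )
            except RuntimeError:
                continue  # permuted arrangement indistinguishable from noise
            kperm[b] = r.estimate
        valid = np.isfinite(kperm)
        if valid.sum() < n_perm // 2:
            raise RuntimeError(
                "permutation distribution degenerate: most permutations have "
                "no resolvable BM rate given the supplied standard errors"
            )
        kperm = kperm[valid]

    q_lo, q_hi = np.percentile(kperm, [2.5, 97.5])
    obs.perm_count = n_perm
    obs.perm_quantiles = (float(q_lo), float(q_hi))
    obs.significant = bool(obs.estimate < q_lo or obs.estimate > q_hi)
    obs.seed = seed
    return obs


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def _lambda_transform(Cm: np.ndarray, lam: float) -> np.ndarray:
    out = lam * Cm
    np.fill_diagonal(out, np.diag(Cm))
    return out


def _lambda_max(Cm: np.ndarray) -> float:
    """Largest lambda keeping C(lambda) positive definite.

    Starts from the branch-length bound min(diag)/max(offdiag) (the largest
    rescaling that keeps every tip edge non-negative) and shrinks until a
    Cholesky factorization succeeds.
    """
    off = Cm[~np.eye(Cm.shape[0], dtype=bool)]
    mx = off.max() if off.size else 0.0
    if mx <= 0:
        return 1.0  # star tree: lambda has no effect
    lam = float(np.min(np.diag(Cm)) / mx)
    for _ in range(60):
        try:
            cho_factor(_lambda_transform(Cm, lam), lower=True)
            return lam
        except LinAlgError:
            lam *= 0.999
    raise RuntimeError("could not find a positive-definite lambda bound")


def pagel_lambda(
    x, C: PhyloCovariance, se=None, labels=None, xatol: float = 1e-6
) -> SignalResult:
    """ML estimate of Pagel's lambda (off-diagonal multiplier of C).

    sigma^2 is profiled analytically when no standard errors are supplied,
    and optimized numerically under covariance sigma^2*C(lambda) + diag(se^2)
    otherwise. Also reports a likelihood-ratio test against lambda = 0
    (chi-squared, 1 df; conservative at the boundary).
    """
    xv, Cm = _as_xc(x, C, labels)
    n = Cm.shape[0]
    if np.ptp(xv) == 0:
        raise ValueError("degenerate trait: constant across tips")
    sev = None
    if se is not None:
        sev = np.asarray(
            se.reindex(list(C.labels)).to_numpy(dtype=float)
            if hasattr(se, "reindex") and not isinstance(se, np.ndarray)
            else se,
            dtype=float,
        )
    lam_max = _lambda_max(Cm)

    if sev is None or np.all(sev == 0):

        def nll(lam: float) -> float:
            V0 = _lambda_transform(Cm, lam)
            fac = cho_factor(V0, lower=True)
            ones = np.ones(n)
            Ci1 = cho_solve(fac, ones)
            s11 = ones @ Ci1
            Cix = cho_solve(fac, xv)
            a = (ones @ Cix) / s11
            quad = xv @ Cix - 2 * a * (ones @ Cix) + a * a * s11
            sigma2 = quad / n
            logdet = 2.0 * np.sum(np.log(np.diag(fac[0])))
            return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        def sigma2_at(lam: float) -> float:
            V0 = _lambda_transform(Cm, lam)
            _, quad, _ = _mvn_profile_ll(xv, V0)
            return quad / n

    else:
        se2 = sev**2
        _, quad0, _ = _mvn_profile_ll(xv, Cm)
        s2_init = max(quad0 / n, 1e-12)

        def nll(lam: float) -> float:
            V0 = _lambda_transform(Cm, lam)
            _, ll = _fit_sigma2_with_se(xv, V0, se2, s2_init, xatol=1e-5)[0:2]
            return -ll

        def sigma2_at(lam: float) -> float:
            V0 = _lambda_transform(Cm, lam)
            return _fit_sigma2_with_se(xv, V0, se2, s2_init, xatol=1e-5)[0]

    res = minimize_scalar(nll, bounds=(0.0, lam_max), method="bounded", options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(
            f"lambda optimization failed on [0, {lam_max:.4f}]: {res.message}"
        )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # bounded search never evaluates the exact endpoints; snap when adjacent
    for edge in (0.0, lam_max):
        if abs(lam_hat - edge) < 10 * xatol and nll(edge) <= res.fun:
            lam_hat, ll_hat = edge, -float(nll(edge))
    ll0 = -float(nll(0.0))
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    return SignalResult(
        statistic_name="lambda",
        estimate=lam_hat,
        sigma2=float(sigma2_at(lam_hat)),
        se_used=sev is not None and bool(np.any(sev > 0)),
        n_tips=n,
        log_likelihood=ll_hat,
        lrt_pvalue=float(chi2.sf(lrt, df=1)),
        notes={"lambda_max": lam_max},
    )
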