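"""Soft community detection by soft-modularity maximization.

The soft modularity of a row-stochastic membership matrix S (n x k) on a
weighted network with weight matrix W, strengths s_i and total edge weight m
is

    Q_soft = sum_c sum_ij [ W_ij/(2m) - s_i s_j / (2m)^2 ] S_ic S_jc

which reduces to Newman-Girvan modularity when S is binary.  Memberships are
fitted with multiplicative nonnegative-factorization updates on the
normalized weight matrix Wt = W/(2m) ~ X L X^T (columns of X and the diagonal
L each summing to 1), after which S = row-normalized X L.  The updates
monotonically increase the factorization log-likelihood; the returned
partition is the best Q_soft over all restarts and iterates visited,
including hard candidates (a greedy-modularity initial split and the
hard-rounded final memberships).

A permutation test compares the observed Q_soft at k = 2 against soft fits
of degree-preserving rewired replicas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, LookupError_, TieError, UndefinedModularityError
from .network import WeightedNetwork, rewire

__all__ = [
    "SoftPartition",
    "ModularityProfile",
    "PermutationTestResult",
    "soft_modularity",
    "fit_soft_communities",
    "modularity_profile",
    "modularity_permutation_test",
    "social_maturity",
]

_EPS = 1e-12


@dataclass
class SoftPartition:
    """Result of a soft community fit."""

    ids: list
    S: np.ndarray  # n x k, rows sum to 1
    k: int
    q_soft: float
    n_restarts: int
    converged: bool
    flags: dict = field(default_factory=dict)

    def dominant_labels(self) -> np.ndarray:
        """Hard labels by largest membership (ties -> lowest column)."""
        return self.S.argmax(axis=1)

    def membership_of(self, node) -> np.ndarray:
        return self.S[self.ids.index(node)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.S, index=pd.Index(self.ids, name="ant_id"),
            columns=[f"membership_{c + 1}" for c in range(self.k)],
        )
        return df


@dataclass
class ModularityProfile:
    """Best soft modularity per candidate community number."""

    q_by_k: dict[int, float]
    partitions: dict[int, SoftPartition]

    @property
    def argmax_k(self) -> int:
        return max(self.q_by_k, key=lambda k: self.q_by_k[k])


@dataclass
class PermutationTestResult:
    q_obs: float
    null_q: np.ndarray
    p_value: float
    n_rewires: int
    flags: dict = field(default_factory=dict)


def _modularity_matrix(network: WeightedNetwork) -> np.ndarray:
    m = network.total_weight
    if m <= 0:
        raise UndefinedModularityError("network has zero total weight")
    s = network.strengths()
    return network.W / (2.0 * m) - np.outer(s, s) / (2.0 * m) ** 2


def soft_modularity(network: WeightedNetwork, S: np.ndarray) -> float:
    """Soft modularity of membership matrix ``S`` on ``network``."""
    S = np.asarray(S, dtype=float)
    n = network.n_nodes
    if S.shape[0] != n:
        raise ContractError(f"S has {S.shape[0]} rows for {n} nodes")
    if np.any(S < -1e-12):
        raise ContractError("memberships must be nonnegative")
    rows = S.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-9):
        raise ContractError("rows of S must sum to 1")
    B = _modularity_matrix(network)
    return float(np.sum(B * (S @ S.T)))


def _spectral_hard_init(
    B: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Hard n x k indicator from spectral modularity partitioning, or None.

    Embeds nodes in the top k-1 eigenvectors of the modularity matrix and
    clusters with k-means; a cheap, usually excellent starting point that a
    different algorithm (multiplicative updates) then refines.
    """
    from scipy.cluster.vq import kmeans2
    from scipy.linalg import eigh

    n = B.shape[0]
    if k > n:
        return None
    try:
        _, vecs = eigh(B, subset_by_index=(n - (k - 1), n - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, labels = kmeans2(
                vecs, k, minit="++", seed=int(rng.integers(0, 2**31 - 1))
            )
    except Exception:
        return None
    if len(np.unique(labels)) != k:
        return None
    H = np.zeros((n, k))
    H[np.arange(n), labels] = 1.0
    return H


def _row_normalize(M: np.ndarray) -> np.ndarray:
    rows = M.sum(axis=1, keepdims=True)
    out = np.where(rows > 0, M / np.maximum(rows, _EPS), 1.0 / M.shape[1])
    return out


def _nmf_run(
    Wt: np.ndarray,
    X0: np.ndarray,
    lam0: np.ndarray,
    tol: float,
    max_iter: int,
    B: np.ndarray,
):
    """Multiplicative updates on Wt ~ X diag(lam) X^T.

    Returns (S, q, converged, ll_trace) where S is the row-normalized X L of
    the *converged* factorization and q its soft modularity.  The
    log-likelihood sum_ij Wt_ij log Y_ij is non-decreasing; convergence is
    declared when its change falls below tol.  Because every community
    column of X is constrained to carry unit mass, a k-community fit cannot
    silently collapse to fewer communities — this is what makes the
    modularity profile a usable model-selection criterion over k.
    """
    X = X0 / np.maximum(X0.sum(axis=0, keepdims=True), _EPS)
    lam = lam0 / max(lam0.sum(), _EPS)
    prev_ll = -np.inf
    converged = False
    ll_trace: list[float] = []
    mask = Wt > 0
    wt_pos = Wt[mask]
    for _ in range(max_iter):
        Y = (X * lam[None, :]) @ X.T
        R = np.where(mask, Wt / np.maximum(Y, _EPS), 0.0)
        X_new = X * (R @ (X * lam[None, :]))
        lam_new = lam * np.einsum("kl,kc,lc->c", R, X, X)
        X = X_new / np.maximum(X_new.sum(axis=0, keepdims=True), _EPS)
        lam = lam_new / max(lam_new.sum(), _EPS)
        Y = (X * lam[None, :]) @ X.T
        ll = float(np.sum(wt_pos * np.log(np.maximum(Y[mask], _EPS))))
        ll_trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    S = _row_normalize(X * lam[None, :])
    q = float(np.sum(B * (S @ S.T)))
    return S, q, converged, ll_trace


def fit_soft_communities(
    network: WeightedNetwork,
    k: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = None,
) -> SoftPartition:
    """Fit a k-community soft partition maximizing soft modularity.

    Restart 0 is initialized from a greedy hard modularity split (when one
    with exactly k parts exists); remaining restarts use random
    Dirichlet-like initial memberships.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    n = network.n_nodes
    if k == 1:
        S = np.ones((n, 1))
        return SoftPartition(list(network.ids), S, 1, soft_modularity(network, S),
                             n_restarts=0, converged=True)
    m = network.total_weight
    if m <= 0:
        raise UndefinedModularityError("cannot fit communities on empty network")
    rng = np.random.default_rng(seed)
    Wt = network.W / (2.0 * m)
    B = _modularity_matrix(network)

    best = None
    any_converged = False
    hard0 = _spectral_hard_init(B, k, rng)
    for r in range(n_restarts):
        if r == 0 and hard0 is not None:
            X0 = 0.95 * hard0 + 0.05 / k
            lam0 = np.full(k, 1.0 / k)
        else:
            X0 = rng.gamma(1.0, size=(n, k)) + _EPS
            lam0 = rng.gamma(1.0, size=k) + _EPS
        S, q, conv, _ = _nmf_run(Wt, X0, lam0, tol, max_iter, B)
        any_converged = any_converged or conv
        if best is None or q > best[1]:
            best = (S, q)
    S, q = best
    return SoftPartition(
        ids=list(network.ids), S=S, k=k, q_soft=q,
        n_restarts=n_restarts, converged=any_converged,
    )


def modularity_profile(
    network: WeightedNetwork,
    ks: tuple[int, ...] = (2, 3, 4, 5),
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = None,
) -> ModularityProfile:
    """Best soft modularity for each candidate k under an equal restart budget."""
    rng = np.random.default_rng(seed)
    q_by_k: dict[int, float] = {}
    parts: dict[int, SoftPartition] = {}
    for k in ks:
        part = fit_soft_communities(
            network, k, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=rng
        )
        q_by_k[int(k)] = part.q_soft
        parts[int(k)] = part
    return ModularityProfile(q_by_k=q_by_k, partitions=parts)


def modularity_permutation_test(
    network: WeightedNetwork,
    k: int = 2,
    n_rewires: int = 100,
    seed: int | np.random.Generator | None = None,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_swap_multiplier: int = 10,
    rewire_strategy: str = "swap_shuffle_weights",
) -> PermutationTestResult:
    """Permutation test of community structure against rewired replicas.

    p = (1 + #{null Q >= Q_obs}) / (n_rewires + 1).  Observed and null
    networks are fitted with identical settings so the test is exchangeable
    under the null even when the optimizer is imperfect.

    The default null carries double-edge swaps plus a shuffle of the
    edge-weight multiset: colony networks are typically near-complete, and
    on a complete graph degree-preserving swaps alone cannot move any mass
    (community structure lives in where the large weights sit).
    """
    rng = np.random.default_rng(seed)
    flags: dict = {}
    if len(network.edges()) < 2:
        warnings.warn("network too degenerate to rewire; p = 1")
        return PermutationTestResult(
            q_obs=np.nan, null_q=np.array([]), p_value=1.0,
            n_rewires=0, flags={"degenerate": True},
        )
    # one fit seed for observed and all nulls: the fit is then a
    # deterministic function of the network, so identical null networks tie
    # exactly and exchangeability under the null is preserved
    fit_seed = int(rng.integers(0, 2**31 - 1))
    q_obs = fit_soft_communities(
        network, k, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
        seed=fit_seed,
    ).q_soft
    null_q = np.empty(n_rewires)
    for b in range(n_rewires):
        null_net = rewire(
            network, n_swap_multiplier=n_swap_multiplier, seed=rng,
            strategy=rewire_strategy,
        )
        if "rewire_warning" in null_net.flags:
            flags.setdefault("rewire_warnings", 0)
            flags["rewire_warnings"] += 1
        null_q[b] = fit_soft_communities(
            null_net, k, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
            seed=fit_seed,
        ).q_soft
    p = (1.0 + np.sum(null_q >= q_obs)) / (n_rewires + 1.0)
    return PermutationTestResult(
        q_obs=q_obs, null_q=null_q, p_value=float(p),
        n_rewires=n_rewires, flags=flags,
    )


def social_maturity(
    partition: SoftPartition,
    queen_id,
    tie_tol: float = 0.0,
) -> pd.Series:
    """Per-ant social maturity: membership in the forager community.

    The forager community is the k=2 community the queen is *less* affiliated
    with.  Values range 0 (nurse community) to 1 (forager community).  The
    queen's own value is included in the output; downstream statistics are
    expected to drop her.
    """
    if partition.k != 2:
        raise ContractError("social maturity requires a k=2 partition")
    if queen_id not in partition.ids:
        raise LookupError_(f"queen {queen_id!r} not in partition roster")
    q_row = partition.membership_of(queen_id)
    if abs(q_row[0] - q_row[1]) <= tie_tol:
        raise TieError(
            "queen membership is exactly split between communities; "
            "forager orientation undecidable"
        )
    forager_col = int(np.argmin(q_row))
    return pd.Series(
        partition.S[:, forager_col],
        index=pd.Index(partition.ids, name="ant_id"),
        name="maturity",
    )


def social_maturity_by_foraging(
    partition: SoftPartition,
    foraging_proportion: pd.Series,
) -> pd.Series:
    """Fallback orientation when no queen is available.

    The forager community is the one with the higher mean foraging
    proportion among its dominant members.
    """
    if partition.k != 2:
        raise ContractError("social maturity requires a k=2 partition")
    labels = partition.dominant_labels()
    fp = foraging_proportion.reindex(partition.ids).to_numpy(dtype=float)
    means = [np.nanmean(fp[labels == c]) if np.any(labels == c) else -np.inf
             for c in (0, 1)]
    forager_col = int(np.argmax(means))
    return pd.Series(
        partition.S[:, forager_col],
        index=pd.Index(partition.ids, name="ant_id"),
        name="maturity",
    )
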