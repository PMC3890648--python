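"""Genetic-structure inference by three routes, plus run alignment and agreement.

Routes:

1. PCA of frequency-normalised genotypes with Tracy-Widom significance for
   the leading eigenvalues, followed by Ward hierarchical clustering of the
   eigenvalue-weighted significant components;
2. a haploid admixture model — each sample i carries ancestry proportions
   q_ik over K clusters with cluster allele frequencies p_kl, and the
   likelihood  L = sum_il log( sum_k q_ik [p_kl if call 1 else 1 - p_kl] )
   is maximised by EM from seeded random starts, with replicate runs and a
   Wilcoxon likelihood test to choose K;
3. neighbor-joining trees on allele-difference distances with locus
   bootstrap support.

Replicate membership matrices are aligned over cluster-label permutations
(CLUMPP-style) and summarised by the symmetric similarity H'.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import linear_sum_assignment
from scipy.special import airy

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tracy-Widom (beta = 1) distribution via the Painleve II representation
#
# The GOE Tracy-Widom CDF is F1(s) = exp(-(I(s) + J(s)) / 2) with
# I(s) = int_s^inf (x - s) q(x)^2 dx,  J(s) = int_s^inf q(x) dx, where q is
# the Hastings-McLeod solution of Painleve II (q'' = s q + 2 q^3, q ~ Ai at
# +inf).  The ODE system is integrated downward from s = 8 where q = Ai.


@lru_cache(maxsize=1)
def _tw1_table() -> PchipInterpolator:
    s0, s1 = 8.0, -10.0

    def rhs(s, y):
        q, dq, I, J, K = y
        return [dq, s * q + 2 * q**3, -K, -q, -(q**2)]

    ai, aip, _, _ = airy(s0)
    # high-order solver with tight tolerances: the Hastings-McLeod solution
    # is unstable to perturbations, and looser settings blow up near s ~ -7
    sol = solve_ivp(
        rhs,
        (s0, s1),
        [ai, aip, 0.0, 0.0, 0.0],
        t_eval=np.linspace(s0, s1, 2001),
        rtol=1e-12,
        atol=1e-14,
        method="DOP853",
    )
    if sol.t[-1] > s1 + 1e-9:  # pragma: no cover - solver fallback
        raise RuntimeError("Tracy-Widom integration failed to reach the left tail")
    s = sol.t[::-1]
    I, J = sol.y[2][::-1], sol.y[3][::-1]
    f1 = np.clip(np.exp(-(I + J) / 2.0), 0.0, 1.0)
    # integration noise in the deep left tail (F1 ~ 1e-8) can break
    # monotonicity; enforce it so p-values are well ordered
    f1 = np.maximum.accumulate(f1)
    return PchipInterpolator(s, f1)


def tracy_widom_sf(x: float) -> float:
    """Upper-tail p-value of the Tracy-Widom (beta=1) law."""
    if x >= 8.0:
        return 0.0
    if x <= -10.0:
        return 1.0
    return float(1.0 - _tw1_table()(x))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # non-increasing
    variance_fractions: np.ndarray
    scores: np.ndarray  # samples x components
    tw_pvalues: np.ndarray
    ld_correct: int
    sample_ids: list[str] = field(default_factory=list)


def _tw_statistic(eigs: np.ndarray) -> float:
    """Patterson moment-matched TW statistic for the largest of ``eigs``."""
    m = len(eigs)
    s1, s2 = eigs.sum(), (eigs**2).sum()
    denom = (m + 1) * s2 - s1**2
    if denom <= 0 or m < 2:
        return -np.inf
    n_eff = (m + 1) * s1**2 / denom
    n_eff = max(n_eff, 2.0 + 1e-9)
    ell = m * eigs[0] / s1
    mu = (np.sqrt(n_eff - 1) + np.sqrt(m)) ** 2 / n_eff
    sigma = (
        (np.sqrt(n_eff - 1) + np.sqrt(m))
        / n_eff
        * (1 / np.sqrt(n_eff - 1) + 1 / np.sqrt(m)) ** (1 / 3)
    )
    return (ell - mu) / sigma


def pca(g: GenotypeMatrix, ld_correct: int = 0) -> PcaResult:
    """Eigenanalysis of frequency-normalised haploid genotypes.

    Loci are centred by their allele frequency and scaled by
    sqrt(p(1-p)); missing calls are imputed to the locus mean before
    scaling; ``ld_correct`` in {0, 1, 2} residualises each locus on that
    many preceding loci (map order) to damp linkage disequilibrium.
    Tracy-Widom p-values are computed sequentially for each component.
    """
    if g.n_samples < 3:
        raise ClusteringError("PCA needs >= 3 samples")
    if ld_correct not in (0, 1, 2):
        raise ClusteringError("ld_correct must be 0, 1 or 2")
    calls = g.calls.astype(float)
    obs = g.calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.where(obs, calls, 0).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
    keep = (n_obs > 0) & (p > 0) & (p < 1)  # drop monomorphic / all-missing
    if keep.sum() < 2:
        raise ClusteringError("fewer than 2 polymorphic loci")
    calls, p = calls[:, keep], p[keep]
    obs = obs[:, keep]
    x = np.where(obs, calls, p[None, :])  # mean imputation
    x = (x - p[None, :]) / np.sqrt(p * (1 - p))[None, :]

    if ld_correct:
        resid = x.copy()
        for j in range(x.shape[1]):
            lo = max(0, j - ld_correct)
            if lo == j:
                continue
            pred = x[:, lo:j]
            beta, *_ = np.linalg.lstsq(pred, x[:, j], rcond=None)
            resid[:, j] = x[:, j] - pred @ beta
        x = resid

    n, L = x.shape
    cov = x @ x.T / L
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]

    fractions = eigvals / eigvals.sum()
    nonzero = eigvals > 1e-10 * eigvals[0]
    m_eff = int(nonzero.sum())
    pvals = np.ones(len(eigvals))
    for i in range(m_eff - 1):
        stat = _tw_statistic(eigvals[i:m_eff])
        pvals[i] = tracy_widom_sf(stat)
    scores = eigvecs * np.sqrt(np.maximum(eigvals, 0))[None, :]
    return PcaResult(
        eigenvalues=eigvals,
        variance_fractions=fractions,
        scores=scores,
        tw_pvalues=pvals,
        ld_correct=ld_correct,
        sample_ids=g.sample_ids,
    )


def select_components(
    p: PcaResult, min_fraction: float = 0.02, k_range: tuple[int, int] = (3, 5)
) -> np.ndarray:
    """Eigenvalue-weighted scores of the leading informative components.

    Takes the largest components whose variance fraction is at least
    ``min_fraction``, clipped into ``k_range``; if fewer qualify, the
    ``k_range[0]`` largest are used with a warning.
    """
    lo, hi = k_range
    eligible = int((p.variance_fractions >= min_fraction).sum())
    k = min(max(eligible, lo), hi)
    if eligible < lo:
        logger.warning(
            "only %d components reach %.0f%% variance; using the %d largest",
            eligible,
            100 * min_fraction,
            lo,
        )
    return p.scores[:, :k]


# ---------------------------------------------------------------------------
# Ward clustering


@dataclass
class HardAssignment:
    labels: np.ndarray  # cluster label per sample
    source: str  # admixture-majority | ward
    sample_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))


def ward_cluster(
    scores: np.ndarray,
    k: int | None = None,
    sample_ids: Sequence[str] | None = None,
    max_k: int = 20,
) -> tuple[HardAssignment, np.ndarray]:
    """Ward-linkage clustering of component scores; returns labels + heights.

    With ``k`` unset, the cut is placed at the largest relative jump between
    successive merge heights (the corresponding number of clusters, capped
    at ``max_k``).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if k is not None and k > n:
        raise ClusteringError("k > number of samples")
    Z = linkage(scores, method="ward")
    heights = Z[:, 2]
    if k is None:
        if n < 3:
            k = 1
        else:
            ratios = np.where(heights[:-1] > 0, heights[1:] / heights[:-1], 1.0)
            # merge i -> i+1 reduces cluster count from n-i-1; cut before the jump
            candidates = [(ratios[i], n - i - 1) for i in range(len(ratios)) if n - i - 1 <= max_k]
            k = max(candidates)[1] if candidates else 1
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return (
        HardAssignment(labels=labels, source="ward", sample_ids=list(sample_ids or [])),
        heights,
    )


# ---------------------------------------------------------------------------
# haploid admixture model (EM)


@dataclass
class MembershipMatrix:
    Q: np.ndarray  # n x K, rows on the simplex
    loglik: float
    seed: int | None = None
    K: int = 0
    converged: bool = True
    n_iter: int = 0
    holdout_loglik: float | None = None  # likelihood of masked calls, if any

    def __post_init__(self):
        self.K = self.Q.shape[1]

    def majority(self, sample_ids: Sequence[str] | None = None) -> HardAssignment:
        return HardAssignment(
            labels=np.argmax(self.Q, axis=1),
            source="admixture-majority",
            sample_ids=list(sample_ids or []),
        )


def _admixture_loglik(x, obs, Q, P) -> float:
    # f[i, l, k] = P(call x_il | ancestry k)
    f = np.where(x[:, :, None] == 1, P.T[None, :, :], 1.0 - P.T[None, :, :])
    mix = np.einsum("ik,ilk->il", Q, f)
    return float(np.log(np.clip(mix, 1e-300, None))[obs].sum())


def admixture_fit(
    g: GenotypeMatrix,
    K: int,
    seed: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 300,
    holdout_fraction: float = 0.0,
    holdout_seed: int | None = None,
) -> MembershipMatrix:
    """Maximum-likelihood haploid admixture by block-relaxation EM.

    Missing calls are skipped.  The EM updates never decrease the
    likelihood; iteration stops at relative tolerance ``tol`` or at
    ``max_iter`` (flagged, not raised).

    ``holdout_fraction`` > 0 masks that share of the observed calls before
    fitting and records their predictive log-likelihood as
    ``holdout_loglik``.  The maximised (training) likelihood grows with K
    even on structureless data because Q adds free parameters per sample;
    the held-out likelihood penalises that overfit and is the quantity to
    feed into :func:`select_k`.
    """
    if K < 1:
        raise ClusteringError("K must be >= 1")
    if K > g.n_samples:
        raise ClusteringError("K > number of samples")
    x_full = g.calls.astype(np.int8)
    obs_full = x_full != MISSING
    x = x_full.copy()
    held = np.zeros_like(obs_full)
    if holdout_fraction > 0:
        mask_rng = np.random.default_rng(seed if holdout_seed is None else holdout_seed)
        held = obs_full & (mask_rng.random(x.shape) < holdout_fraction)
        x = np.where(held, MISSING, x)
    obs = x != MISSING
    n, L = x.shape

    def _finish(Q: np.ndarray, P: np.ndarray, ll: float, converged: bool, it: int):
        h_ll = None
        if holdout_fraction > 0:
            f = np.where(x_full[:, :, None] == 1, P.T[None, :, :], 1.0 - P.T[None, :, :])
            mix = np.einsum("ik,ilk->il", Q, f)
            h_ll = float(np.log(np.clip(mix, 1e-300, None))[held].sum())
        return MembershipMatrix(
            Q=Q, loglik=ll, seed=seed, converged=converged, n_iter=it, holdout_loglik=h_ll
        )

    if K == 1:
        n1 = ((x == 1) & obs).sum(axis=0).astype(float)
        ntot = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ntot > 0, n1 / np.maximum(ntot, 1), 0.5)
        p = np.clip(p, 1e-6, 1 - 1e-6)
        ll = float((n1 * np.log(p) + (ntot - n1) * np.log(1 - p)).sum())
        return _finish(np.ones((n, 1)), p[None, :], ll, True, 0)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.1, 0.9, size=(K, L))
    x1 = (x == 1) & obs

    obs3 = obs[:, :, None]
    is1 = (x == 1)[:, :, None]
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step; the mixture denominator is the per-call likelihood of the
        # current (Q, P), so the log-likelihood tracking is free
        f = np.where(is1, P.T[None, :, :], 1.0 - P.T[None, :, :])
        w = Q[:, None, :] * f  # n x L x K
        denom = w.sum(axis=2)
        ll = float(np.log(np.clip(denom, 1e-300, None))[obs].sum())
        if ll < ll_prev - 1e-6:
            raise AssertionError("EM likelihood decreased")  # pragma: no cover
        if abs(ll - ll_prev) <= tol * max(abs(ll), 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        r = np.where(obs3, w / np.clip(denom[:, :, None], 1e-300, None), 0.0)
        # M-step
        Q = r.sum(axis=1)
        Q /= np.clip(Q.sum(axis=1, keepdims=True), 1e-300, None)
        r_sum = r.sum(axis=0)  # L x K
        r_one = (r * x1[:, :, None]).sum(axis=0)  # L x K
        P = np.clip((r_one / np.clip(r_sum, 1e-300, None)).T, 1e-6, 1 - 1e-6)
    if not converged:
        logger.info("admixture_fit K=%d: not converged in %d iterations", K, max_iter)
    return _finish(Q, P, ll_prev, converged, it)


def replicate_runs(
    g: GenotypeMatrix,
    K: int,
    n_replicates: int = 20,
    seed: int = 0,
    holdout_fraction: float = 0.0,
    n_starts: int = 3,
    **fit_kw,
) -> list[MembershipMatrix]:
    """``n_replicates`` EM runs; each keeps the best of ``n_starts`` starts.

    Multiple seeded random starts per run absorb local-optimum variability
    (the kept run is the one with the highest maximised likelihood).  With a
    holdout fraction, replicate r masks the calls chosen by seed
    ``seed + r`` regardless of K, so replicate likelihoods are paired
    across K values by their index (the pairing :func:`select_k` assumes).
    """
    out = []
    for r in range(n_replicates):
        fits = [
            admixture_fit(
                g,
                K,
                seed=seed + r + 100003 * j,
                holdout_fraction=holdout_fraction,
                holdout_seed=(seed + r if holdout_fraction > 0 else None),
                **fit_kw,
            )
            for j in range(n_starts)
        ]
        out.append(max(fits, key=lambda m: m.loglik))
    return out


def partition_evidence(g: GenotypeMatrix, labels: np.ndarray, alpha: float = 1.0) -> float:
    """Exact marginal log-likelihood of a hard sample partition.

    Integrates the product-Bernoulli cluster model analytically: each
    cluster-locus allele frequency carries a Beta(1, 1) prior and the
    mixture weights a symmetric Dirichlet(``alpha``).  The result is the
    Bayesian evidence ln P(data | partition): it rises when a split
    separates genuinely different allele-frequency profiles and falls when
    a homogeneous cluster is split (the Ockham penalty), which makes it the
    right per-run quantity to feed into :func:`select_k` — the maximised EM
    likelihood itself grows with K on any data and carries no such penalty.
    """
    from scipy.special import gammaln

    x, obs = g.calls, g.calls != MISSING
    labels = np.asarray(labels)
    total = 0.0
    uniq = np.unique(labels)
    for k in uniq:
        rows = labels == k
        n1 = ((x[rows] == 1) & obs[rows]).sum(axis=0)
        n0 = ((x[rows] == 0) & obs[rows]).sum(axis=0)
        total += (gammaln(n1 + 1.0) + gammaln(n0 + 1.0) - gammaln(n1 + n0 + 2.0)).sum()
    sizes = np.array([(labels == k).sum() for k in uniq], dtype=float)
    K, n = len(uniq), len(labels)
    total += (
        gammaln(K * alpha)
        - gammaln(n + K * alpha)
        + gammaln(sizes + alpha).sum()
        - K * gammaln(alpha)
    )
    return float(total)


def evidence_by_k(
    g: GenotypeMatrix,
    k_range: tuple[int, int],
    n_replicates: int = 20,
    seed: int = 0,
    n_starts: int = 3,
    **fit_kw,
) -> tuple[dict[int, list[MembershipMatrix]], dict[int, list[float]]]:
    """Replicate admixture runs over a K range plus their partition evidences.

    Returns ``(runs_by_k, evidence_by_k)`` ready for :func:`select_k`.
    """
    lo, hi = k_range
    runs_by_k: dict[int, list[MembershipMatrix]] = {}
    ev: dict[int, list[float]] = {}
    for k in range(lo, hi + 1):
        runs = replicate_runs(
            g, k, n_replicates=n_replicates, seed=seed, n_starts=n_starts, **fit_kw
        )
        runs_by_k[k] = runs
        ev[k] = [partition_evidence(g, r.majority().labels) for r in runs]
    return runs_by_k, ev


def select_k(
    runs: Mapping[int, Sequence[float]],
    alpha: float = 0.005,
    method: str = "wilcoxon",
) -> int:
    """Choose K from replicate log-likelihoods at each K.

    K is the largest value whose replicate likelihoods are significantly
    higher than those at K-1 (two-sided test at ``alpha``) with every
    smaller step also significant.  ``method`` is the paired Wilcoxon
    signed-rank test (replicates paired by index) or ``ranksums`` for the
    independent rank-sum variant.
    """
    ks = sorted(runs)
    if ks != list(range(ks[0], ks[-1] + 1)) or ks[0] != 1:
        raise ClusteringError("runs must cover a contiguous K range from 1")
    chosen = 1
    for k in ks[1:]:
        prev, cur = np.asarray(runs[k - 1], float), np.asarray(runs[k], float)
        if len(prev) < 2 or len(cur) < 2:
            raise ClusteringError("need >= 2 replicates per K")
        m = min(len(prev), len(cur))
        diffs = cur[:m] - prev[:m]
        try:
            if method == "wilcoxon":
                if np.all(diffs == 0):
                    raise ValueError("all differences zero")
                if np.ptp(diffs) == 0:
                    # every replicate improved by the same amount: the exact
                    # signed-rank p for n all-positive (or all-negative) ranks
                    p = 2.0 ** (1 - m)
                else:
                    _, p = stats.wilcoxon(cur[:m], prev[:m], alternative="two-sided")
            elif method == "ranksums":
                _, p = stats.ranksums(cur, prev)
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError:  # all differences zero
            p = 1.0
        if np.isnan(p):
            p = 1.0
        better = np.median(cur[:m] - prev[:m]) > 0
        if p < alpha and better:
            chosen = k
        else:
            break
    if chosen == 1 and all(
        np.allclose(runs[k], runs[ks[0]][: len(runs[k])]) for k in ks
    ):
        logger.warning("select_k: likelihoods tied everywhere; returning K=1")
    return chosen


# ---------------------------------------------------------------------------
# CLUMPP-style run alignment


def _pair_similarity(qa: np.ndarray, qb: np.ndarray) -> float:
    n = qa.shape[0]
    return 1.0 - np.abs(qa - qb).sum() / (2.0 * n)


def _best_permutation(qa: np.ndarray, qb: np.ndarray) -> tuple[int, ...]:
    """Column permutation of qb best matching qa (exhaustive K<=8, greedy above)."""
    K = qa.shape[1]
    if K <= 8:
        best, best_sim = None, -np.inf
        for perm in itertools.permutations(range(K)):
            sim = _pair_similarity(qa, qb[:, perm])
            if sim > best_sim:
                best_sim, best = sim, perm
        return best
    # greedy: repeatedly match the closest column pair, lowest index first
    cost = np.abs(qa[:, :, None] - qb[:, None, :]).sum(axis=0)  # K x K
    perm = [-1] * K
    used = set()
    for a in range(K):
        order = np.argsort(cost[a], kind="stable")
        for b in order:
            if int(b) not in used:
                perm[a] = int(b)
                used.add(int(b))
                break
    return tuple(perm)


@dataclass
class RunEnsemble:
    runs: list[MembershipMatrix]
    aligned: list[np.ndarray] = field(default_factory=list)
    consensus: np.ndarray | None = None
    H_prime: float = float("nan")


def align_runs(runs: Sequence[MembershipMatrix]) -> RunEnsemble:
    """Align replicate membership matrices over cluster-label permutations.

    Every run is aligned to the first; H' is the mean over run pairs of the
    best-permutation similarity 1 - sum|Q - Q'| / (2n); the consensus is the
    mean of the aligned matrices.
    """
    if not runs:
        raise ClusteringError("no runs")
    shapes = {r.Q.shape for r in runs}
    if len(shapes) != 1:
        raise ClusteringError("runs differ in shape")
    ref = runs[0].Q
    aligned = [ref]
    for r in runs[1:]:
        perm = _best_permutation(ref, r.Q)
        aligned.append(r.Q[:, perm])
    sims = []
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            perm = _best_permutation(runs[i].Q, runs[j].Q)
            sims.append(_pair_similarity(runs[i].Q, runs[j].Q[:, perm]))
    h_prime = float(np.mean(sims)) if sims else 1.0
    consensus = np.mean(aligned, axis=0)
    return RunEnsemble(runs=list(runs), aligned=aligned, consensus=consensus, H_prime=h_prime)


def agreement(a: HardAssignment, b: HardAssignment) -> float:
    """Percent of samples in matching clusters after optimal label matching.

    The confusion matrix is solved as an assignment problem (one-to-one
    label matching maximising the matched diagonal).
    """
    if a.sample_ids and b.sample_ids and a.sample_ids != b.sample_ids:
        raise ClusteringError("assignments cover different samples")
    la, lb = np.asarray(a.labels), np.asarray(b.labels)
    if la.shape != lb.shape:
        raise ClusteringError("assignments cover different samples")
    ua, ub = np.unique(la), np.unique(lb)
    conf = np.zeros((len(ua), len(ub)))
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            conf[i, j] = np.sum((la == va) & (lb == vb))
    ri, ci = linear_sum_assignment(-conf)
    return float(100.0 * conf[ri, ci].sum() / la.size)


# ---------------------------------------------------------------------------
# neighbor joining


def _splits(tree, tip_set: frozenset) -> set[frozenset]:
    """Canonical bipartitions (smaller side, ties by sorted names) of a tree."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tip_set) - 1:
            other = tip_set - side
            canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            out.add(canon)
    return out


def neighbor_joining(
    d: "GeneticDistanceMatrix | np.ndarray | None" = None,
    ids: Sequence[str] | None = None,
    g: GenotypeMatrix | None = None,
    n_boot: int = 0,
    seed: int | None = None,
):
    """Saitou-Nei NJ tree with optional locus-bootstrap support.

    Provide either a distance matrix (``d`` + ``ids``) or a genotype matrix
    ``g`` (allele-difference distances are computed per call).  Bootstrap
    support requires ``g``: loci are resampled with replacement, the
    distances and tree recomputed, and each internal edge labelled with the
    percentage of bootstrap trees containing its bipartition.

    Returns ``(tree, support)`` where ``tree`` is a scikit-bio TreeNode and
    ``support`` maps canonical bipartitions to percentages (empty without
    bootstrap).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    from .differentiation import GeneticDistanceMatrix, _pairwise_diffs

    if d is None:
        if g is None:
            raise ClusteringError("need a distance matrix or a genotype matrix")
        diff, _ = _pairwise_diffs(g.calls)
        values, ids = diff, g.sample_ids
    elif isinstance(d, GeneticDistanceMatrix):
        values, ids = d.values, d.ids
    else:
        values = np.asarray(d, dtype=float)
        if ids is None:
            raise ClusteringError("ids required with a bare matrix")
    if values.shape[0] < 3:
        raise ClusteringError("NJ needs >= 3 taxa")
    if not np.all(np.isfinite(values)):
        raise ClusteringError("distance matrix contains missing entries")

    tree = skbio_nj(DistanceMatrix(values, ids=list(ids)))
    support: dict[frozenset, float] = {}
    if n_boot > 0:
        if g is None:
            raise ClusteringError("bootstrap requires the genotype matrix")
        tip_set = frozenset(ids)
        main = _splits(tree, tip_set)
        counts = {s: 0 for s in main}
        rng = np.random.default_rng(seed)
        for _ in range(n_boot):
            cols = rng.integers(0, g.n_loci, size=g.n_loci)
            diff, _ = _pairwise_diffs(g.calls[:, cols])
            bt = skbio_nj(DistanceMatrix(diff, ids=list(ids)))
            bs = _splits(bt, tip_set)
            for s in counts:
                if s in bs:
                    counts[s] += 1
        support = {s: 100.0 * c / n_boot for s, c in counts.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canon = min(side, tip_set - side, key=lambda s: (len(s), tuple(sorted(s))))
            if canon in support:
                node.name = f"{support[canon]:.0f}"
    return tree, support
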