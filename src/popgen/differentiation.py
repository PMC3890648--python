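"""Genetic distances, hierarchical AMOVA and pairwise F_ST with permutation tests.

AMOVA follows the classical squared-distance decomposition for haploid
multilocus genotypes: with the allele-difference count as the pairwise
distance, sums of squared distances within/among groups yield variance
components and F-statistics (F_ST for the one-level design; F_CT, F_SC and
F_ST for the two-level group/population/individual design).  Significance is
assessed by permuting the appropriate units, mirroring the standard
permutation schemes: individuals among populations for F_ST, whole
populations among groups for F_CT, and individuals among populations within
their group for F_SC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix


class DifferentiationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


@dataclass
class GeneticDistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    metric: str  # allele_difference_count | allele_difference_proportion
    co_scored: np.ndarray | None = None  # pairwise-deletion denominator

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise DifferentiationError("distance matrix shape mismatch")
        self.values = v


def _pairwise_diffs(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of differing loci and of co-scored loci for every sample pair."""
    obs = (calls != MISSING).astype(np.int32)
    x = np.where(calls == MISSING, 0, calls).astype(np.int32)
    # differing co-scored loci: both observed and calls differ
    co = obs @ obs.T
    same1 = x @ x.T  # both == 1 (masked zeros contribute nothing)
    x0 = ((calls == 0).astype(np.int32))
    same0 = x0 @ x0.T
    diff = co - same1 - same0
    return diff.astype(float), co.astype(float)


def genetic_distances(
    g: GenotypeMatrix,
    level: str = "sample",
    metric: str = "allele_difference_count",
) -> GeneticDistanceMatrix:
    """Pairwise allele differences at sample, haplotype or population level.

    Sample/haplotype level: count (or proportion) of differing loci under
    pairwise deletion.  Population level: mean over cross-population sample
    pairs of the sample-level distance.
    """
    if level == "haplotype":
        from .io import collapse_haplotypes

        g = collapse_haplotypes(g).representatives()
        level = "sample"
    diff, co = _pairwise_diffs(g.calls)
    if np.any((co == 0) & ~np.eye(co.shape[0], dtype=bool)):
        import logging

        logging.getLogger(__name__).warning("pairs with zero co-scored loci present")
    if level == "sample":
        if metric == "allele_difference_proportion":
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(co > 0, diff / np.maximum(co, 1), np.nan)
            np.fill_diagonal(vals, 0.0)
        else:
            vals = diff
        return GeneticDistanceMatrix(ids=g.sample_ids, values=vals, metric=metric, co_scored=co)
    if level == "population":
        pops = g.population_index()
        names = list(pops)
        if len(names) < 2:
            raise DifferentiationError("need >= 2 populations")
        if metric == "allele_difference_proportion":
            with np.errstate(invalid="ignore", divide="ignore"):
                base = np.where(co > 0, diff / np.maximum(co, 1), np.nan)
        else:
            base = diff
        out = np.zeros((len(names), len(names)))
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                block = base[np.ix_(pops[names[a]], pops[names[b]])]
                out[a, b] = out[b, a] = float(np.nanmean(block))
        return GeneticDistanceMatrix(ids=names, values=out, metric=metric)
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Variance components, percentages and fixation indices of one AMOVA."""

    levels: list[str]
    components: dict[str, float]  # raw (possibly negative) sigma^2 per level
    components_truncated: dict[str, float]
    percent: dict[str, float]  # from truncated components
    phi: dict[str, float]  # F_ST and, for two-level designs, F_CT / F_SC
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    truncated: bool = False

    @property
    def f_st(self) -> float:
        return self.phi["F_ST"]


def _ss_within_groups(d2: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Sum over groups of (sum of squared distances within group) / group size."""
    total = 0.0
    for rows in groups:
        if len(rows) == 0:
            continue
        sub = d2[np.ix_(rows, rows)]
        total += sub.sum() / (2.0 * len(rows))
    return total


def _amova_components(
    d2: np.ndarray,
    pop_of: np.ndarray,
    group_of: np.ndarray | None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Variance components and fixation indices from squared distances.

    ``pop_of``/``group_of`` are integer labels per individual.  Returns raw
    components; truncation is applied by the caller.
    """
    n = d2.shape[0]
    all_rows = [np.arange(n)]
    ss_total = _ss_within_groups(d2, all_rows)

    pops = [np.where(pop_of == p)[0] for p in np.unique(pop_of)]
    n_p = len(pops)
    ss_wp = _ss_within_groups(d2, pops)  # within populations

    sizes = np.array([len(r) for r in pops], dtype=float)
    N = sizes.sum()

    if group_of is None:
        ss_ap = ss_total - ss_wp
        df_ap, df_wp = n_p - 1, n - n_p
        if df_wp <= 0 or df_ap <= 0:
            raise DifferentiationError("degenerate AMOVA design")
        ms_ap, ms_wp = ss_ap / df_ap, ss_wp / df_wp
        n0 = (N - (sizes**2).sum() / N) / (n_p - 1)
        sigma_w = ms_wp
        sigma_a = (ms_ap - ms_wp) / n0
        comps = {"among_populations": sigma_a, "within_populations": sigma_w}
        tot = max(sigma_a, 0.0) + sigma_w
        phi = {"F_ST": (max(sigma_a, 0.0) / tot) if tot > 0 else 0.0}
        return comps, phi

    groups = [np.where(group_of == k)[0] for k in np.unique(group_of)]
    n_g = len(groups)
    if n_g < 2:
        raise DifferentiationError("two-level AMOVA needs >= 2 groups")
    ss_wg = _ss_within_groups(d2, groups)  # within groups (pop + indiv)
    ss_ag = ss_total - ss_wg  # among groups
    ss_ap_wg = ss_wg - ss_wp  # among populations within groups

    df_ag = n_g - 1
    df_ap = n_p - n_g
    df_wp = n - n_p
    if min(df_ag, df_ap, df_wp) <= 0:
        raise DifferentiationError("degenerate two-level AMOVA design")

    # expected-mean-square coefficients for unbalanced designs (Excoffier-style)
    group_sizes = np.array([len(r) for r in groups], dtype=float)
    pop_sizes_by_group: list[np.ndarray] = []
    for k, rows in enumerate(groups):
        labels = np.unique(pop_of[rows])
        pop_sizes_by_group.append(
            np.array([np.sum(pop_of[rows] == p) for p in labels], dtype=float)
        )
    sum_n2_over_g = sum((s**2).sum() / s.sum() for s in pop_sizes_by_group)
    n_prime = (N - sum_n2_over_g) / df_ap
    sum_n2_all = sum((s**2).sum() for s in pop_sizes_by_group)
    n_dprime = (sum_n2_over_g - sum_n2_all / N) / df_ag
    n_tprime = (N - (group_sizes**2).sum() / N) / df_ag

    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap_wg / df_ap
    ms_wp = ss_wp / df_wp

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_prime
    sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    comps = {
        "among_groups": sigma_a,
        "among_populations_within_groups": sigma_b,
        "within_populations": sigma_c,
    }
    a, b, c = max(sigma_a, 0.0), max(sigma_b, 0.0), sigma_c
    tot = a + b + c
    phi = {
        "F_CT": a / tot if tot > 0 else 0.0,
        "F_SC": b / (b + c) if (b + c) > 0 else 0.0,
        "F_ST": (a + b) / tot if tot > 0 else 0.0,
    }
    return comps, phi


def amova(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
    supergrouping: Mapping[str, str] | None = None,
    n_perm: int = 20000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on squared allele-difference distances.

    ``grouping`` maps sample id -> population (defaults to the metadata
    populations); ``supergrouping`` maps population -> group and adds the
    among-group level.  P-values use the (b+1)/(n_perm+1) convention.
    """
    if grouping is None:
        grouping = {s.accession_id: s.population_id for s in g.samples}
    pop_labels = np.array([grouping[s] for s in g.sample_ids])
    pop_names, pop_of = np.unique(pop_labels, return_inverse=True)
    if len(pop_names) < 2:
        raise DifferentiationError("AMOVA needs >= 2 populations")

    d2, _ = _pairwise_diffs(g.calls)  # count of differing loci == squared Euclidean

    group_of = None
    if supergrouping is not None:
        group_labels = np.array([supergrouping[p] for p in pop_labels])
        _, group_of = np.unique(group_labels, return_inverse=True)

    comps, phi = _amova_components(d2, pop_of, group_of)
    truncated = {k: max(v, 0.0) for k, v in comps.items()}
    tot = sum(truncated.values())
    percent = {k: (100.0 * v / tot if tot > 0 else 0.0) for k, v in truncated.items()}

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = {k: 0 for k in phi}
        n = g.n_samples
        for _ in range(n_perm):
            if group_of is None:
                perm = rng.permutation(n)
                _, phi_p = _amova_components(d2, pop_of[perm], None)
                if phi_p["F_ST"] >= phi["F_ST"] - 1e-12:
                    hits["F_ST"] += 1
            else:
                # F_ST: permute individuals over everything
                perm = rng.permutation(n)
                _, p_st = _amova_components(d2, pop_of[perm], group_of[perm])
                if p_st["F_ST"] >= phi["F_ST"] - 1e-12:
                    hits["F_ST"] += 1
                # F_CT: permute whole populations among groups
                pop_group = np.empty(len(pop_names), dtype=int)
                for k in range(len(pop_names)):
                    pop_group[k] = group_of[np.where(pop_of == k)[0][0]]
                shuf = rng.permutation(pop_group)
                _, p_ct = _amova_components(d2, pop_of, shuf[pop_of])
                if p_ct["F_CT"] >= phi["F_CT"] - 1e-12:
                    hits["F_CT"] += 1
                # F_SC: permute individuals among populations within groups
                pop_of_sc = pop_of.copy()
                for k in np.unique(group_of):
                    rows = np.where(group_of == k)[0]
                    pop_of_sc[rows] = pop_of[rows[rng.permutation(len(rows))]]
                _, p_sc = _amova_components(d2, pop_of_sc, group_of)
                if p_sc["F_SC"] >= phi["F_SC"] - 1e-12:
                    hits["F_SC"] += 1
        p_values = {k: (hits[k] + 1) / (n_perm + 1) for k in hits}

    levels = (
        ["among_populations", "within_populations"]
        if group_of is None
        else ["among_groups", "among_populations_within_groups", "within_populations"]
    )
    return AmovaResult(
        levels=levels,
        components=comps,
        components_truncated=truncated,
        percent=percent,
        phi=phi,
        p_values=p_values,
        n_permutations=n_perm,
        truncated=any(v < 0 for v in comps.values()),
    )


def pairwise_fst(
    g: GenotypeMatrix,
    units: Mapping[str, Sequence[str]] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[dict, dict]:
    """F_ST (two-unit AMOVA) and permutation p for every pair of units.

    ``units`` maps unit name -> sample ids (default: metadata populations).
    Returns (fst, p) as nested dicts keyed by frozenset pairs via tuple.
    """
    if units is None:
        idx = g.population_index()
        units = {p: [g.sample_ids[i] for i in rows] for p, rows in idx.items()}
    names = list(units)
    fst: dict[tuple[str, str], float] = {}
    pvals: dict[tuple[str, str], float] = {}
    rng = np.random.default_rng(seed)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ids = list(units[names[a]]) + list(units[names[b]])
            sub = g.subset(sample_ids=ids)
            grouping = {s: names[a] for s in units[names[a]]}
            grouping.update({s: names[b] for s in units[names[b]]})
            res = amova(
                sub,
                grouping=grouping,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)) if n_perm else None,
            )
            # report the raw (possibly negative) component ratio, flagged via sign
            sa = res.components["among_populations"]
            sw = res.components["within_populations"]
            fst[(names[a], names[b])] = sa / (sa + sw) if (sa + sw) != 0 else 0.0
            if n_perm:
                pvals[(names[a], names[b])] = res.p_values["F_ST"]
    return fst, pvals


@dataclass
class GroupDistanceResult:
    group_a: str
    group_b: str
    raw_mean: float
    corrected: float
    f_st: float
    p_value: float | None = None


def group_distance(
    g: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    names: tuple[str, str] = ("A", "B"),
    n_perm: int = 0,
    seed: int | None = None,
) -> GroupDistanceResult:
    """Raw and net (corrected) mean allele differences plus F_ST between groups.

    corrected = raw - (mean within A + mean within B) / 2
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise DifferentiationError("both groups need >= 2 samples")
    sub = g.subset(sample_ids=a + b)
    d, _ = _pairwise_diffs(sub.calls)
    na = len(a)
    cross = d[:na, na:].mean()
    # within-group means over all ordered pairs (pi-style, self-pairs
    # included): the net distance is then exactly zero for identical groups
    # and invariant to duplicating every member of a group
    within_a = d[:na, :na].mean()
    within_b = d[na:, na:].mean()
    corrected = cross - (within_a + within_b) / 2.0

    grouping = {s: names[0] for s in a}
    grouping.update({s: names[1] for s in b})
    res = amova(sub, grouping=grouping, n_perm=n_perm, seed=seed)
    return GroupDistanceResult(
        group_a=names[0],
        group_b=names[1],
        raw_mean=float(cross),
        corrected=float(corrected),
        f_st=res.f_st,
        p_value=res.p_values.get("F_ST"),
    )
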