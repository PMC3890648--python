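"""Flowering-trait processing and quantitative-trait differentiation (Q_ST).

Non-flowering plants at the end of the experiment are right-censored: they
receive the experiment-end flowering time and a leaf number predicted from
the regression of leaf number on flowering time among flowered plants.
Obligate vernalization requirement is scored per accession as the failure of
every unvernalized plant to flower.  Quantitative differentiation between
accession groups is Q_ST = V_B / (V_B + V_W) from a one-way random-effects
decomposition — the haploid-style formula, with variance components from
either expected mean squares (unbalanced-design moments) or REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraitTable

logger = logging.getLogger(__name__)


class QuantGenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# censoring imputation


@dataclass
class ImputationRecord:
    slope: float
    intercept: float
    ft_limit: float
    ln_at_limit: float
    n_imputed: int


def impute_censored(t: TraitTable, ft_limit: float = 200.0) -> tuple[TraitTable, ImputationRecord]:
    """Assign censored plants FT = ``ft_limit`` and the regression-predicted LN.

    The least-squares regression of leaf number on flowering time is fitted
    on flowered plants; non-flowering plants receive flowering time
    ``ft_limit`` (the experiment end) and the leaf number predicted there.
    Values of flowered plants are never altered.
    """
    d = t.data.copy()
    for col in ("flowering_time", "leaf_number"):
        d[col] = d[col].astype(float)
    flowered = d["flowered"].astype(bool)
    fit_rows = flowered & d["flowering_time"].notna() & d["leaf_number"].notna()
    if fit_rows.sum() < 2:
        raise QuantGenError("need >= 2 flowered plants to fit the LN-on-FT regression")
    ft = d.loc[fit_rows, "flowering_time"].astype(float)
    ln = d.loc[fit_rows, "leaf_number"].astype(float)
    slope, intercept = np.polyfit(ft, ln, 1)
    ln_at_limit = slope * ft_limit + intercept

    censored = ~flowered
    d.loc[censored, "flowering_time"] = ft_limit
    d.loc[censored, "leaf_number"] = ln_at_limit
    rec = ImputationRecord(
        slope=float(slope),
        intercept=float(intercept),
        ft_limit=float(ft_limit),
        ln_at_limit=float(ln_at_limit),
        n_imputed=int(censored.sum()),
    )
    return TraitTable(d), rec


# ---------------------------------------------------------------------------
# vernalization requirement


@dataclass
class FloweringSummary:
    accession: str
    mean_ft: float
    mean_ln: float
    obligate_vernalization: bool
    pct_nonflowering_unvernalized: float


def vernalization_requirement(t: TraitTable) -> list[FloweringSummary]:
    """Per-accession obligate-vernalization scoring from unvernalized plants.

    An accession is obligate when none of its unvernalized plants flowered
    (and, where vernalized records exist, it flowered under vernalization).
    Accessions with no unvernalized plants are skipped with a log entry.
    """
    d = t.data
    out = []
    for acc, sub in d.groupby("accession_id", sort=True):
        unvern = sub[~sub["vernalized"].astype(bool)]
        if len(unvern) == 0:
            logger.warning("accession %s: no unvernalized plants, skipped", acc)
            continue
        pct_nf = 100.0 * (~unvern["flowered"].astype(bool)).mean()
        obligate = pct_nf == 100.0
        vern = sub[sub["vernalized"].astype(bool)]
        if obligate and len(vern) > 0:
            obligate = bool(vern["flowered"].astype(bool).any())
        out.append(
            FloweringSummary(
                accession=str(acc),
                mean_ft=float(unvern["flowering_time"].astype(float).mean()),
                mean_ln=float(unvern["leaf_number"].astype(float).mean()),
                obligate_vernalization=bool(obligate),
                pct_nonflowering_unvernalized=float(pct_nf),
            )
        )
    return out


def compare_obligate_proportions(
    a: Sequence[FloweringSummary], b: Sequence[FloweringSummary]
) -> tuple[float, float, float]:
    """Fisher exact test for regional obligate-vernalization proportions.

    Returns (percent_a, percent_b, p_value).
    """
    ka = sum(s.obligate_vernalization for s in a)
    kb = sum(s.obligate_vernalization for s in b)
    table = [[ka, len(a) - ka], [kb, len(b) - kb]]
    _, p = stats.fisher_exact(table)
    return 100.0 * ka / len(a), 100.0 * kb / len(b), float(p)


# ---------------------------------------------------------------------------
# Q_ST


@dataclass
class QstResult:
    trait: str
    V_B: float
    V_W: float
    Q_ST: float
    method: str
    truncated: bool = False
    p_value: float | None = None
    V_B_raw: float | None = None


def _components_moments(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way random-effects components via expected mean squares.

    Unbalanced designs use the n0 coefficient
    n0 = (N - sum n_i^2 / N) / (k - 1).
    """
    groups = np.unique(labels)
    k = len(groups)
    sizes = np.array([(labels == gname).sum() for gname in groups], dtype=float)
    N = sizes.sum()
    grand = values.mean()
    ss_b = sum(
        sizes[i] * (values[labels == gname].mean() - grand) ** 2
        for i, gname in enumerate(groups)
    )
    ss_w = sum(
        ((values[labels == gname] - values[labels == gname].mean()) ** 2).sum()
        for gname in groups
    )
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (N - k)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    return float((ms_b - ms_w) / n0), float(ms_w)


def _components_reml(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """REML variance components from the one-way random-intercept model."""
    import statsmodels.api as sm

    df = pd.DataFrame({"y": values, "g": labels})
    model = sm.MixedLM.from_formula("y ~ 1", groups="g", data=df)
    with np.errstate(all="ignore"):
        fit = model.fit(reml=True, method="lbfgs")
    v_b = float(fit.cov_re.iloc[0, 0])
    v_w = float(fit.scale)
    return v_b, v_w


def qst(
    values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str],
    method: str = "reml",
    trait: str = "",
    n_perm: int = 0,
    seed: int | None = None,
) -> QstResult:
    """Q_ST = V_B / (V_B + V_W) for per-accession trait values.

    ``values`` maps accession -> trait value, ``grouping`` accession ->
    group.  Groups with a single accession are dropped with a warning.  A
    negative between-group component is truncated to zero (flagged; the raw
    value is retained).  ``n_perm`` adds a permutation p-value by shuffling
    group labels.
    """
    s = pd.Series(values, dtype=float)
    labels = np.array([grouping[a] for a in s.index])
    vals = s.to_numpy()

    keep_groups = [gname for gname in np.unique(labels) if (labels == gname).sum() >= 2]
    dropped = set(np.unique(labels)) - set(keep_groups)
    if dropped:
        logger.warning("qst: dropping single-accession group(s) %s", sorted(dropped))
    mask = np.isin(labels, keep_groups)
    vals, labels = vals[mask], labels[mask]
    if len(keep_groups) < 2:
        raise QuantGenError("Q_ST needs >= 2 groups with >= 2 accessions")

    if method == "anova_moments":
        v_b_raw, v_w = _components_moments(vals, labels)
    elif method == "reml":
        v_b_raw, v_w = _components_reml(vals, labels)
    else:
        raise ValueError(f"unknown method {method!r}")
    truncated = v_b_raw < 0
    v_b = max(v_b_raw, 0.0)
    q = v_b / (v_b + v_w) if (v_b + v_w) > 0 else 0.0

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = labels[rng.permutation(len(labels))]
            vb_p, vw_p = _components_moments(vals, perm)
            vb_p = max(vb_p, 0.0)
            q_p = vb_p / (vb_p + vw_p) if (vb_p + vw_p) > 0 else 0.0
            hits += q_p >= q - 1e-12
        p_value = (hits + 1) / (n_perm + 1)

    return QstResult(
        trait=trait,
        V_B=v_b,
        V_W=v_w,
        Q_ST=float(q),
        method=method,
        truncated=truncated,
        p_value=p_value,
        V_B_raw=v_b_raw,
    )


def accession_means(t: TraitTable, trait: str, vernalized: bool | None = False) -> pd.Series:
    """Per-accession mean of one trait column (default: unvernalized plants)."""
    d = t.data
    if vernalized is not None:
        d = d[d["vernalized"].astype(bool) == vernalized]
    return d.groupby("accession_id")[trait].mean().astype(float)


# ---------------------------------------------------------------------------
# group comparisons


def group_tukey(
    values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str],
    alpha: float = 0.05,
) -> dict[str, str]:
    """One-way ANOVA + Tukey HSD, summarised as compact significance letters.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    s = pd.Series(values, dtype=float)
    labels = np.array([grouping[a] for a in s.index])
    groups = sorted({str(g) for g in labels})
    if len(groups) < 2:
        raise QuantGenError("Tukey needs >= 2 groups")
    sizes = {gname: (labels == gname).sum() for gname in groups}
    if min(sizes.values()) < 2:
        raise QuantGenError("each group needs >= 2 accessions")

    res = pairwise_tukeyhsd(s.to_numpy(), labels, alpha=alpha)
    tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    distinct = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in tbl.iterrows()
        if bool(r["reject"])
    }

    # insertion algorithm for the compact letter display
    letter_sets: list[set[str]] = [set(groups)]
    for pair in distinct:
        a, b = tuple(pair)
        for sset in list(letter_sets):
            if a in sset and b in sset:
                letter_sets.remove(sset)
                sa, sb = sset - {b}, sset - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets.sort(key=lambda sset: sorted(sset))
    letters = {gname: "" for gname in groups}
    for i, sset in enumerate(letter_sets):
        for gname in sorted(sset):
            letters[gname] += chr(ord("a") + i)
    return letters


@dataclass
class RangeComparison:
    min_a: float
    max_a: float
    min_b: float
    max_b: float
    p_value: float

    @property
    def range_a(self) -> float:
        return self.max_a - self.min_a

    @property
    def range_b(self) -> float:
        return self.max_b - self.min_b


def trait_range_compare(
    a: Sequence[float], b: Sequence[float], n_perm: int = 10000, seed: int | None = None
) -> RangeComparison:
    """Observed ranges of two trait sets and a permutation test on their difference."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    obs = abs(np.ptp(a) - np.ptp(b))
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        pa, pb = pool[perm[: len(a)]], pool[perm[len(a):]]
        hits += abs(np.ptp(pa) - np.ptp(pb)) >= obs - 1e-12
    return RangeComparison(
        min_a=float(a.min()),
        max_a=float(a.max()),
        min_b=float(b.min()),
        max_b=float(b.max()),
        p_value=(hits + 1) / (n_perm + 1),
    )
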