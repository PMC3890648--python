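"""Diversity statistics for haploid SNP panels and sequence alignments.

Per analysis unit (population, genetic group or world region) the module
computes the number of multilocus haplotypes N_H, the percentage of
polymorphic loci PL, gene diversity H_S (expected heterozygosity), and
rarefied allelic richness R_S and private allelic richness R_P at a common
subsample size g (hypergeometric rarefaction).  Nucleotide diversity pi is
computed for aligned gene fragments with optional silent-site restriction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, collapse_haplotypes


class DiversityError(ValueError):
    pass


@dataclass
class DiversityRecord:
    """One row of a diversity table (Table-1/2 style)."""

    unit: str
    N: int
    N_H: int | None = None
    PL: float | None = None
    H_S: float | None = None
    H_S_se: float | None = None
    R_S: float | None = None
    R_S_se: float | None = None
    R_P: float | None = None
    R_P_se: float | None = None
    g: int | None = None


# ---------------------------------------------------------------------------
# allele counts


def _allele_counts(g: GenotypeMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus counts of allele 1 and of observed calls within `rows`."""
    sub = g.calls[rows]
    obs = sub != MISSING
    n1 = ((sub == 1) & obs).sum(axis=0)
    n = obs.sum(axis=0)
    return n1, n


def _resolve_rows(g: GenotypeMatrix, unit: Sequence[str] | np.ndarray | None) -> np.ndarray:
    if unit is None:
        return np.arange(g.n_samples)
    unit = list(unit)
    idx = {s: i for i, s in enumerate(g.sample_ids)}
    if all(u in idx for u in unit):
        return np.array([idx[u] for u in unit])
    # otherwise interpret as population ids
    pops = g.population_index()
    rows: list[int] = []
    for u in unit:
        if u not in pops:
            raise DiversityError(f"unknown sample or population id {u!r}")
        rows.extend(pops[u].tolist())
    return np.array(sorted(rows))


# ---------------------------------------------------------------------------
# gene diversity and polymorphic fraction


def gene_diversity(
    g: GenotypeMatrix,
    unit: Sequence[str] | None = None,
    estimator: str = "plain",
) -> tuple[float, float, np.ndarray]:
    """Mean gene diversity over loci, its standard error, and per-locus values.

    plain:    h = 1 - sum_a p_a^2
    unbiased: h * n/(n-1), n = observed calls at the locus.

    Loci with fewer than 2 observed calls (or <1 for plain at n=1) are skipped.
    """
    rows = _resolve_rows(g, unit)
    if rows.size < 2:
        raise DiversityError("gene diversity needs a unit of size >= 2")
    n1, n = _allele_counts(g, rows)
    min_n = 2
    ok = n >= min_n
    if not ok.any():
        raise DiversityError("no locus with >= 2 observed calls in unit")
    p = n1[ok] / n[ok]
    h = 1.0 - (p**2 + (1 - p) ** 2)
    if estimator == "unbiased":
        h = h * n[ok] / (n[ok] - 1)
    elif estimator != "plain":
        raise ValueError(f"unknown estimator {estimator!r}")
    se = h.std(ddof=1) / np.sqrt(h.size) if h.size > 1 else 0.0
    return float(h.mean()), float(se), h


def polymorphic_fraction(g: GenotypeMatrix, unit: Sequence[str] | None = None) -> float:
    """Percent of scorable loci with both alleles observed in the unit."""
    rows = _resolve_rows(g, unit)
    if rows.size < 2:
        raise DiversityError("polymorphic fraction needs a unit of size >= 2")
    n1, n = _allele_counts(g, rows)
    scorable = n >= 1
    if not scorable.any():
        raise DiversityError("no scorable loci in unit")
    poly = (n1 >= 1) & (n1 < n) & scorable
    return float(100.0 * poly.sum() / scorable.sum())


# ---------------------------------------------------------------------------
# rarefaction


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _q_present(n_a: np.ndarray, n: np.ndarray, g_size: int) -> np.ndarray:
    """P(allele with n_a copies out of n appears in a subsample of g_size).

    Q = 1 - C(n - n_a, g) / C(n, g), the hypergeometric inclusion probability.
    """
    n_a = np.asarray(n_a, dtype=float)
    n = np.asarray(n, dtype=float)
    out = np.ones_like(n_a, dtype=float)
    feasible = (n - n_a) >= g_size
    with np.errstate(invalid="ignore"):
        ratio = np.exp(_log_comb(n - n_a, g_size) - _log_comb(n, g_size))
    out[feasible] = 1.0 - ratio[feasible]
    return out


def default_rarefaction_size(g: GenotypeMatrix, units: Mapping[str, Sequence[str]]) -> int:
    """Smallest per-locus observed-call count across units (>= 1 loci kept)."""
    best = None
    for members in units.values():
        rows = _resolve_rows(g, members)
        _, n = _allele_counts(g, rows)
        m = int(n[n > 0].min()) if (n > 0).any() else 0
        best = m if best is None else min(best, m)
    return max(int(best or 0), 1)


def allelic_richness(
    g: GenotypeMatrix,
    units: Mapping[str, Sequence[str]],
    g_size: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Rarefied allelic richness per unit: mean +- SE over loci.

    Per locus, R = sum over alleles of the probability that the allele is
    seen in a random subsample of ``g_size`` observed calls.  Loci with fewer
    than ``g_size`` observed calls in a unit are skipped for that unit.
    """
    if g_size is None:
        g_size = default_rarefaction_size(g, units)
    if g_size < 1:
        raise DiversityError("g_size must be >= 1")
    out: dict[str, tuple[float, float]] = {}
    for name, members in units.items():
        rows = _resolve_rows(g, members)
        n1, n = _allele_counts(g, rows)
        ok = n >= g_size
        if not ok.any():
            raise DiversityError(f"unit {name!r}: no locus with >= g_size calls")
        r = _q_present(n1[ok], n[ok], g_size) + _q_present(n[ok] - n1[ok], n[ok], g_size)
        se = r.std(ddof=1) / np.sqrt(r.size) if r.size > 1 else 0.0
        out[name] = (float(r.mean()), float(se))
    return out


def private_allelic_richness(
    g: GenotypeMatrix,
    units: Mapping[str, Sequence[str]],
    g_size: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Rarefied private allelic richness per unit (mean +- SE over loci).

    For focal unit j and allele a:  Q_j(a) * prod_{k != j} (1 - Q_k(a)),
    the probability that a rarefied sample of unit j contains the allele
    while equally rarefied samples of every other unit lack it.
    """
    if len(units) < 2:
        raise DiversityError("private allelic richness needs >= 2 units")
    if g_size is None:
        g_size = default_rarefaction_size(g, units)
    if g_size < 1:
        raise DiversityError("g_size must be >= 1")

    names = list(units)
    qs = {}  # unit -> (Q_allele1, Q_allele0, locus_ok)
    for name in names:
        rows = _resolve_rows(g, units[name])
        n1, n = _allele_counts(g, rows)
        ok = n >= g_size
        q1 = _q_present(n1, n, g_size)
        q0 = _q_present(n - n1, n, g_size)
        qs[name] = (q1, q0, ok)

    out: dict[str, tuple[float, float]] = {}
    for j in names:
        q1j, q0j, okj = qs[j]
        ok = okj.copy()
        for k in names:
            ok &= qs[k][2]
        if not ok.any():
            raise DiversityError(f"unit {j!r}: no locus rarefiable in all units")
        absent1 = np.ones(ok.sum())
        absent0 = np.ones(ok.sum())
        for k in names:
            if k == j:
                continue
            absent1 *= 1.0 - qs[k][0][ok]
            absent0 *= 1.0 - qs[k][1][ok]
        rp = q1j[ok] * absent1 + q0j[ok] * absent0
        se = rp.std(ddof=1) / np.sqrt(rp.size) if rp.size > 1 else 0.0
        out[j] = (float(rp.mean()), float(se))
    return out


# ---------------------------------------------------------------------------
# diversity tables


def diversity_table(
    g: GenotypeMatrix,
    units: Mapping[str, Sequence[str]],
    g_size: int | None = None,
    estimator: str = "plain",
    min_unit: int = 2,
) -> list[DiversityRecord]:
    """N, N_H, PL, H_S, R_S, R_P per unit; units below ``min_unit`` get '-' rows."""
    if g_size is None:
        usable = {
            k: v for k, v in units.items() if _resolve_rows(g, v).size >= min_unit
        }
        g_size = default_rarefaction_size(g, usable)
    rs = rp = None
    usable = {k: v for k, v in units.items() if _resolve_rows(g, v).size >= min_unit}
    if len(usable) >= 1:
        rs = allelic_richness(g, usable, g_size)
    if len(usable) >= 2:
        rp = private_allelic_richness(g, usable, g_size)

    records = []
    for name, members in units.items():
        rows = _resolve_rows(g, members)
        sub = g.subset(sample_ids=[g.sample_ids[i] for i in rows])
        n_h = collapse_haplotypes(sub).n_haplotypes
        if rows.size < min_unit:
            records.append(DiversityRecord(unit=name, N=rows.size, N_H=n_h, g=g_size))
            continue
        hs, hs_se, _ = gene_diversity(g, members, estimator=estimator)
        rec = DiversityRecord(
            unit=name,
            N=int(rows.size),
            N_H=n_h,
            PL=polymorphic_fraction(g, members),
            H_S=hs,
            H_S_se=hs_se,
            g=g_size,
        )
        if rs is not None and name in rs:
            rec.R_S, rec.R_S_se = rs[name]
        if rp is not None and name in rp:
            rec.R_P, rec.R_P_se = rp[name]
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# nucleotide diversity


@dataclass
class SeqDiversityResult:
    gene: str
    n_sequences: int
    n_polymorphisms: int
    pi_all: float
    pi_silent: float | None
    site_classification: list[str] | None


_VALID = set("ACGT")


def nucleotide_diversity(
    alignment: Sequence[str],
    site_classes: Sequence[str] | None = None,
    gene: str = "",
) -> SeqDiversityResult:
    """Average pairwise difference per site over an equal-length alignment.

    Gaps and ambiguity codes are excluded pairwise: a site enters a pair's
    comparison only when both sequences carry an unambiguous base there.
    ``site_classes`` labels each column ``silent`` / ``nonsilent`` /
    ``excluded``; pi_silent restricts to silent columns.
    """
    seqs = [str(s).upper() for s in alignment]
    if len(seqs) < 2:
        raise DiversityError("need >= 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise DiversityError("sequences differ in length")
    if site_classes is not None and len(site_classes) != L:
        raise DiversityError("site_classes length mismatch")

    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])

    def _pi(cols: np.ndarray) -> float:
        total_diff = 0.0
        total_sites = 0
        n = len(seqs)
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i, cols] & valid[j, cols]
                m = int(both.sum())
                if m == 0:
                    continue
                d = int((arr[i, cols][both] != arr[j, cols][both]).sum())
                total_diff += d / m
                total_sites += 1
        if total_sites == 0:
            raise DiversityError("zero comparable sites")
        return total_diff / total_sites  # mean over comparable pairs

    all_cols = np.arange(L)
    if site_classes is not None:
        all_cols = np.array([k for k, c in enumerate(site_classes) if c != "excluded"])
    pi_all = _pi(all_cols)
    pi_silent = None
    if site_classes is not None:
        silent = np.array([k for k, c in enumerate(site_classes) if c == "silent"])
        if silent.size:
            pi_silent = _pi(silent)

    # segregating sites among fully valid columns
    n_poly = 0
    for k in all_cols:
        col = arr[valid[:, k], k]
        if col.size >= 2 and len(set(col.tolist())) > 1:
            n_poly += 1

    return SeqDiversityResult(
        gene=gene,
        n_sequences=len(seqs),
        n_polymorphisms=n_poly,
        pi_all=pi_all,
        pi_silent=pi_silent,
        site_classification=list(site_classes) if site_classes is not None else None,
    )


def read_fasta(path) -> list[str]:
    """Aligned sequences from a FASTA file, in file order."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
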