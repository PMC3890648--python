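"""Seeded generators for genotype, geography and trait data.

The generators emulate the statistical structure the analyses assume:

* :func:`simulate_island` — hierarchically structured haploid populations
  under the Balding-Nichols model, whose expected F_ST equals the ``F``
  parameter analytically; optional within-deme haplotype duplication mimics
  the extreme haplotype sharing produced by selfing.
* :func:`simulate_stepping_stone` — demes on a line whose allele frequencies
  follow a spatially autocorrelated logit-space random walk, producing
  isolation by distance against the deme coordinates.
* :func:`simulate_admixture` — calls drawn from a mixture over K ancestral
  frequency profiles with a supplied membership matrix Q.
* :func:`simulate_traits` — accession trait values with prescribed between-
  and within-group variances and optional right-censoring at a day limit.

All randomness flows through ``numpy.random.default_rng(seed)``; the seed is
mandatory in :class:`SimulationConfig`, so equal seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ibd import GeoDistanceMatrix, geo_distances
from .io import MISSING, GenotypeMatrix, SampleMeta, SnpLocus, TraitTable


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the genotype generators; ``seed`` is mandatory."""

    seed: int
    n_pops: int = 20
    samples_per_pop: int | Sequence[int] = 8
    n_loci: int = 200
    F: float = 0.3  # Balding-Nichols target differentiation
    selfing_collapse: float = 0.0  # P(sample copies an existing deme haplotype)
    spatial_model: str = "none"  # none | stepping_stone
    ibd_step_sd: float = 0.6  # logit-space random-walk step sd (stepping stone)
    deme_spacing_km: float = 50.0
    admixture_Q: np.ndarray | None = None
    missing_rate: float = 0.0

    def __post_init__(self):
        if not (0 <= self.F < 1):
            raise SimulationError("F must be in [0, 1)")
        for p in (self.selfing_collapse, self.missing_rate):
            if not (0 <= p <= 1):
                raise SimulationError("probabilities must be in [0, 1]")
        if self.seed is None:
            raise SimulationError("seed is mandatory")


@dataclass
class SimulationTruth:
    """Latent values retained for estimator-recovery checks."""

    ancestral_freqs: np.ndarray | None = None
    deme_freqs: np.ndarray | None = None  # (n_pops or K, n_loci)
    Q: np.ndarray | None = None
    F: float | None = None
    ibd_step_sd: float | None = None
    group_effects: np.ndarray | None = None
    accession_values: np.ndarray | None = None


def _sizes(cfg: SimulationConfig) -> list[int]:
    s = cfg.samples_per_pop
    if np.isscalar(s):
        return [int(s)] * cfg.n_pops
    s = list(s)
    if len(s) != cfg.n_pops:
        raise SimulationError("samples_per_pop length != n_pops")
    return [int(x) for x in s]


def _assemble(
    cfg: SimulationConfig,
    calls: np.ndarray,
    pop_of: np.ndarray,
    coords: dict[str, tuple[float, float]] | None,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, MISSING, calls)
    samples = []
    counters: dict[int, int] = {}
    for i, p in enumerate(pop_of):
        counters[p] = counters.get(p, 0) + 1
        pop = f"pop{p + 1:02d}"
        lat, lon = coords[pop] if coords else (float("nan"), float("nan"))
        samples.append(
            SampleMeta(
                accession_id=f"{pop}_s{counters[p]:02d}",
                population_id=pop,
                latitude=lat,
                longitude=lon,
            )
        )
    loci = [SnpLocus(id=f"L{j + 1:04d}", chromosome="1", position=1000 * (j + 1)) for j in range(calls.shape[1])]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls.astype(np.int8))


def _balding_nichols_freqs(
    rng: np.random.Generator, n_units: int, n_loci: int, F: float
) -> tuple[np.ndarray, np.ndarray]:
    p = rng.uniform(0.05, 0.95, size=n_loci)
    if F == 0:
        deme = np.tile(p, (n_units, 1))
    else:
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        deme = rng.beta(a[None, :], b[None, :], size=(n_units, n_loci))
    return p, deme


def _selfing_collapse(
    calls: np.ndarray, pop_of: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """With probability ``prob`` each sample (after the first of its deme)
    copies the haplotype of an earlier sample from the same deme."""
    if prob <= 0:
        return calls
    out = calls.copy()
    for p in np.unique(pop_of):
        rows = np.where(pop_of == p)[0]
        for k, i in enumerate(rows[1:], start=1):
            if rng.random() < prob:
                out[i] = out[rows[rng.integers(0, k)]]
    return out


def simulate_island(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Balding-Nichols island model: E[F_ST] = cfg.F across demes."""
    rng = np.random.default_rng(cfg.seed)
    sizes = _sizes(cfg)
    p, deme = _balding_nichols_freqs(rng, cfg.n_pops, cfg.n_loci, cfg.F)
    pop_of = np.repeat(np.arange(cfg.n_pops), sizes)
    calls = (rng.random((len(pop_of), cfg.n_loci)) < deme[pop_of]).astype(np.int8)
    calls = _selfing_collapse(calls, pop_of, cfg.selfing_collapse, rng)
    g = _assemble(cfg, calls, pop_of, None, rng)
    return g, SimulationTruth(ancestral_freqs=p, deme_freqs=deme, F=cfg.F)


def simulate_stepping_stone(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, GeoDistanceMatrix, SimulationTruth]:
    """Linear stepping-stone: neighbouring demes have correlated frequencies.

    Deme logit-frequencies follow a random walk with step sd ``ibd_step_sd``;
    a step sd of 0 draws each deme independently (no spatial signal).  Demes
    sit ``deme_spacing_km`` apart along a meridian.
    """
    if cfg.spatial_model != "stepping_stone":
        raise SimulationError("cfg.spatial_model must be 'stepping_stone'")
    rng = np.random.default_rng(cfg.seed)
    sizes = _sizes(cfg)
    p = rng.uniform(0.2, 0.8, size=cfg.n_loci)
    z0 = np.log(p / (1 - p))
    deme_z = np.empty((cfg.n_pops, cfg.n_loci))
    if cfg.ibd_step_sd > 0:
        deme_z[0] = z0 + rng.normal(0, cfg.ibd_step_sd, cfg.n_loci)
        for i in range(1, cfg.n_pops):
            deme_z[i] = deme_z[i - 1] + rng.normal(0, cfg.ibd_step_sd, cfg.n_loci)
    else:
        # independent demes: same marginal spread, no spatial autocorrelation
        deme_z[:] = z0[None, :] + rng.normal(0, 1.0, (cfg.n_pops, cfg.n_loci))
    deme = 1 / (1 + np.exp(-deme_z))

    pop_of = np.repeat(np.arange(cfg.n_pops), sizes)
    calls = (rng.random((len(pop_of), cfg.n_loci)) < deme[pop_of]).astype(np.int8)
    calls = _selfing_collapse(calls, pop_of, cfg.selfing_collapse, rng)

    lat0 = 31.0  # arbitrary mid-latitude origin
    coords = {
        f"pop{i + 1:02d}": (lat0 + i * cfg.deme_spacing_km / 111.19, -7.0)
        for i in range(cfg.n_pops)
    }
    g = _assemble(cfg, calls, pop_of, coords, rng)
    geo = geo_distances(coords)
    return g, geo, SimulationTruth(
        ancestral_freqs=p, deme_freqs=deme, ibd_step_sd=cfg.ibd_step_sd
    )


def simulate_admixture(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Calls from the haploid admixture model with known Q and P.

    ``cfg.admixture_Q`` is n x K with rows on the simplex; ancestral cluster
    frequencies P come from the Balding-Nichols draw at ``cfg.F``.  Each
    sample is assigned round-robin to a pseudo-population by its majority
    ancestry so the population-aware operations remain usable.
    """
    Q = cfg.admixture_Q
    if Q is None:
        raise SimulationError("admixture_Q required")
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or np.any(Q < 0) or not np.allclose(Q.sum(axis=1), 1, atol=1e-8):
        raise SimulationError("Q rows must be nonnegative and sum to 1")
    rng = np.random.default_rng(cfg.seed)
    K = Q.shape[1]
    p, P = _balding_nichols_freqs(rng, K, cfg.n_loci, cfg.F)
    mix = Q @ P  # per-sample allele-1 probability
    calls = (rng.random(mix.shape) < mix).astype(np.int8)
    pop_of = np.argmax(Q, axis=1)
    g = _assemble(cfg, calls, pop_of, None, rng)
    return g, SimulationTruth(ancestral_freqs=p, deme_freqs=P, Q=Q, F=cfg.F)


def simulate_traits(
    grouping: Sequence[str],
    V_B: float,
    V_W: float,
    censor_at: float | None = None,
    seed: int = 0,
    plants_per_accession: int = 5,
    plant_sd: float = 2.0,
    baseline: float = 100.0,
    ln_slope: float = 0.75,
    ln_noise_sd: float = 2.0,
) -> tuple[TraitTable, SimulationTruth]:
    """Per-plant flowering times with prescribed variance components.

    ``grouping`` gives each accession's group label.  Accession flowering
    time = baseline + group effect ~ N(0, V_B) + accession residual
    ~ N(0, V_W); plants add N(0, plant_sd^2) noise.  Leaf number follows
    LN = ln_slope * FT + noise.  With ``censor_at`` set, plants whose FT
    exceeds it are marked non-flowering with traits unrecorded.
    """
    if V_B < 0 or V_W < 0:
        raise SimulationError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(grouping))
    effects = {gname: rng.normal(0, np.sqrt(V_B)) for gname in groups}
    rows = []
    acc_values = []
    for i, gname in enumerate(grouping):
        acc = f"acc{i + 1:03d}"
        value = baseline + effects[gname] + rng.normal(0, np.sqrt(V_W))
        acc_values.append(value)
        for plant in range(plants_per_accession):
            ft = value + rng.normal(0, plant_sd)
            ft = max(ft, 1.0)
            ln = max(ln_slope * ft + rng.normal(0, ln_noise_sd), 1.0)
            flowered = censor_at is None or ft <= censor_at
            rows.append(
                {
                    "accession_id": acc,
                    "plant_id": f"{acc}_p{plant + 1}",
                    "flowering_time": ft if flowered else np.nan,
                    "leaf_number": round(ln) if flowered else np.nan,
                    "flowered": flowered,
                    "vernalized": False,
                    "group": gname,
                }
            )
    table = TraitTable(pd.DataFrame(rows))
    truth = SimulationTruth(
        group_effects=np.array([effects[gr] for gr in groups]),
        accession_values=np.array(acc_values),
    )
    return table, truth


def simulate_hierarchical(
    seed: int,
    pop_sizes_by_group: Mapping[str, Sequence[int]],
    n_loci: int,
    F_ct: float,
    F_sc: float,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, dict[str, str], SimulationTruth]:
    """Two-level Balding-Nichols model: populations nested in genetic groups.

    Group allele frequencies are drawn from the ancestral frequency at
    differentiation ``F_ct`` and population frequencies from their group's
    at ``F_sc``, so the expected variance shares mirror a two-level AMOVA
    with those fixation indices.  Returns the genotype matrix, the
    population -> group map and the latent truth.
    """
    if not (0 < F_ct < 1 and 0 < F_sc < 1):
        raise SimulationError("F_ct and F_sc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_loci)

    def _bn(base: np.ndarray, F: float) -> np.ndarray:
        a = np.clip(base * (1 - F) / F, 1e-3, None)
        b = np.clip((1 - base) * (1 - F) / F, 1e-3, None)
        return rng.beta(a, b)

    samples: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    group_of: dict[str, str] = {}
    deme_freqs = []
    pi = 0
    for gname, sizes in pop_sizes_by_group.items():
        gf = _bn(p, F_ct)
        for size in sizes:
            pf = _bn(gf, F_sc)
            deme_freqs.append(pf)
            pi += 1
            pop = f"pop{pi:02d}"
            group_of[pop] = str(gname)
            for j in range(int(size)):
                rows.append((rng.random(n_loci) < pf).astype(np.int8))
                samples.append(
                    SampleMeta(
                        accession_id=f"{pop}_h{j + 1:02d}",
                        population_id=pop,
                        subregion=str(gname),
                    )
                )
    calls = np.array(rows, dtype=np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, MISSING, calls)
    loci = [
        SnpLocus(id=f"L{j + 1:04d}", chromosome="1", position=1000 * (j + 1))
        for j in range(n_loci)
    ]
    g = GenotypeMatrix(samples=samples, loci=loci, calls=calls)
    truth = SimulationTruth(ancestral_freqs=p, deme_freqs=np.array(deme_freqs), F=F_ct)
    return g, group_of, truth


#: per-population haplotype counts of the regional study, by genetic group
#: (4 groups holding 7/14/28/16 of the 65 distinct haplotypes)
MOROCCAN_POP_SIZES = {
    "G1": [2, 2, 1, 2],
    "G2": [4, 2, 3, 3, 2],
    "G3": [5, 6, 7, 2, 6, 1, 1],
    "G4": [10, 2, 2, 2],
}


def moroccan_design(seed: int) -> tuple[GenotypeMatrix, dict[str, str], SimulationTruth]:
    """The regional study design at desk scale: 65 haplotype samples in 20
    populations nested in 4 genetic groups, typed at 130 biallelic loci.

    The fixation indices come from the published two-level variance shares
    (43.1% among groups, 40.2% among populations within groups, 18.4%
    within populations): F_ct = 0.431 and F_sc = 0.402 / (0.402 + 0.184).
    """
    return simulate_hierarchical(
        seed=seed,
        pop_sizes_by_group=MOROCCAN_POP_SIZES,
        n_loci=130,
        F_ct=0.431,
        F_sc=0.402 / (0.402 + 0.184),
    )
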