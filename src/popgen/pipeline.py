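"""End-to-end orchestration of the analysis tiers.

A single :class:`AnalysisConfig` drives locus filtering, haplotype
collapsing, diversity tables, AMOVA, isolation by distance, and the two
clustering routes with their agreement score, optionally followed by trait
Q_ST.  Every stochastic stage draws its seed from the master seed by a fixed
offset, so re-running a config reproduces every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, differentiation, diversity, ibd, io, quantgen

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
_STAGE_SEEDS = {"amova": 11, "mantel": 23, "cluster": 37, "nj": 53, "qst": 71}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run."""

    genotype_table: str
    sample_meta: str | None = None
    snp_map: str | None = None
    traits: str | None = None
    tier: str = "regional"  # regional | bi-regional | worldwide
    out_dir: str = "results/run"
    max_missing: float = 0.25
    drop_monomorphic: bool = True
    drop_population_missing: bool = True
    rarefaction_g: int | None = None  # None: smallest per-locus count across units
    n_perm_amova: int = 20000
    n_perm_mantel: int = 10000
    k_range: tuple[int, int] = (1, 10)
    n_replicates: int = 20
    seed: int = 1

    def __post_init__(self):
        if self.tier not in {"regional", "bi-regional", "worldwide"}:
            raise ValueError(f"unknown tier {self.tier!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Plain key=value text config (lists as comma-separated)."""
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if f.name == "k_range":
                lo, _, hi = raw.partition(":")
                kwargs[f.name] = (int(lo), int(hi))
            elif f.type in ("int", "int | None"):
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            elif f.type == "bool":
                kwargs[f.name] = raw.lower() in {"1", "true", "yes"}
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


def _fmt_pm(x, se, nd=3) -> str:
    if x is None:
        return "-"
    return f"{round(x, nd)}±{round(se if se is not None else 0.0, nd)}"


def report_tables(records, out_path: str | Path) -> pd.DataFrame:
    """Diversity records to a Table-1/2-shaped CSV (N, N_H, PL, H_S, R_S, R_P)."""
    rows = []
    for r in records:
        rows.append(
            {
                "unit": r.unit,
                "N": r.N,
                "N_H": r.N_H,
                "PL": None if r.PL is None else round(r.PL),
                "H_S": _fmt_pm(r.H_S, r.H_S_se),
                "R_S": _fmt_pm(r.R_S, r.R_S_se, 2),
                "R_P": _fmt_pm(r.R_P, r.R_P_se),
                "g": r.g,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df


def amova_table(res, out_path: str | Path) -> pd.DataFrame:
    rows = []
    for level in res.levels:
        rows.append(
            {
                "level": level,
                "sigma2": round(res.components[level], 5),
                "percent": round(res.percent[level], 2),
            }
        )
    for k, v in res.phi.items():
        rows.append({"level": k, "sigma2": round(v, 4), "percent": None,
                     "p": res.p_values.get(k)})
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the full analysis and write its report bundle to cfg.out_dir.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    raises :class:`PipelineError` naming the stage; reports already written
    stay on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log_lines = [f"seed={cfg.seed}", f"tier={cfg.tier}"]

    # -- genotype_io ---------------------------------------------------------
    try:
        g = io.read_genotypes(cfg.genotype_table, cfg.snp_map, cfg.sample_meta)
        if g.n_samples == 0 or g.n_loci == 0:
            raise io.GenotypeError("empty genotype table")
        g, report = io.filter_loci(
            g,
            max_missing=cfg.max_missing,
            drop_monomorphic=cfg.drop_monomorphic,
            drop_population_missing=cfg.drop_population_missing,
        )
        log_lines.append(f"filter: {report.summary()}")
        haps = io.collapse_haplotypes(g)
        log_lines.append(f"haplotypes: {haps.n_haplotypes}")
        results["matrix"], results["filter_report"], results["haplotypes"] = g, report, haps
    except (OSError, ValueError) as e:
        raise PipelineError("genotype_io", str(e)) from e

    # -- diversity -----------------------------------------------------------
    try:
        pops = g.population_index()
        units = {p: [g.sample_ids[i] for i in rows] for p, rows in pops.items()}
        records = diversity.diversity_table(g, units, g_size=cfg.rarefaction_g)
        report_tables(records, out / "diversity_by_population.csv")
        results["diversity"] = records
    except ValueError as e:
        raise PipelineError("diversity", str(e)) from e

    # -- differentiation -----------------------------------------------------
    try:
        multi = {p: rows for p, rows in pops.items() if len(rows) >= 2}
        if len(multi) >= 2:
            keep_ids = [g.sample_ids[i] for rows in multi.values() for i in rows]
            g_amova = g.subset(sample_ids=keep_ids)
            am = differentiation.amova(
                g_amova, n_perm=cfg.n_perm_amova, seed=cfg.seed + _STAGE_SEEDS["amova"]
            )
            amova_table(am, out / "amova.csv")
            results["amova"] = am
    except ValueError as e:
        raise PipelineError("differentiation", str(e)) from e

    # -- ibd -----------------------------------------------------------------
    try:
        coords = {}
        for p, rows in pops.items():
            m = g.samples[rows[0]]
            coords[p] = (m.latitude, m.longitude)
        if all(np.isfinite(c[0]) and np.isfinite(c[1]) for c in coords.values()) and len(coords) >= 4:
            geo = ibd.geo_distances(coords)
            gen = differentiation.genetic_distances(
                g, level="population", metric="allele_difference_proportion"
            )
            gen_m = gen.values[np.ix_(
                [gen.ids.index(p) for p in geo.ids], [gen.ids.index(p) for p in geo.ids]
            )]
            mt = ibd.mantel_test(
                geo.values, gen_m, n_perm=cfg.n_perm_mantel,
                seed=cfg.seed + _STAGE_SEEDS["mantel"],
            )
            results["mantel"] = mt
            pd.DataFrame(
                {
                    "geo_km": geo.values[np.triu_indices(len(geo.ids), 1)],
                    "genetic": gen_m[np.triu_indices(len(geo.ids), 1)],
                }
            ).to_csv(out / "ibd_scatter.csv", index=False)
            log_lines.append(f"mantel: r={mt.r:.3f} p={mt.p:.4g}")
    except ValueError as e:
        raise PipelineError("ibd", str(e)) from e

    # -- clustering ----------------------------------------------------------
    try:
        reps = haps.representatives() if cfg.tier == "regional" else g
        pca_res = clustering.pca(reps, ld_correct=2)
        scores = clustering.select_components(pca_res)
        ward, _ = clustering.ward_cluster(scores, sample_ids=reps.sample_ids)

        base = cfg.seed + _STAGE_SEEDS["cluster"]
        runs_by_k, liks = clustering.evidence_by_k(
            reps, cfg.k_range, n_replicates=cfg.n_replicates, seed=base
        )
        k_star = (
            clustering.select_k(liks)
            if cfg.k_range[0] == 1
            else max(liks, key=lambda k: np.median(liks[k]))
        )
        final_runs = runs_by_k[k_star]
        ens = clustering.align_runs(final_runs)
        best = max(final_runs, key=lambda r: r.loglik)
        adm = best.majority(sample_ids=reps.sample_ids)
        ward_k, _ = clustering.ward_cluster(scores, k=k_star, sample_ids=reps.sample_ids)
        agree = clustering.agreement(adm, ward_k)

        qdf = pd.DataFrame(
            ens.consensus, columns=[f"q_{j + 1}" for j in range(k_star)]
        )
        qdf.insert(0, "accession", reps.sample_ids)
        qdf.insert(1, "population", reps.populations)
        qdf.to_csv(out / "membership_consensus.csv", index=False)
        pd.DataFrame(
            {
                "component": np.arange(1, len(pca_res.eigenvalues) + 1),
                "eigenvalue": pca_res.eigenvalues,
                "variance_fraction": pca_res.variance_fractions,
                "tw_p": pca_res.tw_pvalues,
            }
        ).to_csv(out / "pca_eigenvalues.csv", index=False)

        tree, _ = clustering.neighbor_joining(g=reps, n_boot=0)
        io.write_newick(tree, out / "nj_tree.nwk")

        results["pca"] = pca_res
        results["selected_k"] = k_star
        results["H_prime"] = ens.H_prime
        results["agreement"] = agree
        results["ward"] = ward
        results["admixture"] = adm
        log_lines.append(
            f"cluster: K={k_star} H'={ens.H_prime:.3f} agreement={agree:.1f}%"
        )
    except ValueError as e:
        raise PipelineError("clustering", str(e)) from e

    # -- quantgen (optional) -------------------------------------------------
    if cfg.traits is not None:
        try:
            t = io.TraitTable.read(cfg.traits)
            t, imput = quantgen.impute_censored(t)
            means = quantgen.accession_means(t, "flowering_time")
            if "group" in t.data.columns:
                grouping = (
                    t.data.drop_duplicates("accession_id")
                    .set_index("accession_id")["group"]
                    .to_dict()
                )
                q = quantgen.qst(means, grouping, method="reml", trait="flowering_time")
                results["qst"] = q
                log_lines.append(f"qst[FT]: {q.Q_ST:.3f}")
            results["traits"], results["imputation"] = t, imput
        except ValueError as e:
            raise PipelineError("quantgen", str(e)) from e

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    summary = {
        "n_samples": g.n_samples,
        "n_loci": g.n_loci,
        "n_haplotypes": haps.n_haplotypes,
        "selected_k": results.get("selected_k"),
        "agreement_pct": results.get("agreement"),
        "fst": results["amova"].f_st if "amova" in results else None,
        "mantel_r": results["mantel"].r if "mantel" in results else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    results["summary"] = summary
    return results
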