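#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analysis steps.

Produces, under results/synthetic_inputs/:
  * the regional genotype panel (65 haplotype samples, 20 populations in 4
    genetic groups, 130 SNPs) from the hierarchical generator whose fixation
    indices are fixed from the published AMOVA variance shares;
  * a stepping-stone panel with population coordinates for the
    isolation-by-distance analysis;
  * a flowering-trait table (per-plant flowering time and leaf number with
    right-censoring at 200 days) for the Q_ST analysis.

Usage: python analysis/01_simulate_study.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from popgen import io
from popgen.simulate import (
    SimulationConfig,
    moroccan_design,
    simulate_stepping_stone,
    simulate_traits,
)

OUT = Path("results/synthetic_inputs")


def write_meta(g, path, region="Morocco", group_of=None):
    pd.DataFrame(
        [
            {
                "accession_id": s.accession_id,
                "population_id": s.population_id,
                "subregion": s.subregion,
                "region": region,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "group": (group_of or {}).get(s.population_id, s.subregion),
            }
            for s in g.samples
        ]
    ).to_csv(path, index=False)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    g, group_of, _ = moroccan_design(seed=args.seed)
    io.write_genotypes(g, OUT / "regional_genotypes.csv")
    write_meta(g, OUT / "regional_meta.csv", group_of=group_of)
    print(
        f"regional panel: {g.n_samples} haplotype samples, "
        f"{len(g.population_index())} populations, {g.n_loci} loci "
        f"-> {OUT / 'regional_genotypes.csv'}"
    )

    cfg = SimulationConfig(
        seed=args.seed + 2000, n_pops=15, samples_per_pop=6, n_loci=150,
        spatial_model="stepping_stone", ibd_step_sd=0.6,
    )
    gs, geo, _ = simulate_stepping_stone(cfg)
    io.write_genotypes(gs, OUT / "stepping_genotypes.csv")
    write_meta(gs, OUT / "stepping_meta.csv", region="transect")
    print(f"stepping-stone panel: {gs.n_samples} samples along a "
          f"{cfg.n_pops}-deme transect -> {OUT / 'stepping_genotypes.csv'}")

    grouping = [f"G{1 + i // 5}" for i in range(20)]  # 4 groups x 5 accessions
    # wide between/within-group spread around a 140-day mean so that a
    # realistic late tail of accessions fails to flower by the 200-day limit
    t, _ = simulate_traits(grouping, V_B=3600.0, V_W=1225.0, censor_at=200.0,
                           seed=args.seed + 3000, plants_per_accession=15,
                           plant_sd=5.0, baseline=140.0)
    t.write(OUT / "flowering_traits.csv")
    n_cens = int((~t.data["flowered"]).sum())
    print(f"trait table: {len(t.data)} plants, {n_cens} censored at 200 d "
          f"-> {OUT / 'flowering_traits.csv'}")


if __name__ == "__main__":
    main()
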