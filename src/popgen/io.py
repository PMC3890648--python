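"""Reading, validation, filtering and export of haploid SNP genotype tables.

The central container is :class:`GenotypeMatrix`: an accession-by-locus matrix
of haploid biallelic calls coded 0/1 with ``-1`` for missing, together with
per-sample metadata (population / subregion / region / coordinates) and a SNP
map (chromosome, position, ascertainment panel).  Selfing lines are treated as
haploid multilocus genotypes throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: symbols in input tables interpreted as a missing call
MISSING_SYMBOLS = {"", "NA", "NaN", "nan", "N", "?", "-", "-9", "."}


class GenotypeError(ValueError):
    """Structural problem in genotype input (dimension/id mismatch, empty panel)."""


@dataclass(frozen=True)
class SnpLocus:
    """One SNP marker: name, map location and ascertainment panel (CE/IP/W)."""

    id: str
    chromosome: str = ""
    position: int = 1
    panel: str = ""
    alleles: tuple[str, str] | None = None  # e.g. ("A", "G"); allele 0 first

    def __post_init__(self):
        if self.position < 1:
            raise GenotypeError(f"locus {self.id}: position must be >= 1")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one accession (wild selfing line treated as haploid)."""

    accession_id: str
    population_id: str
    subregion: str = ""
    region: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")

    def __post_init__(self):
        if not self.population_id:
            raise GenotypeError(f"sample {self.accession_id}: empty population id")
        if np.isfinite(self.latitude) and abs(self.latitude) > 90:
            raise GenotypeError(f"sample {self.accession_id}: |latitude| > 90")
        if np.isfinite(self.longitude) and abs(self.longitude) > 180:
            raise GenotypeError(f"sample {self.accession_id}: |longitude| > 180")


@dataclass
class GenotypeMatrix:
    """Haploid biallelic calls for ``samples x loci`` with missing as -1."""

    samples: list[SampleMeta]
    loci: list[SnpLocus]
    calls: np.ndarray  # int8, shape (n_samples, n_loci), values {0, 1, -1}

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        bad = set(np.unique(self.calls)) - {0, 1, MISSING}
        if bad:
            raise GenotypeError(f"invalid call codes: {sorted(bad)}")
        ids = [s.accession_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = {i for i in ids if ids.count(i) > 1}
            raise GenotypeError(f"duplicate sample id(s): {sorted(dup)}")
        lids = [l.id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise GenotypeError("duplicate locus ids in map")

    # -- basic accessors -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [s.accession_id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def populations(self) -> list[str]:
        return [s.population_id for s in self.samples]

    def population_index(self) -> dict[str, np.ndarray]:
        """Map population id -> integer row indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.population_id, []).append(i)
        return {k: np.array(v) for k, v in out.items()}

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def subset(
        self,
        sample_ids: Iterable[str] | None = None,
        locus_ids: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples)
        cols = np.arange(self.n_loci)
        if sample_ids is not None:
            want = list(sample_ids)
            idx = {s: i for i, s in enumerate(self.sample_ids)}
            missing_ids = [s for s in want if s not in idx]
            if missing_ids:
                raise GenotypeError(f"unknown sample id(s): {missing_ids[:5]}")
            rows = np.array([idx[s] for s in want])
        if locus_ids is not None:
            want = list(locus_ids)
            idx = {l: i for i, l in enumerate(self.locus_ids)}
            missing_ids = [l for l in want if l not in idx]
            if missing_ids:
                raise GenotypeError(f"unknown locus id(s): {missing_ids[:5]}")
            cols = np.array([idx[l] for l in want])
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            loci=[self.loci[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids)


# ---------------------------------------------------------------------------
# reading


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    """Delimited text reader that sniffs comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=None, engine="python", dtype=str, **kw)


def read_genotypes(
    table_path: str | Path,
    map_path: str | Path | None = None,
    meta_path: str | Path | None = None,
    columns: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a samples-by-loci genotype table plus SNP map and sample metadata.

    The genotype table has a header row of locus ids and the accession id in
    the first column.  Calls may be coded ``0/1``, ``A/B``, or as nucleotides
    (resolved against the ``alleles`` column of the SNP map, e.g. ``A/G``).
    Any unrecognised symbol is mapped to missing and counted in the log.

    ``columns`` optionally renames metadata/map column headers, e.g.
    ``{"population_id": "pop"}`` — supplementary-table layouts vary.
    """
    table = _read_table(table_path, index_col=0)
    table.index = table.index.astype(str)
    col = dict(columns or {})

    loci_by_id: dict[str, SnpLocus] = {}
    if map_path is not None:
        m = _read_table(map_path)
        m = m.rename(columns={v: k for k, v in col.items() if v in m.columns})
        for _, row in m.iterrows():
            alleles = None
            if "alleles" in m.columns and isinstance(row.get("alleles"), str):
                parts = row["alleles"].replace("|", "/").split("/")
                if len(parts) == 2:
                    alleles = (parts[0].strip().upper(), parts[1].strip().upper())
            loci_by_id[str(row["id"])] = SnpLocus(
                id=str(row["id"]),
                chromosome=str(row.get("chromosome", "")),
                position=int(float(row.get("position", 1))),
                panel=str(row.get("panel", "")),
                alleles=alleles,
            )
        unknown = [l for l in table.columns if l not in loci_by_id]
        if unknown:
            raise GenotypeError(f"loci absent from map: {unknown[:5]}")
    loci = [loci_by_id.get(l, SnpLocus(id=str(l))) for l in table.columns]

    metas: list[SampleMeta] = []
    if meta_path is not None:
        mt = _read_table(meta_path)
        mt = mt.rename(columns={v: k for k, v in col.items() if v in mt.columns})
        mt.index = mt["accession_id"].astype(str)
        absent = [s for s in table.index if s not in mt.index]
        if absent:
            raise GenotypeError(f"samples absent from metadata: {absent[:5]}")
        for sid in table.index:
            row = mt.loc[sid]
            metas.append(
                SampleMeta(
                    accession_id=sid,
                    population_id=str(row["population_id"]),
                    subregion=str(row.get("subregion", "") or ""),
                    region=str(row.get("region", "") or ""),
                    latitude=float(row.get("latitude", np.nan)),
                    longitude=float(row.get("longitude", np.nan)),
                )
            )
    else:
        metas = [SampleMeta(accession_id=s, population_id=s) for s in table.index]

    calls = np.full(table.shape, MISSING, dtype=np.int8)
    n_unknown = 0
    for j, locus in enumerate(loci):
        coding: dict[str, int] = {"0": 0, "1": 1, "A": 0, "B": 1, "a": 0, "b": 1}
        if locus.alleles is not None:
            # nucleotide dialect takes precedence over the letter A/B dialect
            coding = {locus.alleles[0]: 0, locus.alleles[1]: 1}
        column = table.iloc[:, j]
        for i, v in enumerate(column):
            sym = "" if pd.isna(v) else str(v).strip()
            if sym in MISSING_SYMBOLS:
                continue
            code = coding.get(sym, coding.get(sym.upper()))
            if code is None:
                n_unknown += 1
                continue
            calls[i, j] = code
    if n_unknown:
        logger.warning("mapped %d unrecognised call symbols to missing", n_unknown)

    return GenotypeMatrix(samples=metas, loci=loci, calls=calls)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the 0/1 call table (missing as NA), round-trippable by read_genotypes."""
    df = g.to_frame().replace(MISSING, pd.NA)
    df.to_csv(path, index_label="accession_id")


# ---------------------------------------------------------------------------
# locus filtering


@dataclass
class FilterReport:
    """Counts and locus ids removed by each filter, in application order."""

    n_input: int
    removed_missing: list[str] = field(default_factory=list)
    removed_monomorphic: list[str] = field(default_factory=list)
    removed_population_missing: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(
            map(
                len,
                (
                    self.removed_missing,
                    self.removed_monomorphic,
                    self.removed_population_missing,
                ),
            )
        )

    def summary(self) -> str:
        return (
            f"{self.n_input} loci in; removed {len(self.removed_missing)} by "
            f"missingness, {len(self.removed_monomorphic)} monomorphic, "
            f"{len(self.removed_population_missing)} population-missing; "
            f"{self.n_retained} retained"
        )


def filter_loci(
    g: GenotypeMatrix,
    max_missing: float = 0.25,
    drop_monomorphic: bool = True,
    drop_population_missing: bool = False,
    scope: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the panel filters in fixed order and return matrix + report.

    Filters, within ``scope`` (sample ids; default all samples):

    1. missingness — drop loci whose missing fraction is >= ``max_missing``;
    2. monomorphism — drop loci where a single allele is observed;
    3. population-missing — drop loci with no observed call in at least one
       whole population of the scope.

    The returned matrix is restricted to the scope samples.  The fixed order
    makes the per-filter counts reproducible.
    """
    if scope is not None:
        scope = list(scope)
        if not scope:
            raise GenotypeError("empty scope")
        g = g.subset(sample_ids=scope)

    report = FilterReport(n_input=g.n_loci)
    keep = np.ones(g.n_loci, dtype=bool)
    obs = g.calls != MISSING

    frac_missing = 1.0 - obs.mean(axis=0)
    drop = keep & (frac_missing >= max_missing)
    report.removed_missing = [g.loci[j].id for j in np.where(drop)[0]]
    keep &= ~drop

    if drop_monomorphic:
        has0 = ((g.calls == 0) & obs).any(axis=0)
        has1 = ((g.calls == 1) & obs).any(axis=0)
        drop = keep & ~(has0 & has1)
        report.removed_monomorphic = [g.loci[j].id for j in np.where(drop)[0]]
        keep &= ~drop

    if drop_population_missing:
        pop_idx = g.population_index()
        all_missing_some_pop = np.zeros(g.n_loci, dtype=bool)
        for rows in pop_idx.values():
            all_missing_some_pop |= ~obs[rows].any(axis=0)
        drop = keep & all_missing_some_pop
        report.removed_population_missing = [g.loci[j].id for j in np.where(drop)[0]]
        keep &= ~drop

    if not keep.any():
        raise GenotypeError("all loci removed by filtering: empty panel")
    out = g.subset(locus_ids=[g.loci[j].id for j in np.where(keep)[0]])
    logger.info("filter_loci: %s", report.summary())
    return out, report


# ---------------------------------------------------------------------------
# multilocus haplotypes


@dataclass
class HaplotypeSet:
    """Distinct multilocus haplotypes and the sample -> haplotype assignment."""

    haplotypes: np.ndarray  # (n_haplotypes, n_loci) int8
    assignment: np.ndarray  # (n_samples,) int, haplotype index per sample
    source: GenotypeMatrix
    missing_rule: str = "strict"

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    def per_population_counts(self) -> dict[str, int]:
        """N_H per population: distinct haplotypes among its samples."""
        out = {}
        for pop, rows in self.source.population_index().items():
            out[pop] = len(set(self.assignment[rows].tolist()))
        return out

    def representatives(self) -> GenotypeMatrix:
        """One representative sample per haplotype, as a new matrix.

        The representative is the member with the fewest missing calls; its
        metadata (population etc.) is carried over.
        """
        reps = []
        for h in range(self.n_haplotypes):
            members = np.where(self.assignment == h)[0]
            best = members[np.argmin((self.source.calls[members] == MISSING).sum(axis=1))]
            reps.append(int(best))
        samples = [self.source.samples[i] for i in reps]
        return GenotypeMatrix(
            samples=samples, loci=list(self.source.loci), calls=self.source.calls[reps]
        )


def collapse_haplotypes(g: GenotypeMatrix, missing_rule: str = "strict") -> HaplotypeSet:
    """Group samples into distinct multilocus haplotypes.

    strict
        two samples share a haplotype iff their call vectors are identical,
        missing being a state of its own.
    wildcard
        samples are merged (transitively, via union-find) whenever they agree
        at every locus where both have observed calls.
    """
    if g.n_samples == 0:
        raise GenotypeError("empty matrix")
    n = g.n_samples
    if missing_rule == "strict":
        seen: dict[bytes, int] = {}
        assignment = np.empty(n, dtype=int)
        for i in range(n):
            key = g.calls[i].tobytes()
            assignment[i] = seen.setdefault(key, len(seen))
    elif missing_rule == "wildcard":
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        obs = g.calls != MISSING
        for i in range(n):
            for j in range(i + 1, n):
                both = obs[i] & obs[j]
                if not np.any(g.calls[i, both] != g.calls[j, both]):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        roots: dict[int, int] = {}
        assignment = np.array([roots.setdefault(find(i), len(roots)) for i in range(n)])
    else:
        raise ValueError(f"unknown missing_rule {missing_rule!r}")

    n_h = int(assignment.max()) + 1
    haplos = np.full((n_h, g.n_loci), MISSING, dtype=np.int8)
    for h in range(n_h):
        members = g.calls[assignment == h]
        observed = members != MISSING
        for j in range(g.n_loci):
            vals = members[observed[:, j], j]
            if vals.size:
                haplos[h, j] = vals[0]
    return HaplotypeSet(
        haplotypes=haplos, assignment=assignment, source=g, missing_rule=missing_rule
    )


# ---------------------------------------------------------------------------
# interchange formats


def write_structure_format(g: GenotypeMatrix, path: str | Path) -> None:
    """One row per haploid individual: id, population integer, calls (-9 missing)."""
    pops = {p: k + 1 for k, p in enumerate(dict.fromkeys(g.populations))}
    with open(path, "w") as fh:
        for meta, row in zip(g.samples, g.calls):
            cells = [str(int(c)) if c != MISSING else "-9" for c in row]
            fh.write(f"{meta.accession_id}\t{pops[meta.population_id]}\t" + "\t".join(cells) + "\n")


def read_structure_format(path: str | Path) -> GenotypeMatrix:
    """Read back a file written by :func:`write_structure_format`."""
    ids, pops, rows = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            pops.append(parts[1])
            rows.append([MISSING if c == "-9" else int(c) for c in parts[2:]])
    calls = np.array(rows, dtype=np.int8)
    samples = [
        SampleMeta(accession_id=i, population_id=f"pop{p}") for i, p in zip(ids, pops)
    ]
    loci = [SnpLocus(id=f"L{j + 1}") for j in range(calls.shape[1])]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode as Newick with branch lengths."""
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# trait tables


@dataclass
class TraitTable:
    """Per-plant flowering records.

    Columns: accession_id, plant_id, flowering_time (days), leaf_number,
    flowered (bool), vernalized (bool).  Non-flowering plants carry NaN
    trait values until censoring imputation.
    """

    data: pd.DataFrame

    REQUIRED = ["accession_id", "plant_id", "flowering_time", "leaf_number", "flowered", "vernalized"]

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        d = self.data
        flowered = d["flowered"].astype(bool)
        ft = pd.to_numeric(d["flowering_time"], errors="coerce")
        if ((ft <= 0) & flowered).any():
            raise ValueError("flowering_time must be > 0 for flowered plants")
        ln = pd.to_numeric(d["leaf_number"], errors="coerce")
        if ((ln < 1) & ln.notna()).any():
            raise ValueError("leaf_number must be >= 1 when recorded")

    @classmethod
    def read(cls, path: str | Path) -> "TraitTable":
        d = pd.read_csv(path, sep=None, engine="python")
        for c in ("flowered", "vernalized"):
            if d[c].dtype == object:
                d[c] = d[c].astype(str).str.lower().isin({"1", "true", "yes", "y"})
            else:
                d[c] = d[c].astype(bool)
        return cls(d)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)
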