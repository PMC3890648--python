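# Supplementary input tables (not bundled)

The published-data reproduction (`tests/test_acceptance.py::
test_published_dataset_reproduction` and the `regional` pipeline tier on
real data) expects the study's supplementary tables here, converted to
delimited text:

* `genotypes.csv` — accessions × SNPs call table; first column
  `accession_id`, header row of locus ids; calls 0/1, A/B or nucleotides;
  empty/`NA`/`N`/`?`/`-9` treated as missing.
* `snp_map.csv` — columns `id, chromosome, position, panel[, alleles]`
  (panel ∈ {CE, IP, W}; `alleles` like `A/G` when calls are nucleotides).
* `sample_meta.csv` — columns `accession_id, population_id, subregion,
  region, latitude, longitude`.

These tables are journal supplementary material and are not redistributed
with the package; without them the published-data test fails by design and
every other test runs on synthetic data.
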