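# rbhnet

Signed reciprocal-best-hit (RBH) networks over stabilized-ICA components of
multi-dataset gene-expression collections, for characterizing molecular
relationships between disease groups (e.g. inverse comorbidity).

The pipeline has three steps:

1. **Decompose** each gene-by-sample expression dataset independently with
   stabilized ICA (multi-run FastICA, icasso-style clustering, centrotype
   components with a stability index) into *metagenes* (gene weights) and
   *metasamples* (per-sample activities), then orient every component either
   by the **long-tail** rule (metagene skewness points positive) or the
   **disease-pointing** rule (case metasample weights rank above controls,
   by a Wilcoxon rank-sum statistic).
2. **Link** components of every dataset pair by signed reciprocal best hits:
   a +RBH is a mutually maximal positive Spearman correlation over shared
   genes, a −RBH a mutually minimal negative one; the union over all pairs
   forms a signed, weighted network.
3. **Isolate** the subnetwork of one sign between two disease groups
   (e.g. negative edges between "AD" and "LC"), detect communities with
   weighted Markov clustering (MCL), and annotate them: consensus metagenes
   with sign alignment along community edges, top-contributing genes beyond
   3 SD, Fisher/hypergeometric enrichment against GMT signature collections,
   subtype association tests, and matching of external metagene tables.

A fully parameterized synthetic generator (`rbhnet.synthetic`) plants shared
latent sources with inverted case/control association across groups, so the
whole pipeline is testable end to end without any data downloads.

## Run the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(RBH oracle equivalence, orientation contracts, MCL and modularity
correctness, enrichment exactness, end-to-end planted-structure recovery).

## CLI

```sh
# generate a synthetic collection with planted structure + registry
rbhnet simulate --out fixtures/ --groups AD:2:40,LC:2:40 --seed 7

# full pipeline from a dataset registry (YAML listing matrix/labels files)
rbhnet pipeline --registry fixtures/registry.yaml --out run/ \
    --orientation disease_pointing --seed 7

# or stage by stage
rbhnet decompose --registry fixtures/registry.yaml --out run/dec --seed 7
rbhnet network --decomps run/dec --out run/net.tsv
rbhnet communities --network run/net.tsv --out run/comm --group-a AD --group-b LC
rbhnet annotate --decomps run/dec --network run/net.tsv \
    --communities run/comm/communities.tsv --out run/ann \
    --group-a AD --group-b LC --reference-group LC --gmt signatures.gmt
```

Every pipeline run writes its intermediates (decomposition TSVs + JSON
sidecars, edge-list TSV, community table, stats JSON) and a `manifest.json`
under the output directory; runs are deterministic under a fixed `--seed`.

Input formats: expression matrices are TSV/CSV with gene symbols in the
first column and sample names in the header; labels files map each sample to
`case`/`control` (optionally a subtype); signature collections are standard
GMT.

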