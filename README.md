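# acsiva

Assemblage centroid-standardized isotope vector analysis (ACSIVA): a toolkit
for describing consumer trophic positions as vectors from local assemblage
centroids in δ¹⁵N/δ¹³C space, summarizing taxa with circular statistics, and
reconstructing ancestral niche-vector states on a phylogeny.

## What it does

1. **Vector standardization** (`acsiva.isotope_tables`) — reads a per-specimen
   isotope table (specimen, species, genus, site, δ13C, δ15N), computes
   species means per site, forms each site's centroid as the *unweighted*
   mean of species means (so sample-size imbalance cannot bias it), and
   expresses every specimen as a vector (angle in [0, 360), ‰ magnitude)
   from its local centroid.
2. **Circular statistics** (`acsiva.circular_stats`) — mean vector (μ, r),
   circular variance/SD, von Mises concentration κ̂ (piecewise ML
   approximation with small-sample correction), Rayleigh's Z test with a
   second-order series p-value, Rao's spacing test with bracketed p-values
   from a packaged critical-value table (or seeded Monte Carlo), and a
   circular-linear correlation.
3. **Two analysis partitions** (`acsiva.pipeline`) — per-genus summaries from
   pooled individual vectors, and from per-(genus, site) mean directions;
   plus richness-bias tests correlating vector direction/length with
   assemblage species richness.
4. **Ancestral states** (`acsiva.phylo`) — genus mean vectors projected to
   Cartesian components (r·cosμ+1, r·sinμ+1), internal-node states solved
   exactly by branch-length-weighted least squares (weighted squared-change
   parsimony), converted back to angles with quadrant correction, binned
   into 45° sectors, and axis-sign transitions counted along branches.
5. **Synthetic fixtures** (`acsiva.fixtures`) — seeded Yule trees, Brownian
   evolution of vector components, and assemblage sample tables with
   von Mises genus directions, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic bundle (samples.csv, tree.nwk, truth.json)
acsiva fixtures make -o bundle --seed 1 --n-genera 12 --n-sites 10

# both genus-summary partitions (TSV + JSON + run manifest)
acsiva summarize --samples bundle/samples.csv -o out

# ancestral niche-vector states on a Newick tree
acsiva ancestral --samples bundle/samples.csv --tree bundle/tree.nwk -o out_anc
acsiva ancestral ... --unit-lengths   # all branch lengths treated as 1

# richness-bias correlation tests
acsiva correlate --samples bundle/samples.csv -o out_corr
```

Column names are remappable via a YAML config (`--config`), which can also
declare genus splits (species → operational group label). Exit codes:
0 success, 1 usage error, 2 data error. Every run writes a
`run_manifest.json` with input hashes, config hash and versions.

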