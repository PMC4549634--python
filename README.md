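# ignomap

Ignorance maps of sampling-effort bias for presence-only biodiversity data.

Open-access biodiversity databases — museum collections, atlases, citizen
science portals — hold presence-only records gathered with no sampling
design. The records map where observers went at least as much as where
species live, and a missing record can mean "truly absent" or "nobody
looked". `ignomap` turns the pooled records of a *reference taxonomic group*
(a set of species surveyed with the same methods, used as a surrogate for
effort) into a per-grid-cell **ignorance score** `I ∈ [0, 1]`: 1 means no
sampling information at all, 0 means maximal credibility that missing
reports reflect true absences. The resulting rasters plug directly into
species-distribution workflows as masks, bias/background layers,
certainty weights, pseudo-absence selectors and Bayesian prior layers.

## The algorithms

Per-cell effort `x_i` is either the raw observation count `N_i` or the
species observation index `O_i = N_i / R_i` (observations per observed
species, 0 where `N_i = 0`), where `R_i` is the cell's species richness.
Three transforms map effort to ignorance:

| Algorithm | Formula | Character |
|---|---|---|
| Normalization | `I_i = 1 − x_i / x_m` | linear in effort; depends on the dataset maximum `x_m` |
| Log-normalization | `I_i = 1 − ln(x_i + 1) / ln(x_m + 1)` | separates "few" from "enough" under long-tailed counts |
| Half-ignorance | `I_i = O50 / (x_i + O50)` | independent of `x_m`; `O50` is the effort at which `I = 0.5` |

All three give `I = 1` at zero effort and are non-increasing in effort; the
two normalizing forms reach exactly 0 at the dataset maximum, while
half-ignorance decays asymptotically and is therefore comparable across
datasets with very different maxima. `O50` encodes your confidence per
observation: `O50 = 1` says a single report halves the ignorance;
`O50 = 0.5` trusts it further (one report drops `I` to 0.333); `O50 = 5`
demands several reports before scores fall.

Downstream, `certainty = 1 − I` weights estimate layers, cells with
`I > threshold` can be masked out, cells with no focal-species record and
`I ≤ threshold` become pseudo-absences, and `p_i = 0.5·I_i` gives a
Bernoulli prior occurrence probability for unobserved cells (an unsurveyed
cell, `I = 1`, is occupied or not with equal probability).

## Worked example

Simulate a biased butterfly dataset (three observer hotspots on a
20 × 20 km landscape), grid it at 1 km, and score it with the
half-ignorance algorithm:

```sh
ignomap simulate --seed 11 --n-records 20000 --out occ.csv
ignomap summarize --occurrences occ.csv --group butterflies \
    --from 2000-01-01 --to 2009-12-31 \
    --cell-size 1000 --extent 0 0 20000 20000 \
    --out-n n_obs.tif --out-r n_species.tif
ignomap ignorance --n-raster n_obs.tif --algorithm half --o50 1 --out ignorance.tif
```

which prints

```
wrote 20000 records to occ.csv
gridded 20000 of 20000 filtered records (0 outside extent, 0 outside region)
wrote ignorance raster (half_ignorance) to ignorance.tif
```

Per-cell counts range 2–254; with `O50 = 1` the ignorance scores span
0.004–0.333, and 353 of the 400 cells score `I ≤ 0.1` — the landscape is
densely enough sampled that even off-hotspot cells carry some credibility,
while the least-visited cells (two records) still retain a third of the
maximum ignorance. Every output raster gets a `*.provenance.json` sidecar
recording the inputs, filters, parameters, counts and seed that produced
it. The same stages are callable as a library (`ignomap.summarize_to_grid`,
`ignomap.ignorance_half`, …), and pre-summarized per-cell portal tables can
enter at the `ignorance` stage via `--summary`.

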