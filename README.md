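# asimm — immigration mass-balance analysis for activated-sludge communities

Activated-sludge (AS) wastewater-treatment reactors receive a continuous
stream of microorganisms with the influent. How much of the sludge
community is actually *grown* in the reactor, and how much is only there
because it keeps immigrating? `asimm` answers this question the way a
controlled reactor experiment does: by combining paired 16S relative
abundances from the influent and the sludge with a steady-state
mass-balance model, and by contrasting reactors fed live influent solids
against sterile (autoclaved) controls and substrate-only controls.

The package is aimed at environmental microbiologists and environmental
engineers analysing genus-level amplicon count tables from such
experiments, and it ships a complete forward simulator of the
three-phase, 27-reactor experimental design (3 inoculum blocks × 3 feed
conditions × triplicates, sampled at phase boundaries and rarefied to
40,000 reads) so that every analysis step can be validated against known
ground truth.

## The model

For a completely mixed reactor at steady state with solids retention
time θ<sub>x</sub> and hydraulic retention time θ, the growth rate of
taxon *i* with decay rate *b<sub>i</sub>* and immigration level
*m<sub>i</sub>* (the fraction of its sludge biomass that immigrated
rather than grew) is

> μ<sub>i</sub> = (1/θ<sub>x</sub> + b<sub>i</sub>) (1 − m<sub>i</sub>),  
> m<sub>i</sub> = X<sub>Bio,i,Inf</sub> / [X<sub>Bio,i,AS</sub> (θ/θ<sub>x</sub>) (1 + b<sub>i</sub>θ<sub>x</sub>)].

Expressed in the relative abundances a sequencing experiment measures
(f<sub>Inf</sub>, f<sub>AS</sub>), with f<sub>Capt</sub> the capture
fraction of influent biomass, X<sub>Tot</sub> the solids concentrations
and γ<sub>DNA</sub> the DNA extraction yields:

> f<sub>AS</sub> = R · f<sub>Inf</sub> / (1 − μ<sub>net</sub> θ<sub>x</sub>),  R = (θ<sub>x</sub>/θ) · f<sub>Capt</sub> · (X<sub>Tot,Inf</sub> γ<sub>Inf</sub>) / (X<sub>Tot,AS</sub> γ<sub>AS</sub>)

where μ<sub>net</sub> = μ − b. Inverting gives the per-genus net growth
rate from one pair of measured abundances,
μ<sub>net</sub> = (1/θ<sub>x</sub>)(1 − R·f<sub>Inf</sub>/f<sub>AS</sub>).
In log–log space taxa with equal μ<sub>net</sub> lie on 45° lines; the
line with intercept log₁₀(R) is the zero-net-growth border separating
taxa that could persist without immigration (above) from those that are
diluted faster than they grow (below).

On top of the model the package implements the four-way population
classification (core resident / non-core resident / growing immigrant /
residual immigrant, from occupancy, abundance and sterile-control
contrasts), the Phase-3 persistence odds-ratio test, and the supporting
community-ecology statistics (Jaccard and Bray–Curtis dissimilarity,
ANOSIM, PCoA, UPGMA, richness and shared-genus fractions), all written
against plain TSV interfaces.

## Worked example

Simulate one reactor set and run the whole analysis:

```bash
asimm all --out demo --seed 7
```

prints (abridged):

```
## Category summary (Table-1 style)
                    n_genera  pct_reads_mean  pct_reads_sd
category
core_resident             65       72.803796      3.855879
non_core_resident        116       21.799630      2.298431
growing_immigrant         85       10.364722      0.732098
residual_immigrant        57        1.460000      0.100856

## Net growth scatter data
genera with growth records: 323
zero-growth border: log10(f_AS) = -0.4314 + log10(f_Inf)

## Phase-3 persistence
                 persisting  lost
phase2_sign
mu_net_positive          26     1
mu_net_negative          30    26
odds_ratio: 22.533

## ANOSIM (Jaccard, by feed, Phase-2 reactors)
R = 0.564, p = 0.001 (999 permutations)
```

Reading the output: roughly three quarters of reads belong to a small
set of core resident genera selected by the common substrate, while a
much more diverse immigrant community contributes ~10% of reads.
Immigrant genera sit on a log–log abundance scatter whose zero-growth
border lies at log₁₀(R) = −0.43 for the default operating parameters
(θ<sub>x</sub> = 5 d, θ = 1.8 d). After immigration stops (Phase 3), a
growing immigrant with a positive Phase-2 net growth rate is far more
likely to persist than one with a negative rate (odds ratio ≫ 1), and
reactors that had received live solids separate cleanly from
substrate-only controls (ANOSIM).

Each step is also available separately (`asimm simulate / classify /
growth / stats / persistence`) on your own count, taxonomy and metadata
TSVs; see `asimm --help`.

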