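# ducttrace

Quantitative clonal lineage-tracing analysis on branched ductal networks.

During branching morphogenesis of exocrine glands (the embryonic mouse
submandibular salivary gland is the motivating system), renewing progenitors
sit in the endbuds of a growing ductal tree, amplify through rounds of tip
bifurcation, and differentiate into four compartments: acinar, luminal
ductal, basal ductal and myoepithelial cells.  Sparse multicolor (confetti)
labelling turns each induced progenitor into a clone whose footprint on the
reconstructed tree records where it was born, how potent it was and how far
its progeny dispersed.  `ducttrace` implements the full quantitative chain
for such experiments, for developmental biologists and biostatisticians who
have (or want to simulate) a reconstructed tree plus a labelled-cell table:

- **Tree model and I/O** — ducts as a rooted tree with generation index
  ("level", main duct = 1), duct lengths and terminal acini; JSON trees,
  CSV cell tables, Newick export.
- **Clone analysis** — grouping same-color cells into clones, inference of
  each clone's common ancestor (CA: the deepest duct whose subtree holds
  the whole clone), removal of non-renewing clones confined to a single
  duct/acinus, potency classification (uni/bi/multipotent) with standard
  errors of proportion, clone spans, size distributions, and subclone
  density profiles with linear-vs-exponential growth model selection.
- **Merger model** — closed-form probabilities of labelling-induced clone
  merger.  With `M` labelling events of one color over `N` endbuds and
  `p = M/N`:

  `P_c = 1 − (1 − 1/N)^M`,  `P_1 = (M/N)(1 − 1/N)^(M−1)`,
  `P_merger = 1 − P_1/P_c ≈ 1 − p/(e^p − 1) ≈ p/2`,

  and for 4 colors the co-label fraction `C = 1 − Q_1/Q_* ≈ 3p/2 =
  3·P_merger`, which lets the observable cross-color co-labelling of CA
  endbuds estimate the unobservable same-color merger rate as `C/3`.
- **Clone simulator** — the stochastic null model of clone dispersion: a
  single tip cell walks the tree towards the endpoints, doubling at each
  bifurcation with progeny segregated at random between daughter branches
  (or coherently, as the rejected alternative), depositing density units in
  traversed ducts; used for clone-size/density predictions and
  simulation-based merger rates.
- **Progenitor census** — conversion of clones' fractional contributions to
  their CA subtrees into the number of renewing tip progenitors per
  compartment: `N_c = 100/(f_u·c_u + f_b·c_b + f_m·c_m)` with clone-type
  fractions `f` and mean percentage contributions `c`, using a fixed cell
  census (acinar and myoepithelial cells per acinus, luminal and basal
  cells per micron of duct).
- **Synthetic data** — a generator that grows trees by stochastic tip
  bifurcation, induces Poisson labelling over endbuds at unequal per-color
  intensities, grows clones with the simulator and emits cells consistent
  with the census model, with complete ground truth for recovery tests.

## Worked example

```python
import ducttrace as dt

data = dt.generate_dataset(dt.SyntheticConfig(), seed=1)
study = dt.CloneStudy(data.tree, data.cells, min_ca_level=7)
print(study.fit().summary())
```

```
Clonal lineage-tracing study
============================================================
Ducts: 3177   depth: 12
Cells: 760   clones: 24 (23 renewing, 1 non-renewing)

Potency of renewing clones (proportion +/- SEP)
     uni:  0.304 +/- 0.096   (n=7)
      bi:  0.348 +/- 0.099   (n=8)
   multi:  0.348 +/- 0.099   (n=8)

Co-labelled CAs: 0/23  C = 0.000  =>  P_merger ~ C/3 = 0.000

Subclone density growth: preferred model = linear (linear slope 0.0039/level)
Clone sizes: mean 33.0, exp decay scale 20.8, size~subtree Spearman rho = 0.20

Renewing tip progenitors per compartment (representative-
labelling assumption; flag = within endbud-size bound)
          acinar: N =   69.4   [ok]
         luminal: N =   57.4   [ok]
           basal: N =   26.3   [ok]
   myoepithelial: N =   22.1   [ok]
```

Reading the report: of 24 clones, 23 span more than one duct ("renewing",
i.e. their founders multiplied through endbud bifurcations) and split
roughly evenly between uni-, bi- and multipotent classes, each with its
standard error of proportion.  No CA endbud carried clones of two colors in
this small cohort, so the inferred merger rate is zero.  The subclone
density profile grows linearly with level distance from the CA — the
signature of progenitors mixing and segregating randomly at bifurcations
(coherent dispersion would grow exponentially).  The per-compartment
progenitor counts convert the clones' mean fractional contributions into
pool sizes; all fall below the ~117-cell endbud bound.

The closed-form merger model at the study scale (`N=112` endbud CAs at
risk, `M≈10` clones per color):

```python
from ducttrace.merger import MergerParams, merger_report
r = merger_report(MergerParams(N=112, M=10))
# P_c=0.0858  P_merger=0.0399  C=0.1303
```

A command-line interface mirrors the library: `ducttrace synth`,
`simulate`, `analyze`, `merger`, `census` and `run` (YAML-configured
end-to-end pipeline); see `ducttrace --help`.

## Documentation

`docs/methods.md` describes the models, their assumptions, all tunable
parameters with defaults and units, what the synthetic generator does and
does not emulate, and known limitations.
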