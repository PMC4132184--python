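# cohesion-screen

Statistics and plumbing for a common systems-biology workflow: deciding
whether the proteins that co-purify with a bait in a TAP-MS experiment
form a *real* physical module, and whether knocking them down
reproduces the bait's phenotype.

The package grew out of a C. elegans study design — a
spliceosome-associated bait (CACN-1), two bait purification replicates
plus an untagged negative control, a whole-proteome reference
interactome, and an RNAi screen scoring gonad-arm shapes for
distal-tip-cell (DTC) migration defects — but every stage is generic:

1. **Hit filtering** (`filter_candidates`) — keep a protein only if it
   was seen in ≥ 2 independent bait replicates, never in a control
   purification, and is on no contaminant blocklist; every decision is
   audited.
2. **Network assembly** (`build_seed_graph`, `expand_parsimony`) — the
   candidates' induced subgraph from a reference interactome, expanded
   to first-order neighbours that interact with ≥ 2 seed members
   (parsimony rule, single pass).
3. **PIE cohesiveness test** (`PieCohesion`) — is the gene set more
   internally connected than chance? With observed induced edges
   *e_obs* and a null of `n_rand` random gene sets matched for size
   and node-degree composition,

       PIE = e_obs / mean(e_null),   p = (1 + #{e_null ≥ e_obs}) / (1 + n_rand).

4. **Screen scoring** (`PhenotypeScreen`) — per-treatment Fisher exact
   tests of %-normal against control on five-category phenotype
   tables, with count reconstruction from printed percentages,
   significance tiers (p < 0.05, p < 0.0005) and a BH q column.

A synthetic-data module (`cohesion_screen.synth`) generates reference
networks with planted cohesive modules (degree-preserving rewiring, so
the degree-matched null stays honest), TAP-MS tables with shared
contaminant background, and multinomial phenotype screens — the whole
pipeline is testable offline.

## Worked example

The package bundles a DTC-migration RNAi screen table (integer
percentages over five gonad-arm outcome categories per knockdown).
Reanalysing it end to end:

```python
import cohesion_screen as cs
from cohesion_screen.datasets import INTERACTOR_IDS

records, roles = cs.load_dtc_screen()
res = cs.screen_summary(records, interactor_ids=INTERACTOR_IDS)
print(res.summary())
```

```
RNAi phenotype screen: Fisher exact tests vs control
============================================================
control: 101/102 normal
treatments tested: 11  unscored: 5
significant (tiers (0.0005, 0.05)): 9 of 14 screened interactors
significant outside interactor set: 2

 treatment  normal  defective     n  pct_normal  odds_ratio  p_two_sided      tier         q_bh
   W03H9.4    29.0       85.0 114.0   25.438596    0.003378 1.721454e-33 four_star 1.893600e-32
   C07A9.2    46.0       50.0  96.0   47.916667    0.009109 1.364703e-18 four_star 3.752932e-18
   ...
Y57A10A.19    96.0        8.0 104.0   92.307692    0.118812 3.509587e-02      star 3.509587e-02
```

Reading this: counts were reconstructed from the printed percentages
(control: 101 of 102 arms normal), each knockdown row was tested
against the control with a two-sided Fisher exact test on
normal-vs-defective, and 9 of the screened candidate interactors show
a significant DTC-migration defect — the bait knockdown itself
(`W03H9.4`) at the strongest tier, p < 0.0005. Five interactor
treatments arrested as larvae (`unscored`) and are excluded, not
counted as hits.

Cohesiveness of a gene set against a reference interactome:

```python
from cohesion_screen.synth import SynthNetworkConfig, make_planted_reference

net, members = make_planted_reference(
    SynthNetworkConfig(planted_size=27, planted_edge_multiplier=3.0, rng_seed=1)
)
print(cs.pie_analysis(net, members, n_rand=10_000, seed=1).summary())
```

```
Physical interaction enrichment (PIE)
==============================================
gene-set size                27
observed induced edges       56
null mean (SD)               0.948 (0.965)
PIE score                    59.0468
empirical p (add-one)        9.999e-05
random sets                  10000
degree matching              binned
seed                         1
```

The 27 planted-module genes induce 56 edges where degree-matched
random sets average ~0.9; the permutation p hits its 10,000-draw floor
(1/10,001, i.e. p < 0.0001).

There is also a CLI over the same functions:

```sh
cohesion-screen simulate network --seed 3 --planted-size 27 --out-prefix sim
cohesion-screen pie --reference sim_edges.tsv --reference-nodes sim_nodes.tsv \
    --nodes sim_module.tsv --n-rand 10000 --seed 1 -o pie.json
cohesion-screen run --config pipeline.yaml   # filter -> network -> PIE -> screen
```

See `docs/methods.md` for the models, defaults and limitations.

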