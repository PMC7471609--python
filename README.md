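# fluxkit

Condition-specific constraint-based simulation and multi-omics integration
for genome-scale metabolic models (GSMs) of *Clostridium thermocellum* and
similar fermentative anaerobes.  It is aimed at metabolic engineers and
systems biologists who need to (i) simulate fluxes under measured
fermentation constraints, (ii) train ATP-maintenance parameters from
extracellular flux datasets, (iii) confront proteomics fold changes with
simulated flux fold changes, and (iv) screen deletion mutants for
lethality and medium-supplement rescue.

## What it computes

All methods operate on the feasible flux space
`Ω_k = {v : S·v = 0, l_k ≤ v ≤ u_k}` of an SBML L3+FBC model, with
measured fluxes entering as `l = μ − σ`, `u = μ + σ` and gene deletions
zeroing the bounds of reactions whose GPR evaluates false.

* **FBA** — `max c·v over Ω_k` (HiGHS LP).
* **Quadratic pFBA** — `min Σ_j v_j² over Ω_k` (OSQP); strictly convex,
  hence a unique flux distribution with no growth pre-step.
* **Loopless FVA** — per-reaction `[v_min, v_max]`, with mixed-integer
  loop-law constraints excluding thermodynamically infeasible internal
  cycles; the interval midpoint (*FVA centre*) summarises range shifts.
* **GAM/NGAM training** — regress maximum ATP-hydrolysis flux on measured
  growth rate across conditions: the slope is the growth-associated
  maintenance (mmol ATP/gCDW), the intercept the non-growth-associated
  maintenance (mmol ATP/gCDW/h).
* **Fold-change omics integration** — simulated fold changes
  `FC_j = log2 floor(v_j,mut/|v_up,mut|) − log2 floor(v_j,wt/|v_up,wt|)`
  (ε = 1e-4 flooring) from pFBA fluxes and FVA centres; measured reaction
  fold changes as the mean gene log2-FC over each GPR; *consistent*
  reactions share a strict sign between measured and at least one
  simulated fold change; Pearson r is reported over the consistent set.
* **Phenotype screens** — mutant growth as percent of wild type (lethal
  below 20%), supplement rescues, and exhaustive single-reaction-deletion
  scans.

A deterministic fixtures module generates toy models (including a redox
core with ferredoxin/NAD(P)H pools, maturase-dependent hydrogenases and an
NADPH-consuming rescue route) and synthetic maintenance/omics datasets
with known ground truth, so the whole pipeline is testable offline.

## Worked example

Generate the redox toy fixture with its synthetic proteomics dataset, then
run the integration protocol and the mutant screens:

```sh
$ fluxkit fixtures omics --seed 1 --out demo
$ fluxkit model stats demo/toy_redox.xml
genes   13
metabolites     20
reactions       24
blocked_percent 0.0

$ fluxkit omics-fc demo/toy_redox.xml --wt demo/wt.yaml --mut demo/mut.yaml \
      --delete-genes hydG,ech --gene-fc demo/gene_fc.tsv --out records.tsv
# mapped=6/24 consistent=6 r_pfba=1.0 r_fva=0.5499542507363566

$ fluxkit screen growth demo/toy_redox.xml --condition demo/wt.yaml \
      --delete-genes hydG,ech,adhE
hydG+ech+adhE   wt=2.923        mut=0   percent=0.0     lethal=True

$ fluxkit screen rescue demo/toy_redox.xml --condition demo/wt.yaml \
      --delete-genes hydG,ech,adhE --supplement EX_kiv_e
hydG+ech+adhE + EX_kiv_e        percent=100.0   lethal=False
```

Reading the numbers: the synthetic proteomics table maps onto 6 of the 24
reactions, all 6 are sign-consistent with the simulated fold changes, and
because the planted gene fold changes equal the true simulated values the
pFBA correlation is exactly 1.  Deleting both hydrogenase routes (via the
shared maturase gene *hydG* plus *ech*) and the ethanol route leaves the
cell no electron sink, so growth collapses to 0% of the wild type
(lethal); opening ketoisovalerate uptake restores 100% of wild-type growth
through the NADPH-consuming isobutanol route — the in-silico analogue of
supplement rescue of a redox-blocked mutant.

The same commands accept a deposited genome-scale SBML model and real
condition/fold-change files; see `tests/test_deposited_model.py` for the
expected layout under `data/`.

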