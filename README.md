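# scpdyn

Tools for dissecting how a receptor-triggered whole-cell response —
neurite outgrowth (NOG) — is assembled from many interacting subcellular
processes (SCPs).  The package is aimed at systems biologists who have
time-resolved differential expression (RNA-seq and/or proteomics), a
leveled SCP ontology with horizontal interactions, fluorescence line
profiles from microfluidic outgrowth chambers, and want to go from gene
lists to context-specific SCP networks and to a mechanistic
vesicle-transport model of the growth process itself.

## What it computes

**Differential calling.**  DEGs by adjusted p ≤ 0.05 (FDR) and a
pseudocount-stabilized fold change log2((FPKM_treated+1)/(FPKM_control+1))
at a cutoff of ±log2(1.5) (stringent) or ±log2(1.3) (relaxed); DEPs by a
≥2-peptide filter, within-run normalization to untreated references, an
equal-variance two-sided t-test and a ±log2(1.1) fold-change cutoff.

**Standard and dynamic enrichment.**  One-sided Fisher exact tests of
up/down gene lists per time point against SCPs of a 1–4-leveled
ontology.  Dynamic enrichment additionally generates *function-specific
SCPs* — unions of 2–3 SCPs strongly connected by same-level horizontal
interactions (top 20% of level-2 strengths, top 25% of level-3) — ranks
singles and combinations together by p-value, keeps the top 3 (level 2)
or top 5 (level 3) predictions, and assembles them into SCP networks
with −log10 p timelines.

**NOG quantification.**  Fluorescence profiles are resampled to a 0.1 μm
grid; cell-body profiles undergo damage QC (highest strict-window peak
within 50 μm of the wall must reach ≥ 85% of the 100 μm-window maximum);
neurite profiles are normalized to the control mean at 100 μm, read out
at the distances where the control falls to 75/50/25%, cleaned with
Dixon's Q test (n ≥ 4, confidence 0.9), and classified per gene by
one-sample two-sided t-tests (significant: any p ≤ 0.05; may influence:
any p ≤ 0.1).

**Vesicle-transport model.**  A compartmental ODE model of membrane flux
from the TGN to the growth cone and back (budding limited by membrane
*and* cargo at the TGN, kinesin transport with a 10%-bound / 90%-reservoir
microtubule constraint, fusion, endocytosis, dynein return), plus a
closed-form flux-balance solution: given an outgrowth velocity v and a
membrane back-transport rate Q_back, the anterograde flux must satisfy
J_A = (2πr·v + Q_back)/a_v and every consumed v-SNARE/kinesin receptor
must be recycled at ≤ cap copies per retrograde vesicle, which yields the
required total copy numbers, a hyperbolic rise as Q_back falls, and a
stall threshold below which growth at v is infeasible.

A `synthetic` module generates every input — ontology files, expression
and proteomics tables, profile CSVs, model parameter sets — with seeded
determinism and ground-truth manifests.

## Worked example

```python
import math
from scpdyn.synthetic import (synth_ontology, synth_expression,
                              ExpressionSpec, expression_records,
                              default_model_params)
from scpdyn.diffexpr import call_degs, group_calls
from scpdyn.enrichment import dynamic_enrichment
from scpdyn.vesicle import analytic_parameter_solution

ontology, truth = synth_ontology(seed=0)
pair = truth["strong_pairs"][2][0]          # two strongly interacting SCPs
spec = ExpressionSpec(planted={(6.0, "up"): tuple(pair)},
                      planted_gene_fraction=0.4)
frame, _ = synth_expression(ontology, spec, seed=0)
calls = call_degs(expression_records(frame), min_abs_log2fc=math.log2(1.5))
up6 = group_calls(calls)[(6.0, "up")]
for rank, res in enumerate(dynamic_enrichment(up6, ontology, level=2), 1):
    print(f"rank {rank}: {res.unit_id:15s} overlap {res.overlap:2d}/{res.unit_size:3d} "
          f"p = {res.p_value:.3g}")

params = default_model_params("feasible", seed=1)
for q in (40.0, 15.0, 10.0):
    sol = analytic_parameter_solution(10.0, q, params)
    print(f"back rate {q:5.1f} um^2/h -> feasible={sol.feasible}",
          f"snares={sol.required_snare_total:.0f}" if sol.feasible else sol.detail)
```

prints

```
rank 1: L2_000+L2_006   overlap 12/ 30 p = 1.05e-23
rank 2: L2_000          overlap  6/ 15 p = 5.12e-11
rank 3: L2_006          overlap  6/ 15 p = 5.12e-11
back rate  40.0 um^2/h -> feasible=True snares=8364
back rate  15.0 um^2/h -> feasible=True snares=14400
back rate  10.0 um^2/h -> feasible=False recycling needs 12.42 snares per retrograde vesicle, above the per-vesicle cap of 12
```

Each planted SCP alone carries only a modest signal (6 of 15 genes in a
12-gene list), but their union explains the whole list, so the 2-SCP
combination outranks both singles — the mechanism by which dynamic
enrichment surfaces cooperating processes that standard enrichment would
rank individually.  In the model block, halving the membrane back
transport from 40 to 15 μm²/h nearly doubles the v-SNARE copies the cell
must hold, and below ~12 μm²/h a 10 μm/h outgrowth velocity becomes
infeasible: forward growth depends on membrane back transport because
back-moving vesicles are what return the fusion and motor proteins.

A command-line interface mirrors the library
(`scpdyn synth all --seed 0 --out fixture/`, `scpdyn deg call`,
`scpdyn nog test`, `scpdyn model scan`, ...).

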