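# treeot

Lineage-aware trajectory inference for single-cell time courses, built on
entropic optimal transport over lineage trees.

## The problem

A scRNA-seq time course samples *different* cells at each time point:
measurement is destructive, so the ancestor–descendant relationships
between an early sample {x₁,…,xₙ} and a late sample {y₁,…,yₘ} are lost.
State-based trajectory inference (Waddington-OT style) reconnects the two
snapshots by assuming cells move little between samples — it fails
wherever cells with similar expression have different histories, as in
convergent differentiation. CRISPR barcoding and invariant-lineage
organisms provide exactly the missing information: a lineage tree over
the late sample. `treeot` uses that tree to infer each late cell's
ancestor state and couples the samples through those inferred ancestors.
It is aimed at computational biologists analyzing scRNA-seq time courses
with lineage readouts, and at methodologists benchmarking trajectory
inference.

## The method

Cells follow a drift–diffusion process dXₜ = v(Xₜ)dt + √(2D) dBₜ in a
Euclidean state space. Two couplings are implemented as scikit-learn
style estimators:

* **`StateCoupling`** — entropic OT between the raw samples:
  γ = argmin Σᵢⱼ γᵢⱼ‖xᵢ − yⱼ‖² − ε H(γ), the maximum-likelihood coupling
  of a pure diffusion when ε = D(t₂−t₁).
* **`LineageCoupling`** — conditional on the lineage tree 𝒯 of the late
  sample, node states form a Gaussian graphical model whose precision is
  the tree Laplacian with edge weights 1/(D·|t_u−t_v|). Conditioning on
  the observed leaves gives each late cell j a Gaussian ancestor state at
  t₁ with mean μⱼ and variance σ²ⱼ; the coupling solves entropic OT with
  cost ‖xᵢ − μⱼ‖²/σ²ⱼ.

Supporting modules: `tree` (Hamming distances, neighbor joining, an
ultrametric branch-length correction solved as a QP, Newick I/O),
`evaluate` (exact discrete Wasserstein-2 ancestor/descendant prediction
errors against a ground-truth coupling), `simulate` (embedded lineage
trees: SDE + division + mutating barcodes, four benchmark scenarios),
and `prep` (time bins, partial-annotation strategies, reference-tree
ground truth). A `treeot` command-line tool wraps simulation, fitting,
evaluation and benchmarking.

## Worked example

Simulate a convergent trajectory (two clusters each split; two of the
four resulting clusters then merge), fit both couplings, and score them
against the simulation's ground truth:

```python
from treeot import (SimulationConfig, simulate_tree, StateCoupling,
                    LineageCoupling, evaluate_coupling)

cfg = SimulationConfig.for_scenario("convergent", seed=0)
sim = simulate_tree(cfg)
print(f"{len(sim.early_ids)} cells at t1={cfg.t1}, "
      f"{len(sim.late_ids)} cells at t2={cfg.t2}")

state = StateCoupling(epsilon=0.05).fit(sim.early_states, sim.late_states)
lineage = LineageCoupling(epsilon=0.05, t1=cfg.t1, t2=cfg.t2).fit(
    sim.early_states, sim.late_states, tree=sim.tree, cell_ids=sim.late_ids)

for name, est in [("state-only", state), ("lineage-aware", lineage)]:
    rep = evaluate_coupling(est.coupling_, sim.coupling_true,
                            sim.early_states, sim.late_states,
                            check_marginals=False)
    print(f"{name:14s} ancestor error {rep.ancestor_error_normalized:.3f}  "
          f"descendant error {rep.descendant_error_normalized:.3f}  "
          f"link accuracy {rep.link_accuracy:.3f}")
```

Output:

```
54 cells at t1=5.0, 200 cells at t2=7.0
state-only     ancestor error 0.095  descendant error 0.099  link accuracy 0.110
lineage-aware  ancestor error 0.050  descendant error 0.119  link accuracy 0.148
```

Errors are normalized by the noninformative independent coupling (1.0 =
no information, 0.0 = exact recovery). The merged late cluster mixes two
ancestries; the lineage tree halves the ancestor prediction error by
assigning each merged cell to the early cluster its relatives came from,
at a small cost in descendant error at this entropy level. `link
accuracy` is the probability mass placed on true ancestor–descendant
pairs.

The same comparison across an entropy grid, including a tree fitted from
simulated barcodes instead of the true tree:

```bash
treeot benchmark --scenario convergent --seed 0 --out scan/
```

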