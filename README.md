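# hypermotifs

Network motifs — small recurring subgraph patterns such as the
feedforward loop (FFL) or the toggle switch — are the building blocks of
directed networks in biology, neuroscience, engineering and language.
This package implements the next level of organization: **hypermotifs**,
arrangements in which two motifs are joined either by *sharing nodes* (a
**combination**, written `A{i}*B{j}`) or by *linking edges* (an
**interaction**, `A{i,j}+B{k,l}`). It is aimed at systems biologists and
network scientists who want to ask not only *which* motifs a network
uses, but *how those motifs are wired together* and *what dynamics
emerge* from the assembly.

## What it does

- **Combinatorics** — counts and enumerates all topologically distinct
  ways two motifs can be joined. Two motifs with `nA` and `nB` nodes can
  share `Nv` nodes with `1 ≤ Nv ≤ min(nA, nB) − 1` (each motif must stay
  an autonomous subgraph), and can be linked by up to `2·nA·nB` directed
  cross-edges, giving `2^(2·nA·nB)` labeled interaction topologies.
  Core combination topologies are deduplicated up to isomorphism: two
  FFLs combine in exactly **12** distinct ways, two mutual-feedback
  dyads in 1, a dyad and an FFL in 3.
- **Census** — exact enumeration of connected k-node subgraphs (ESU),
  exact canonicalization for k ≤ 4, and motif Z-scores against a
  degree-preserving edge-switching null.
- **Roles** — motif positions partitioned into automorphism orbits
  (FFL: input / intermediate / output; a 3-cycle: one symmetric role).
- **Enrichment** — the detection pipeline: Jaccard overlap
  `J(n_i, n_j) = |n_i ∩ n_j| / |n_i ∪ n_j|` between every pair of motif
  role node-sets (diagonals use the fraction of nodes repeating within a
  role), compared to 100 randomized networks that preserve N, E, every
  node's in/out degree **and the full 3-node subgraph census**;
  `Z = (J − mean)/sd`, one-sided normal p, Benjamini–Hochberg, calls at
  q < 0.05.
- **Dynamics** — Hill-function ODE models
  (`dX/dt = β·G(regulators) − α·X`, activation `Y^n/(k^n+Y^n)`,
  repression `k^n/(k^n+Y^n)`, AND/OR gates) for named circuits and their
  assemblies: toggle switch, Lock-ON, damped oscillator, coherent and
  incoherent FFLs, self-loop combinations, shared-edge loop pairs, and
  mutually interacting FFLs — with fixed-point classification,
  trajectory labeling (pulse / damped / sustained oscillation) and
  phase-synchronization metrics.
- **Synthetic + downsample** — seeded benchmark networks with planted
  motif combinations and ground-truth manifests, and the neighborhood
  random-walk downsampler for very large inputs.

## Worked example

Plant 40 FFL cascades (the output node of one FFL is the input of the
next) onto a sparse random background, then ask which role pairs overlap
more than the census-preserving null allows:

```python
from hypermotifs.census import named_motif
from hypermotifs.combinatorics import enumerate_combinations
from hypermotifs.synthetic import Planting, generate_planted_network
from hypermotifs.enrichment import detect_hypermotifs

ffl = named_motif("FFL")
patterns = enumerate_combinations(ffl, ffl)
print(f"{len(patterns)} core topologies for FFL*FFL")

cascade = next(p for p in patterns if p.notation == "FFL{output}*FFL{input}")
net, truth = generate_planted_network(
    200, 300, [Planting(cascade, 40, reuse="background")], seed=11)
records = detect_hypermotifs(net, n_random=100, alpha=0.05, seed=5,
                             motif_classes=[ffl])
for r in records:
    if not r.is_diagonal:
        print(f"{r.role_i[2]:>12s} ~ {r.role_j[2]:<12s} "
              f"J={r.jaccard:.3f} null={r.null_mean:.3f}+-{r.null_sd:.3f} "
              f"z={r.z:+.2f} q={r.q:.2e} {r.call}")
```

prints (about a minute; the 100-network ensemble dominates):

```
12 core topologies for FFL*FFL
      output ~ intermediate J=0.205 null=0.305+-0.041 z=-2.46 q=1.37e-02 under
      output ~ input        J=0.427 null=0.226+-0.033 z=+6.04 q=4.68e-09 over
intermediate ~ input        J=0.207 null=0.319+-0.045 z=-2.50 q=1.37e-02 under
```

The planted cascade pair (`output ~ input`) is strongly overrepresented:
its observed Jaccard overlap (0.427) far exceeds what networks with the
same degrees and 3-node census produce (0.226 ± 0.033). The two other
pairs come out *under*represented — cascades consume the role slots, so
alternative junctions occur less often than the census alone would
suggest. On the unplanted background the same pipeline makes no call.

The same steps are available from the shell:

```bash
hypermotifs combine-enum --motif-a FFL --motif-b FFL
hypermotifs synth --nodes 200 --edges 300 --plant "FFL.output*FFL.input:40" \
    --seed 11 --out net.tsv --manifest truth.tsv
hypermotifs detect net.tsv --nrand 100 --seed 5 --motif FFL --out records.tsv
hypermotifs simulate circuit.spec --x0 X=0.5 --tend 100
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-enumerates the core combination topologies of two coherent type-1
FFLs from scratch (shared-node counts 1 and 2, isomorphism and A/B
exchange deduplicated) and writes the count as JSON. It reads nothing
outside the repository.

## Layout

- `src/hypermotifs/` — `graphio`, `census`, `roles`, `combinatorics`,
  `enrichment`, `dynamics`, `synthetic`, `downsample`, `cli`
- `docs/methods.md` — model assumptions, null-model mechanics, fixture
  parameters, known limitations
- `tests/` — unit, property and end-to-end suites
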