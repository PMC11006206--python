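# fibersync

Graph fibrations, fiber building blocks and cluster synchronization in small
neuronal networks.

## What this package is for

Groups of neurons that receive *identical input histories* synchronize their
activity, whatever the details of their dynamics. The right formalism for
"identical input history" is the **input tree** of a node — the rooted tree of
all walks terminating at it — and the right symmetry is the **graph
fibration**: nodes with isomorphic input trees form a *fiber* and collapse
onto one node of a base graph. Fibers are found as the coarsest *balanced
coloring* (equitable partition): each color must receive the same
multiplicity of in-edges from every other color. Automorphism *orbits* are a
stricter symmetry (they also constrain outputs); every orbit sits inside a
fiber, but not conversely.

`fibersync` implements this program end to end for small circuits of the kind
found in the *C. elegans* locomotion connectome (directed chemical-synapse
networks of ~22–30 neurons, undirected gap-junction networks of ~20–29
neurons, integer synaptic multiplicities):

- **`graphs`** — integer-weighted directed multigraphs, edge-list/GraphML
  I/O, input trees, input-tree isomorphism, quotient (base) graphs.
- **`partitioning`** — minimal balanced coloring by iterated refinement;
  automorphism generators by backtracking search; orbit partitions.
- **`building_blocks`** — fiber building blocks (FBBs) and their fiber
  numbers |n, ℓ⟩: the branching ratio n (limit of input-tree layer-size
  ratios a_{i+1}/a_i, irrational for nested-loop "Fibonacci fibers") and the
  trail count ℓ; multilayer signatures |n₁, ℓ₁⟩ ⊕ |n₂, ℓ₂⟩ + …
- **`dynamics`** — admissible in-degree coupled ODEs (gap junction,
  sigmoidal chemical synapse, synaptic-variable chemical synapse), threshold
  equilibria, fiber-symmetric stimuli, RK4 integration with optional
  random-walk noise.
- **`stability`** — model Jacobians at the threshold equilibrium and
  eigenvalue sweeps over stimulus strength.
- **`sync_metrics`** — Level of Synchronicity (Gaussian-kernel) and Phase
  Locking Value matrices, ideal block matrices, difference scores, kernel
  calibration.
- **`synthetic_data`** — planted-fiber random lifts and worked-example
  fixtures, so everything is testable without connectome downloads.
- **`pipeline`** — the three simulation studies (free running, driven at 90%
  of the instability threshold, weight-perturbation robustness).

## Worked example

The nested-loop block with in-multiplicities C←M:1, C←P:2, M←C:1, M←P:2,
P←C:2, P←M:2 is the smallest interesting Fibonacci fiber:

```python
>>> import fibersync as fs
>>> net, _ = fs.fixture("cyan_multigraph")
>>> fs.build_input_tree(net, "C", 5).layer_sizes
[1, 3, 11, 35, 123, 403]
>>> round(fs.branching_ratio(net, "C"), 4)
3.3723
>>> fs.trail_count(net, "C")
6
```

The layer sizes obey t(n+3) = 9·t(n+1) + 8·t(n); their growth rate 3.3723…
(the real root of λ³ = 9λ + 8) is irrational, the signature of loops of
lengths 2, 3 and 4 nested through C. The six edge-simple trails into C are
M→C; P→C; M→P→C; P→M→C; P→M→P→C; M→P→M→C, so this block carries fiber
numbers |3.372, 6⟩. By contrast a hub fed by two independent sources is
|0, 2⟩, and a single fiber of four neurons wired in a bidirectional square
collapses to a doubling base, |2, 0⟩:

```python
>>> sq, part = fs.fixture("bidirectional_square")
>>> base = fs.quotient_graph(sq, fs.minimal_balanced_coloring(sq))
>>> fs.branching_ratio(base, base.nodes[0])
2.0
```

On the dynamics side, a fiber-constant state stays exactly fiber-constant
under any of the three models, and the Level of Synchronicity of two
trajectories a constant 0.1 mV apart at kernel scale σ = 0.1 mV is
exp(−1/2) ≈ 0.61 — the calibration used to read the LoS matrices.

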