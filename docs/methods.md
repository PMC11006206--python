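# Methods

## Graph model

Networks are directed multigraphs over string-labelled neurons with positive
integer edge multiplicities (synaptic contact counts). Gap-junction networks
are undirected; an undirected edge is stored as two opposed directed edges of
equal weight, so every algorithm reasons about in-edges only. A *binary*
view clamps multiplicities to 1; both views are supported because the
partition structure of a circuit should not depend on which one is analysed
when weights are assigned per fiber pair (a property the tests check on the
planted fixtures). Real-valued weights appear only after the controlled
perturbation used in the robustness study; all symmetry analysis runs on the
unperturbed integer network.

## Input trees and fibers

The input tree of a node v is the layered multiset of all walks terminating
at v; layer i holds a_i entries, one per walk of length i. Layers are stored
as node→count tables, so a_60 on a block growing at ratio 3.37 is an exact
integer rather than an enumeration of ~10³¹ tree nodes.

Two nodes belong to the same fiber when their input trees are isomorphic;
depth n−1 suffices to decide this. Isomorphism is decided by canonical
bottom-up color refinement rather than explicit bijection search: starting
from a single color, each round recolors nodes by their **total in-multiplicity
per (color, sign) class**. Aggregating totals (not per-edge multisets) is
essential — one edge of weight 2 contributes two indistinguishable child
subtrees, exactly like two single edges from same-colored tails — and makes
the stable partition of the refinement coincide with input-tree-isomorphism
classes, i.e. with the coarsest balanced coloring. Refinement is monotone and
stabilizes within n rounds; nodes are processed in sorted order so results
are reproducible.

Automorphisms are found by an in-house backtracking search along a
stabilizer chain: for each node v in order and each candidate u compatible
with a symmetric (in+out) refinement coloring, one automorphism fixing all
earlier nodes and mapping v→u is sought; the transversal elements collected
this way generate the full group. Orbits are the connected components of
node→image links over the generators (group closure adds no components).
The search is intended for ≤64 nodes — comfortably above the ~30-neuron
circuits it targets — and refuses larger inputs explicitly. An adapter seam
(any generating set can be fed to `orbit_partition`'s union-find) allows
plugging a faster engine.

## Fiber building blocks and fiber numbers

For each fiber, the building block is synthesized in the total space from
four rules: the fiber's nodes; their immediate in-neighbors (regulators);
the shortest non-self loops through a fiber node (all tied witnesses
included, with deterministic BFS tie-breaks); and, when those rules leave the
subgraph disconnected, the shortest bridging paths (such blocks are labelled
*composite*). Fiber numbers are computed on the block's base:

- **n**, the branching ratio, is the spectral radius of the weighted
  in-adjacency restricted to nodes that can reach the root (0 for finite
  trees). Raw consecutive layer ratios oscillate (3.18, 3.51, 3.28, … on the
  worked nested-loop block), so the eigenvalue is cross-validated against a
  12-step geometric mean of layer sizes at depth 60, which cancels any
  periodic modulation of period dividing 12; disagreement beyond the
  tolerance (default 10⁻³ relative) raises a diagnostic error.
- **ℓ**, the trail count, is the exact number of edge-simple trails
  terminating at the root, enumerated by depth-first search on the simple
  (multiplicity-ignored) base **with the root's out-edges removed**. The
  convention matters: trails through the root would otherwise be counted for
  blocks whose root sits on loops, and the removal convention is the one that
  reproduces the worked enumeration (six trails into C). Enumeration is
  capped at 64 edges.

Classification: *finite* if n = 0; *n-loop* if n is within 10⁻⁶ (relative)
of an integer ≥ 1; *Fibonacci* otherwise (irrational growth from nested
loops); *composite* overrides when the bridging rule fired.

Multilayer signatures lay the circuit's fibers out by backward BFS distance
from the main fiber, each fiber appearing once at its shallowest layer, with
⊕ between layers and + within a layer. Fibers whose elementary block has no
edges (pure sources) are skipped: their entire contribution to the topology
is the regulator trail already counted in ℓ one layer down. This convention
renders a two-source hub as a single layer |0, 2⟩ and the two-looping-fiber
chain as |1, 1⟩ ⊕ |1, 2⟩.

`fibonacci_base_collapse` quotients a block's base by its own minimal
balanced coloring and asserts the dominant eigenvalue is preserved — the
worked nested-loop block collapses to a two-node base with a self-loop and
the same ratio 3.3723.

## Admissible dynamics

Three in-degree coupled models share the leak f(V) = −α_leak (V − V_rest):

- gap: V̇_i = f(V_i) − α_gap Σ_j Ã_ji (V_i − V_j) + α_ext I_i
- chem I: coupling Φ(V_j)(V_i − V_s,j) with sigmoid Φ
- chem II: coupling s_j (V_i − V_s,j), ṡ_i = a_r Φ(V_i)(1 − s_i) − a_d s_i

Defaults (units mV, s, pA, pF): α_leak = 10 s⁻¹, α_gap = α_chem = 100 s⁻¹,
α_ext = 1 pF⁻¹ (so 1 pA shifts V̇ by 1 V/s), V_rest = −37 mV, γ = 125 V⁻¹
(the 0.1→0.9-over-36-mV formula gives ≈122 V⁻¹ and is available),
a_r = 1 s⁻¹, a_d = 5 s⁻¹, hence s_eq = a_r/(a_r + 2a_d) = 1/11 ≈ 0.09. All
chemical edges are excitatory (V_s = 0 mV) unless an edge sign or a
per-neuron override selects the inhibitory reversal (−70 mV). Per-neuron
parameter heterogeneity and synaptic delays are out of scope by design.

The sigmoid is centered per neuron on the **threshold voltage**: the solution
of the steady-state linear system obtained by freezing Φ at 0.5 (and s at
s_eq for chem II) with I_ext = I_drive. For chemical models the system is
diagonal; gap coupling contributes the off-diagonal Laplacian part. The
solver refuses condition numbers above 10¹². By construction, plugging the
threshold state back into the right-hand side gives a residual at round-off
level — a self-consistency the tests assert — and any fiber-symmetric
stimulus admits an exactly fiber-synchronous solution.

Integration is classic RK4, default dt = 0.1 ms. Noise stimuli are Gaussian
random walks, one path per targeted fiber when sharing is on (preserving the
coloring's input symmetry), min–max rescaled into ±noise_scale per run and
held constant across the four stages of each step; the deterministic drive
and oscillation are evaluated at exact stage times. Runs are bit-reproducible
per seed, and the integrator aborts with the first non-finite step on
divergence. Initial conditions default to V_rest (and s_eq); the simulation
studies use −35 mV by convention, which is a separate knob from V_rest.

## Stability

Jacobians are evaluated at the threshold equilibrium, where Φ = 0.5 and
Φ′ = γ/4. The gap Jacobian −α_leak I − α_gap L is stimulus-independent and
negative definite for the default rates, so gap circuits are stable under
any drive. The chem I Jacobian carries the stimulus through the equilibrium
voltages in its off-diagonal Φ′-terms; the chem II Jacobian is the 2n×2n
block matrix whose ∂V/∂s block is −α_chem Ã_ji (V_i − V_s,j), with the
remaining blocks obtained by differentiating the model (all blocks are
verified against central finite differences at 10⁻⁶ relative tolerance).
"Positive eigenvalue" means real part > 10⁻⁹. The sweep walks a stimulus
grid on both signs, recomputes the equilibrium and the leading eigenvalue at
each point, and refines the first crossing by bisection to 0.01 pA. On the
mutually-coupled pair the crossing has a closed form (the off-diagonal term
overwhelming the leak), which the tests use as an oracle, and simulations
10% above/below the detected threshold show/preserve the left-right voltage
bifurcation.

## Synchrony metrics

LoS_ij is the mean over the analysis window (default: final 1 s) of
exp(−(V_i − V_j)²/2σ²); σ = 0.1 mV is the operating point, at which a
constant 0.1 mV offset scores ≈0.61. The first window sample is included.
Calibration descends a decade grid from 10 mV and returns the largest σ at
which the mean cross-fiber LoS drops below 0.001 (grid configurable;
degenerate single-fiber partitions return the grid maximum with a warning).
Binarization maps entries ≥ 1 − ε to 1 with ε = 0.005 — an exact "round
below 1 to 0" is ill-posed for floats — and the difference score subtracts
the binarized observation from the ideal block matrix, sums off-diagonal
entries and divides by 2(n² − n): zero is perfect fiber agreement, negative
flags extra cross-fiber synchrony (not an error of the prediction), positive
flags missing within-fiber synchrony. PLV uses the analytic-signal
instantaneous phase of mean-removed traces (the extraction method is this
package's choice, not a constraint of the formalism).

## Synthetic study networks

The real repaired locomotion sub-networks are not redistributable, so the
generator emulates their statistics: a base graph on k cells with integer
multiplicities is lifted so every node of cell i receives exactly B_ji
in-edges from cell j. Because a lift preserves input trees, the planted
partition is guaranteed to be the minimal balanced coloring whenever the
base's own coloring is discrete; the generator certifies this on every draw
(directed draws resample on failure, up to a cap). Directed lifts sample
tails uniformly per seed; undirected lifts use deterministic circulant
(within-cell) and round-robin (between-cell) wirings chosen so that a
simultaneous cyclic rotation of every cell is an automorphism — hence fiber
= orbit on every undirected draw, mirroring the gap-junction circuits. The
`*_like` fixtures instantiate the connectome's node/fiber counts (22/4 and
30/10 directed; 20/6 and 29/6 undirected, one singleton fiber, left-right
interneuron pairs as their own size-2 cells, nested-loop interneuron cores
feeding motor fibers). They are synthetic stand-ins: they reproduce the
sizes, symmetry structure and weight ranges of the study circuits, not their
anatomy, so passing tests certify the machinery, not statements about the
worm. Weight perturbation subtracts N(0, std²) from every weight
independently (std grid 0–0.1), preserving edge support.

## Simulation studies and problem sizes

Study 1 (free running) draws initial voltages around the resting potential
over a spread grid and checks the LoS block structure against the coloring;
fibers may additionally synchronize with each other, which is reported, not
failed. Study 2 drives the marked interneuron-pair fiber at 90% of the
swept instability threshold with a 5% oscillation (2 Hz; gap circuits get a
second 1 Hz motor-fiber channel, without which they stay globally
synchronous). Study 3 jitters weights over the std grid with several seeds
per level under the fixed drive 0.1 pA + 0.5 pA oscillation + ±0.01 pA
noise (max amplitude 0.61 pA, asserted), averages LoS per level and tracks
the masked within-block difference; PLV typically stays high within fibers
after the strict LoS has collapsed.

Library defaults match the study conventions (5 s runs, dt = 0.1 ms, 10
repetitions, std grid 0–0.1 in 0.01 steps). The test suite and the
acceptance script run the same code at reduced sizes — 1–2 s horizons,
dt = 1 ms, a few repetitions and grid points — which this package treats as
its desk-scale configuration; RK4 at dt = 1 ms is well inside the stability
region of the default rates, and the invariance checks hold at round-off
level there.

## Known limitations

- The automorphism search is exponential in the worst case; it is meant for
  the ≤64-node regime and prunes with refinement colors only.
- Trail counting is exact enumeration; blocks with more than 64 base edges
  are refused rather than approximated.
- The stochastic integrator's stage treatment of noise (piecewise constant
  per step) is first-order in the noise; it is adequate for the small
  bounded random-walk stimuli used here, not a general SDE scheme.
- `sweep_instability` reports the first crossing per sign; it does not
  classify bifurcation types or continue branches.
- Rectifying gap junctions, synaptic delays and per-neuron parameter
  heterogeneity are deliberately unsupported.
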