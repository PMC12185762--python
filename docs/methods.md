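# Methods

## The model

`epimech` simulates a proliferating epithelial monolayer containing stiff,
non-dividing multiciliated cells (MCCs) as a two-dimensional vertex model,
and quantifies the mechanical signature such cells imprint on their
neighbourhood, alongside analysis procedures for macropinocytosis
event/track data measured on segmented tissue.

### Mesh and topology

The monolayer is a simply connected patch of polygonal cells stored as
vertex positions plus two signed incidence matrices: `A` (edges × vertices,
one −1 tail and one +1 head per row) and `B` (cells × edges, ±1 for the
traversal direction of each cell's counter-clockwise boundary loop).
`B·A = 0` expresses that every cell boundary is a closed loop; together with
per-edge cell counts (interior edges border exactly two cells, boundary
edges one) and the disc Euler relation `V − E + C = 1`, this is the
invariant checked by `validate_topology` and preserved by every mutating
operation (cell division, T1 neighbour exchange, boundary-edge collapse).

Coordinates are nondimensional: the unit of area is the bulk preferred cell
area `A0 = 1`, and all lengths scale accordingly.

### Constitutive law

Forces are logarithmic in the strains.  A cell `i` with area `A_i`,
perimeter `L_i` and stiffness prefactor `σ_i` exerts

- internal pressure `p_i = −σ_i ln(A_i/A0_i)` (positive when squeezed below
  its preferred area), and
- cortical tension `t_i = σ_i Γ ln(L_i/L0)`,

with `Γ` the relative cortical stiffness and `L0` the preferred perimeter, a
bare length in units where `A0 = 1`.  Both forces derive from the potential

```
E = Σ_i σ_i [A_i ln(A_i/A0_i) − A_i + A0_i]
  + Σ_i σ_i Γ [L_i ln(L_i/L0) − L_i + L0]
  + P_ext · (total monolayer area)
```

whose bracketed terms are non-negative with their minima at the preferred
values, so `∂E/∂A_i = −p_i` and `∂E/∂L_i = t_i`.  The uniform external
pressure `P_ext` enters as an energy proportional to the total tiled area,
equivalently an inward traction on boundary edges.  MCCs differ from bulk
cells only in `σ` (σ = 10 in the main condition, multiplying both pressure
and tension) and in being barred from division.

Defaults put the tissue in the jammed, solid-like regime: `Γ = 0.2`,
`L0 = 0.75`, `P_ext = 0.5`.  The exact logarithmic form is this package's
defining contract; other nondimensionalisations of "logarithmic force–strain"
exist, so absolute stress magnitudes should not be compared across codes,
while the qualitative neighbourhood contrasts are robust to this choice.

### Dynamics

Vertices follow overdamped gradient descent `x ← x + (dt/η) F` with
`F = −∇E` assembled analytically through the cell boundary loops (verified
against central finite differences to a relative error below 1e-5).  The
step is adaptive: a trial step that raises the energy is rejected and `dt`
halved; ten consecutive accepted steps grow `dt` by 1.1× (capped at 0.5).
Energy is therefore non-increasing across accepted steps, and relaxation
terminates when the largest vertex force drops below `force_tol` (default
1e-6; the scaled test profile uses 1e-4) or a step budget is exhausted
(flagged, never raised).

Topological moves during relaxation:

- **T1 exchange** — an interior edge shorter than `t1_threshold = 0.05`
  between two three-fold vertices is rotated 90° about its midpoint, set to
  1.5× the threshold, and its two former cells lose adjacency while the two
  flanking cells gain it.
- **Boundary collapse** — a boundary edge squeezed below the threshold by
  the external pressure has no T1 partner; its endpoints are fused at the
  midpoint (V and E each drop by one, preserving the Euler relation).
  Without this move the relaxation stalls on the kink such an edge creates.

**Division**: when a cell's age exceeds its cycle time it is split by a
chord through its centroid perpendicular to its long axis (principal axis of
the polygon's second area moment; the conventional shortest-axis rule).
Daughters get age 0, `A0 = 1` immediately, inherit `σ` and flags, and redraw
their cycle time from `cycle_time · U[1−j, 1+j]` with `cycle_time = 1`,
jitter `j = 0.2`.  Founder ages are drawn uniformly on `[0, cycle_time)` so
the population divides asynchronously.  Divisions are processed one at a
time in age order, so cell-count thresholds are hit exactly.

### The experiment

One protocol run grows the 61-cell regular hexagonal patch to 400 cells,
assigns MCC identities, continues to 800 cells, stops all division, and
relaxes to equilibrium; ensembles run 10 replicates with consecutive seeds.
MCC placement draws uniformly from the non-peripheral cells, removing each
chosen cell's first, second and third topological neighbour shells from the
pool until the pool empties — a maximal selection in which any two MCCs are
separated by at least three intermediate cells.  Spacing is guaranteed at
introduction and only logged if later rearrangements violate it.  A named
scaled profile (rings = 3, 100 → 200 cells) provides the same experiment at
test size.

During growth, relaxation runs to a looser tolerance (1e-3) with a bounded
step budget per division; only the final state is equilibrated tightly.
This quasi-static-but-not-adiabatic growth is a deliberate trade-off;
tightening it changes individual realisations but not the neighbourhood
statistics systematically.

### Stress measures and enrichment statistics

The per-cell stress tensor is

```
S_i = −(p_i − P_ext)·I + (1/A_i) Σ_{e∈i} t_i (ℓ_e ⊗ ℓ_e)/|ℓ_e|
```

Its isotropic pressure part, `−(p_i − P_ext)`, is reported as the
**effective pressure**: zero for a bulk cell in equilibrium with the
external load, negative for cells compressed below that point.  The most
compressed cells therefore sit in the *lowest* decile of effective pressure.
**Shear stress** is half the difference of the principal values,
rotation-invariant and non-negative.  **Tension** is `t_i` itself.

Cells are grouped as MCC / MCC-adjacent (sharing an edge with an MCC) /
non-adjacent, with peripheral cells excluded outright.  Within each
replicate, the decile cut is the pooled 90th (or 10th) empirical percentile
over adjacent ∪ non-adjacent cells (linear interpolation; values exactly at
the cut are not beyond it), and each group's fraction beyond the cut is
recorded.  Replicates are the unit of analysis: the adjacent vs non-adjacent
fractions are compared across the ensemble with a classical two-sided paired
t-test.

At the full protocol size this reproduces the designed contrast: MCC
neighbours are enriched in the lowest decile of effective pressure and of
tension and in the highest decile of shear (all p < 0.05 across 10
replicates).  At the 200-cell scaled profile the *direction* of all three
enrichments is robust (≥9/10 repeat ensembles), but each replicate carries
only ~5 MCCs (~25 adjacent cells), so joint significance of all three
metrics is not reliably available at that size — a statistical-power
limitation of the scaled profile, not of the effect.

### Junction-tension inference

Relative junction tensions are inferred from geometry alone, in the style of
CellFIT restricted to its tension terms: at every interior node of the
junction network (degree ≥ 3; two-fold points are pass-through points of a
junction curve; boundary-touching nodes are excluded because substrate
forces are unknown there) force balance `Σ_j t_j û_j = 0` contributes two
rows, with `û_j` the unit tangent of the first straight segment directed
away from the node.  The homogeneous least-squares system is solved under
the normalisation `mean(t) = 1` via its KKT equations; junctions touching no
interior node are unconstrained and reported as NaN, and rank deficiency
beyond the global scale is flagged.  Curved-interface and Laplace-pressure
terms of the full CellFIT formulation are omitted — the quantity of interest
is relative junctional tension.

Junctions are ranked N1–N4 by contiguity from a macropinocytotic event (N1 =
the event's junction(s), N2 = junctions sharing a node with N1, …, first
label wins), and before/after ratios average the per-ring mean tension over
1–4 frames on each side.

### Known-tension oracle geometries

Validating the inference needs geometries whose true tensions are known
*exactly*.  A generic random tension field on a network with a pinned
boundary admits no straight-edge equilibrium (balance at trivalent nodes
fixes the junction angles, which a generic field cannot satisfy globally —
attempting to relax such a network collapses 20–40% of its edges).  The
generator instead uses the Maxwell reciprocal property of Voronoi
tessellations: at every interior Voronoi vertex, tensions equal to the dual
Delaunay edge lengths balance exactly, because each Voronoi edge is
perpendicular to its dual edge and a triangle's sides sum to zero.
Generator points are adjusted by least squares so the Delaunay edge lengths
rank-match a lognormal sample (mean 1, CV 0.3), and the **achieved** lengths
of the final triangulation are returned as the truth, keeping the balance
residual at machine precision (~1e-13, contract < 1e-8).  The achieved CV is
~0.25 when targeting 0.3: the length distribution of a triangulation cannot
be deformed to an arbitrary target.  At CV = 0 the exact triangular lattice
is used (uniform lengths, honeycomb diagram).  Inference on these geometries
recovers the truth with Pearson r ≈ 1.0.

### Event and track analysis

The event quantifications operate on an event table (host cell, onset,
duration, peak ruffle area, junctional/medial location, MCC-adjacency class)
and uniform-interval tracks of per-cell apical area and per-junction length.
Conventions: an event "ends" at onset + duration rounded to the nearest
frame; the per-event area loss is measured from the onset frame to the end
frame, and events overlapping another event of the same cell are dropped
from the loss/size correlation (no clean attribution).  Fold changes are
`log2(after/before)` with no pseudocount — a zero basal count is an error,
mirroring the requirement of an adequate basal recording.  The remodeling
index is, per time bin (default 2 min), the mean over cells of
`|ΔA|/A_start` in percent — purely area-based, hence insensitive to rigid
motion — reported alongside the number of events *active* in the bin.  The
post-extrusion comparison counts events within 10 min among direct former
neighbours vs cells within twice the mean neighbour-centroid distance
(the dimensionally ambiguous "radius twice the neighbour area" is read as a
length); control alignment times for synchronised traces and control windows
for junction changes are cycled deterministically through the observed event
times rather than drawn at random.

### Synthetic data generation

`gen_tissue` emulates a segmented epithelial field: Poisson-disc points,
Voronoi tessellation clipped to a disc, three Lloyd iterations, mean cell
area 412 µm² (so that a 94 µm² ruffle is ~23% of a cell), with optional
MCC labelling by the same exclusion-radius rule as the simulation.
`gen_events` draws events per cell as a Poisson process (default 0.15
events/cell/hour, ×2 for MCC-adjacent cells; MCCs never host events), with
truncated-normal durations (9.3 ± 2.3 min, > 1 min) and peak areas (94 ± 36
µm², bounded by the host area), fractional area loss
`0.10 · peak/94 + N(0, 0.046)` ramped linearly over the event and permanent
thereafter, a 10% shortening of one host junction for junctional events, and
0.5% multiplicative per-frame measurement noise.  The loss-noise SD 0.046
was calibrated once, analytically, so the loss/size correlation at n = 43
events centres near r² = 0.4: with `Var(0.1·X/94) = (0.1·36/94)²` and
measurement noise ~5e-5, `r² = 0.00147/(0.00147+0.046²+5e-5) ≈ 0.40`.
`gen_compression_wave` produces a Gaussian pulse of events in time (2
expected events/cell, ≥80% of cells host one), optional extrusions whose
former neighbours have their post-extrusion event rate suppressed ×0.3, and
an inhibitor mode (rate ×0.1, extrusions ×3).

What the generators deliberately do not emulate: pixel-level segmentation
error, drift and tracking failures, cell division or shape change during
recordings, spatial correlation of event timing beyond the adjacency-rate
bias, and curved junctions.  Passing the recovery tests therefore shows the
estimators are correct and well-calibrated for data with the stated
statistical structure, not that they are robust to segmentation artefacts.

## Problem sizes and determinism

Unit tests run on 19–120-cell meshes; the ensemble statistics use the
200-cell scaled profile (10 replicates per ensemble) plus one full-size
ensemble; tension recovery uses twenty ~50-cell geometries; event recovery
uses a 300-cell field at the measured sample sizes (n = 43 cells, 40
junctions, 90 ruffles, ~191 events).  Every stochastic component draws from
a named stream derived from one user seed (`SeedSequence([seed,
crc32(name)])`), so adding an analysis step never perturbs the simulation
trajectory, and repeated runs are bit-identical.

## Known limitations

- Absolute stresses depend on the package's specific logarithmic
  nondimensionalisation; only relative/qualitative contrasts are portable.
- The simulator has no apoptosis/extrusion, no active junction
  fluctuations, no curved substrate, and open (non-periodic) boundaries.
- The tension inference ignores interface curvature and pressure; on curved
  real tissue it inherits CellFIT's corresponding bias.
- The scaled 200-cell profile underpowers the three-way significance test
  (see above); use the full profile for inference-grade statistics.
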