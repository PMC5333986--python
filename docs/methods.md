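# Methods

## Model

The package treats humoral immunity as a homeostatic control problem in
two coordinates per interaction: free antibody (paratope) concentration
[Ab] and dissociation constant K_D, both molar.  All binding is
single-site mass action at equilibrium,

    K_D = [Ab]·[Ag]/[AbAg],   saturation = [Ab]/([Ab] + K_D),

so [Ab] = K_D marks 50% saturation of an epitope.  Kinetics (on/off
rates), avidity and valence are out of scope: inputs are *apparent* K_D
values, and [Ab]/[Ag] are paratope/epitope concentrations as given — the
package never converts immunoglobulin molarity to paratope molarity
(valence 2 for IgG, 10 for pentameric IgM would be the user's
conversion).  A single well-mixed fluid compartment (blood plasma) is
assumed.

### Competitive equilibrium

For clones i and epitopes j with totals A_i, G_j and affinity matrix
K_D(i,j) (absent entries = +inf = no binding, always excluded from sums
rather than represented by large floats), the free concentrations solve

    ab_i = A_i / (1 + Σ_j g_j / K_D(i,j)),
    g_j  = G_j / (1 + Σ_i ab_i / K_D(i,j)),

with complexes c_ij = ab_i·g_j/K_D(i,j).  The solver iterates both
relations Jacobi-style with geometric-mean damping (factor 0.5 in log
space), declares convergence when the largest relative change drops below
1e-12 (cap 1e5 iterations), then always attempts a Newton refinement
(scipy's hybrid Powell method on log-concentrations) and keeps whichever
iterate has the smaller conservation residual.  A state is returned only
if the relative residual is below 1e-9; otherwise a solver error carries
the residual.  On random dense systems up to 50×50 with totals and K_D
log-uniform over 1e-12..1e-4 M the measured residuals are ~1e-15 and the
1×1 case agrees with the conservation-quadratic closed form to ~1e-14
relative.  The pairwise closed form uses the numerically stable root
c = 2AG/(S + sqrt(S² − 4AG)), S = A+G+K, which is exact in both the weak
and stoichiometric limits for the complex; note that the free
concentration of a nearly exhausted species is recovered accurately by
the system solver but suffers cancellation in the closed form.

### Network semantics

* Node = set of clones with an identical binding profile (the network
  counts distinct antigen-binding properties); the node id is the
  smallest member clone id.  A flag (`merge_identical=False`) keeps one
  node per clone, in which case identical profiles join by a
  zero-weight edge.
* Node radius = antigen-binding capacity [Ab]_free/K_D at the *cognate*
  epitope (the clone's lowest K_D; ties break to the smallest epitope
  id).  For a merged node the members' free antibody sums over the shared
  cognate K_D.  Aggregating capacity over all bound epitopes is a
  possible extension, not implemented.
* Distance(i,j) = mean over shared bound epitopes of |pK_D_i − pK_D_j|,
  pK_D = −log10 K_D.  "Bound" means K_D ≤ binding cutoff (default 1e-4 M,
  the weakest natural-antibody affinity).  A linear-scale variant (mean
  |K_Di − K_Dj| in molar) exists for comparison but is dominated by the
  strongest binder across six decades, so the log form is canonical.
  The distance is symmetric with d(i,i) = 0 and satisfies the triangle
  inequality only for triples sharing one common epitope set; with
  varying shared sets it is not a global metric, and no global metric
  property is asserted.
* Edge iff the two nodes share at least one bound epitope *and* their
  distance is at most the distance cutoff (default 3 pK_D units, an
  exposed parameter — some cutoff is needed for disconnection to be
  expressible on a continuous distance).
* Giant component = largest connected component by node count (ties to
  the component holding the smallest clone id); its member clones are
  the immunological self.  Everything else is extruded.

### Response rules

* TI: ab_total ×= fold (fold > 1); no K_D changes, hence bitwise-identical
  edge weights.  Long-lived plasma cells may be TI-boosted.
* TD: cognate K_D ×= 10^(−delta_pkd), floored at 1e-11 M (affinity
  maturation has physical limits); every non-cognate K_D ×=
  10^(+polyreactivity_decay); entries weakened past the binding cutoff
  are dropped.  Defaults delta_pkd = 1 and decay = 0.5 per step; how much
  polyreactivity is lost per maturation step is not empirically
  constrained, so the decay is an explicit knob.  Cognate identity is
  re-evaluated after the step.  Long-lived plasma cells reject TD and
  regulation (frozen-clone error): their interactions are hardwired.
* Regulation: multiplicative bisection on ab_total in log10 space until
  |log10(ab_free/K_D_cognate)| < tolerance (default 0.01, ≤ 200
  iterations).  The bracket is analytic — ab_total = K_D can only
  undershoot, ab_total = K_D·(1 + Σ_e G_e/K_D(e)) can only overshoot —
  so the controller converges in a few dozen solves; an unreachable
  target returns the best-effort state with a warning.  Regulation is
  single-clone; cooperative cluster-level control is expressed by
  regulating several clones sharing an epitope.
* Antigen challenge: scales an existing epitope's total or adds a new
  (non-self) epitope with supplied per-clone affinities, after which
  cognate identities may change.
* Time is event-ordered logical time; the system is re-equilibrated and
  the network rebuilt after every event.  No ODE kinetics are modeled —
  the model specifies equilibrium states and discrete response types.

### Landscape

Log-spaced [Ab] × K_D grids (default 1e-12..1e-4 M per axis, covering the
printed 1e-4..1e-10 M interaction range with margin) carry saturation and
a zone label: release (< 0.1), control, eliminate (> 0.9).  Only the 50%
set point is model-fixed; the 0.1/0.9 borders are exposed defaults.
Response-type annotations (natural/TI at K_D 1e-4..1e-6 M, TD at
1e-8..1e-10 M) are containment-only rectangles; their [Ab] spans are
schematic defaults.

## Synthetic repertoire generator

The generator emulates a natural (B1/MZ, IgM) repertoire in a latent
Euclidean shape space (default 2-D unit hypercube; the space exists only
inside the generator — the network never sees coordinates):

| parameter | default | meaning |
|---|---|---|
| n_clusters × clones_per_cluster | 5 × 8 | clonally related groups (shared heavy chain) |
| n_epitopes | 40 | self epitopes, uniform in the hypercube |
| cluster_spread | 0.05 | latent sd of clones around their centroid |
| affinity_decay | 2.0 | pK_D lost per latent distance unit |
| kd_cognate_range | 1e-6..1e-4 M | natural-antibody affinity range |
| cognate_jitter | 0.25 decades | within-cluster spread of cognate K_D |
| kd_cap | 1e-4 M | weakest stored interaction |
| ab_total_range | 1e-12..1e-8 M | per-clone antibody (log-uniform); the floor is the order of a single plasma cell's continuous secretion, an invented default |
| ag_total_range | 1e-6..1e-4 M | abundant self antigen (log-uniform) |
| mz_fraction | 0.2 | MZ vs B1 cell type assignment |

A clone's K_D to epitope e is cognate K_D × 10^(affinity_decay·(d_e −
d_min)); entries above kd_cap are dropped, so polyreactivity is one
exponential-decay parameter.  Cognate affinities are hierarchical:
a cluster-level base K_D (log-uniform over the jitter-shrunk range) with
per-clone jitter of ±0.25 decades, so cluster mates sit close on the
affinity axis as well as in shape space — with fully independent per-clone
cognate draws, the kd_cap truncation compresses distant pairs' shared
affinities toward the cap and intra-cluster distances would not be
smaller than inter-cluster ones.  Concentration draws are log-uniform
because the ranges span several decades.

With these defaults the repertoire is in the weak-coupling homeostatic
regime: total antibody (≤ ~4e-7 M summed) binds a small fraction of
abundant antigen (≥ 1e-6 M per epitope), every B1/MZ node radius is ≪ 1
(shared TI production), the graph has a single giant component, and six
default TD steps extrude a clone.  Consequences for testing: the TI rule
"only the boosted node's radius changes" is exact only in the uncoupled
limit — competition propagates a boost to other clones' free antibody at
the ~1e-3 relative level here — so off-target radii are asserted
unchanged to within 1% rather than bitwise.

What the generator does *not* emulate: sequence-level antibodies,
class-switch mechanics, anti-idiotype interactions (antibodies as
epitopes), germinal-center selection, or measured human repertoire
statistics.  Passing tests therefore show the model's internal rules and
numerics on a realistic-scale synthetic system, not agreement with
experimental repertoire data.

## Problem sizes

The test suite and the acceptance script run the default 40×40 fixture,
random systems up to 50×50, and event sequences of ≤ 6 steps; these sizes
keep every property exercised (competition, clustering, extrusion) while
a full run completes in seconds on one core.  The solver itself scales as
a dense matrix–vector product per iteration and handles hundreds of
clones comfortably.

## Known limitations

* Free-antibody regulation and network radii use the cognate epitope
  only; multi-epitope aggregation is not implemented.
* The distance cutoff (3 pK_D) and zone thresholds (0.1/0.9) are
  conventions, not derived quantities; conclusions about connectivity
  should be checked for robustness against them.
* The closed-form pair solver loses precision in the free concentration
  of a species that is ~100% bound (catastrophic cancellation); use the
  system solver when that quantity matters.
* Equilibrium-only: transient dynamics between events are instantaneous
  by construction.
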