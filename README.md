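# gqm — quantitative antibody homeostasis

`gqm` simulates the humoral immune system as a quantitative, network-level
homeostat.  It is aimed at systems immunologists and modelers who want to
reason about antibody function in terms of concentrations and affinities
rather than qualitative specificity: how much antibody, at which
dissociation constant, saturates which antigen, and what interaction
network emerges when a whole repertoire competes for a shared pool of
epitopes.

## The model

The core identity is the equilibrium dissociation constant of a
paratope–epitope interaction,

    K_D = [Ab]·[Ag] / [AbAg]      (all concentrations molar),

with [Ab] the *free paratope* and [Ag] the *free epitope* concentration.
An epitope's fractional saturation is [Ab]/([Ab] + K_D): exactly 0.5 when
[Ab] = K_D.  That diagonal of the [Ab] × K_D landscape is the set point
at which antigen concentration is best *controlled*; far below it antigen
is *released*, far above it antigen is marked for *elimination*.

On top of this sit:

* **A competitive equilibrium solver** — many clones × many epitopes,
  coupled through conservation of each clone's total antibody and each
  epitope's total antigen, solved by damped fixed-point iteration with a
  Newton refinement (absent interactions are K_D = +inf and never enter a
  sum).
* **A synthetic repertoire generator** — clusters of clonally related
  antibodies in a latent shape space, cognate affinities in the
  natural-antibody range K_D = 1e-6..1e-4 M, cross-reactivity decaying
  exponentially with latent distance.
* **The antibody–epitope network** — one node per distinct binding
  profile with radius [Ab]_free/K_D (antigen-binding capacity) and edge
  weights equal to the mean |ΔpK_D| over shared epitopes.  The giant
  connected component is the model's immunological self.
* **Response dynamics** — thymus-independent (TI) events scale a clone's
  antibody output without moving it; thymus-dependent (TD) affinity
  maturation lowers the cognate K_D while shedding polyreactivity, which
  eventually extrudes the node from the giant component; homeostatic
  regulation steers [Ab]_free onto K_D (50% saturation of the cognate
  epitope); long-lived plasma cells are hardwired fix posts.

## Worked example

```python
from gqm import (GeneratorConfig, generate_repertoire, solve_equilibrium,
                 build_network, giant_component, extruded_nodes,
                 cognate_epitope, regulate, simulate, ResponseEvent,
                 fractional_saturation, estimate_b1_count)

rep, mat = generate_repertoire(GeneratorConfig(seed=7))
state = solve_equilibrium(rep, mat)
net = build_network(rep, mat, state)
print(len(rep.clones), mat.n_entries, net.number_of_edges(),
      len(giant_component(net)))
# 40 778 634 40
```

The 40-clone natural repertoire forms 778 interactions and a single
superconnected component of all 40 clones — abundant self, controlled by
shared low-affinity binding.  Regulating one clone drives its free
antibody onto its cognate K_D:

```python
c = rep.clone_ids[0]
kd = mat.kd(c, cognate_epitope(c, mat))          # 4.786e-05 M
rep2, _, st2, res = regulate(rep, mat, c, tolerance=0.01)
print(st2.ab_free_of(c), fractional_saturation(st2.ab_free_of(c), kd))
# 4.821e-05  0.502    -> free antibody ~ K_D, cognate epitope half saturated
```

Six TD maturation steps (ΔpK_D = 1 per step, polyreactivity decay 0.5)
extrude the clone from the self network:

```python
events = [ResponseEvent(kind="TD", clone_id=c, delta_pkd=1.0,
                        polyreactivity_decay=0.5)] * 6
traj = simulate(rep, mat, events)
print([c in extruded_nodes(s.network) for s in traj.snapshots])
# [False, False, False, False, True, True, True]
```

and the published blood arithmetic comes out directly:

```python
estimate_b1_count(4e9, 0.05, 0.05, 5)   # 4e9 WBC/L, 5% B, 5% B1, 5 L
# 50000000.0  -> 5e7 circulating B1 cells
```

## Command line

```sh
gqm generate --seed 7 --out run/       # clones.tsv, epitopes.tsv, affinity.tsv
gqm solve    --clones run/clones.tsv --epitopes run/epitopes.tsv \
             --affinity run/affinity.tsv --out run/
gqm network  --clones run/clones.tsv --epitopes run/epitopes.tsv \
             --affinity run/affinity.tsv --out run/   # GraphML + components
gqm simulate --config events.yaml --out run/sim/
gqm landscape --out run/                # saturation.tsv, zone.tsv
```

All tables are TSV with 17-significant-digit floats and `#` provenance
headers; identical config and seed reproduce byte-identical outputs.

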