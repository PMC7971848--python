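# Methods

## Model

`cgsynapse` simulates the assembly of co-inhibitory immune complexes at
the interface between a T cell and an antigen-presenting cell (APC).
The interface is two parallel flat surfaces 20 nm apart with periodic
boundaries in x and y.  Four protein species live on these surfaces as
rigid bodies of a few coarse-grained groups, 10 nm tall:

| species | surface | groups | binding sites |
|---|---|---|---|
| CTLA-4 (preformed homodimer) | T cell | 4 | two trans sites (one per monomer) |
| B7 | APC | 4 | one trans site + one side site |
| PD-1 | T cell | 3 | one trans site |
| PD-L1 | APC | 3 | one shared site |

Binding sites sit at the 10 nm tip of each molecule, i.e. at the
mid-plane of the gap, so trans partners from opposite surfaces meet
there.  Exactly four reactions are possible: the CTLA-4/B7 and
PD-1/PD-L1 trans-interactions, B7-B7 homodimerization, and the B7/PD-L1
cis-interaction.  Site exclusivity is structural: each site holds at
most one bond, B7's single side site serves the homodimer or the cis
bond, and PD-L1's single site serves PD-1 or B7.  This reproduces the
competition at the heart of the network — cis engagement of PD-L1
removes B7 side sites from dimerization and PD-L1 from PD-1 engagement.

Each 1 ns step runs two scenarios:

1. **Diffusion.**  Mobile units are visited in random order.  A unit is
   a single molecule or a whole trans-only complex; any component that
   contains a same-surface bond (homodimer or cis) is immobile, which is
   the model's stand-in for cytoskeletal trapping of laterally
   oligomerized proteins and the driver of lateral aggregation.  A unit
   receives a Gaussian translation with per-axis variance `2*D_t*dt`
   and a Gaussian rotation about its centroid (s.d. `D_r*dt`, one
   rotational degree of freedom about the membrane normal).  Moves that
   would overlap hard-core groups of another component are rejected;
   the unit stays put for that step.
2. **Reaction.**  Every live bond dissociates independently with its
   per-step probability `p_off = p_on * exp(dG0)` (dG0 in kT, kT = 1;
   more negative = stronger = slower dissociation).  Then all pairs of
   free sites whose classes match a rule and whose 3-D site-site
   distance is within the 0.5 nm cutoff are collected, shuffled, and
   fire with probability `p_on` (default 1), first-come-first-served on
   consumed sites.  Sites freed by a dissociation in the same step are
   refractory until the next step; a still-close pair then re-associates
   at the next association pass — that is geminate recombination.  The
   refractory rule makes a pinned eligible pair an exact two-state
   Markov chain with stationary occupancy `p_on/(p_on + p_off)`, which
   is the closed-form oracle used in the tests.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `dt` | 1 ns | step duration |
| `cutoff` | 0.5 nm | association trigger distance |
| `gap` | 20 nm | intermembrane distance |
| `D_mono_t` | 0.01 nm²/ns (10 µm²/s) | monomer translational diffusion |
| `D_mono_r` | 1°/ns | monomer rotational step scale |
| `D_cplx_t` | 0.005 nm²/ns (5 µm²/s) | trans-complex translational diffusion |
| `D_cplx_r` | 0.28°/ns | trans-complex rotational scale |
| `p_on` | 1 | association probability when the cutoff criterion is met |
| affinities | 0 … −13 kT | per-rule binding free energies |

The macroscopic on-rate corresponding to `p_on = 1` at this cutoff is
of order 10⁹ M⁻¹s⁻¹ (diffusion-limited); `p_on` is a config knob but
plays no role in the canonical scenarios.

## Geometry choices

Only which interfaces exist is fixed by structure; lateral placements of
the coarse-grained groups are the package's own canonical choice:

* CTLA-4 dimer: two body groups (hard-core radius 1 nm) at ±1 nm, two
  trans sites at ±2 nm on opposite faces — so one dimer can bridge two
  different B7 molecules, enabling zipper oligomers.
* B7: two stacked body groups on the axis; trans site and side site
  180° apart at 1 nm.
* PD-1/PD-L1: two stacked body groups; single site at 1 nm.

Binding-site groups carry no hard core (radius 0): they are interaction
centers, and a 1 nm core would make the 0.5 nm association cutoff
unreachable under excluded volume.  With these choices a B7=B7
homodimer flanked by two CTLA-4 receptors is geometrically constructible
as a linear repeat; the construction is verified by a test.  Cluster
packing density (and hence the exact equilibrium bond counts) depends on
these offsets; this is an irreducible modelling freedom.

On binding, the relative pose of the two partners is frozen as-is (no
snap to an idealized geometry): the 0.5 nm cutoff keeps bound geometry
near-ideal and avoids teleporting moves.

**Excluded volume.**  Steric exclusion between hard-core groups of
*different* components is implemented (rejection of violating moves and
of initial placements) but OFF by default.  The choice was made by
comparing both variants of the two-species clustering scenario at full
duration: with inter-molecular exclusion on, association into the dense
zipper phase is sterically arrested (the homodimer count saturates
25-30% low and the system is still far from equilibrium at 10⁷ ns);
without it, the homodimer count and the ~5×10⁶ ns equilibration
timescale of the scenario are reproduced.  The model's clustering
mechanism — immobilization of laterally bonded complexes — does not
require steric caging.  Set ``excluded_volume=True`` to study the
sterically-confined variant; the packing validation and the placement
rejection sampling then apply.

## Numerical implementation

The engine is array-based and JIT-compiled (numba).  Neighbor search
uses a linked-cell grid plus Verlet lists with a 6 nm skin, refreshed
when accumulated drift could let an unlisted pair enter interaction
range; candidate search additionally keeps an *active-cell* mask so
that, with `p_on = 1`, only neighborhoods where something moved or a
site was freed are re-probed (with `p_on = 1` every eligible in-range
pair is resolved the step it appears, so quiet neighborhoods cannot
hold new candidates; the incremental and exhaustive searches produce
bit-identical trajectories, which is asserted by a test).  Gaussian
displacements are consumed from a buffer generated by a seeded PCG64
stream; discrete draws use the kernel RNG seeded per operation.  Bond
lifetimes are sampled geometrically (memoryless, lazily) instead of per
step.  Runs are bit-reproducible from `(config, seed)`.

Components of the bond graph are recomputed by BFS whenever a bond
forms or breaks (the graph has maximum degree 2, so components are
paths or rings of molecules).  Stochastic tie-breaks: candidate pairs
are shuffled per step; a consumed site silently invalidates later
candidates that touch it.

Degenerate inputs: an empty system is valid (the clock just advances);
over-packed systems are rejected either by a coarse area check (>60%
hard-core coverage of a surface) at validation or by bounded rejection
sampling (2000 attempts per molecule) at placement.

## Analysis conventions

* **Equilibrium tail.**  Heat-map cells and scenario summaries report
  the mean of each bond count over the last 20% of the run, matching
  proportionally the last-2×10⁶-ns window of a 10⁷ ns trajectory used
  for the wild-type/mutant comparison.
* **Equilibrium detection.**  Block means (10 samples per block); the
  earliest block after which every bond count's block-to-block relative
  change stays below the tolerance (default 5%).
* **Changepoint.**  Best two-segment piecewise-linear fit; a breakpoint
  is reported when it removes at least half of the single-line SSE.
* **Morphology.**  MONOMER/DIMER by size; LINEAR when the molecule
  bond graph is a simple path and the 2-D gyration-tensor anisotropy
  λ₂/λ₁ < 0.2; PLANAR when size ≥ 6 and λ₂/λ₁ ≥ 0.2; OTHER otherwise.
  Coordinates are unwrapped along bonds first, so labels are invariant
  under rigid motion and periodic re-wrapping (property-tested).
  The thresholds are an operationalization of the visual categories
  "linear oligomer" vs "two-dimensional cluster" and are exposed as
  keyword arguments.
* **Box-whisker summaries** use quartiles and 1.5·IQR whiskers (the
  most extreme samples inside the fences).

## Scenario presets and scaled runs

The presets in `cgsynapse.presets` encode the canonical scenarios (see
`PRESET_NOTES`): the two-species clustering test (`fig2`), affinity and
density sweeps (`fig3_grid`, `fig4_grid`, `s1_*`, `s2_grid`,
`s3_ratio_*`), the weak/strong-cis kinetic comparison (`fig5_*`), the
full four-species network (`fig6_*`), and the wild-type vs cis-knockout
pair (`fig7_wt`/`fig7_mt`).  The knockout disables association for the
cis rule rather than setting its affinity to 0 kT, because the mutant
scenario is defined by the complete absence of cis bonds; the 0 kT
variant remains expressible through the affinities.

Presets default to the full 10⁷ ns duration.  `scale_config` (or the
CLI `--scale` flag) shortens runs proportionally; the acceptance script
and the heavier tests run scaled-down trajectories (2–5×10⁶ ns per run,
3 seeds per scenario; reduced 3×3 grids for sweep properties) and
document the sizes they use in their own headers.  The mutant/wild-type
and sweep *orderings* are robust at these scales; the absolute
equilibrium counts of slowly-coarsening scenarios approach their
long-run values from below, so scaled runs are chosen long enough that
the reported tail means have plateaued.

## What the generator does and does not emulate

All inputs are synthetic by construction — the model *is* the data
generator.  It captures membrane confinement, rotational restriction,
site exclusivity, avidity of the dimeric receptor, excluded volume and
immobilization-driven clustering.  It does not capture membrane
deformation, intramolecular flexibility, size-dependent diffusion of
oligomers, cytoskeletal transport, B7-1/B7-2 differences or CD28
competition.  Quantitative agreement of simulated bond counts with any
particular experimental system is therefore not implied; the meaningful
outputs are the relative effects (competition, coupling, morphology)
under controlled energetics.

## Known limitations

* Equilibrium cluster geometry depends on the canonical lateral site
  offsets (above); absolute bond counts shift by order 10% under
  reasonable alternative choices.
* The immobilization rule is all-or-nothing; real oligomers retain slow
  mobility.
* With `p_on < 1` the incremental candidate bookkeeping is disabled and
  the engine falls back to exhaustive per-step scans (slower, same
  semantics).
* One large simulation step (1 ns) per reaction attempt means on-rates
  are only resolved down to the step timescale.
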