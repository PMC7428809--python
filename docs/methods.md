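# Methods

## The model

`cryptsim` simulates an epithelial tissue as a fixed hexagonal lattice of
crypt slots (axial-coordinate parallelogram, hard edges, no wrap-around;
default 5×5). Each living slot holds a crypt: a well-mixed population of
stem cells with a homeostatic target size `crypt_size` (default 10). An
implicit transient-amplifying compartment (`ta_cells_per_stem`, default
2048) is carried for total-cell reporting only; it contributes no dynamics
and no mutations.

Every stem cell runs three exponential clocks — symmetric division (+1
cell), asymmetric division (no population change, one mutation
opportunity), and loss (−1 cell). Rates are products of three factors:

1. **Genotype.** Each beneficial division mutation multiplies the division
   rate by `fitness_factor` (1.01); each deleterious division mutation by
   its reciprocal. Survival mutations act the same way on the loss rate
   (deleterious raises it by 1.01 per hit, beneficial lowers it). The
   reciprocal 0.990099… is always computed as `1/fitness_factor`, never
   stored, so the pair cannot drift apart.
2. **Within-crypt feedback.** Below target, division is amplified by
   `division_effect_base ** ((crypt_size − n)/crypt_deviation)`; above
   target, loss is amplified by the analogous expression. The feedback
   multiplier *multiplies the base clock* — at the target size it is
   exactly 1, so the baseline is balanced (division 0.05/day vs loss
   0.04878/day). An additive second-clock reading would silently double
   the equilibrium loss rate; we reject it for that reason.
3. **Between-crypt release.** While a crypt borders ≥1 dead slot, its loss
   feedback is suppressed entirely and its division rate gains one factor
   of `dead_neighbor_division_multiplier` (2) per dead neighbor. This is
   what lets a crypt grow to the fission threshold.

`crypt_deviation` defaults to 2.0. The model's provenance is ambiguous
between 2.0 and 0.2 for this constant; we adopt 2.0 (the tabulated value)
and leave it configurable — at 0.2 the feedback is so stiff that the
population pins to the target, which changes quantitative but not
qualitative behavior.

**Mutations.** Each division opportunity (two per symmetric division, one
per daughter; one on the retained cell of an asymmetric division) flips two
independent coins using the cell's current rates: a general mutation
(probability `mutation_rate`, default 5e-4/division) and a TSG hit
(`tsg_mutation_rate`, 5e-7). A general mutation is deleterious with
probability `deleterious_fraction` (split 50/50 between division and
survival effects), otherwise beneficial with split 40/40/20 between
division, survival, and the mutator phenotype. A single mutator mutation
multiplies both of the clone's mutation rates `mutator_factor`-fold
(default 100), each capped (`mutation_rate_max` 5e-2,
`tsg_mutation_rate_max` 5e-5); further mutator mutations are recorded but
do nothing. The first TSG hit is neutral; a cell reaching
`tsg_hits_for_initiation` (2) ends the run as **initiation**, and whether
that cell was a mutator is recorded at that moment.

`deleterious_fraction` has no single canonical value — it is the model's
central swept unknown (0.45–0.95). The default is 0.5, the balanced
starting condition of the baseline experiments.

**Crypt lifecycle.** When a crypt's last cell dies the slot is marked dead
at that time (a lifespan record goes to the turnover log) and every living
neighbor's dead-neighbor count rises. After any event that increases a
crypt's population, fission is checked: at `bifurcation_factor ×
crypt_size` cells (≥, default 2.0) with at least one dead neighboring
slot, a uniformly chosen dead neighbor receives a uniform random half
(`floor(n/2)`, sampled without replacement) of the cells with their full
mutation states — a partition, never a copy. Ties among several dead
neighbors are broken uniformly with the run's generator. When all slots
are dead the run ends as **tissue_death**. Runs otherwise end censored at
`max_days` (29220 d = 80 years). A crypt reaching `uncontrolled_threshold
× crypt_size` cells can optionally end the run as
**uncontrolled_proliferation**; this endpoint is tracked but disabled by
default, since the model's reported outcomes concern TSG inactivation.

## Scheduling algorithm

The engine is an exact discrete-event simulation. Because all clocks are
exponential and rates change only at events, rates are recomputed from the
current state at every step (lazy refresh; memorylessness makes this
statistically exact — no stale clocks).

Waiting-time floors (`division_min_time` 0.05 d on both division kinds,
`loss_min_time` 0 on loss) are applied per sampled waiting time,
`max(sample, floor)`. We exploit two identities to draw one floored
exponential per *kind* instead of three per *cell*:
`min_i max(T_i, F) = max(min_i T_i, F)` for clocks sharing a floor `F`,
and the argmin of competing exponentials is rate-proportional regardless
of the minimum's value. Per event, each kind draws one aggregate floored
exponential; the earliest kind fires; the cell is chosen
rate-proportionally within the kind. This reproduces per-cell floored
clocks exactly. If both division kinds floor to exactly `F`, the kind is
chosen rate-proportionally (the residual approximation within this
already-rare tie is negligible and documented here).

**Thinning of silent asymmetric divisions.** Asymmetric divisions dominate
the event count (ratio 20:1) yet change nothing unless a mutation occurs.
By default the asymmetric kind fires at `rate × P(any mutation at one
opportunity)` and, when it fires, the mutation pattern is drawn from the
conditional distribution; the number of silent asymmetric divisions in
each inter-event interval is Poisson-sampled for the division counters.
This is exact for exponential waiting times; the 0.05-d floor technically
couples successive asymmetric draws of one cell, and thinning ignores that
coupling for silent draws (each silent division would be displaced by at
most the floor, ~5·10⁻⁵ of the event's own waiting-time scale). Disabling
thinning (`thin_asymmetric=False`) schedules every asymmetric division
explicitly at ~30× the event count.

**Implementation.** The hot loop is a numba-JIT kernel operating on
struct-of-arrays state, returning to Python only for rare bookkeeping
(mutation-log drain, crypt extinction/fission registration, buffer refills)
and endpoints. All randomness is consumed from a buffer of uniforms
pre-drawn from the run's seeded numpy generator, so identical
`(params, seed)` give bit-identical results; replicate seeds are derived
from the base seed via `SeedSequence` and are mutually distinct. A pure
Python path built from the public `next_event`/`apply_event` operations
implements the same dynamics for inspection; the test suite checks the two
paths' per-cell rates agree exactly and their population distributions
agree statistically. Per-cell Poisson counts use Knuth's method below mean
64 and a normal approximation above (counts are reporting-only there).

## Statistics

- **Cumulative hazard**: Kaplan–Meier product-limit survival over replicate
  endpoint times (initiation = event, everything else censored), with
  `H(t) = −ln Ŝ(t)`; where `Ŝ` reaches 0 the hazard is reported as `inf`.
  Nelson–Aalen is available as an alternative (`method="nelson-aalen"`).
  Estimation is delegated to lifelines; tests verify it against an
  independent brute-force product-limit computation including tie patterns.
- **Mutator fixation**: fraction of living crypts whose every stem cell is
  a mutator, at the end of the run whatever the endpoint; undefined (NaN,
  excluded from averages) when no crypt is alive.
- **Mutator agreement by distance**: over unordered pairs of living crypts
  at each exact hex distance `d ≥ 1`, the fraction with equal fixation
  status. Exact lattice distance is used rather than Euclidean bands;
  classes without pairs are omitted.
- **Crypt fitness**: mean over a crypt's cells of genotype-intrinsic
  division minus loss rate. Feedback and dead-neighbor factors are
  deliberately excluded so fitness is comparable across architectures
  whose transient feedback states differ; the unmutated value is exactly
  `0.05 − 0.04878 = 0.00122`/day.
- **Turnover and burden**: crypt birth/death counts and lifespans from the
  turnover log; mutation and division events per day; time-weighted mean
  stem cells per crypt (integral of `n_total/n_living_crypts` dt over the
  run).

## What the simulation does and does not emulate

The simulator is its own data generator; no biological data files are
consumed. Default parameters are the baseline condition: a 5×5 lattice of
10-cell crypts for 80 simulated years, balanced division and loss, with
mutation rates set unrealistically high to compensate for simulating a
tissue fragment ~10⁶-fold smaller than a human colon. Consequently all
outputs are qualitative orderings and proportions, not calendar-time
predictions; passing tests show the mechanisms (mutation-load selection
against mutators, metapopulation purging, fission-driven clonal spread),
not human incidence rates.

Test ensembles are scaled for runtime: trend tests use a 3×3 lattice with
the TSG rate raised 10× (5e-6) and 50 replicates per condition. For the
mutator-strength comparison (factor 10 vs 100) the TSG *cap* is raised 10×
alongside, because with the cap fixed both strengths saturate to the same
capped TSG rate and the comparison would be vacuous at this scale; scaling
rate and cap together preserves the baseline's relative rate structure.
Where replicate-count incidence saturates, arms are compared by cumulative
incidence at the reference arm's median initiation time.

## Known limitations

- One-cell crypts are viable here: with fission triggering the moment a
  released neighbor reaches 2 cells, dead slots refill ~10× faster than
  1-cell crypts die, so whole-tissue extinction is vanishingly rare over
  80 years. Earlier reports of unviability at this extreme presumably
  depend on implementation details of crypt regrowth (e.g., a strict
  fission threshold with active loss feedback during regrowth) that the
  stated assumptions do not pin down.
- The mutation model has a single constant effect size; there is no
  distribution of fitness effects and no back mutation.
- Within-crypt space is not modeled (cells are well mixed), and the
  transient-amplifying compartment is implicit.
- The uncontrolled-proliferation threshold is bookkeeping by default; how
  such runs should be treated (censoring versus event) is a modeling
  choice left to the user via `enable_uncontrolled_endpoint`.
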