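# Methods

## The model

`moexsim` simulates six spatially separated, demographically stable
populations of an ape-like species whose individuals can innovate
behaviours from a fixed latent repertoire, and then asks whether the
*method of exclusion* — the standard distributional approach used to
identify animal culture — classifies the resulting behaviour
distributions as cultural.  The point of the design is what the agents
*cannot* do: no specifics of behavioural form are ever transmitted
between individuals.  Social influence enters only as *socially
mediated reinnovation* (triggering): seeing a behaviour expressed
around you raises the chance that you independently reinvent it from
your own latent repertoire.

### World

Six sites at fixed planar positions carry populations of fixed sizes
N = {20, 42, 49, 76, 50, 95}.  The default coordinates reproduce the
relative geography of the six classic long-term ape field sites: two
small western populations far from an eastern cluster of four.  The
geometry is load-bearing (see *Propensity gradients* below), which is
why it ships as a concrete default rather than an arbitrary sketch;
it is fully configurable.

The latent repertoire holds 64 behaviours: 32 social, in four
sub-categories ("play", "display", "groom", "courtship") of eight
interchangeable behaviours each, and 32 food-related, partitioned by
default into 10 sub-categories of sizes [8, 5, 4, 4, 3, 2, 2, 2, 1, 1]
whose nutrients alternate Y, Z, Y, Z, … (five of each).  The main
sources describe the food partition only as "a variable number of
behaviours in each sub-category", so the default is a package choice;
any partition summing to 32 with both nutrients present is accepted.

### Propensity gradients

Each behaviour carries, per site, a genetic propensity `p_g`, and each
food behaviour an ecological availability `p_e` (social behaviours are
never ecologically limited: `p_e = 1`).  With probability `alpha_g`
(resp. `alpha_e`) a behaviour's row varies across sites along a
geographic gradient; otherwise it is one uniform(0, 1) draw shared by
all sites.  A gradient row is built by drawing an anchor point
uniformly from the map region the sites live on, computing Euclidean
distances to each site, min–max rescaling them to [0, 1] and
inverting: the nearest site gets exactly 1 and the farthest exactly 0,
so a gradient-assigned behaviour is strictly impossible at its
farthest site.

The anchor-point region is consequential and deliberately explicit in
the configuration.  Because the gradient assigns its zero to the
*farthest* site, the share of gradients that bar each site depends on
how much map area lies on the far side of the other sites.  The
default region is the continental extent of the map (a rectangle
reaching far east and south of the site cloud, as the continent does),
under which the small western populations are barred most often; a
polygonal region (e.g. a landmass outline) or the sites' plain
bounding box can be configured instead.  Sensitivity runs show this
choice moves the size–culture rank correlation from ≈ 0 (bounding
box) to ≈ 0.5–0.6 (continent-scale regions) while leaving cultural
counts, sweep corners and local-restriction rarity essentially
unchanged — the magnitude (though not the existence) of the
population-size effect in this model is largely a geographic-gating
phenomenon, which is worth keeping in mind when comparing correlation
magnitudes against field analyses.

### Demography

A time step is one month.  Agents face no mortality before month 300
(25 years); from then a constant 1%-per-month hazard applies, and
exceeding month 720 (60 years) is certain death.  Every death is
replaced in place by a newborn with an empty repertoire, so population
sizes never change.  Initial ages are uniform on [0, 300) months and
initial repertoires are empty — runs are long enough (see below) that
the initial condition is forgotten by census time.

### Innovation dynamics

Per step and agent, at most one new behaviour can be acquired.  The
two categories are processed in random order per agent; for each, an
acquisition is attempted with probability drawn from
Normal(1 − state, sigma) clipped to [0, 1], where *state* measures how
well the category's functional needs are met:

* social state = (sub-categories with ≥ 1 expressed behaviour) / 4;
* food state = (F − |F_Y − F_Z|) / C with F fulfilled sub-categories
  of which F_Y provide nutrient Y and F_Z nutrient Z, C the number of
  food sub-categories — total intake penalised by nutrient imbalance.

Needier agents innovate more; a saturated agent (state 1) almost never
does.  `sigma` defaults to 0.05: small noise that preserves the
monotone state–innovation relation while avoiding a hard determinism
at the boundaries.

Which behaviour is attempted depends on `S`, the probability that the
acquisition is socially mediated.  With probability `S` the behaviour
is drawn with weights proportional to *(current expresser count in the
population) + 1*; with probability 1 − S the draw is uniform.  The
unit baseline in the weighted branch is deliberate and load-bearing:
social exposure *catalyses* reinnovation of common behaviours but
never vetoes what an individual could innovate alone, so behaviours
whose expresser count has drifted to zero remain individually
reachable.  (It also makes the weighted draw well-defined in a naive
population, where all counts are zero and the draw is simply uniform.)
Without the baseline, the set of behaviours a population can ever
express at S = 1 is frozen by the first few steps, small populations
keep drastically fewer behaviours, and the census outputs — the
size–culture correlation, the number of locally restricted behaviours
— leave the empirically reported regime entirely.

The chosen behaviour is finally acquired with probability `p_g`
(social) or `p_g · p_e` (food) at the agent's site.  Drawing a
behaviour the agent already owns, or failing the gate, consumes that
category's attempt without effect; the first successful acquisition
ends the agent's turn for the step.  Frequency counts are snapshotted
once per step (synchronous update), so within-step processing order
carries no bias.

Sites never interact: each consumes its own random substream spawned
from the master seed, so any site's trajectory is bit-reproducible and
independent of every other site — a property the tests assert
directly.

### Census (method of exclusion)

After `t_max` = 6000 steps (500 years, enough for the behavioural
distribution to become stationary — checked by comparing censuses at
months 6000 and 7000), each behaviour at each site is classified:
**customary** (expressed by > 50% of at least one non-empty age
class), **habitual** (≥ 2 expressers), **present** (exactly 1),
**ecological explanation** (unexpressed and `p_e = 0`), else
**absent**.  Age classes default to [0, 192), [192, 480), [480, 720]
months (juvenile / prime adult / elder); the cut-points are a package
choice and configurable, and the distribution-level checks are
insensitive to them.  An observational "unknown" level cannot occur:
simulation output is fully observed.

Each behaviour's cross-site profile then receives a pattern, evaluated
in the precedence order A → B → C → D, which a brute-force enumeration
over all 5⁶ level vectors confirms is exhaustive and unambiguous:

* **A** — expressed at every site;
* **B** — reaching habitual frequency nowhere;
* **C** — every absence ecologically explained;
* **D** — habitual or customary somewhere yet absent elsewhere with no
  ecological explanation: the operational definition of a *cultural*
  behaviour under the distributional approach.

Derived statistics: the cultural count (number of pattern-D
behaviours), per-population counts of expressed pattern-D behaviours,
and *locally restricted* behaviours (expressed at exactly one site).

## Experiments

* **Sweep** — the default grid crosses alpha_e ∈ {0.5 … 1.0} (six
  values) with alpha_g ∈ {0, 0.125, 0.25, 0.375, 0.5} (five values) at
  S = 1, 20 replicates per cell: 600 runs.  The exact grid spacing
  within the stated ranges is a package choice.
* **Size–culture correlation** — 100 runs at S = 1, alpha_e = 0.8,
  alpha_g = 0.2; per run and site, the number of expressed pattern-D
  behaviours is paired with the site's population size; the 600 pooled
  pairs are rank-correlated.  Spearman's rho (average ranks for ties,
  asymptotic p-value) is the default; Pearson and a permutation
  p-value are available for sensitivity.
* **S-effect** — replicate runs across values of S at fixed alphas;
  mean cultural counts decrease with S but stay positive even at
  alpha_e = alpha_g = 0.

Every run's seed is derived from the experiment's base seed and grid
position and recorded in the output row, so any row can be regenerated
in isolation.

## Numerical and implementation choices

* Populations are stored columnar (age vector + boolean agent ×
  behaviour matrix) and each step is fully vectorised across agents; a
  full 6000-step, six-site run takes a few seconds on one core.
* Random draws per step have a fixed shape regardless of outcomes, so
  runs are bit-reproducible; uniforms are pre-drawn in blocks of 256
  steps for speed.
* Weighted selection uses an exact inverse-CDF draw on the cumulative
  weights; uniform draws use the same underlying uniforms, so the two
  branches consume identical amounts of randomness.
* Mortality is checked after the age increment, with the hazard
  applying from month 300 inclusive; the longevity cap is enforced as
  certain death, not age freezing.
* Degenerate inputs are rejected early (`ConfigurationError`): alphas
  or S outside [0, 1], food partitions not summing to 32 or missing a
  nutrient, duplicate site coordinates, empty populations.  A
  rank correlation on a constant variable raises
  `UndefinedCorrelationError` rather than returning NaN.

## Problem sizes used in the checks

The bundled test suite runs the distribution-level checks at 20
replicates per condition (the size–culture check at 30 runs, which
suffices to establish the sign of the correlation), and the
`scripts/acceptance.py` reproduction uses 100 runs for the pooled
correlation and 20 per condition elsewhere — the replicate counts the
experiments themselves specify.  Unit tests run on a miniature
two-site, eight-behaviour world where exact bookkeeping can be checked
by hand.

## What the generator does and does not emulate

All inputs are generated internally; there is no field data anywhere
in the pipeline.  The synthetic world reproduces the *structural*
conditions of the classic wild-ape censuses — six sites with realistic
relative geography and published population sizes, a behaviour
repertoire of realistic size and sub-structure, frequency-dependent
but non-copying social influence, genetic and ecological gating with
controllable cross-site variability — and the census machinery applied
to it is the real classification scheme.  It does not emulate:
observation effort (hence no "unknown" category), seasonality or
environmental change (propensities are fixed per run), migration or
any inter-site contact, sex or kin structure, or any transmission of
behavioural form.  Passing checks therefore show what the *method*
concludes when applied to a fully known, copying-free world; they say
nothing about which learning mechanisms real apes use.

## Known limitations

* The food sub-category partition, age-class cut-points, sigma and the
  gradient-point region are defaults chosen once where the sources
  leave them open; headline outputs are robust in direction, but exact
  cultural counts shift with these choices.
* The size–culture correlation is small and partly geometric in
  origin (peripheral sites are gated more often); with only six sites
  per run its per-run estimate is extremely noisy, which is why it is
  only ever computed on pooled pairs.
* At S = 0 the model still innovates (uniformly), so "no social
  influence" means no frequency dependence, not behavioural stasis.
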