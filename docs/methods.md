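# Methods

## The model

`evofoodweb` simulates the assembly of food webs by iterating two
processes on separate time scales: fast bioenergetic population dynamics,
which decide which species are viable in the community the other species
create, and rare stochastic speciation events, which insert new species
as variants of existing ones. Every species `i` carries three heritable
traits: body mass `m_i`, feeding centre `f_i` (the prey mass at which its
attack rate peaks) and feeding range `s_i` (the width of its attack
kernel on the log10 prey-mass axis). All quantities are dimensionless
model units; the single external resource has mass `m_0 = 1`.

### Population dynamics

Biomass densities obey

    dB_0/dt = R (1 - B_0/K) B_0 - sum_j g_j0 B_j
    dB_i/dt = B_i sum_j e_j g_ij - sum_j g_ji B_j - x_i B_i

with a Beddington–DeAngelis functional response

    g_ij = a_ij B_j / (1 + h_i sum_k a_ik B_k + sum_l c_il B_l).

The attack rate is `a_ij = a_0 m_i^{p_a} N_ij(m_j)` with the Gaussian
kernel

    N_ij(m) = exp(-(log10(m/f_i))^2 / (2 s_i^2)) / (s_i sqrt(2 pi)),

normalised over log10 prey mass so that a broad feeding range buys
coverage at the cost of a lower peak attack rate. Interference
competition between consumers is proportional to the overlap of their
kernels,

    I_il = exp(-(log10 f_i - log10 f_l)^2 / (2 (s_i^2+s_l^2)))
           / sqrt(2 pi (s_i^2+s_l^2)),

via `c_il = c_food I_il / I_ii` for `i != l`; normalising by the focal
species' self-overlap `I_ii = 1/(2 s_i sqrt(pi))` makes the matrix
asymmetric — at equal centres `c_il/c_li = s_i/s_l`, so specialists exert
more pressure than generalists. Within-species interference is stronger
(territoriality, mating): the diagonal is `c_ii = c_food + c_intra`.

### Speciation and extinction

Speciation events arrive as a Poisson process with rate `omega = 1e-4`
per unit time, rare enough that the community is normally near a
population-dynamical fixed point between events. A parent is drawn
uniformly among extant consumers (variants: probability proportional to
biomass, or to inverse generation time `~ m^0.25`). The mutant draws
log10 body mass uniformly within a factor 2 of the parent, its feeding
centre 0.5–3 decades below its own mass (prey 3–1000 times smaller), and
its feeding range uniformly on [0.5, 1.5]; it is seeded at the extinction
threshold, `B_j = m_j * epsilon` with `epsilon = 2e-4`, and that biomass
is taken from the parent. Robustness variants (truncated-Gaussian body
mass with cutoff at two standard deviations, globally uniform log mass on
[10^-0.5, 10^6], heredity of `f` and `s` via truncated Gaussians clipped
to the default intervals) are switchable in `EvolutionParams`.

At every integer time, species whose population density `B_i/m_i` has
dropped below `epsilon` are removed (strictly below: a mutant seeded
exactly at the threshold survives its first check). All extinctions
falling between two consecutive speciation events form one extinction
avalanche; in this model cascades are triggered by a single successful
mutant, so this delimitation matches the mechanism. Extinction checks
also run at segment boundaries (speciation and snapshot times); checking
more often than the unit grid cannot rescue or doom a species spuriously
and keeps the avalanche bookkeeping exact.

Each run starts from a single ancestor (`m = 100`, `f = 1`, `s = 1`, so
it takes the resource at its peak attack rate) with `B_1 = m_1 * epsilon
= 2e-2`, and the resource at carrying capacity `B_0 = K = 100`.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `R` | 1 | resource maximum mass-specific growth rate (sets the time unit) |
| `K` | 100 | resource carrying capacity |
| `e_animal`, `e_plant` | 0.85, 0.45 | assimilation efficiency for animal / plant prey; `e_plant` applies only to the resource |
| `a0`, `p_a` | 1, -0.25 | attack-rate prefactor and allometric exponent (see below) |
| `h0`, `q_h` | 0.4, +0.25 | handling time per unit prey biomass |
| `x0`, `q_x` | 0.314, -0.25 | mass-specific respiration |
| `c_food` | 0.8 | interspecific interference scale (protocol grid: 0.6 or 0.8) |
| `c_intra` | 1.4 | extra within-species interference (grid: 1.4 or 1.8) |
| `omega` | 1e-4 | speciation rate per unit time |
| `epsilon` | 2e-4 | extinction threshold on density B/m |

### Allometric scaling: why these exponents

All mass-specific rates scale as `m^-0.25`: respiration
`x_i = 0.314 m^-0.25`, peak attack `a_0 m^-0.25 / (s sqrt(2 pi))`, and
maximum intake `1/h_i = 2.512 m^-0.25` — i.e. maximum consumption is
8 times metabolism, the standard bioenergetic consumer-resource
convention. This mass-invariant parameterisation means a consumer's
dynamics look the same at any absolute mass up to a uniform rescaling of
time, which is what lets the assembly process stack trophic levels
across six orders of magnitude in body mass instead of privileging one
scale. We verified the alternative of making attack rates *increase*
with consumer mass (exponents of +0.45 to +0.75 with the same kernel):
the ancestor then overshoots so violently that its density crosses the
extinction threshold during the initial boom–bust transient, or the
resource is grazed to a standing stock too low to support further
diversification. All constants are configuration-overridable.

## Numerics

* **Integrator.** `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`,
  `atol = 1e-12`. Between speciation events the community sits in a
  stiff quasi-stationary regime where explicit embedded Runge–Kutta
  pairs are forced into steps of a few time units by a micro-oscillation
  around the stable focus; LSODA traverses the same segments in ~1/250
  of the steps with endpoint agreement at the 1e-5 level. `RK45` stays
  available through the `method` argument.
* **Extinction checks.** Each integration segment uses dense output,
  evaluated on the integer-time grid; at the first threshold crossing
  the trajectory is truncated, the species removed, and integration
  restarted. If the right-hand side is quasi-stationary
  (`max |dB/dt| < 1e-12 * max(B)`), the segment is skipped — nothing can
  cross a threshold while the state is numerically constant.
* **Negative excursions.** Biomasses below `-1e-8` abort with a
  diagnostic carrying the state; smaller excursions are clipped to zero
  at segment ends. The dynamics keep exact zeros invariant, so this only
  absorbs rounding noise.
* **Trophic levels.** Flow-based levels solve `(I - D) TL = 1` with diet
  fractions `D` from assimilated flows `e_j g_ij` (handles loops and
  cannibalism; a pure self-feeding diet is singular and reported by node
  id). Short-weighted levels average the shortest-path level with the
  prey-averaged level from the same linear-system form with uniform diet
  weights; nodes with no path to the resource are reported as NaN.
* **Tie-breaks and boundaries.** Mutation intervals are closed; the
  extinction comparison is strict; link-cutoff comparisons use `>=`
  (a single-prey consumer always keeps its link under the average rule).
* **RNG.** One seeded `numpy.random.Generator` drives event times,
  parent choice and trait draws; the seed is recorded in all outputs and
  checkpoints (the generator state round-trips through JSON), so a run
  is a pure function of (config, seed).

## Analysis conventions

Gaussian kernels never vanish, so binary webs require a weak-link
cutoff. The default rule keeps links contributing at least 75% of the
consumer's average assimilated intake `e_j g_ij` (averaged over prey
with positive flow — with Gaussian kernels all flows are positive, so
this only guards numerical underflow). The alternative rule keeps links
whose attack rate is at least 15% of the consumer's *potential* maximum,
read as its kernel peak independent of which prey are present
(`reference="realized_max"` switches to the realized row maximum).

Connectance is `L/S^2` with `S` counting consumers plus the resource
(the resource is a node of the web; with that convention mean generality
= mean vulnerability = `L/S` exactly). Herbivores are consumers whose
prey set is exactly the resource; omnivores feed on prey of at least two
distinct integer-rounded short-weighted levels; loop membership is a
strongly-connected-component test ignoring self-links. Chains are
simple directed paths from a top species to the resource (enumeration
capped at 1e6 paths); maximum similarity is the mean over consumers of
the best Jaccard overlap of role-tagged predator-and-prey sets.
Clustering and characteristic path length are computed on the undirected
projection without self-loops, path length over reachable pairs only.

The avalanche-size power-law exponent comes from least squares of log
density on log size over discrete-aware logarithmic bins: the last bin
edge is clipped to the largest observed size and bin centres are
geometric means of the integer range covered, which keeps the estimator
unbiased (checked by recovering generating exponents 1.5–4 from
synthetic samples). Unbinned per-size regression is available
(`binning="none"`); fewer than two distinct sizes leave the exponent
undefined.

## Fixtures and what desk-scale runs show

`fixtures.four_species_community()` is a four-node toy (two specialist
herbivores of different mass plus a predator whose kernel covers both,
preferring the heavier one) whose trait and biomass constants were
chosen so that the 75%-average cutoff yields exactly the edges
1→0, 2→0, 3→1, 3→2; all analysis operations are hand-checkable on it.
`fixtures.random_community(n, seed)` draws traits from the default
mutation intervals at biomass ten times the threshold.

The reference protocol runs 5e8 time units and samples 80 webs from
t = 1e8 onwards; communities reach roughly 60 species. Tests and the
acceptance script run 4e6–1e7 time units (a thousand speciation events),
which is enough to assemble 20–30 species on 3–4 trophic levels with
body-mass clusters, ongoing turnover and a steep avalanche-size
distribution — the same qualitative regime, smaller and younger. What a
passing desk-scale run does *not* show: the asymptotic network size, the
long-run stationarity of the metric distributions, and a tightly
estimated avalanche exponent (the distribution spans barely one decade
even at full scale). Longer runs are restartable via checkpoints written
every 1e7 time units.

## Known limitations

* One basal resource: every herbivore shares it, which narrows the
  vulnerability distribution relative to webs with many basal species.
* Species are points on the mass axis (no within-species size
  structure), narrowing generality/vulnerability further.
* The avalanche exponent estimate at desk scale rests on a size range of
  about one decade; treat it as a steepness indicator, not a precise
  exponent.
* Checkpoint restarts reproduce the state and RNG stream, but a run
  split into segments takes snapshot times from the same absolute grid —
  changing the grid between restarts changes the sample.
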