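# Methods

## Model structure and assumptions

The deterministic core is a discrete-time (annual) recursion over six
queen classes — diploid genotype (ww, wi, ii) × effective drone mate
class (w, i) — for a univoltine haplodiploid social wasp in a single
well-mixed 1 km² patch. Key biological assumptions:

- Queens mate only in autumn; a queen's matings are summarised by one
  *effective* mate class, the allele of the sperm she uses, drawn from
  the viable-sperm pool with probability j (wild-type) / 1−j (carrier).
- Drones are produced in proportion to queen-class densities (haploid
  males carry a single maternal allele; wi queens contribute each allele
  in equal measure).
- A mating with a carrier drone transfers no viable sperm with
  probability p; a gyne is unfertilised only if *all* of her m matings
  fail, giving f = 1 − (pcD_i/(D_w + cD_i))^m with m a real-valued
  exponent (default 2.5, the observed 2–3 matings per queen).
- Homing acts in the germline of fertilised daughters: a heterozygous
  daughter becomes homozygous for the drive with probability h.
- All gynes — fertilised or not — compete for spring nest sites, folded
  with overwinter survival into the single factor g = s/(1 + sΣG/n).
  Unfertilised or carrier-sterilised nests then fail, which is why f and
  the (1−p) production factor are applied separately from g.

One step therefore runs: gyne production (scaled by the *current*
queens' stored sperm load Z^b) → drone production → mating (f, j, next
Z) → density-dependent establishment (g) → next summer census. Z is the
population-level viable fraction of stored sperm and is initialised to
1 for all-wild-type founding states.

A consequence of this timing worth knowing: the mate classes of
generation t+1 queens are set by generation t's drone pool, so drive
spread carries a one-generation mating lag. For the fitness-neutral
drive (h=1, p=0) the non-carrier queen fraction follows
u(t+1) = u(t)·u(t−1) (Fibonacci-exponent decay), and a release of 100
carrier queens/km² into equilibrium needs 10 generations to exceed 99%
carriers — not the 7 generations a lag-free reduction u(t+1) = u(t)²
would give.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| h | homing (conversion) probability | 0 | — |
| p | carrier-drone sterility (P(no viable sperm per mating)) | 0 | — |
| c | carrier-drone mating competitiveness | 1 | — |
| m | mean matings per gyne (real exponent) | 2.5 | — |
| s | overwinter gyne survival | 0.02 | — |
| n | nest-site competition factor | 1500 | nests km⁻² |
| λ | potential gynes per nest | 560 | — |
| b | sperm-load fecundity exponent | 0 | — |
| release_density | queens added per release event | 100 | queens km⁻² |

With the defaults the wild-type model is a Beverton–Holt-type map
Q' = sλQ/(1 + sλQ/n) with fixed point n(sλ−1)/(sλ) = 1366.07 nests/km².
The field-reported summer density for the parameterised habitat is
1350 km⁻², a ~1.2% gap we attribute to processes outside the printed
equations (e.g. a background mating-failure rate of unknown frequency);
we implement the equations as-is and treat 1350 as correct to within 2%.

The sperm-load exponent b defaults to 0, and 0 is also what the
headline thresholds require: the analytic eradication threshold
d\* = (1 − 1/(sλ))^(1/m) ≈ 0.963 ("at least 96% of queens") follows from
the low-density growth condition sλ(1 − d^m) < 1 with no sperm-load
term, and the dynamic grid scans reproduce the partial-sterility
eradication bound p ≈ 0.8 and spread bound h ≈ 0.94 only with b = 0
(b = 1 moves the eradication bound down to p ≈ 0.64, because the
Z^b fecundity penalty makes suppression much easier). b > 0 remains
fully supported and is exercised by the forced-fraction suppression
curves, where increasing b lowers the carrier proportion needed for a
given impact.

## Threshold analyses

*Critical carrier fraction* (complete drone sterility): the smallest
pinned carrier fraction d at which the low-density growth factor
sλ·(1 − φ^m)·Z^b drops below 1, where φ = cd/((1−d) + cd) is the
competitiveness-weighted carrier share of the drone pool and
Z = (1−d)/((1−d) + cd). Closed form at b = 0, c = 1; otherwise
bracketed root finding (scipy `brentq`, tolerance 1e-6). The derivation
assumes carriers are homozygous, so the forced-fraction dynamics pin
the composition with heterozygous carrier mass folded into the
homozygous classes (mate-class mix preserved); preserving heterozygotes
verbatim would halve their drone-pool contribution and contradict the
threshold the curves are meant to illustrate.

*Dynamic bounds*: `minimal_eradication_sterility` and
`minimal_spreading_homing` scan p (or h) on a 0.01 grid; each cell
releases 100 homozygous carrier queens (class q_ii_w, i.e. already
fertilised by wild-type drones) into the wild-type equilibrium and runs
500 generations. Eradication means total density < 1 nest/km² (the
quasi-extinction proxy — the deterministic model never reaches exactly
zero); spread means the carrier queen fraction exceeds 0.90 at some
point. Released queens enter the summer census directly (they are
introduced queens, not gynes competing for sites) and q_ii_w is the
default release class because, under complete sterility, queens mated
to carrier drones found nests that produce no gynes. The 500-generation
horizon comfortably contains the slow dynamics near the bounds (about
150 generations to eradication at p = 0.8, h = 1).

## Stochastic engine

The integer-state twin replaces each deterministic factor with a
sampling step whose expectation matches it: Poisson per-class gyne
output with mean λZ^b (× (1−p) for carrier-mated queens); multinomial
daughter genotypes including homing; per-gyne mate counts of 2 or 3
with equal probability (mean 2.5); competitiveness-weighted partner
draws, with fertilisation failing only if every mating is sterile;
Bernoulli(j) effective mate class; binomial overwinter survival at g
evaluated at the realised total gyne count. Drone abundances stay
proportional to queen counts (as in the deterministic model) rather
than being sampled. One caveat: with integer mate counts the realised
fertilisation probability is 1 − (q² + q³)/2 for per-mating sterility
odds q, slightly different from the deterministic 1 − q^2.5; the two
coincide whenever q = 0, and the engine's tested claim is only
*expectation agreement* with the deterministic model — exact one-step
agreement at large wild-type populations, 2%-level trajectory agreement
for neutral drives in large populations, plus pure drift (replicate
variance around a frozen deterministic frequency) in small ones.
Replicate r uses `numpy.random.default_rng(base_seed + r)`, making runs
reproducible at the trajectory level.

What the generator does *not* emulate: environmental stochasticity,
spatial structure and dispersal, resistance-allele (NHEJ) evolution,
partial within-queen sperm mixing (the effective-mate-class
approximation), and parameter uncertainty. Passing tests therefore
validate the demographic logic of the model, not field-level forecasts.

## Scenario presets

Named presets encode the standard scenarios: one-off releases of a
plain sterility gene (fig2a: h=0, p=1), a fitness-neutral drive (fig2b:
h=1, p=0), full- and partial-sterility drives (fig2c: p=1; fig2d:
p=0.3, i.e. 70% of carrier matings successful) and their imperfect
homing variants (fig2e–g: h=0.8); forced-fraction suppression curve
families over polyandry (fig3a) and sperm-load exponents (fig3b); the
(h, p) phase scan (fig4a); and ten-yearly management programmes —
95% culls, repeated releases of a complete-sterility construct, and
their combination (fig5a–e). Where a scenario's exact settings are not
published we chose once: fig4b-family runs use p = 0.9 (inside the
eradication-capable band) with h = 0.8; the fig5 homing-rate contrast
uses h = 1 (fig5c), 0.8 (fig5d) and 0.95 (fig5e); repeating schedules
start at generation 0. Within a generation culls are applied before
releases, so queens released "immediately after" a cull survive it.

## Numerical notes and conventions

- Degenerate pools: with no competitive drones f = 0 (a warning is
  logged); with no viable sperm j = 1 and Z = 1 by convention — both
  are then multiplied by zero production. The zero state maps to the
  zero state and is absorbing in both engines.
- The mate-class split is computed multiplicatively as {j, 1−j} on each
  genotype bracket — algebraically identical to the (1−j)/j ratio form
  but defined as j → 0.
- Conservation holds exactly: the six next-generation classes sum to
  f·g·ΣG (asserted to machine precision in the tests).
- Equilibrium iteration stops at a relative change of 1e-12 per step;
  forced-fraction equilibria at 1e-9, or immediately when density falls
  below the quasi-extinction threshold.
- A neutral-drive invariant subtlety: the drive-allele frequency of the
  *queen genotypes alone* can dip transiently after a homozygous
  release when h < 1 (daughters carry one maternal allele; the balance
  sits in the drone pool). The monotone quantity is the frequency over
  the full gene pool — two queen alleles plus the stored sperm allele —
  and that is what the property test asserts.

## Known limitations

Single patch, no immigration; deterministic drone proportionality even
in the stochastic engine; no resistance evolution, so long-horizon
eradication forecasts are optimistic; quasi-extinction below one nest
per km² is a modelling convention, not a biological extinction
criterion; the forced-fraction curves treat population composition as
externally imposed and say nothing about whether a drive can reach that
composition on its own (the dynamic scans answer that).
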