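# vespadrive

Population-dynamic modelling of CRISPR homing gene drives for control of
the invasive common wasp (*Vespula vulgaris*), a haplodiploid social
insect. The package is aimed at pest-management modellers and gene-drive
risk assessors who need numerical abundance predictions — suppression
and eradication outcomes — rather than allele-frequency trajectories
alone.

## The model

Summer queen density (one nest per queen), in a well-mixed 1 km² patch,
is structured by the queen's diploid genotype (*ww*, *wi*, *ii*; *w* =
wild-type allele, *i* = drive allele) and by the effective drone class
she mated with the previous autumn (*w* or *i*), giving six classes
Q<sub>ww_w</sub> … Q<sub>ii_i</sub>. The drive targets spermatogenesis:
a mating with a carrier drone transfers no viable sperm with probability
*p*, and homing converts heterozygous daughters to homozygotes with
probability *h*.

Each annual step computes, from the current census:

- drone pool: D<sub>w</sub> ∝ Q<sub>ww_w</sub> + Q<sub>ww_i</sub> +
  ½(Q<sub>wi_w</sub> + Q<sub>wi_i</sub>), D<sub>i</sub> ∝
  ½(Q<sub>wi_w</sub> + Q<sub>wi_i</sub>) + Q<sub>ii_w</sub> + Q<sub>ii_i</sub>;
- fertilisation of gynes mating *m* times (default *m* = 2.5) in a pool
  where carrier drones compete with weight *c*:
  *f* = 1 − (pcD<sub>i</sub>/(D<sub>w</sub> + cD<sub>i</sub>))<sup>m</sup>;
- wild-type share of viable sperm
  *j* = D<sub>w</sub>/(D<sub>w</sub> + c(1−p)D<sub>i</sub>) and sperm
  load Z = (D<sub>w</sub> + c(1−p)D<sub>i</sub>)/(D<sub>w</sub> + cD<sub>i</sub>);
- gyne production ΣG = λZ<sup>b</sup>(Q<sub>·_w</sub> + (1−p)Q<sub>·_i</sub>)
  with λ = 560 gynes per nest, optionally scaled by the sperm load
  (exponent *b*);
- density-dependent overwinter survival g = s/(1 + sΣG/n) with s = 0.02
  and nest-site competition factor n = 1500 km⁻² — all gynes, fertilised
  or not, compete for sites;
- the six-class update: genotype production brackets (with homing terms
  (1−h), h, (1+h)/2) multiplied by λZ<sup>b</sup>·f·g and split into
  mate classes with weights {j, 1−j}.

An integer-state stochastic twin samples every stage (Poisson gyne
output, multinomial genotypes, per-gyne mating, binomial survival) to
capture demographic stochasticity and gene drift. Intervention
schedules add timed carrier-queen releases and population culls.

## Worked example

Release 100 homozygous carrier queens per km² of a fitness-neutral
drive (*h* = 1, *p* = 0) into the wild-type equilibrium:

```python
from vespadrive import ModelParams, release_into_equilibrium, infiltration_time

params = ModelParams(h=1.0, p=0.0)
traj = release_into_equilibrium(params, generations=15)
print(round(traj.states[0].total, 1))        # 1466.1
print(infiltration_time(traj, 0.99))         # 10
print(round(traj.final.carrier_fraction, 4)) # 1.0
```

The population starts at its equilibrium of 1366.1 nests/km² plus the
100 released queens; the drive needs 10 queen generations (= years) to
exceed 99% carrier queens, and sweeps to fixation without changing
total density (the construct is fitness-neutral).

The same scenarios are available from the shell:

```bash
vespadrive simulate --preset fig2b --generations 15 --out fig2b.csv
vespadrive threshold --dynamic
vespadrive scan --p-min 0 --p-max 1 --p-step 0.05 --out scan.csv
vespadrive preset-list
```

`vespadrive threshold` prints the analytic results: the wild-type
equilibrium (1366.07 nests/km²) and the critical carrier fraction for
eradication under complete drone sterility, d\* = (1 − 1/(sλ))^(1/m) ≈
0.963 — at least 96% of queens must carry the construct. With
`--dynamic` it also scans for the minimal drone sterility at which a
perfect-homing drive eradicates the population (p = 0.80) and the
minimal homing rate at which such a drive still spreads through >90% of
queens (h = 0.94).

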