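# phenodiv — Phenological Hill numbers

`phenodiv` measures how diversely the species of an ecological community
spread a recurring biological activity — flowering, breeding calls,
fruiting, migration — over time. It is aimed at community ecologists with
species-by-time intensity records (counts per survey night, open flowers
per census, ...) who want a single interpretable number, in units of
*effective phenological curves*, summarizing the community's temporal
niche structure, plus its profile across the diversity order q.

## The measure

Each species' discrete record is first turned into a smooth continuous
curve z_i(t) by a continuous wavelet transform (analytic Morlet kernel,
ω₀ = 6) with an attenuation threshold τ controlling how much fine-scale
wiggle survives the reconstruction. Pairs of curves are compared with a
modified Morisita–Horn overlap distance

    O_ij = 1 − 2∫z_i z_j dt / (∫z_i² dt + ∫z_j² dt)   ∈ [0, 1],

which is 0 for pointwise-identical curves and 1 for temporally disjoint
ones. With relative intensities p_i = ∫z_i / Σ_j ∫z_j and the Rao-type
standardizing factor Q = Σ_i Σ_j O_ij p_i p_j, the phenological Hill
number of order q ≥ 0 is

    qPD = [ Σ_i Σ_j (O_ij / Q) (p_i p_j)^q ] ^ (1 / (2(1−q))),

with the usual Shannon-limit form at q = 1:

    ¹PD = exp( −½ Σ_i Σ_j (O_ij / Q) p_i p_j ln(p_i p_j) ).

S equally weighted, pairwise disjoint curves give qPD = S at every
order; a community of identical curves has Q = 0 and is assigned
qPD = 0. Low q weighs rare phenologies richness-style; q = 2 weighs
dominant ones.

## Worked example

Generate the benchmark scenario of 40 staggered activity pulses with a
geometric intensity gradient (ratio 0.9), then run the pipeline. The
simulated curves are already smooth, so smoothing is skipped:

```sh
phenodiv simulate --case b --length 360 -o simB.csv
phenodiv run -i simB.csv --skip-smoothing --q 0 --q 1 --q 2 -d out
```

prints

```
S = 40, Q = 0.945789
^(0)PD = 40.613
^(1)PD = 24.4773
^(2)PD = 18.9629
```

Read: the community holds 40 species (S) whose pulses barely overlap
(Q close to its disjoint ceiling 39/40 = 0.975). Ignoring intensities
(q = 0) it behaves like ~40.6 maximally distinct phenological curves —
slightly above S because Q < 1. As q rises, the intensity gradient
makes rare late-season pulses count for less, and the effective number
of dominant phenologies falls to ~19. The declining profile (written to
`out/profile.csv`, 41 orders over 0 ≤ q ≤ 2) is the signature of
dominance in timing; with equal intensities (case `a`) the profile is
flat at exactly 40.

The same `run` command applied to a real, already wavelet-transformed
species-by-time table (wide CSV: `time,<sp1>,<sp2>,...`) reproduces a
field study's diversity profile; start from raw counts by omitting
`--skip-smoothing`. Library use mirrors the CLI:

```python
import phenodiv as ph

comm = ph.read_community("counts.csv", layout="wide")
smooth = ph.smooth_community(comm, ph.SmoothingConfig(tau=2.0))
d = ph.distance_matrix(smooth)
w = ph.relative_intensities(smooth)
profile = ph.pd_profile(d, w, q_min=0.0, q_max=2.0, steps=41)
```

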