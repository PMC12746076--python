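# raptormech

Comparative biomechanics of prey lifting in raptors — how hawks
(Accipitridae) and owls (Strigidae) differ in the skeletal lever that
dorsiflexes the foot, and in the material behaviour of the tendon that
powers it.

Birds of prey pin, grasp and lift prey by dorsiflexing the foot at the
ankle. The m. tibialis cranialis inserts on a tubercle a short distance
down the tarsometatarsus (the fused lower-leg bone), while the prey
resists at the bone's distal end — a third-class lever. For a prey item of
mass *m*:

    RP = m · g                    resistance of prey (N)
    F  = RP · RA / FA             required muscle force (N)
    MA = FA / RA                  mechanical advantage
    τ  = F · RA                   torque (N·m)

where FA is the inlever (ankle joint to tendon insertion) and RA the
outlever (joint to prey). Owls place the tubercle proportionally farther
down a shorter, stouter bone, so their MA (0.29–0.34 among the focal
species) exceeds that of hawks (0.14–0.22): an owl needs less muscle force
to lift the same prey.

The tendon side of the system is characterised by cyclic tensile tests:
five triangular strain ramps to a target elongation (2–10 % of resting
length) at 50 mm min⁻¹, logged at 50 Hz. The package turns those
load–displacement traces into engineering stress σ = F/A₀ and strain
ε = δ/L₀, fits regional elastic moduli on the J-shaped rising curve (toe,
early-linear and late-linear slopes from the central five points of each
third), integrates the hysteresis loop trapezoidally, and reports
resilience — the fraction of strain energy returned on unloading.

Group comparisons come in two flavours: exact Mann–Whitney U tests on
small specimen samples, and phylogenetically informed tests — Pagel's λ by
maximum likelihood and PGLS ANOVA/MANOVA whose p-values come from
residual-randomization permutation (RRPP) — implemented from first
principles on the Brownian-motion variance–covariance matrix of a tree.

Because raw tensometer traces and the comparative trait set are not
published, the package ships a first-class synthetic-data module: a
closed-form J-curve constitutive model whose modulus, loop areas and
resilience are known exactly (so the whole tensile pipeline is testable
against analytic ground truth), Gaussian specimen populations around the
published species means, and Brownian traits with tunable λ on trees.

## Worked example

```python
from raptormech import lever

table = lever.lever_table(lever.focal_geometries(), lever.focal_scenarios())
print(lever.format_table(table).head(6).to_string(index=False))
```

```
           species            prey  RP_N   RA_m   FA_m   MA  muscle_force_N  torque_Nm
Accipiter striatus Tamias striatus  1.37 0.0514 0.0072 0.14            9.80       0.50
    Astur cooperii Tamias striatus  1.37 0.0669 0.0127 0.19            7.23       0.48
 Buteo jamaicensis Tamias striatus  1.37 0.0823 0.0181 0.22            6.24       0.51
    Megascops asio Tamias striatus  1.37 0.0312 0.0089 0.29            4.81       0.15
         Asio otus Tamias striatus  1.37 0.0411 0.0119 0.29            4.74       0.19
  Bubo virginianus Tamias striatus  1.37 0.0626 0.0213 0.34            4.04       0.25
```

Lifting a 140 g chipmunk takes 9.8 N of muscle force in the sharp-shinned
hawk (MA 0.14) but only 4.0 N in the great horned owl (MA 0.34); the
corresponding ankle torques are 0.50 and 0.25 N·m.

Processing a synthetic tensometer trace recovers the generator's material
properties:

```python
from raptormech import synthetic, tensile

params = synthetic.TendonModelParams(resilience=0.75, pretension=0.5, seed=1)
result = tensile.process_trace(synthetic.generate_tendon_trace(params))
print(round(result.zero_offset, 3), round(result.resilience, 3))
# 0.495 0.75
```

The zeroing rule recovers the 0.5 N pre-tension and the loop integration
returns the constitutive resilience of 0.75.

A full demonstration run (synthetic specimens, lever table, tensile
processing, phylogenetic tests, manifest) lives behind the CLI:

```bash
raptormech demo --out demo_run --seed 1
```

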