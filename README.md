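# branchkin

Kinetic modeling and single-molecule analysis of **Arp2/3-complex branching
nucleation** and its coordinate regulation by two classes of nucleation
promoting factors (NPFs): dimeric N-WASP VCA (type I, here the artificially
dimerized GST-VCA) and cortactin (type II).

The scientific question the package addresses is *how cortactin synergizes
with dimeric VCA to accelerate branched actin assembly*. Three candidate
mechanisms are implemented as variants of one mass-action reaction network
and compared against bulk pyrene-actin polymerization data:

- **filament recruitment** — cortactin concentrates Arp2/3 complex on
  filament sides (emulated by adding side-binding sites without barbed
  ends);
- **obligatory displacement** — cortactin binds the nascent branch junction
  and displaces GST-VCA, unlocking the activation step
  (k<sub>dis</sub> ≫ k<sub>nuc</sub>);
- **VCA recycling** — cortactin frees GST-VCA sequestered at mature branch
  junctions.

Alongside the ODE machinery, the package implements the single-molecule
TIRF (smTIRF) pipeline used to measure the cortactin kinetics that feed the
model: spot detection, nearest-neighbor tracking, the four-rule track
filter, dwell-time → off-rate estimation from binned survival curves
(τ = 1/k<sub>off</sub>), a filament binding-site census, and
fraction-bound affinity estimation
(K<sub>D</sub> = [ligand]/f<sub>bound</sub> − [ligand]). Seeded synthetic
generators emulate every input — noisy pyrene trace ensembles, censored
exponential dwell times, and full two-channel TIRF movies with ground
truth — so the whole analysis chain is testable without external data.

**Audience**: quantitative cytoskeleton biochemists and modelers who want a
reproducible, scriptable counterpart to COPASI-style kinetic fitting and
ImageJ/Matlab single-molecule workflows.

## The model

The network comprises up to 29 mass-action reactions over ~26 species
(µM, s): spontaneous nucleation (dimer/trimer intermediates), barbed-end
elongation with a 0.12 µM critical concentration, sequential actin loading
on GST-VCA, Arp2/3 activation via NPF/monomer/filament-side assembly into a
nascent branch junction, and the activation steps

    nascent junction --k_nuc-->  mature junction + new barbed end        (all variants)
    cortactin:nascent --k_dis--> cortactin:junction + free GST-VCA       (displacement)

Parameter estimation is global Levenberg–Marquardt on log-transformed rate
constants, fitting all traces of a reaction set simultaneously; the quality
of fit is a mean-weighted residual sum of squares (per-trace RSS divided by
the squared trace mean, averaged over traces).

## Worked example

```python
from branchkin import (Conditions, build_network, simulate,
                       sequestered_vca_fraction)
from branchkin.traces import PolymerizationTrace, half_time_to_equilibrium

cond = Conditions(actin_monomer=3.0, arp23=0.02,   # µM
                  gst_vca_monomeric=0.1, cortactin=1.0, t_end=2000.0)
res = simulate(build_network("displacement"), cond)
trace = PolymerizationTrace(res.time, res.polymerized_actin, total_actin=3.0)
print(round(half_time_to_equilibrium(trace), 1))   # 74.0  (s)
print(round(res.polymerized_actin[-1], 3))         # 2.878 (µM)

rec = simulate(build_network("recycling"),
               Conditions(actin_monomer=3.0, arp23=0.02,
                          gst_vca_monomeric=0.1, t_end=2000.0))
print(round(sequestered_vca_fraction(rec), 2))     # 3.16  (%)
```

At saturating (1 µM) cortactin the displacement model reaches half-maximal
polymerization in ~74 s versus ~390 s without cortactin, and ~2.88 of the
3 µM actin is polymerized at equilibrium (0.12 µM remains monomeric, the
barbed-end critical concentration). In the recycling model only ~3% of
GST-VCA ends up sequestered at branch junctions — free GST-VCA never limits
the reaction, which is why recycling cannot produce synergy.

The same run from the shell:

```sh
branchkin simulate --variant displacement --cortactin 1.0 --out out/
branchkin fit --demo --variant branching --out fit/      # recovery demo
branchkin smtrack --synthetic --seed 1 --out sm/         # movie pipeline
branchkin synth --kind traces --variant displacement --out data/
```

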