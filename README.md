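# mitralmech

Mechanics and hemodynamics of mitral-valve chordae tendineae rupture.

Rupture of chordae tendineae — the collagenous cords tethering the mitral
leaflets to the papillary muscles — produces leaflet prolapse and mitral
regurgitation (MR). How severe the regurgitation becomes depends on *which*
chordae fail: an isolated marginal chord on a commissural scallop may be
nearly harmless, while losing every chord on two scallops produces severe MR
and collapses forward output. `mitralmech` provides a desk-scale, fully
deterministic toolchain for studying this question:

- **`constitutive`** — anisotropic hyperelastic leaflet material (modified
  Holzapfel–Gasser–Ogden form with two fiber families) with analytic stress,
  plus a one-dimensional Ogden law for chordal tissue. Stresses are verified
  against finite-difference energy gradients.
- **`chordae`** — an idealized three-dimensional chordal network (17
  papillary-muscle origins, five chord groups, branched insertions into six
  leaflet scallops), seven named rupture scenarios, and a tension-only
  nonlinear truss solver with Newton iteration. Reports per-chord tensions,
  papillary-muscle reaction forces and a per-group force-distribution table.
- **`hemodynamics`** — quantification of transvalvular flow waveforms:
  splitting the mitral regurgitant volume into its closing and leakage
  components, regurgitant fraction, MR grading.
- **`energetics`** — pressure–volume-loop analysis: stroke work, forward
  (useful) stroke work, end-systolic potential energy, pressure–volume area
  and left-ventricular mechanical efficiency.
- **`synthetic`** — seeded generators for physiologic flow/pressure waveforms
  and PV loops with exact, recoverable ground truth.
- **`published`** — a replay table of per-scenario hemodynamic component
  volumes so that all derived quantities (regurgitant volume and fraction,
  grades) are recomputed, never hard-coded.
- **`cli`** — a `mitralmech` command-line interface tying the stages together.

## The models

### Leaflet material

The leaflet strain energy is an exponential isotropic matrix term plus two
dispersed fiber families (directions $m_1, m_2$ at $\pm\theta$ to the
circumferential axis):

$$
W = C_{10}\left[e^{C_{01}(\bar I_1-3)}-1\right]
  + \frac{k_1}{2k_2}\sum_{i=1,2}\left[e^{k_2\langle\kappa\bar I_1+(1-3\kappa)\bar I_{4i}-1\rangle^2}-1\right]
  + \frac{1}{D}(J-1)^2,
$$

with deviatoric invariants $\bar I_1$, $\bar I_{4i}$ of
$\bar C = J^{-2/3}F^\top F$, dispersion $\kappa \in [0, 1/3]$, and a
tension-only switch: a fiber family contributes only when its dispersed
stretch measure $\kappa\bar I_1 + (1-3\kappa)\bar I_{4i} - 1$ is positive.
`stress_mhgo` returns the analytic second Piola–Kirchhoff and Cauchy stresses.

### Chordal tissue and network

Each chord follows an incompressible one-dimensional Ogden law
(`ogden_nominal_stress`); axial force is nominal stress times undeformed
cross-sectional area, and is clamped to zero in compression — chordae are
strings, not struts. The network solver finds the static equilibrium of the
pinned truss under leaflet-side loads via damped Newton iteration with load
stepping, and verifies global force balance: papillary-muscle reactions sum
to the negative of the applied load to machine precision.

Rupture scenarios remove chord sets by scallop and group (isolated marginal
rupture on P1/P2/P3, partial rupture spilling into the adjacent scallop half,
and total rupture of two scallops including basal chords), and
`compare_scenarios` reports how tension redistributes onto survivors.

### Hemodynamic quantification

Given mitral and aortic flow over one systole, the mitral regurgitant volume
is $RV_{MV} = -\int \min(q_{mv},0)\,dt$, split at the reference valve-closure
time $t_{close}$ (the control beat's first upward zero crossing of mitral
flow) into a *closing* volume (physiologic, before closure) and a *leakage*
volume (pathologic, after closure). With forward aortic stroke volume
$SV_{AV}$, the regurgitant fraction is
$RF_{MV} = 100\,RV_{MV}/(SV_{AV}+RV_{MV})$, graded mild (< 30 %), moderate
(30–50 %) or severe (> 50 %).

### Energetics

Stroke work is the signed area of the PV loop; forward stroke work is
$\int \max(q_{av},0)\,p_{ao}\,dt$ over systole; potential energy is
$\tfrac12 p_{es}(v_{es}-v_0)$; the pressure–volume area is $PVA = PE + SW$
and efficiency is $100\,fSW/PVA$. All energies are reported in joules
(1 mmHg·ml = 1.33322 × 10⁻⁴ J).

## Worked example

```python
from mitralmech import chordae, constitutive, energetics, hemodynamics, synthetic

# 1. Synthesize a control-beat flow record and quantify it
rec, truth = synthetic.gen_waveforms_with_truth()
s = hemodynamics.summarize(rec, t_close=truth.t_close)
print(f"closing volume : {s.closing_volume:6.2f} ml")
print(f"leakage volume : {s.leakage_volume:6.2f} ml")
print(f"RV_MV          : {s.rv_mv:6.2f} ml")
print(f"RF_MV          : {s.rf_mv:6.2f} %  ({s.grade})")

# 2. Solve the chordal network after an isolated P2 marginal-chord rupture
net = chordae.build_network(seed=0)
sc = chordae.scenario_segments(net, "isolated_P2")
load = chordae.loads_from_pressure(net, 120.0, scenario=sc)
sol = chordae.solve_static_tensions(net, sc, load, constitutive.EXAMPLE_OGDEN_PARAMS)
print(chordae.pm_force_distribution(net, sol).round(1))

# 3. Ventricular energetics for the same beat
loop = synthetic.gen_pv_loop()
e = energetics.summarize_energetics(loop, rec)
print(f"SW  = {e.sw:.3f} J   fSW = {e.fsw:.3f} J")
print(f"PE  = {e.pe:.3f} J   PVA = {e.pva:.3f} J   efficiency = {e.efficiency:.1f} %")
```

Output:

```
closing volume :   8.64 ml
leakage volume :   0.59 ml
RV_MV          :   9.23 ml
RF_MV          :  13.68 %  (mild)
     AML_marginal  AML_strut  PML_marginal  PML_intermediate  PML_basal
APM          30.8       11.5          19.2              19.2       19.2
PPM          28.6       19.0          19.0               4.8       28.6
SW  = 0.874 J   fSW = 0.854 J
PE  = 0.330 J   PVA = 1.205 J   efficiency = 70.9 %
```

## Command line

```bash
mitralmech generate --out data/ --seed 3          # 8 scenario waveform CSVs + truth
mitralmech analyze-flow --record data/waveforms_isolated_P2.csv \
    --control data/waveforms_control.csv --out flow.json
mitralmech scenario-suite --out suite/ --replay   # full 8-scenario summary table
mitralmech chordae-solve --scenario isolated_P2 --out tensions.csv
mitralmech material-eval --out material/          # stress curves + gradient check
```

`scenario-suite --replay` recomputes the derived hemodynamics of all eight
rupture scenarios from their component volumes:

```
    scenario  rv_av_ml  closing_volume_ml  leakage_volume_ml  sv_av_ml  rv_mv_ml  lvsv_ml  rf_mv_pct    grade aha_category
     control      4.27               8.65               0.62     58.22      9.27    67.49      13.74     mild  progressive
 isolated_P3      4.34               8.54               3.36     55.18     11.90    67.08      17.74     mild  progressive
 isolated_P1      4.63              10.21               4.54     51.55     14.75    66.30      22.25     mild  progressive
partial_P2P1      4.73              11.26               6.47     48.43     17.73    66.16      26.80     mild  progressive
 isolated_P2      4.61              11.86              12.46     41.94     24.32    66.26      36.70 moderate  progressive
partial_P2P3      5.05              13.19              13.33     39.72     26.52    66.24      40.04 moderate  progressive
  total_P2P3      4.62              16.25              31.04     20.46     47.29    67.75      69.80   severe       severe
  total_P2P1      4.72              17.08              34.45     16.16     51.53    67.69      76.13   severe       severe
```

Regurgitant fraction rises monotonically from 13.7 % (control) to 76.1 %
(total rupture of the P2 and P1 chordae); only the two total-rupture
scenarios cross the 50 % severe threshold.

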