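# flexistab

Flexibility-guided consensus design of thermostabilizing point mutations,
plus the quantitative assays used to judge the designs.

## The problem

Industrial enzymes — the motivating case is a fungal lipase — often denature
at process temperatures. A cheap, rational route to stabilization combines
two observations:

1. **Crystallographic B-factors report flexibility.** The temperature factor
   of an atom is proportional to its mean-square displacement, so residues
   whose Cα B-factors stand far above the chain average sit in mobile, often
   destabilizing, loops.
2. **Consensus residues tend to stabilize.** Across a family of homologs
   (e.g. thermophilic relatives), the most frequent residue at an alignment
   position is, on average, the more stable choice.

`flexistab` intersects the two: it z-scores the Cα B-factor profile,

```
B'_i = (B_i − ⟨B⟩) / σ(B),
```

flags contiguous runs of residues with `B' ≥ θ` (default `θ = 1`, run length
≥ 3) as flexible regions, maps them onto columns of a homolog multiple
sequence alignment, and proposes "mutate wild type → consensus" wherever the
plurality consensus differs from the query and passes conservation/gap
filters. For the motivating lipase, the flexible stretch 63-TKWDCK-68
against family consensus 63-TNITCT-68 yields exactly the four classic
candidates **K64N, W65I, D66T, K68T**.

The package also implements the downstream characterization a mutagenesis
campaign needs:

* **Michaelis–Menten kinetics** by Lineweaver–Burk regression (OLS of `1/v`
  on `1/[S]`; `Vmax = 1/intercept`, `Km = slope/intercept`) with a nonlinear
  least-squares cross-check; catalytic efficiency `kcat/Km` and fold changes.
* **Thermal inactivation**: first-order decay fits of residual-activity time
  courses (`t½ = ln 2 / k`), a nearest-to-50 % read-off method for comparing
  with published time courses, and residual-activity gains in percentage
  points.
* **Conformational-ensemble read-outs**: Kabsch superposition, per-residue
  RMSF, and geometric hydrogen-bond occupancy from multi-MODEL PDB
  ensembles.
* **Seeded synthetic generators** for every input kind (structure with a
  planted flexibility bump, alignment with a planted consensus, kinetic and
  decay tables, ensembles with known fluctuations and planted H-bond
  schedules), each with a machine-readable `truth.json` manifest.

The kinetic and decay fits are scikit-learn style estimators
(`MichaelisMentenRegressor`, `FirstOrderDecay`) and compose with sklearn
tooling; everything else is plain functions over small dataclasses.

## Worked example

Generate the planted worked example and run the design pipeline:

```bash
flexistab simulate pdb_profile --seed 11 --out pdbdir
flexistab simulate msa --seed 12 --out msadir
flexistab bnorm pdbdir/structure.pdb
```

```
150 residues, <B> = 26.40 A^2, sigma(B) = 9.89 A^2 (population sd)
flexible region 63-68 (peak B' = 3.11)
```

The chain's B-factors average 26.40 Å²; after z-scoring, residues 63–68 are
the only run of three or more residues with `B' ≥ 1` (they reach `B' ≈ 3.1`,
i.e. three standard deviations above the chain mean).

```bash
flexistab design pdbdir/structure.pdb msadir/alignment.fasta --query-id query
```

```
4 candidate substitution(s), ranked:

label      B_norm  cons_freq    score  flags
W65I        3.105      0.714    0.857
D66T        3.072      0.667    0.833
K68T        3.108      0.600    0.800
K64N        3.090      0.593    0.796
```

Each row is one proposed substitution: `W65I` means "replace W at position
65 with the consensus residue I", supported by the position's flexibility
(`B_norm`) and by the fraction of non-gap homologs carrying the consensus
residue (`cons_freq`, here 71 % of 92 sequences). Positions 63 and 67 emit
nothing because the consensus already equals the wild type there. The score
(equal-weight mix of capped flexibility and conservation) only orders the
list.

Half-lives from a synthetic 60 °C inactivation course (true t½ ≈ 65 min plus
2 % noise):

```bash
flexistab simulate decay --seed 14 --out decdir --param temperature_C=60.0
flexistab halflife decdir/inactivation.csv
flexistab halflife decdir/inactivation.csv --method nearest-timepoint
```

```
enzyme @ 60 C: t1/2 = 67.0 min (first-order-fit), k = 0.01035 /min
enzyme @ 60 C: t1/2 = 60.0 min (nearest-timepoint)
```

The fit method estimates the decay constant from the whole course; the
read-off method returns the sampled time whose residual activity is closest
to 50 % (here the 60 min sample), which is how half-lives are typically
quoted from published time-course figures.

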