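# chromokin

Energy-conversion model of purple-bacterial chromatophore vesicles: a
generalized-Förster excitation-transfer network computing the light-harvesting
quantum yield from pigment geometry, coupled to a steady-state kinetic model of
quinone cycling, cytochrome-bc1-limited turnover, ATP synthesis and overall
energy conversion efficiency, plus a vesicle-composition optimality sweep.

## What it does

- **`chromokin.geometry`** — synthetic vesicle builder. Generates pigment
  coordinates and transition dipoles for LH2 complexes (18-BChl B850 ring with
  alternating α/β sites plus 9 non-network B800 BChls), RC-LH1 core complexes
  (28-BChl B875 ring around a 4-BChl reaction center), placed on a sphere by
  seeded contact-growth packing. Reads/writes a TSV pigment-table dialect and
  PDB-style records (BCL residues with MG/NB/ND atoms). The reference vesicle
  carries 63 LH2, 11 dimeric + 2 monomeric RC-LH1 complexes, 4 cytochrome bc1
  dimers, 2 ATP synthases — 2469 BChls, LH2:RC stoichiometry 2.625.
- **`chromokin.excitons`** — per-cluster effective Hamiltonians (registry site
  energies and nearest-neighbor couplings, point-dipole long-range couplings),
  exciton states with thermal populations, Gaussian spectral overlaps and
  inter-cluster generalized-Förster transfer rates.
- **`chromokin.qyield`** — excitation-migration rate matrix with dissipation
  and charge-separation channels, quantum yield by linear solve, an
  independent stiff time-propagation oracle, and the LH2:RC stoichiometry
  interpolation used in composition sweeps.
- **`chromokin.kinetics`** — photon flux, cytbc1-limited quinone cycling time
  (two-state Poisson interpolation), RC availability, steady-state ATP
  turnover and energy conversion efficiency vs light intensity, and turnover
  capacity reports.
- **`chromokin.sweep`** — ATP production over a grid of (cytbc1, RC-LH1)
  dimer counts at fixed membrane area, with LH2 count compensating footprint
  changes and absorbed flux tracking pigment content.
- **`chromokin.cli`** — `chromokin` command with `build`, `rates`, `qy`,
  `kinetics`, `sweep`, `all` (full pipeline with run manifest) and `fixtures`
  subcommands.

Units: energies in wavenumbers (cm⁻¹), distances in Å, times in s.

## CLI

```sh
# build the reference vesicle and write its pigment table
chromokin build --seed 0 --out pigments.tsv

# transfer rates and quantum yield
chromokin rates --table pigments.tsv --out rates.tsv
chromokin qy --table pigments.tsv --check-oracle

# steady-state kinetics over an intensity grid, and the composition sweep
chromokin kinetics --imin 1 --imax 1000 --points 50 --out kinetics.csv
chromokin sweep --intensity 10 --out sweep.csv

# everything at once, with a machine-readable manifest
chromokin all --seed 0 --outdir run/
```

Configuration is a flat key-value YAML file with dotted namespaces
(`geometry.*`, `exciton.*`, `kinetics.*`, `sweep.*`), passed via `--config`;
every override is validated before any stage runs.

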