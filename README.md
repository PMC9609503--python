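# ramagg

Quantitative analysis of protein aggregation from Raman spectra and
molecular structures, built around hen egg-white lysozyme (HEWL) as the
model system.  HEWL incubated at alkaline pH (12.2) aggregates spontaneously
at room temperature; its Raman spectrum records the transformation — the
Amide I band shifts from α-helix-dominated (~1657 cm⁻¹) to β-sheet-dominated
(~1671 cm⁻¹), the S–S stretching band at 505 cm⁻¹ fades as disulphide bonds
break, and a dozen side-chain and backbone marker bands shift, broaden or
decay.  `ramagg` turns those raw spectra into secondary-structure
percentages, marker time series, and a kinetic classification of the
aggregation pathway, and provides the matching geometric analyses
(RMSD, centre-of-mass distances, Cys–Cys maps, contact detection) for
structures and trajectories of the aggregating dimer.

## The model

Every Raman band is an area-normalised Lorentzian

L(ν̃; ν̃₀, γ, A) = (A/π) · γ / ((ν̃ − ν̃₀)² + γ²)

with FWHM = 2γ and peak height A/(πγ).  After cosmic-ray spike removal,
anchor-point baseline subtraction and normalisation to the
conformation-insensitive phenylalanine band at 1004 cm⁻¹, the Amide I region
(1600–1720 cm⁻¹) is deconvolved into exactly four components — random coil
(1647), α-helix (1657), β-sheet (1671) and β-turn (1688 cm⁻¹) — and the
component areas are read directly as secondary-structure percentages:
pct_c = 100·A_c/ΣA.  Marker trajectories y(t) are fit with the
four-parameter logistic y₀ + (y_max − y₀)/(1 + e^(−k(t−t₅₀))), and the lag
time is the tangent construction t₅₀ − 2/k (floored at 0).  A median lag
beyond the sampling resolution (2 h) marks amyloid-like
nucleation–elongation kinetics; its absence marks amorphous (isodesmic)
aggregation.

Structural quantities follow the field's standard definitions: backbone RMSD
after least-squares (Kabsch) superposition, mass-weighted inter-chain COM
distance, SG–SG Cys pair maps (8 × 8 = 64 combinations for two HEWL
chains), φ/ψ-window secondary-structure content, and geometric non-bonded
contact detection (hydrogen bond ≤ 3.5 Å, salt bridge ≤ 4.0 Å, π–cation
≤ 6.0 Å, π–π ≤ 5.5 Å).

Because no public dataset accompanies the study design, the package ships a
first-class synthetic-data module (`ramagg.synthetic`) that generates
spectra, aggregation time courses and two-chain trajectories with exactly
known ground truth; every analysis stage is validated against it.

## Worked example

```python
import ramagg as rg

# a synthetic aggregation time course at pH 12.2 (isodesmic, no lag phase)
pairs = rg.generate_timecourse("isodesmic", noise_sd=0.005, seed=42)

for i in (0, 6, 11):                             # 0 h, 24 h, 240 h
    spectrum, truth = pairs[i]
    processed = rg.preprocess(spectrum)          # spikes -> baseline -> 1004 norm
    fit, ss = rg.deconvolve_amide1(processed)
    print(f"t={truth.time_h:6.1f} h  alpha={ss.alpha:5.1f}%  "
          f"beta={ss.beta_sheet:5.1f}%   (truth {truth.ss['alpha']:.1f}/"
          f"{truth.ss['beta_sheet']:.1f})")
```

prints

```
t=   0.0 h  alpha= 50.0%  beta= 23.0%   (truth 50.0/23.0)
t=  24.0 h  alpha= 38.5%  beta= 31.5%   (truth 38.6/31.4)
t= 240.0 h  alpha= 20.1%  beta= 45.1%   (truth 20.2/44.8)
```

— the α-helix content falls from ~50 % toward 20 % while β-sheet rises from
~23 % toward 45 %, the signature of the alkaline aggregation transition.
The same run through the full pipeline (`ramagg run --config cfg.yaml`, or
`ramagg.run_pipeline`) additionally produces the marker table, sigmoid fits
and the kinetic classification (`amorphous_like` here: the change starts
immediately, with no lag).

A command-line interface mirrors the stages:

```bash
ramagg simulate --regime isodesmic --seed 42 --outdir runs/sim
ramagg deconvolve runs/sim/synthetic-isodesmic-t240h.txt
ramagg structure --synthetic-dimer --seed 1
ramagg run --config config.yaml --outdir runs/full
```

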