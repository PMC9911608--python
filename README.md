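# fretclem

Computational toolkit for **FRET-CLEM**: correlative fluorescence-lifetime
FRET imaging and platinum-replica electron microscopy of clathrin-coated
structures (CCSs) on unroofed plasma membranes.

Clathrin light chains (CLC) change conformation as a flat clathrin lattice
curves into a coated pit. FLIM-FRET between EGFP- and ShadowY-labelled CLC
reads out inter-fluorophore distances at the ångström scale, while the
paired platinum-replica EM image classifies each diffraction-limited spot
as a flat, domed or sphere lattice. This package implements the whole
computational chain for that experiment — with a synthetic-data generator
standing in for the microscope — for researchers analysing time-correlated
single photon counting (TCSPC) FLIM data, correlating it with EM
segmentations, or modelling FRET geometries in protein lattices.

## The models at the core

**TCSPC decay.** Photon arrival histograms are modelled as a
bi-exponential convolved with a Gaussian instrument response of width τ_G:

    F(t) = F0 [ P1 H(t; t0, τ1, τG) + (1 − P1) H(t; t0, τ2, τG) ]
    H(t; t0, τ, τG) = ½ exp(τG²/2τ² − (t−t0)/τ) · erfc((τG² − τ(t−t0)) / (√2 τ τG))

fitted by Poisson maximum likelihood (multi-start L-BFGS-B on a periodic
extension of F for wrapped late photons). FRET efficiency follows from the
amplitude-weighted lifetime τ_a = P1 τ1 + (1 − P1) τ2 of the donor with
(DA) and without (D) acceptor:

    E = 1 − τ_a,DA / τ_a,D

For structures below the ~10⁴-photon budget a bi-exponential is not
identifiable and the center-of-mass mean lifetime of the histogram is the
per-structure surrogate (no background subtraction).

**Lattice FRET.** A donor on one CLC can transfer to acceptor-bearing CLCs
on the five surrounding heavy chains. Each site carries an acceptor
independently with probability equal to the acceptor occupancy
(ShadowY-CLC bound / all four site states); for a configuration of
occupied sites at distances rᵢ, rates add:

    E = S / (1 + S),   S = Σᵢ (R0 / rᵢ)⁶,   R0 = 60 Å (EGFP–ShadowY)

and the expectation enumerates all 2⁵ configurations exactly.

**Membrane quenching.** Dipicrylamine (DPA) in the membrane quenches a
fluorophore at height z above the plane with E = S/(1+S),
S = π σ R0⁶ / (2 z⁴) (point-to-plane Förster integral, σ the DPA surface
density); lifetime loss on DPA addition ranks constructs by axial height.

**Correlation.** FLIM images (80 nm/pixel) are registered onto EM frames
(1.2 nm/pixel) by a least-squares affine fitted to flat/domed fiducials,
resampled by nearest-neighbour inverse mapping (photon counts stay
integral), and per-structure rectangular-ROI mean lifetimes are compared
with the flat-class mean of the same cell. Cells enter the donor+acceptor
analysis only if their cellular average lifetime is below 2.1 ns (evidence
that the dark acceptor is expressed). EM morphometrics report per-class
mean area, density, and occupied membrane fraction.

## Worked example

`examples/01_decay_fitting.py` simulates one structure's photon budget and
fits it:

```
true tau_a          : 1.880 ns
fitted tau_a        : 1.904 ns  (redchi 1.00)
fitted components   : P1=0.42, tau1=0.87 ns, tau2=2.64 ns
mean (center-of-mass) lifetime: 2.117 ns
FRET efficiency     : 0.268  (true 0.277)
```

At 10⁴ photons the amplitude-weighted lifetime is recovered to ~1% and the
derived FRET efficiency to ~0.01. `examples/04_clem_pipeline.py` runs the
full six-cell synthetic experiment:

```
cells kept by the 2.1 ns acceptor filter: 6/6
mean lifetime shift vs flat: domed +0.077 ns, sphere +0.170 ns
```

The lifetime shift grows from flat through domed to sphere because the
simulated donor–acceptor separation increases as the lattice curves — the
direction the correlative experiment is designed to detect. The other
examples cover the lattice occupancy model (`02_lattice_fret.py`) and DPA
axial ranking (`03_membrane_quenching.py`).

A thin CLI wraps the same library calls:

```sh
fretclem pipeline --seed 20 --out demo_run
fretclem fit-decay histogram.csv
fretclem scan-lattice --occupancy 0.4 --spacing 0.6 --bounds 6
```

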