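"""Fit a single-structure TCSPC decay and estimate its FRET efficiency.

Simulates the photon budget of one clathrin-coated structure (~10,000
photons over 150 frames), fits the IRF-convolved bi-exponential by Poisson
maximum likelihood, and converts the amplitude-weighted lifetime into a
FRET efficiency against the donor-only reference.
"""

from fretclem import (
    DecayParams,
    fit_biexponential,
    fret_efficiency,
    mean_lifetime,
    sample_decay_photons,
)

# a partially quenched donor: 40% fast component at 0.8 ns
truth = DecayParams(F0=1.0, P1=0.4, tau1=0.8, tau2=2.6, tauG=0.15, t0=2.0)
tau_donor_only = 2.6  # ns, unquenched EGFP reference

hist = sample_decay_photons(truth, n_photons=10_000,
                            background_fraction=0.005, seed=42)
fit, diag = fit_biexponential(hist)
summ = mean_lifetime(hist, t_reference=fit.t0)

print(f"true tau_a          : {truth.tau_a:.3f} ns")
print(f"fitted tau_a        : {fit.tau_a:.3f} ns  (redchi {diag.redchi:.2f})")
print(f"fitted components   : P1={fit.P1:.2f}, tau1={fit.tau1:.2f} ns, "
      f"tau2={fit.tau2:.2f} ns")
print(f"mean (center-of-mass) lifetime: {summ.tau_mean:.3f} ns")
print(f"FRET efficiency     : {fret_efficiency(fit.tau_a, tau_donor_only):.3f}"
      f"  (true {fret_efficiency(truth.tau_a, tau_donor_only):.3f})")
# The amplitude-weighted lifetime is the FRET-relevant summary; the
# center-of-mass lifetime is the low-photon surrogate used per structure.
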