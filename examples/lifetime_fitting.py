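"""Membrane-tension readout from a biexponential fluorescence decay.

Two synthetic photon decays mimic a membrane-tension probe on a resting
cell (dominant lifetime 4.7 ns) and on a freshly compressed cell
(+12%, ~5.3 ns).  The fitted dominant component tau1 is the tension
readout; the fast minor component carries only a small share of the
signal.
"""

from mechanoquant import DecayTrace, fit_biexponential
from mechanoquant.synthetic import gen_decay

for label, tau_true, seed in (("resting (Ctrl)", 4.7, 11), ("compressed (T0)", 4.7 * 1.12, 12)):
    t, counts = gen_decay(tau1=tau_true, tau2=1.0, i1=9.0, i2=1.0,
                          n_photons=100_000, seed=seed)
    fit = fit_biexponential(DecayTrace(t, counts))
    print(
        f"{label}: tau1 = {fit.tau1:.2f} ns (true {tau_true:.2f}), "
        f"tau2 = {fit.tau2:.2f} ns, minor-signal share = "
        f"{100 * fit.minor_signal_fraction:.1f}%"
    )
print("A ~12% rise of tau1 after compression reports increased membrane tension.")
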