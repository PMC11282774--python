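"""Classifying intracellular nanoparticle transport from trajectories.

A labeled mixture of Brownian (freely diffusing) and directed
(motor-transported) tracks is sampled at 0.5 s over 20 s, as in live
imaging of delivered beads.  Each track's time-averaged MSD is fitted to
MSD ~ tau^alpha; accepted fits (R^2 > 0.75) with alpha <= 1 count as
diffusive and 1 < alpha < 2 as actively transported.
"""

from mechanoquant import population_fractions
from mechanoquant.synthetic import gen_trajectories
from mechanoquant.transport import TransportClassification, classify_trajectories

trajs, labels = gen_trajectories(n=100, frac_directed=0.4, D=0.05, v=0.5,
                                 D_directed=0.01, seed=1)
table = classify_trajectories(trajs)
fractions = population_fractions([
    TransportClassification(r.label, r.alpha, r.r_squared)
    for r in table.itertuples(index=False)
])

print(table.head(5).to_string(index=False))
print(f"\ntracked: {fractions['n_tracked']}, accepted (R^2 > 0.75): {fractions['n_accepted']}")
print(f"diffusive: {fractions['pct_diffusive']:.0f}%  transported: {fractions['pct_transported']:.0f}%")
print(
    "Planted: 60% Brownian. Directed tracks are detected reliably, but a "
    "pure Brownian track sits exactly on the alpha = 1 decision boundary, "
    "so the diffusive share reads low — see docs/methods.md."
)
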