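"""Score classic ENM variants with r_B and the pairwise error ε_σ.

Evaluates two spring models on one synthetic dataset: the model that
generated the data (a 10 Å homogeneous cutoff network) and the
parameter-free variant whose springs decay as d^-2.  r_B is the Pearson
correlation between predicted and observed per-residue fluctuations; ε_σ
is the mean error on predicted inter-residue distance spreads, normalised
per pair by the decorrelated expectation and clamped at 100%.
"""

import stiffnet as sn
from stiffnet import enm, evaluation as ev

generator = enm.preset("enm10", gamma=3.0)
ensembles, _ = sn.generate_dataset(sn.FixtureSpec(
    n_proteins=6, n_residues=(50, 60), n_models=100, model=generator,
    include_equilibrium_model=True, seed=3))

for name in ("enm10", "pfenm"):
    model = enm.preset(name, gamma=3.0)
    report = ev.evaluate_variant(ensembles, model)
    agg = report.aggregate
    print(f"{name:6s}  r_B = {agg['r_b']:.3f}   eps_sigma = "
          f"{agg['eps_sigma']:.3f}   (short {agg['eps_sigma_short']:.3f}, "
          f"mid {agg['eps_sigma_mid']:.3f})")

print()
print("The generating model scores near-zero eps_sigma and r_B close to 1.")
print("The d^-2 variant predicts per-residue fluctuations decently but")
print("misses pair correlations, which the pairwise measure exposes.")
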