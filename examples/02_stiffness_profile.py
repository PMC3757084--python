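"""Mean-protein-environment stiffness profile from a synthetic dataset.

Generates a small dataset of NMR-like ensembles from a known elastic
network, pools the inter-residue distance variances into (amino-acid pair,
distance-bin) cells, and prints the distance dependence of the apparent
stiffness - the aggregate signature of cooperativity that the potential
derivation consumes.
"""

import stiffnet as sn
from stiffnet import fluctuations as fl
from stiffnet.ensemble_io import superpose_ensemble

ensembles, truth = sn.generate_dataset(sn.FixtureSpec(
    n_proteins=8, n_residues=(50, 60), n_models=25, seed=7))

stats = []
for ens in ensembles:
    sup = superpose_ensemble(ens)
    stats.extend(fl.compute_pair_statistics(sup, d_max=15.0))

binning = fl.DistanceBinning(0.5, 3.0, 15.0)
profile = fl.aggregate_stiffness(stats, binning)
profile = fl.sparse_corrected_stiffness(profile, n0=500)

print("distance bin    pairs (weighted)   k_app (all types)  k_unc-ratio")
for left in profile.all_bins():
    key = (fl.ALL_TYPES, left)
    print(f"{left:4.1f}-{left + 0.5:4.1f} A    {profile.counts[key]:12.0f}"
          f"      {profile.k_app(fl.ALL_TYPES, left):10.3f}")

print()
print("The generating network is a homogeneous 10 A cutoff model, yet the")
print("pooled apparent stiffness decays with distance: short-range pairs")
print("sit in a stiffer shared environment.  This distance profile is the")
print("experimental side of the iterative potential derivation.")
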