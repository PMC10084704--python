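"""Generate a synthetic HTE screen and write it as CSV files.

The generator emulates a Buchwald-Hartwig-style combinatorial screen: a
full cross of 15 aryl halides x 4 ligands x 3 bases x 22 additives, with
per-component DFT-like descriptors, planted main effects, a
substrate-coupled additive shift and bounded noisy yields.
"""

import numpy as np

import metarf as mf

dataset, truth = mf.gen_dataset(mf.SynthConfig(seed=0))
path = mf.write_dataset_csvs(dataset, "scratch/synthetic_hte")

y = dataset.yields
print(f"reactions:      {dataset.n} (full cross, {dataset.feature_dim}-dim encodings)")
print(f"additives:      {len(dataset.group_values())}")
print(f"yield mean/sd:  {y.mean():.1f} / {y.std():.1f} percent")
print(f"clipped at 0/100: {100 * np.mean((y == 0) | (y == 100)):.1f}% of reactions")
print(f"files written under: {path.parent}")

# the planted additive shifts are recoverable from group means, which is
# what a successful few-shot learner must pick up from 5 measurements
grand = y.mean()
obs = [y[dataset.groups == g].mean() - grand for g in truth.group_shifts]
r = np.corrcoef(obs, list(truth.group_shifts.values()))[0, 1]
print(f"corr(group mean - grand mean, planted shift) = {r:.3f}")
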