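"""Encode one protein as the 820-dimensional composition/profile vector.

Builds a small synthetic protein and a matching profile, featurizes it,
and shows how the 20 AAC + 400 DC + 400 PSSM blocks are laid out.
"""

import numpy as np

from ubp_pred import featurize
from ubp_pred.synthetic import SyntheticConfig, generate_proteins, generate_pssm

config = SyntheticConfig(seed=7, n_pos=1, n_neg=0)
record = generate_proteins(config)[0]
pssm = generate_pssm(record, config)

fv = featurize(record, pssm)

print(f"protein {record.id}: {record.length} residues")
print(f"feature vector length: {len(fv.values)}")
print(f"AAC block sum:  {fv.values[:20].sum():.6f}   (residue frequencies)")
print(f"DC block sum:   {fv.values[20:420].sum():.6f}   (dipeptide frequencies)")
print(f"PSSM block sum: {fv.values[420:].sum():.1f}      (raw profile score sums)")
top = np.argsort(fv.values[:20])[::-1][:3]
for i in top:
    print(f"  most frequent residue feature: {fv.names[i]} = {fv.values[i]:.3f}")
# The AAC and DC blocks are probability distributions over residues and
# residue pairs; the PSSM block aggregates evolutionary conservation scores
# by the residue occupying each position.
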