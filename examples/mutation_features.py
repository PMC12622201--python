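"""Commutative-algebra embedding of a toy point mutation.

Generates a wild-type / mutant structure pair (idealized geometry,
differing only at the mutated residue), selects the mutation-site and
16 A neighborhood atoms, and assembles the multiscale embedding:
per structure, 2 complexes x 9 element pairs x 4 statistics x 28 grid
points = 2016 values, concatenated as [WT | MT | WT - MT].
"""

import tempfile
from pathlib import Path

import numpy as np

from srpersist import MutationSpec, featurize_mutation, make_mutation_pair

wt_text, mt_text, manifest = make_mutation_pair(
    seed=42, n_residues=8, site_index=3, wt_aa="D", mt_aa="G")
print("toy sequence:", manifest.expected["sequence_wt"],
      f"(D{manifest.expected['position']}G mutation)")

with tempfile.TemporaryDirectory() as tmp:
    wt_path = Path(tmp) / "wild.pdb"
    mt_path = Path(tmp) / "mutant.pdb"
    wt_path.write_text(wt_text)
    mt_path.write_text(mt_text)
    spec = MutationSpec(wt_path, mt_path, chain="A",
                        position=manifest.expected["position"],
                        wild_aa="D", mutant_aa="G", cutoff=16.0)
    vec = featurize_mutation(spec)

print("embedding length:", len(vec), "=", len(vec.layout.structures), "x",
      vec.layout.block_length)
diff = vec.block("DIFF")
print("nonzero DIFF coordinates:", int(np.count_nonzero(diff)),
      "-- the mutation's structural footprint")
labels = vec.layout.labels()
top = np.argsort(np.abs(vec.values[2 * 2016: 3 * 2016]))[::-1][:5] + 2 * 2016
print("largest WT-MT differences (coordinate: value):")
for i in top:
    print(f"  {labels[i]}: {vec.values[i]:+.0f}")
# labels read structure:complex:site-elem+nbhd-elem:statistic:grid-index;
# losing the aspartate side chain mostly changes oxygen-pair face counts
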