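"""Z-score profile of the real genome against composition-preserving nulls.

The combined randomization (synonymous-codon permutation + consensus-
preserving intron shuffles + UTR rotations) destroys shared motifs while
conserving proteins, codon usage, GC and splicing signals.  The Z profile
measures, in SD units, how far the real mean ARSI sits above that null at
each offset from the ORF start; a peak near offset 0 localizes the
planted regulatory band.
"""

import numpy as np

from arsi import analysis
from arsi.profiles import WindowParams
from arsi.synthetic import SyntheticSpec, synthesize_genome

ds = synthesize_genome(SyntheticSpec(n_genes=80, seed=42))
zs = analysis.zscore_profiles(ds.parts, WindowParams(wl=41, n=4),
                              anchors=("orf_start",),
                              scheme=("codons", "introns", "utrs"),
                              R=20, seed=42)
zp = zs["orf_start"]
masked = np.where(zp.defined, zp.z, -np.inf)
peak = int(zp.offsets[int(np.argmax(masked))])
print(f"null ensemble: R={zp.n_replicates} replicates")
print(f"Z peak at offset {peak:+d} (planted band is +/-50 nt): "
      f"z={np.max(masked):.2f}")
for off in (-120, -50, 0, 50, 120):
    i = np.where(zp.offsets == off)[0][0]
    print(f"  offset {off:+4d}: real {zp.real[i]:.3f}  "
          f"null {zp.null_mean[i]:.3f}+/-{zp.null_sd[i]:.3f}  z={zp.z[i]:+.2f}")
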