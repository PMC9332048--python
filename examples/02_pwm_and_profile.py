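"""Build a dinucleotide PWM for one planted class and inspect its profile.

The 16-row matrix counts ordered base pairs per alignment column; after
standardization against the background and the K_d/R^2 normalization, the
per-column statistic X(j) is ~N(0,1) for background columns, so the planted
conserved core near the annotated start stands out as a sharp peak.
"""

import numpy as np

from ppscan import (
    SynthSpec,
    build_frequency_matrix,
    compute_pwm,
    conservation_profile,
    generate,
    normalize_pwm,
)

result = generate(SynthSpec(chrom_length=150_000, class_sizes=(80, 40),
                            n_background_genes=20, n_decoys_per_class=5, seed=5))
seqs, labels = result.member_sequences()
members = [s for s, l in zip(seqs, labels) if l == 1]

freq = build_frequency_matrix(members)
pwm = normalize_pwm(compute_pwm(freq))
print(f"class 1: {freq.n_seq} members, L1 = {freq.l1}, "
      f"normalization: K_d -> {pwm.normalization['kd_after']:.2e}, "
      f"R^2/L1 -> {pwm.normalization['r2_after'] / pwm.l1:.6f}")

x = conservation_profile(pwm)
peak = int(np.argmax(x)) + 2
print(f"conservation peak X = {x.max():.1f} at column {peak} "
      f"(annotated start is column 501)")
print(f"columns with |X| > 4: {(np.abs(x) > 4).sum()} of {x.size}")
# |X| > 4 columns are non-random dinucleotide usage; the peak sits in the
# planted conserved core just upstream of the start, as in real promoters.
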