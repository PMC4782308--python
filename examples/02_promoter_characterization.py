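"""Promoter sequence analysis around simulated TSS.

Extracts -45..+5 windows around the planted TSS, computes per-position
information content against the genome composition, scans for the sigma-70
-10 element with a null-calibrated PWM threshold, and tabulates the -1/+1
initiation dinucleotide (YR) classes.
"""

import numpy as np

from capseq import (SimConfig, TssRecord, build_pwm, dinucleotide_classes,
                    extract_windows, genome_background, information_content,
                    sample_null_windows, scan_fraction_with_motif,
                    simulate_genome)

genome, genes, truth = simulate_genome(SimConfig(seed=1))
records = [TssRecord("sim", t.position, t.strand, 1, t.strength) for t in truth.tss]

windows = extract_windows(records, genome, upstream=45, downstream=5)
bg = genome_background(genome)
ic = information_content(windows, bg)
offsets = np.arange(len(ic)) - 45
m10 = ic[(offsets >= -12) & (offsets <= -7)].max()
flank = float(np.median(ic[offsets <= -40]))
print(f"information content, -10 region peak: {m10:.2f} bits "
      f"(flank median {flank:.3f} bits)")

rng = np.random.default_rng(0)
sites = ["".join(b if rng.random() > 0.2 else rng.choice(list("ACGT"))
                 for b in "TATAAT") for _ in range(100)]
pwm = build_pwm(sites, bg)
null = sample_null_windows(genome, 500, rng=rng)
frac, null_frac = scan_fraction_with_motif(windows, pwm, null, null_quantile=0.95)
print(f"windows with a -10 motif hit: {frac:.2f} "
      f"(null windows: {null_frac:.2f}, nominal 0.05)")

classes = dinucleotide_classes(records, genome)
print("-1/+1 class fractions:",
      {k: round(v, 3) for k, v in classes.group_fractions.items()})

# High bits at -12..-7 reflect the planted TATAAT box; nearly every promoter
# window scores above the random-genome threshold, while random windows hit
# at the nominal 5% rate. The YR fraction mirrors the planted -1 pyrimidine /
# +1 purine initiation bias.
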