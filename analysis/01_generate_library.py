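#!/usr/bin/env python
"""Build the synthetic barcode library and its T0 sequencing replicates.

Generates a narrow-spread inoculum (99% of barcodes within a six-fold
frequency range), sequences it as four technical T0 replicates, and applies
the master-list filter (>10 RPM in >=2 of 4 replicates). Writes the library,
the T0 count table and the qualified barcode list under results/library/.
"""

from pathlib import Path

import numpy as np

from tumorclones.clonestats import build_master_list, rpm_normalize, shannon_entropy
from tumorclones.synthetic import generate_inoculum, sample_sequencing_counts

SEED = 1
N_BARCODES = 10_000          # scaled-down stand-in for the ~40,000-barcode pool
CELLS_PER_BARCODE = 125      # study mean: 5e6 cells / ~40,000 barcodes
DEPTH = 1_000_000

out = Path("results/library")
out.mkdir(parents=True, exist_ok=True)

library = generate_inoculum(
    N_BARCODES, fold_range=6.0, central_mass=0.99,
    total_cells=CELLS_PER_BARCODE * N_BARCODES, seed=SEED,
)
library.to_tsv(out / "inoculum.tsv")

t0 = sample_sequencing_counts(
    library.frequencies, depth=DEPTH, n_replicates=4, seed=SEED,
    barcode_ids=library.barcode_ids, sample_name="T0",
)
t0.to_tsv(out / "t0_counts.tsv")

master = build_master_list(rpm_normalize(t0), min_rpm=10.0, min_replicates=2)
(out / "master_barcodes.txt").write_text("\n".join(sorted(master)) + "\n")

f = library.frequencies
q_lo, q_hi = np.quantile(f, [0.005, 0.995])
print(f"library: {len(library)} barcodes, {library.total_cells:.3g} cells")
print(f"central-99% frequency spread: {q_hi / q_lo:.2f}-fold (target <= 6)")
print(f"inoculum Shannon entropy: {shannon_entropy(f):.3f} nats "
      f"(uniform bound {np.log(len(library)):.3f})")
print(f"master list: {len(master)} of {len(library)} barcodes qualify "
      f"at depth {DEPTH:g}")
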