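"""Generate a synthetic seven-strategy fed-batch study and summarize it.

Builds the full screen (7 feeding strategies x 3-4 replicates, daily time
courses to day 11, glycoform samples at the exponential and stationary
phases, glycation profiles) with known ground truth.
"""

import numpy as np

from glycofeed import default_config, generate_study

study = generate_study(default_config(seed=1))

print(f"time courses : {len(study.courses)} replicates")
print(f"glycoforms   : {study.glycoforms.abundances.shape[0]} samples "
      f"x {study.glycoforms.abundances.shape[1]} species")
print()
print(f"{'strategy':8s} {'max VCD':>8s} {'final titer':>12s} {'final viab.':>12s}")
for name in ("STD", "STD+", "LoG", "LoG+", "HiF", "HIP", "HIP+"):
    reps = [c for c in study.courses if c.strategy == name]
    max_vcd = np.mean([c.vcd.max() for c in reps])
    titer = np.mean([c.titer[-1] for c in reps])
    viab = np.mean([c.viability[-1] for c in reps])
    print(f"{name:8s} {max_vcd:8.1f} {titer:12.0f} {viab:12.1f}")

print()
print("Max VCD is in 10^6 cells/mL, titer in mg/L, viability in %.")
print("The low-glucose strategies (LoG, LoG+) run out of carbon and collapse")
print("before harvest; the pH-triggered strategies (HIP, HIP+) grow to a")
print("lower, sustainable density — the feeding regimen shapes the process.")
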