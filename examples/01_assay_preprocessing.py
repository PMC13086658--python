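"""Normalize raw dual-luciferase readings and gate by cytotoxicity.

Builds a tiny raw plate table (solvent-control and treated wells), converts
it to fold-induction relative to the solvent control, then truncates the
curve at the highest non-cytotoxic concentration from an MTT profile.
"""

import numpy as np
import pandas as pd

import pparqsar as p

# one biological replicate: 3 SC wells and 2 doses with rising FLuc signal
rows = []
for t, ratio in enumerate((1.0, 1.2, 0.8)):
    rows.append({"group": "SC", "concentration": 0.0, "bio_rep": 1,
                 "tech_rep": t + 1, "FLuc": ratio * 100, "RLuc": 100.0})
for conc, fold in [(10.0, 1.5), (50.0, 3.0), (100.0, 6.0)]:
    for t in range(3):
        rows.append({"group": "treated", "concentration": conc, "bio_rep": 1,
                     "tech_rep": t + 1, "FLuc": fold * 100, "RLuc": 100.0})

drs = p.normalize_reporter(pd.DataFrame(rows), compound_id="demo")
print("fold-induction per concentration (SC wells average to 1.0):")
print(drs.records.groupby("concentration")["response"].mean().round(3))

# MTT: 79% viability at 100 µM violates the 80% rule, so the top dose is cut
profile = p.ViabilityProfile("demo", np.array([10.0, 50.0, 100.0]),
                             np.array([98.0, 95.0, 79.0]))
cutoff = p.highest_noncytotoxic(profile)
print(f"\nhighest non-cytotoxic concentration: {cutoff} µM")

trimmed = p.truncate_to_noncytotoxic(drs, profile)
print(f"dose levels kept after truncation: "
      f"{sorted(trimmed.records['concentration'].unique().tolist())}")
# The 100 µM rows are removed: responses there could reflect toxicity, not
# receptor activation, and would bias the dose-response fit.
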