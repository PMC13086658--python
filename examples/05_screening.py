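"""Batch screening of a SMILES list with applicability-domain flagging.

Trains a small linear model on real descriptors of a homologous PFAS panel
(with a synthetic log-linear response), then screens a mixed list containing
the training congeners, two out-of-range perfluorinated diacids, and one
unparseable SMILES.
"""

import numpy as np

import pparqsar as p
from pparqsar.screen import records_to_frame

panel = (p.make_pfas_like_series("PFCA", [4, 5, 6, 7, 8, 9])
         + p.make_pfas_like_series("PFSA", [4, 5, 6, 7, 8])
         + p.make_pfas_like_series("PFECA", [4, 5, 6]))
matrix, _ = p.featurize(panel)
std = p.standardize(matrix.subset(
    ["autocorr:ATSC5dv", "autocorr:GATS5p", "phys:TPSA"]))
rng = np.random.default_rng(0)
y = np.exp(3.0 + std.values.to_numpy() @ np.array([-0.6, 0.2, 0.3])
           + rng.normal(0, 0.05, len(panel)))
model = p.fit(std, y)
print(f"trained on {len(panel)} congeners, "
      f"h* = {p.critical_leverage(len(model.feature_names), len(panel)):.3f}")

query = panel + [
    ("diacid-C4", "OC(=O)C(F)(F)C(F)(F)C(=O)O"),   # TPSA outside training box
    ("broken", "C(((("),                            # unparseable
]
records, summary = p.screen(query, model)
print(f"\nscreened {summary['n_total']}: {summary['n_in_domain']} in domain, "
      f"{summary['n_out_of_domain']} out, {summary['n_failed']} failed")
print(f"median in-domain predicted BMD: {summary['median_in_domain_bmd']:.1f} µM")

print("\nmost potent in-domain predictions (lowest BMD first):")
print(p.top_k(records, 3)[["id", "predicted_bmd", "leverage", "in_domain"]]
      .round(3).to_string(index=False))

flagged = records_to_frame(records)
print("\nout-of-domain or failed records:")
print(flagged.loc[~flagged["in_domain"].astype(bool),
                  ["id", "predicted_bmd", "failure_reason"]].to_string(index=False))
# Out-of-domain compounds keep their prediction but are excluded from the
# ranking: the model has no training support for them.
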