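"""Compute the four descriptor blocks for a PFAS panel and clean them.

Featurizes a homologous panel covering all five PFAS subgroups, applies the
cleaning cascade (non-finite, low-variance, |r| > 0.9 pruning) and z-scores
the survivors, printing what each step removed.
"""

import pparqsar as p

panel = (p.make_pfas_like_series("PFCA", [3, 4, 5, 6, 7, 8, 9, 10])
         + p.make_pfas_like_series("PFSA", [4, 5, 6, 7, 8])
         + p.make_pfas_like_series("PFECA", [4, 5, 6, 7])
         + p.make_pfas_like_series("PFESA", [4, 5, 6])
         + p.make_pfas_like_series("FTS", [4, 6, 8]))

matrix, failures = p.featurize(panel)
print(f"{len(panel)} compounds featurized, {len(failures)} failures")
blocks = {}
for c in matrix.feature_names:
    blocks[c.split(":")[0]] = blocks.get(c.split(":")[0], 0) + 1
print("raw block widths:", blocks)

cleaned = p.clean(matrix)
reasons = {}
for _, why in cleaned.removal_manifest:
    reasons[why] = reasons.get(why, 0) + 1
print(f"cleaning removed {len(cleaned.removal_manifest)} features {reasons}; "
      f"{len(cleaned.feature_names)} remain")

std = p.standardize(cleaned)
print("state:", std.state, "| binary features keep 0/1, continuous are z-scored")

named = ["autocorr:ATSC5dv", "autocorr:GATS5p", "phys:TPSA"]
present = [c for c in named if c in matrix.feature_names]
print("\nexample descriptor values (raw scale):")
print(matrix.values.loc[["PFCA-C8", "PFSA-C8", "PFECA-C6"], present].round(3))
# ATSC5dv tracks how valence electrons autocorrelate 5 bonds apart (chain
# length sensitive); TPSA separates carboxylic (37.3) from sulfonic (54.4)
# head groups.
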