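"""Monotone-trend gating before dose-response modelling.

A compound only enters BMD estimation when its response shows a statistically
significant ascending relationship with concentration.  The gate is a
one-sided t test on the slope of biological-replicate mean responses regressed
on dose ranks (rank transform makes the test invariant to the concentration
spacing of the design).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .assay import DoseResponseSet

__all__ = ["trend_gate"]


def trend_gate(drs: DoseResponseSet, alpha: float = 0.05) -> bool:
    """True iff an ascending concentration-response trend rejects at alpha.

    Technical replicates are collapsed to biological-replicate means first, so
    pseudo-replication does not inflate the test.
    """
    means = drs.replicate_means()
    doses = np.sort(means["concentration"].unique())
    if doses.size < 3:
        raise ValueError(f"trend test needs >= 3 dose groups, got {doses.size}")
    rank = {c: r for r, c in enumerate(doses)}
    x = means["concentration"].map(rank).to_numpy(dtype=float)
    y = means["response"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    # one-sided: H1 is an ascending trend
    p_one_sided = res.pvalue / 2.0 if res.slope > 0 else 1.0 - res.pvalue / 2.0
    return bool(p_one_sided < alpha)
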