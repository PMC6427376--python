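"""Published point estimates used as inputs to the attribution-share
arithmetic.

These are the reported mean deaths prevented or delayed per year in Sweden
(reference year 2016) by dietary-change scenario and sex, from a published
macro-simulation of adherence to the Nordic nutrient recommendations. They
are external inputs — this package's own runs use its parameter file and
synthetic registry tables instead — and serve to exercise the
share-of-total summary on a real published table.
"""

from __future__ import annotations

from .scenarios import ALL_LABEL

__all__ = ["PUBLISHED_DEATHS_AVERTED", "published_shares"]

#: (scenario label, sex) -> mean deaths prevented or delayed.
PUBLISHED_DEATHS_AVERTED: dict[tuple[str, str], float] = {
    ("Fruits and vegetables", "male"): 1905.0,
    ("Fruits and vegetables", "female"): 1073.0,
    ("Fruits and vegetables", "total"): 3013.0,
    ("Fiber", "male"): 718.0,
    ("Fiber", "female"): 1285.0,
    ("Fiber", "total"): 2025.0,
    ("Fats", "male"): 623.0,
    ("Fats", "female"): 245.0,
    ("Fats", "total"): 969.0,
    ("Salt", "male"): 666.0,
    ("Salt", "female"): 180.0,
    ("Salt", "total"): 1057.0,
    (ALL_LABEL, "male"): 3626.0,
    (ALL_LABEL, "female"): 2553.0,
    (ALL_LABEL, "total"): 6405.0,
}


def published_shares() -> dict[tuple[str, str], int]:
    """Integer share-of-total percentages recomputed from the published
    point estimates (component scenario relative to the combined scenario,
    within sex and overall)."""
    from .simulate import component_shares

    return component_shares(PUBLISHED_DEATHS_AVERTED, combined_label=ALL_LABEL)
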