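"""Deterministic random-stream management.

One user-facing integer seed is expanded into independent substreams, one per
named component, so that e.g. adding an extra draw inside the count simulator
does not perturb the cohort simulator run under the same seed.
"""

from __future__ import annotations

import numpy as np

# stable component keys; never renumber
_COMPONENT_KEYS = {
    "organoid_counts": 1,
    "organoid_noise": 9,
    "cohort": 2,
    "xspecies": 3,
    "fit_draws": 4,
    "ppc": 5,
    "gsea_perm": 6,
    "sampler": 7,
    "summarize": 8,
}


def substream(seed: int, component: str) -> np.random.Generator:
    """Return a Generator for a named component derived from a global seed."""
    try:
        key = _COMPONENT_KEYS[component]
    except KeyError:
        raise KeyError(f"unknown RNG component {component!r}") from None
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
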