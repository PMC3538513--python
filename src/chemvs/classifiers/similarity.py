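"""Tanimoto similarity screening.

A library compound is a virtual hit when its Tanimoto coefficient to at
least one known active exceeds the cut-off (default 0.9, the stricter end of
the customary 0.8-0.9 range).  Both sides must be scaled by the same
reference ScalingModel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..chemspace import tanimoto_matrix

DEFAULT_CUTOFF = 0.9


@dataclass
class SimilarityScreenResult:
    hits: np.ndarray        # bool per library row
    best_sim: np.ndarray    # best similarity per library row
    best_active: np.ndarray  # index of the best-matching active per row


def similarity_screen(
    actives: np.ndarray,
    library: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> SimilarityScreenResult:
    actives = np.atleast_2d(np.asarray(actives, dtype=float))
    library = np.atleast_2d(np.asarray(library, dtype=float))
    if actives.shape[0] == 0:
        raise ValueError("empty active set")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    sim = tanimoto_matrix(library, actives)
    sim = np.nan_to_num(sim, nan=0.0)  # all-zero pairs carry no similarity
    best_active = np.argmax(sim, axis=1)
    best_sim = sim[np.arange(sim.shape[0]), best_active]
    return SimilarityScreenResult(
        hits=best_sim > cutoff,
        best_sim=best_sim,
        best_active=best_active,
    )
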