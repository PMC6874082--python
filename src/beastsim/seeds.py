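"""Deterministic seed derivation.

One master seed reproduces a whole run. Each pipeline stage draws its own
child seed from the master via a ``SeedSequence`` keyed on a fixed stage id
(and an optional index, e.g. the participant's enrolment position), so stages
can be re-run independently and in any order. Child seeds are kept below
2**31 so they fit any consumer that expects a small non-negative integer.
"""

from __future__ import annotations

import numpy as np

STAGE_IDS = {
    "schedule": 1,
    "bank": 2,
    "cohort": 3,
    "sessions": 4,
    "harness": 5,
}


def child_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a reproducible child seed for a pipeline stage.

    Parameters
    ----------
    master : int
        The run's master seed.
    stage : str
        One of ``schedule``, ``bank``, ``cohort``, ``sessions``, ``harness``.
    index : int
        Disambiguates repeated draws within a stage (participant index,
        replicate index, ...).
    """
    if stage not in STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master), STAGE_IDS[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
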