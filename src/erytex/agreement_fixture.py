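"""Deterministic construction of a three-rater grade table with an exact
number of unanimous assessments — the input the published agreement
percentage is recomputed from."""

from __future__ import annotations

import numpy as np
import pandas as pd

from erytex.pipeline import TIMEPOINTS
from erytex.stats import RATERS


def agreement_fixture(n_unanimous: int, n_subjects: int = 20, seed: int = 0) -> pd.DataFrame:
    """Long-format grade table (subject, timepoint, rater, grade) with exactly
    ``n_unanimous`` of the ``n_subjects * 3`` assessments unanimous."""
    total = n_subjects * len(TIMEPOINTS)
    if not 0 <= n_unanimous <= total:
        raise ValueError(f"n_unanimous must lie in [0, {total}]")
    rng = np.random.default_rng(seed)
    unanimous_slots = set(rng.choice(total, size=n_unanimous, replace=False).tolist())
    rows = []
    slot = 0
    for s in range(1, n_subjects + 1):
        for tp in TIMEPOINTS:
            base = int(rng.integers(0, 5))
            if slot in unanimous_slots:
                grades = [base, base, base]
            else:
                # exactly one rater deviates by one grade (clamped away from base)
                deviant = int(rng.integers(0, 3))
                other = base + 1 if base < 4 else base - 1
                grades = [other if k == deviant else base for k in range(3)]
            for rater, grade in zip(RATERS, grades):
                rows.append(
                    {"subject": f"S{s:03d}", "timepoint": tp, "rater": rater, "grade": grade}
                )
            slot += 1
    return pd.DataFrame(rows)
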