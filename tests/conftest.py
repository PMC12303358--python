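import datetime as dt

import numpy as np
import pandas as pd
import pytest

from flarecc.preprocess import DAILY_COLUMNS, EXPOSURES, ParticipantSeries

START = dt.date(2021, 3, 1)


def series_from_pains(pains, impacts=None, pid="P0001", exposures=None):
    """Build a ParticipantSeries from a day-indexed pain list (None = the
    whole day missing).  Exposures default to constant 3 / plausible
    continuous values on observed days."""
    rows = []
    for i, p in enumerate(pains):
        if p is None:
            continue
        row = {"participant_id": pid, "date": START + dt.timedelta(days=i), "pain": float(p)}
        if impacts is None:
            row["impact"] = 3.0
        else:
            row["impact"] = float(impacts[i]) if impacts[i] is not None else np.nan
        for e in EXPOSURES:
            if exposures and e in exposures:
                row[e] = float(exposures[e][i])
            elif e == "sleep_efficiency_pct":
                row[e] = 85.0
            elif e == "sedentary_pct":
                row[e] = 60.0
            elif e == "time_in_bed_h":
                row[e] = 8.0
            else:
                row[e] = 3.0
        rows.append(row)
    df = pd.DataFrame(rows, columns=DAILY_COLUMNS)
    return ParticipantSeries(pid, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """A deterministic 30-participant simulated cohort."""
    from flarecc import SimConfig, generate_cohort

    diary, truth = generate_cohort(SimConfig(n_participants=30, seed=99))
    return diary, truth
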