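"""Detect pain flares in one participant's diary and assess carry-on impact.

The series has a personal pain median of 2; the above-threshold rule finds a
5-day flare whose illness impact stays elevated one extra day after the pain
has returned to the median.
"""

import datetime as dt

import pandas as pd

from flarecc import ParticipantSeries, assess_carry_on, detect_flares
from flarecc.preprocess import DAILY_COLUMNS

pains = [2, 1, 2, 4, 4, 5, 3, 2, 2, 1]
impacts = [2, 1, 2, 4, 4, 4, 3, 3, 2, 1]
start = dt.date(2021, 3, 1)
rows = []
for i, (p, im) in enumerate(zip(pains, impacts)):
    row = {c: None for c in DAILY_COLUMNS}
    row.update(
        participant_id="P0001", date=start + dt.timedelta(days=i), pain=p, impact=im
    )
    rows.append(row)
series = ParticipantSeries("P0001", pd.DataFrame(rows, columns=DAILY_COLUMNS))

print(f"personal pain median: {series.pain_median}")
print(f"personal impact median: {series.impact_median}\n")
for definition in ("aa", "at", "mat"):
    for ep in detect_flares(series, definition):
        assessment = assess_carry_on(ep, series)
        print(
            f"{definition.upper():3s}: onset {ep.onset_date} end {ep.end_date} "
            f"({ep.duration_days} days), carry-on affected: {assessment.affected}"
            + (
                f", impact elevated for {assessment.impact_duration_days} day(s) after the end"
                if assessment.affected and assessment.impact_duration_days
                else ""
            )
        )
print(
    "\nA flare starts on a day meeting the onset rule (above the personal"
    "\nmedian) and ends on the first return to the median or lower; the"
    "\ncarry-on assessment asks whether illness impact outlasts the pain."
)
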