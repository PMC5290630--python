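"""Screening incomplete longitudinal visits by weighted completeness.

A patient's visits rarely measure every clinical indicator (BMI, LVEDD,
SNIP, WISC...).  The screen scores each visit by the summed weights of the
indicators actually measured, discards visits missing an indispensable
indicator, and returns the most informative visits first.
"""

import pandas as pd

from dystrokit import ScreeningConfig, smart_screen

visits = pd.DataFrame(
    {
        "id": [1, 1, 1],
        "visit": [1, 2, 3],
        "Age": [8.5, 9.2, 10.5],
        "BMI": [19.5, None, 13.9],
        "LVEDD": [37.0, 41.0, None],
        "SNIP": [11.3, 51.0, 25.8],
        "WISC": [None, None, 85.0],
    }
)
print("visit table (blank = not measured):")
print(visits.to_string(index=False))

print("\nunit weights, no hard requirements:")
print(smart_screen(visits).to_string(index=False))

cfg = ScreeningConfig(weights={"LVEDD": 2.0}, indispensable={"BMI"})
print("\nLVEDD weighted 2x, BMI indispensable:")
print(smart_screen(visits, cfg).to_string(index=False))

print(
    "\nScore = sum of weight_i x present_i: visit 2 is discarded outright "
    "(no BMI), and the cardiac measurement's double weight promotes visit 1 "
    "over visit 3."
)
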