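"""Score IHC staining observations and classify expression.

H-score = sum over intensities i of i x bin(percent of cells at i), with
percent bins 0-4; samples with H-score >= 6 are called high expression.
"""

import pandas as pd

from tracm7g.ihcscore import score_table

samples = pd.DataFrame(
    {
        "sample": ["case01", "case02", "case03"],
        "pct0": [100, 0, 10],
        "pct1": [0, 40, 20],
        "pct2": [0, 60, 30],
        "pct3": [0, 0, 40],
    }
)
print(score_table(samples).to_string(index=False))
# case01 is fully negative (H = 0, low); case02 scores 2x3 + 1x2 = 8 (high);
# case03 mixes all intensities.
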