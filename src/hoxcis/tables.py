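"""Published reference tabulations used by the worked examples and the
reproduction script.

``LUMBAR_VERTEBRAL_COUNTS`` is the skeletal phenotyping of the deletion
line at postnatal day 22: number of animals per genotype scored with six
lumbar vertebrae (L6), a mixed L6/S1 identity, or five lumbar vertebrae
(L5). ``T3_POLYCOMB_DE`` is the direction split of the differentially
expressed putative Polycomb targets in the posterior trunk sample (T3),
with the corresponding split among expressed non-target genes.
"""

from __future__ import annotations

import pandas as pd

LUMBAR_VERTEBRAL_COUNTS = pd.DataFrame(
    {
        "L6": [1, 1, 1],
        "L6/S1": [2, 1, 1],
        "L5": [8, 9, 8],
    },
    index=pd.Index(["wt", "het", "del"], name="genotype"),
)

#: (up-regulated, down-regulated) differentially expressed genes in T3
T3_POLYCOMB_DE = {
    "targets": {"up": 10, "down": 50},
    "non_targets": {"up": 141, "down": 423},
}
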