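"""Class-label constants.

The positive class is always the long non-coding RNA: training sets treat
lncRNAs as positives and mRNAs as negatives, and every metric downstream
(sensitivity, precision, ...) is computed with that orientation. The
orientation is fixed on purpose and not configurable.
"""

LNCRNA = "lncRNA"
MRNA = "mRNA"

LABELS = (LNCRNA, MRNA)
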