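"""Published reference values from the collaborative SERS trial.

These are the printed results of the original interlaboratory study of
six SERS methods for adenine quantification (raw data deposited at
Zenodo, record 3572358).  They serve as inputs for consistency checks
and for the reproduction script — nothing in this module is computed.

Figures of merit are range-normalized and printed as whole percent;
BIAS is signed.  N is the pooled residual count per method.
"""

from __future__ import annotations

__all__ = [
    "PUBLISHED_FOMS",
    "SELECTION_COUNTS",
    "PUBLISHED_INV_SEP",
    "ZENODO_RECORD",
]

ZENODO_RECORD = "3572358"

#: method -> (N, RMSEP %, SEP %, BIAS %)
PUBLISHED_FOMS: dict[str, tuple[int, float, float, float]] = {
    "cAg@532": (25, 24.0, 21.0, 11.0),
    "cAg@785": (35, 19.0, 19.0, -4.0),
    "cAu@785": (25, 13.0, 13.0, 3.0),
    "sAg@532": (35, 29.0, 27.0, 11.0),
    "sAg@785": (30, 13.0, 12.0, 4.0),
    "sAu@785": (25, 28.0, 29.0, -2.0),
}

#: data-selection workflow counters of the trial
SELECTION_COUNTS = {
    "planned": 48,
    "delivered": 41,
    "integrity_rejected": 2,  # parafilm interference, one lab, two methods
    "calibration_rejected": 4,  # r^2 < 0.6 or F p-value > 0.01
    "accepted": 35,
}

#: methods below the screening threshold, with their published 1/SEP
PUBLISHED_INV_SEP = {"sAg@532": 3.72, "sAu@785": 3.49}
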