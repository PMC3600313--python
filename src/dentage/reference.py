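"""Access to packaged reference data.

The published calibration study prints per-age-group summary rows (n,
mean, sd of DA-CA) per sex and standard; they ship as package data so the
consistency checks and moment-matched simulations can run offline.
"""

from __future__ import annotations

import json
from importlib.resources import files


def load_reference_summaries() -> dict:
    """Printed cohort summary rows (per-sex age-group n/mean/sd tables)."""
    text = files("dentage.data").joinpath("reference_summaries.json").read_text()
    return json.loads(text)
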