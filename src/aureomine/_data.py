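"""Access to packaged data tables (pK scales, hydropathy, backgrounds)."""

from __future__ import annotations

import json
from importlib import resources


def load_table(name: str) -> dict:
    with resources.files("aureomine.data").joinpath(name).open() as fh:
        return json.load(fh)
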