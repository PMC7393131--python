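import numpy as np
import pandas as pd
import pytest

from radiometab.msprep import MetabolitePanel


def make_panel(values, condition="baseline"):
    """Build a long-format panel from {metabolite: {cell_line: [replicates]}}."""
    rows = []
    for met, per_line in values.items():
        for line, reps in per_line.items():
            for i, area in enumerate(reps, start=1):
                rows.append({
                    "metabolite": met,
                    "sample": f"{line}_{condition}_r{i}",
                    "cell_line": line,
                    "condition": condition,
                    "replicate": i,
                    "area": area,
                })
    return MetabolitePanel(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
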