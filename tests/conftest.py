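import numpy as np
import pytest

from wheatimpute import (GenotypePanel, MaskedPanel, MaskState, ScenarioSpec,
                         designate_arrays, simulate_panel)
from wheatimpute.panel import MISSING
from wheatimpute.simulate import PanelParams

# small desk-scale panel that keeps the default marker density
# (2.25 cM spacing), so the calibrated LD level carries over
SMALL = PanelParams(n_lines=120, n_markers=160, n_chrom=2,
                    map_length_cm=360.0, seed=1)


@pytest.fixture(scope="session")
def small_panel():
    panel, gmap = simulate_panel(SMALL)
    return panel, gmap


@pytest.fixture(scope="session")
def small_design(small_panel):
    _, gmap = small_panel
    return designate_arrays(gmap, 1573 / 9926)


def make_masked(panel: GenotypePanel, mask_cells) -> MaskedPanel:
    """Hand-built MaskedPanel masking the given (line, marker) index pairs."""
    mask = np.full(panel.calls.shape, MaskState.OBSERVED, dtype=np.int8)
    mask[panel.calls == MISSING] = MaskState.ORIG_MISSING
    for i, j in mask_cells:
        assert panel.calls[i, j] != MISSING
        mask[i, j] = MaskState.MASKED
    masked = mask == MaskState.MASKED
    truth = np.where(masked, panel.calls, MISSING).astype(np.int8)
    calls = panel.calls.copy()
    calls[masked] = MISSING
    return MaskedPanel(GenotypePanel(panel.line_ids, panel.marker_ids, calls),
                       mask, truth, ScenarioSpec("gbs", missing_rate=0.5))
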