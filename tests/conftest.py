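import numpy as np
import pytest

from panelscope.panel_model import PanelDefinition, TargetRegion, bin_panel, load_bundled_panel
from panelscope import cnv_caller as cnv


@pytest.fixture(scope="session")
def bundled_panel():
    return load_bundled_panel()


@pytest.fixture(scope="session")
def bundled_bins(bundled_panel):
    return bin_panel(bundled_panel)


@pytest.fixture()
def tiny_panel():
    """One 5 kb region, bin length 50 -> 100 bins."""
    return PanelDefinition(regions=[TargetRegion("chr1", 0, 5000, "GENE", "ex1")], bin_length=50)


@pytest.fixture()
def tiny_bins(tiny_panel):
    return bin_panel(tiny_panel)


@pytest.fixture()
def flat_pool(tiny_bins):
    flat = np.full(len(tiny_bins), 500.0)
    members = [cnv.BinDepths(f"ref{i}", flat.copy(), "female") for i in range(3)]
    return cnv.ReferencePool(members=members, bins=tiny_bins)
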