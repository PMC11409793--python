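import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from reslice3d2d import phantom


@pytest.fixture(scope="session")
def validation_ds():
    return phantom.generate_validation_dataset()


@pytest.fixture(scope="session")
def edge_volume():
    return phantom.generate_edge_phantom(seed=0)


@pytest.fixture(scope="session")
def edge_reference(edge_volume):
    return phantom.edge_reference_header(edge_volume)


@pytest.fixture(scope="session")
def validation_tree(tmp_path_factory):
    """Validation dataset written as a DICOM tree on disk."""
    out = tmp_path_factory.mktemp("validation_dicom")
    phantom.generate_validation_dataset(out)
    return out
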