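import numpy as np
import pytest

from grainrisk.io_config import SampleRecord, default_parameters


def make_record(sample_id="s1", crop="rice", lon=106.0, lat=26.5,
                f_mgkg=2.0, cd_mgkg=0.1) -> SampleRecord:
    return SampleRecord(sample_id=sample_id, crop=crop, lon=lon, lat=lat,
                        f_mgkg=f_mgkg, cd_mgkg=cd_mgkg)


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_records():
    """Nine fixed samples, three per crop, with irregular float values."""
    rows = [
        ("r1", "rice", 104.123456, 25.654321, 1.0, 0.05),
        ("r2", "rice", 106.2, 26.3, 2.0, 0.15),
        ("r3", "rice", 108.9, 28.1, 3.0, 0.25),
        ("c1", "corn", 104.4, 25.9, 1.5, 0.0),
        ("c2", "corn", 105.5, 27.7, 2.5, 0.08),
        ("c3", "corn", 107.6, 28.8, 8.125, 0.30000000000000004),
        ("w1", "wheat", 103.9, 24.9, 0.271, 0.012),
        ("w2", "wheat", 106.0, 26.0, 4.0, 0.135),
        ("w3", "wheat", 109.1, 29.0, 9.143, 0.537),
    ]
    return [make_record(*row) for row in rows]
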